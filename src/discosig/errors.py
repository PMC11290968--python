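"""Exception hierarchy shared across the package."""


class DiscosigError(Exception):
    """Base class for all package errors."""


class FormatError(DiscosigError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(DiscosigError):
    """An input violates a documented precondition or invariant."""


class UndefinedStatisticError(DiscosigError):
    """A statistic is mathematically undefined on the given data
    (e.g. a correlation of a zero-variance vector, a log-rank test
    with no events in either group)."""
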