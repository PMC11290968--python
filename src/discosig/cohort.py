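"""Patient expression cohort: genes x patients plus labels and survival."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .matrix import MatrixTable


@dataclass(frozen=True)
class SurvivalRecord:
    """Overall survival for one patient: follow-up time in days and the
    event indicator (1 = death observed, 0 = censored)."""

    os_time: float
    os_event: int

    def __post_init__(self) -> None:
        if self.os_time <= 0:
            raise ValidationError(f"os_time must be > 0, got {self.os_time}")
        if self.os_event not in (0, 1):
            raise ValidationError(f"os_event must be 0 or 1, got {self.os_event}")


@dataclass
class ExpressionCohort:
    """Expression matrix over a labelled tumor cohort.

    ``expr`` holds genes x patients values on the declared ``scale``
    ("log2" for microarray-style log intensities, "linear" for
    nonnegative abundances); every patient carries a molecular subgroup
    label and, optionally, overall survival.
    """

    expr: MatrixTable
    subgroup: dict[str, str]
    survival: dict[str, SurvivalRecord] | None = None
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValidationError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        patients = set(self.expr.col_ids)
        unlabeled = patients - set(self.subgroup)
        if unlabeled:
            raise ValidationError(f"patients without subgroup label: {sorted(unlabeled)[:5]}")
        if self.survival is not None:
            missing = patients - set(self.survival)
            if missing:
                raise ValidationError(
                    f"survival map present but missing patients: {sorted(missing)[:5]}"
                )

    @property
    def patients(self) -> list[str]:
        return list(self.expr.col_ids)

    @property
    def genes(self) -> list[str]:
        return list(self.expr.row_ids)

    def subgroup_levels(self) -> list[str]:
        return sorted({self.subgroup[p] for p in self.patients})

    def patients_in(self, subgroup: str) -> list[str]:
        return [p for p in self.patients if self.subgroup[p] == subgroup]

    def has_survival(self) -> bool:
        return self.survival is not None
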