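"""Subgroup-differentiating disease signatures.

For every gene and molecular subgroup, the signature value is the log2
fold change of the subgroup's central expression against the central
expression of the whole cohort.  Two variants mirror the two summaries
used for tumor-subgroup work: a median-based *disease signature*
(robust, used for drug-signature discordance scoring) and a mean-based
*marker* profile.  On log2-scale cohorts the fold change is a plain
difference of central values; on linear-scale cohorts it is
``log2((c_subgroup + eps) / (c_all + eps))`` with a pseudocount ``eps``
guarding zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import ExpressionCohort
from .errors import ValidationError


@dataclass
class SubgroupSignature:
    """Per-subgroup ``gene -> log2 fold change`` maps sharing one gene set."""

    per_subgroup: dict[str, dict[str, float]]
    method: str  # "median" | "mean"

    @property
    def subgroups(self) -> list[str]:
        return list(self.per_subgroup)

    @property
    def genes(self) -> list[str]:
        first = next(iter(self.per_subgroup.values()))
        return list(first)

    def values_for(self, subgroup: str, genes: list[str]) -> np.ndarray:
        table = self.per_subgroup[subgroup]
        return np.array([table[g] for g in genes])


def _central(values: np.ndarray, method: str) -> np.ndarray:
    return np.median(values, axis=1) if method == "median" else np.mean(values, axis=1)


def _signature(cohort: ExpressionCohort, method: str, eps: float) -> SubgroupSignature:
    levels = cohort.subgroup_levels()
    if len(levels) < 2:
        raise ValidationError(
            f"need at least 2 subgroups to differentiate, got {levels}"
        )
    for s in levels:
        n = len(cohort.patients_in(s))
        if n < 2:
            raise ValidationError(f"subgroup {s!r} has {n} patient(s); need >= 2")
    expr = cohort.expr.values
    if np.isnan(expr).any():
        raise ValidationError("cohort expression contains missing values")
    overall = _central(expr, method)
    col_of = {p: j for j, p in enumerate(cohort.patients)}
    per_subgroup: dict[str, dict[str, float]] = {}
    for s in levels:
        cols = [col_of[p] for p in cohort.patients_in(s)]
        centre = _central(expr[:, cols], method)
        if cohort.scale == "log2":
            log2fc = centre - overall
        else:
            if np.any(centre + eps <= 0) or np.any(overall + eps <= 0):
                raise ValidationError(
                    "linear-scale cohort has nonpositive central expression + eps; "
                    "increase the pseudocount"
                )
            log2fc = np.log2((centre + eps) / (overall + eps))
        per_subgroup[s] = dict(zip(cohort.genes, log2fc.astype(float)))
    return SubgroupSignature(per_subgroup=per_subgroup, method=method)


def subgroup_log2fc(cohort: ExpressionCohort, eps: float = 1.0) -> SubgroupSignature:
    """Median-based disease signature: per gene, log2 fold change of the
    subgroup median against the whole-cohort median."""
    return _signature(cohort, "median", eps)


def subgroup_markers(cohort: ExpressionCohort, eps: float = 1.0) -> SubgroupSignature:
    """Mean-based subgroup markers: identical contract to
    :func:`subgroup_log2fc` with the mean replacing the median."""
    return _signature(cohort, "mean", eps)
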