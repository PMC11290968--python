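"""Quartile survival stratification, the two-group log-rank test, and
hierarchical patient clustering on signature genes.

The survival analysis mirrors the standard outcome-association recipe
for an expression program: average the program's genes per patient,
split the cohort into expression quartiles Q1 (lowest) .. Q4 (highest),
and compare survival of Q4 against Q1 with the Mantel-Cox log-rank
test.  The same machinery works for a single gene (pass a one-gene
list).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .cohort import ExpressionCohort
from .errors import UndefinedStatisticError, ValidationError

logger = logging.getLogger(__name__)

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class SurvivalStratification:
    """Result of a Q4-vs-Q1 gene-set survival comparison."""

    score: dict[str, float]  # patient -> mean gene-set expression
    quartile: dict[str, str]  # patient -> Q1..Q4
    logrank_chi2: float
    logrank_p: float
    n_q1: int
    n_q4: int


@dataclass
class ClusterResult:
    """Agglomerative clustering of patients on a gene panel."""

    linkage_tree: np.ndarray  # scipy linkage matrix, (n-1, 4)
    labels_at_k: dict[int, dict[str, int]]
    distance: str
    linkage: str
    genes_used: list[str]


def geneset_score(cohort: ExpressionCohort, genes: list[str]) -> dict[str, float]:
    """Per-patient unweighted mean expression over the listed genes.

    Genes absent from the cohort are skipped with a logged count; at
    least one must be present.
    """
    idx = cohort.expr.row_index()
    present = [g for g in genes if g in idx]
    if not present:
        raise ValidationError(f"none of the {len(genes)} gene(s) are in the cohort")
    n_missing = len(genes) - len(present)
    if n_missing:
        logger.warning("%d of %d gene-set genes absent from cohort", n_missing, len(genes))
    rows = [idx[g] for g in present]
    means = cohort.expr.values[rows].mean(axis=0)
    return dict(zip(cohort.patients, means.astype(float)))


def quartile_stratify(score: dict[str, float]) -> dict[str, str]:
    """Assign each patient to an expression quartile Q1 (lowest) .. Q4.

    Patients are sorted ascending by score, ties broken by patient id,
    then split into four contiguous rank blocks whose sizes differ by at
    most one.  When ``n`` is not divisible by 4 the extra patients go to
    the *lowest* blocks (``numpy.array_split`` convention), so e.g.
    n = 10 splits as (3, 3, 2, 2).
    """
    if len(score) < 8:
        raise ValidationError(f"need at least 8 patients to form quartiles, got {len(score)}")
    ordered = sorted(score, key=lambda p: (score[p], p))
    blocks = np.array_split(np.asarray(ordered, dtype=object), 4)
    out: dict[str, str] = {}
    for q, block in zip(QUARTILES, blocks):
        for p in block:
            out[p] = q
    return out


def logrank_test(
    group_a: list[tuple[float, int]], group_b: list[tuple[float, int]]
) -> tuple[float, float]:
    """Two-group Mantel-Cox log-rank test.

    Each group is a list of ``(time, event)`` pairs with event 1 for an
    observed death and 0 for censoring.  At every distinct event time
    the observed deaths in group A are compared with their
    expectation under the hypergeometric null given the risk sets; the
    statistic ``(O_A - E_A)^2 / V`` is referred to chi-square with 1 df.
    Tied deaths at one time are counted together.
    """
    for name, grp in (("A", group_a), ("B", group_b)):
        if not grp:
            raise ValidationError(f"group {name} is empty")
        for t, e in grp:
            if t <= 0:
                raise ValidationError(f"group {name}: time must be > 0, got {t}")
            if e not in (0, 1):
                raise ValidationError(f"group {name}: event must be 0 or 1, got {e}")
    times = np.array([t for t, _ in group_a] + [t for t, _ in group_b])
    events = np.array([e for _, e in group_a] + [e for _, e in group_b])
    in_a = np.array([True] * len(group_a) + [False] * len(group_b))
    if events.sum() == 0:
        raise UndefinedStatisticError("no events in either group; log-rank undefined")

    o_minus_e = 0.0
    variance = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((times == t) & (events == 1)).sum())
        d_a = int(((times == t) & (events == 1) & in_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if variance == 0:
        raise UndefinedStatisticError(
            "log-rank variance is zero (all events at times with a one-sided risk set)"
        )
    chi2 = o_minus_e**2 / variance
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def q4_vs_q1_survival(cohort: ExpressionCohort, genes: list[str]) -> SurvivalStratification:
    """Associate a gene set's aggregated expression with survival.

    Composes :func:`geneset_score`, :func:`quartile_stratify` and a
    Q4-vs-Q1 :func:`logrank_test`; Q2/Q3 patients are excluded from the
    test.
    """
    if not cohort.has_survival():
        raise ValidationError("cohort has no survival data")
    score = geneset_score(cohort, genes)
    quartile = quartile_stratify(score)
    surv = cohort.survival
    assert surv is not None

    def group(q: str) -> list[tuple[float, int]]:
        return [
            (surv[p].os_time, surv[p].os_event) for p in quartile if quartile[p] == q
        ]

    g4, g1 = group("Q4"), group("Q1")
    chi2, p = logrank_test(g4, g1)
    return SurvivalStratification(
        score=score,
        quartile=quartile,
        logrank_chi2=chi2,
        logrank_p=p,
        n_q1=len(g1),
        n_q4=len(g4),
    )


def cluster_patients(
    cohort: ExpressionCohort,
    genes: list[str],
    k: int,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> ClusterResult:
    """Hierarchically cluster patients on a gene panel.

    Rows are restricted to the panel and standardized per gene (mean 0,
    sd 1 across patients) before computing patient-patient distances;
    constant genes are dropped with a warning.  Labels for the requested
    ``k`` are cut from the merge tree.
    """
    if k < 1 or k > len(cohort.patients):
        raise ValidationError(f"k={k} out of range for {len(cohort.patients)} patients")
    idx = cohort.expr.row_index()
    present = [g for g in genes if g in idx]
    if len(present) < 2:
        raise ValidationError(f"need at least 2 panel genes in the cohort, got {len(present)}")
    x = cohort.expr.values[[idx[g] for g in present]]
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k_ in zip(present, keep) if not k_]
        logger.warning("dropping %d constant gene(s): %s", len(dropped), dropped[:5])
    present = [g for g, k_ in zip(present, keep) if k_]
    if not present:
        raise ValidationError("all panel genes are constant across patients")
    x = x[keep]
    xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    tree = scipy_linkage(xs.T, method=linkage, metric=distance)
    labels = fcluster(tree, t=k, criterion="maxclust")
    return ClusterResult(
        linkage_tree=tree,
        labels_at_k={k: dict(zip(cohort.patients, (int(v) for v in labels)))},
        distance=distance,
        linkage=linkage,
        genes_used=present,
    )
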