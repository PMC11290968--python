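"""Drug-disease discordance scoring and dependency ranking.

A drug's consensus response signature opposes a tumor subgroup's
expression program when the two are *discordant*: Spearman's rank
correlation between the drug's consensus z values and the subgroup's
log2 fold changes, over the shared genes, is negative.  A negative rho
is the response prediction itself; a permutation p-value (gene-label
shuffles) is reported alongside but does not gate the call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .consensus import ConsensusSignature
from .disease import SubgroupSignature
from .errors import UndefinedStatisticError, ValidationError
from .matrix import MatrixTable

MIN_SHARED_GENES = 3


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"vectors must be 1-d of equal length, got {x.shape} vs {y.shape}")
    if len(x) < MIN_SHARED_GENES:
        raise ValidationError(f"need at least {MIN_SHARED_GENES} pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("vectors must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("correlation undefined for a zero-variance vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class SubgroupScore:
    rho: float
    n_genes: int
    predicted_responsive: bool
    perm_p: float | None = None  # one-sided P(rho_perm <= rho_obs)


@dataclass
class ResponseScore:
    """Per-subgroup discordance of one drug signature against one
    disease signature set."""

    per_subgroup: dict[str, SubgroupScore]
    shared_genes: list[str]
    unmatched_drug_genes: list[str]


def _permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float,
                   n_permutations: int, rng: np.random.Generator) -> float:
    """One-sided permutation p for discordance: shuffle gene labels of
    one rank vector and count permutations at least as negative."""
    n = len(rx)
    perm = np.argsort(rng.random((n_permutations, n)), axis=1)
    xp = rx[perm]  # (P, n) permuted ranks
    rx_c = xp - xp.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
    rho_perm = (rx_c @ ry_c) / denom
    return float((1 + np.sum(rho_perm <= rho_obs)) / (1 + n_permutations))


def discordance_score(
    drug_sig: ConsensusSignature,
    disease_sig: SubgroupSignature,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> ResponseScore:
    """Score each subgroup's discordance with the drug signature.

    Genes are aligned by exact id match between the drug signature and
    the disease signature's gene universe; unmatched drug-signature
    genes are reported, never imputed.  ``predicted_responsive`` is the
    bare sign test ``rho < 0``.  Set ``n_permutations=0`` to skip the
    permutation p-value.
    """
    disease_genes = set(disease_sig.genes)
    shared = [g for g in drug_sig.genes if g in disease_genes]
    unmatched = [g for g in drug_sig.genes if g not in disease_genes]
    if len(shared) < MIN_SHARED_GENES:
        raise ValidationError(
            f"only {len(shared)} shared genes between the drug signature "
            f"({len(drug_sig)} genes) and the disease signature "
            f"({len(disease_genes)} genes); need >= {MIN_SHARED_GENES}"
        )
    z = np.array([drug_sig.entries[g].consensus_z for g in shared])
    rng = np.random.default_rng(seed)
    per_subgroup: dict[str, SubgroupScore] = {}
    for s in disease_sig.subgroups:
        fc = disease_sig.values_for(s, shared)
        rho = spearman_rho(z, fc)
        perm_p = None
        if n_permutations > 0:
            rx = stats.rankdata(z)
            ry = stats.rankdata(fc)
            perm_p = _permutation_p(rx, ry, rho, n_permutations, rng)
        per_subgroup[s] = SubgroupScore(
            rho=rho, n_genes=len(shared), predicted_responsive=rho < 0, perm_p=perm_p
        )
    return ResponseScore(
        per_subgroup=per_subgroup, shared_genes=shared, unmatched_drug_genes=unmatched
    )


def rank_dependencies(
    down_genes: list[str],
    dependency: MatrixTable,
    lineage_cols: list[str] | None = None,
) -> list[tuple[str, float | None]]:
    """Rank genes by mean dependency score, most essential first.

    Dependency scores follow the RNAi-screen convention: more negative
    means the gene is more required for cell-line survival.  Genes
    absent from the dependency table are listed last with a ``None``
    score.
    """
    table = dependency if lineage_cols is None else dependency.subset_cols(lineage_cols)
    idx = table.row_index()
    present = [g for g in down_genes if g in idx]
    absent = [g for g in down_genes if g not in idx]
    if not present:
        raise ValidationError(
            f"none of the {len(down_genes)} genes are in the dependency table"
        )
    scored = [(g, float(np.nanmean(table.values[idx[g]]))) for g in present]
    scored.sort(key=lambda t: (t[1], t[0]))
    return scored + [(g, None) for g in absent]
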