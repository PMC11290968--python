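"""Multi-cell-line consensus transcriptional response signature.

Given level-5-style differential z-score profiles of a drug across many
cell lines, a gene enters the consensus signature when it moves in the
same direction (|z| at or above a change threshold ``z_min``) in at
least a fraction ``tau`` of the cell lines.  The signature value of a
retained gene is the mean z over *all* cell lines — responders and
non-responders alike — so a gene that fires strongly in a subset keeps
an attenuated but directional consensus value.

Defaults ``tau = 0.30`` and ``z_min = 2.0``: 30% directional agreement
across lines, with "changed" operationalised as roughly a two-sided 0.05
exceedance on a standard-normal differential score.  A gene whose up-
and down-fractions *both* reach ``tau`` is direction-conflicted and is
excluded — a consensus signature must be directional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .matrix import MatrixTable


@dataclass(frozen=True)
class SignatureEntry:
    consensus_z: float  # mean z over all cell lines (available-case under missing data)
    direction: str  # "up" | "down" — the direction that met tau
    agreement: float  # fraction of (available) cell lines supporting that direction


@dataclass(frozen=True)
class SignatureParams:
    tau: float
    z_min: float
    timepoint: str | None = None


@dataclass
class ConsensusSignature:
    """Per-gene consensus z values with the retention parameters that
    produced them."""

    entries: dict[str, SignatureEntry]
    params: SignatureParams

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    def consensus_z(self, gene: str) -> float:
        return self.entries[gene].consensus_z


def collapse_cell_lines(profiles: MatrixTable, timepoint: str) -> MatrixTable:
    """Restrict profile columns to one timepoint and average replicate
    columns within each cell line, yielding one column per cell line.

    Column metadata must carry ``cell_line`` and ``timepoint`` keys;
    columns without metadata fall back to ids of the form
    ``"<cell_line>:<timepoint>"`` (the convention used when profiles
    round-trip through GCT, which has no column-metadata slot).
    Cell-line column order follows first appearance in the input.
    """
    selected: list[int] = []
    col_info: dict[str, dict[str, str]] = {}
    for j, col in enumerate(profiles.col_ids):
        meta = profiles.col_meta.get(col)
        if meta is None or "cell_line" not in meta or "timepoint" not in meta:
            if ":" in col:
                line, _, tp = col.partition(":")
                meta = {"cell_line": line, "timepoint": tp}
            else:
                raise ValidationError(
                    f"column {col!r} lacks cell_line/timepoint metadata and its "
                    "id is not of the form 'cell_line:timepoint'"
                )
        col_info[col] = meta
        if meta["timepoint"] == timepoint:
            selected.append(j)
    if not selected:
        raise ValidationError(f"no columns at timepoint {timepoint!r}")
    lines: list[str] = []
    groups: dict[str, list[int]] = {}
    for j in selected:
        line = col_info[profiles.col_ids[j]]["cell_line"]
        if line not in groups:
            groups[line] = []
            lines.append(line)
        groups[line].append(j)
    values = np.column_stack(
        [np.nanmean(profiles.values[:, groups[line]], axis=1) for line in lines]
    )
    return MatrixTable(
        row_ids=list(profiles.row_ids),
        col_ids=lines,
        values=values,
        row_meta=dict(profiles.row_meta),
        col_meta={line: {"cell_line": line, "timepoint": timepoint} for line in lines},
    )


def build_consensus(
    profiles_by_line: MatrixTable,
    tau: float = 0.30,
    z_min: float = 2.0,
    timepoint: str | None = None,
) -> ConsensusSignature:
    """Build the consensus signature from a genes x cell-lines z matrix.

    Retention rule per gene (available-case under missing values):
    ``frac_up = #(z >= z_min) / n_available`` and symmetrically
    ``frac_down``; the gene is kept iff exactly one of the two fractions
    reaches ``tau``.  The stored ``consensus_z`` is the plain
    (available-case) mean over all cell lines.
    """
    if not 0 < tau <= 1:
        raise ValidationError(f"tau must be in (0, 1], got {tau}")
    if z_min <= 0:
        raise ValidationError(f"z_min must be > 0, got {z_min}")
    n_lines = len(profiles_by_line.col_ids)
    if n_lines < 2:
        raise ValidationError(f"need at least 2 cell lines, got {n_lines}")
    z = profiles_by_line.values
    available = ~np.isnan(z)
    n_avail = available.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac_up = np.where(n_avail > 0, np.nansum(z >= z_min, axis=1) / np.maximum(n_avail, 1), 0.0)
        frac_down = np.where(n_avail > 0, np.nansum(z <= -z_min, axis=1) / np.maximum(n_avail, 1), 0.0)
        mean_z = np.where(n_avail > 0, np.nansum(np.where(available, z, 0.0), axis=1) / np.maximum(n_avail, 1), np.nan)
    up_ok = frac_up >= tau
    down_ok = frac_down >= tau
    keep = up_ok ^ down_ok  # direction-conflicted genes (both) are dropped
    entries: dict[str, SignatureEntry] = {}
    for i in np.flatnonzero(keep):
        direction = "up" if up_ok[i] else "down"
        agreement = float(frac_up[i] if up_ok[i] else frac_down[i])
        entries[profiles_by_line.row_ids[i]] = SignatureEntry(
            consensus_z=float(mean_z[i]), direction=direction, agreement=agreement
        )
    return ConsensusSignature(
        entries=entries, params=SignatureParams(tau=tau, z_min=z_min, timepoint=timepoint)
    )


def top_genes(
    sig: ConsensusSignature, k: int, universe: list[str] | None = None
) -> ConsensusSignature:
    """Keep the ``k`` strongest genes by |consensus_z| (optionally after
    restricting to ``universe``), ties broken by lexicographic gene id."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    genes = sig.genes
    if universe is not None:
        allowed = set(universe)
        genes = [g for g in genes if g in allowed]
    ranked = sorted(genes, key=lambda g: (-abs(sig.entries[g].consensus_z), g))
    kept = ranked[:k]
    return ConsensusSignature(
        entries={g: sig.entries[g] for g in kept}, params=sig.params
    )


def split_directions(sig: ConsensusSignature) -> tuple[list[str], list[str]]:
    """Partition signature genes into (upregulated, downregulated) lists."""
    up = [g for g, e in sig.entries.items() if e.direction == "up"]
    down = [g for g, e in sig.entries.items() if e.direction == "down"]
    return up, down
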