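"""Labelled numeric matrix container used for every genes-by-samples table.

``MatrixTable`` is deliberately minimal: unique string row/column ids, a
float matrix with NaN marking explicitly-missing cells, and optional
per-id string metadata maps (e.g. ``cell_line`` / ``timepoint`` for
perturbation columns).  Identifiers are opaque strings compared
case-sensitively after whitespace trimming; no symbol mapping is ever
applied, so distinct ids never merge silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

MetaMap = dict[str, dict[str, str]]


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what} ids: {sorted(set(dups))}")


@dataclass
class MatrixTable:
    """Genes-by-samples numeric matrix with string ids and optional metadata.

    Parameters
    ----------
    row_ids, col_ids:
        Unique identifiers; stored trimmed of surrounding whitespace.
    values:
        Float array of shape ``(len(row_ids), len(col_ids))``.  ``NaN``
        encodes an explicitly missing cell; infinities are rejected.
    row_meta, col_meta:
        Optional ``id -> {key: value}`` string maps.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    row_meta: MetaMap = field(default_factory=dict)
    col_meta: MetaMap = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.row_ids = [str(r).strip() for r in self.row_ids]
        self.col_ids = [str(c).strip() for c in self.col_ids]
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} column ids"
            )
        if np.isinf(self.values).any():
            raise ValidationError("matrix contains non-finite (inf) values")

    # -- convenience accessors -------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.row_ids)}

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.row_index()[gene]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        row_meta: MetaMap | None = None,
        col_meta: MetaMap | None = None,
    ) -> "MatrixTable":
        return cls(
            row_ids=[str(i) for i in df.index],
            col_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            row_meta=row_meta or {},
            col_meta=col_meta or {},
        )

    def subset_cols(self, cols: list[str]) -> "MatrixTable":
        idx = {c: j for j, c in enumerate(self.col_ids)}
        missing = [c for c in cols if c not in idx]
        if missing:
            raise ValidationError(f"unknown columns: {missing}")
        j = [idx[c] for c in cols]
        return MatrixTable(
            row_ids=list(self.row_ids),
            col_ids=list(cols),
            values=self.values[:, j].copy(),
            row_meta=dict(self.row_meta),
            col_meta={c: dict(self.col_meta.get(c, {})) for c in cols},
        )

    def subset_rows(self, rows: list[str]) -> "MatrixTable":
        idx = self.row_index()
        missing = [r for r in rows if r not in idx]
        if missing:
            raise ValidationError(f"unknown rows: {missing}")
        i = [idx[r] for r in rows]
        return MatrixTable(
            row_ids=list(rows),
            col_ids=list(self.col_ids),
            values=self.values[i, :].copy(),
            row_meta={r: dict(self.row_meta.get(r, {})) for r in rows},
            col_meta=dict(self.col_meta),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MatrixTable):
            return NotImplemented
        return (
            self.row_ids == other.row_ids
            and self.col_ids == other.col_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
            and self.row_meta == other.row_meta
            and self.col_meta == other.col_meta
        )
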