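"""Readers and writers for the pipeline's external text formats.

Supported formats:

* GCT 1.2 — ``#1.2`` header, ``nrows<TAB>ncols`` dimensions line, then a
  tab-separated body whose first two columns are ``Name`` and
  ``Description``.  ``NA`` or an empty cell marks a missing value.
* Cohort TSV pair — an expression table (GCT or plain TSV, genes x
  patients) plus a metadata TSV with ``sample_id``, ``subgroup`` and
  optional ``os_time`` / ``os_event`` columns.
* Dose-response CSV — long format with ``dose_a``, ``dose_b``,
  ``response_pct`` (replicate rows averaged) and an optional constant
  ``response_kind`` column.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort, SurvivalRecord
from .errors import FormatError, ValidationError
from .doseresponse import DoseResponseSurface
from .matrix import MatrixTable

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"NA", ""}


def _parse_cell(token: str, path: str, line_no: int) -> float:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}: line {line_no}: non-numeric cell {token!r}"
        ) from None


def read_gct(path: str | Path) -> MatrixTable:
    """Read a GCT 1.2 matrix; row order is preserved, the Description
    column is kept as row metadata, ``NA``/empty cells become missing."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        got = lines[0] if lines else "<empty file>"
        raise FormatError(f"{path}: line 1: expected '#1.2' header, got {got!r}")
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated file: missing dimensions or header line")
    dims = lines[1].split("\t")
    try:
        nrows, ncols = int(dims[0]), int(dims[1])
    except (IndexError, ValueError):
        raise FormatError(
            f"{path}: line 2: expected 'nrows<TAB>ncols', got {lines[1]!r}"
        ) from None
    header = lines[2].split("\t")
    if len(header) != ncols + 2:
        raise FormatError(
            f"{path}: line 3: header has {len(header)} fields, expected "
            f"{ncols + 2} (Name, Description, {ncols} samples)"
        )
    col_ids = [c.strip() for c in header[2:]]
    body = lines[3:]
    if len(body) != nrows:
        raise FormatError(
            f"{path}: declared {nrows} rows but body has {len(body)} data lines"
        )
    row_ids: list[str] = []
    row_meta: dict[str, dict[str, str]] = {}
    values = np.empty((nrows, ncols))
    for i, line in enumerate(body):
        fields = line.split("\t")
        if len(fields) != ncols + 2:
            raise FormatError(
                f"{path}: line {i + 4}: has {len(fields)} fields, expected {ncols + 2}"
            )
        rid = fields[0].strip()
        row_ids.append(rid)
        desc = fields[1].strip()
        if desc:
            row_meta[rid] = {"description": desc}
        values[i] = [_parse_cell(tok, str(path), i + 4) for tok in fields[2:]]
    return MatrixTable(row_ids=row_ids, col_ids=col_ids, values=values, row_meta=row_meta)


def _format_value(v: float) -> str:
    if np.isnan(v):
        return "NA"
    return repr(float(v))


def write_gct(table: MatrixTable, path: str | Path) -> None:
    """Write a MatrixTable in the GCT 1.2 dialect.

    Values are written with full (shortest round-trip) precision so that
    ``read_gct(write_gct(t)) == t`` bit-exactly.  Ids containing tab or
    newline are rejected: they would corrupt the delimiter structure.
    """
    for ident in list(table.row_ids) + list(table.col_ids):
        if "\t" in ident or "\n" in ident:
            raise ValidationError(f"id {ident!r} contains a delimiter character")
    nrows, ncols = table.shape
    lines = ["#1.2", f"{nrows}\t{ncols}", "\t".join(["Name", "Description"] + table.col_ids)]
    for i, rid in enumerate(table.row_ids):
        desc = table.row_meta.get(rid, {}).get("description", "")
        if "\t" in desc or "\n" in desc:
            raise ValidationError(f"description for {rid!r} contains a delimiter character")
        cells = [_format_value(v) for v in table.values[i]]
        lines.append("\t".join([rid, desc] + cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_expression(path: Path) -> MatrixTable:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if first.strip() == "#1.2":
        return read_gct(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MatrixTable.from_dataframe(df)


def read_cohort(
    expr_path: str | Path,
    meta_path: str | Path,
    scale: str = "log2",
) -> ExpressionCohort:
    """Assemble an :class:`ExpressionCohort` from an expression table and
    a sample-metadata TSV.

    Patients present in both files are retained (expression-table
    order); patients missing from the metadata are dropped with a logged
    count.  Survival columns (``os_time``, ``os_event``) are optional but
    must be complete and valid when present.
    """
    expr = _read_expression(Path(expr_path))
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "subgroup"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"{meta_path}: metadata must have columns {sorted(required)}, "
            f"got {list(meta.columns)}"
        )
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        dups = meta.index[meta.index.duplicated()].tolist()
        raise ValidationError(f"{meta_path}: duplicate sample_id entries: {dups}")
    shared = [p for p in expr.col_ids if p in meta.index]
    if not shared:
        raise ValidationError(
            "no overlapping patients between expression columns and metadata sample_id"
        )
    dropped = len(expr.col_ids) - len(shared)
    if dropped:
        logger.warning("dropping %d patient(s) absent from metadata", dropped)
    expr = expr.subset_cols(shared)
    subgroup = {p: str(meta.at[p, "subgroup"]) for p in shared}

    survival = None
    if "os_time" in meta.columns and "os_event" in meta.columns:
        survival = {}
        for p in shared:
            ev = meta.at[p, "os_event"]
            if float(ev) not in (0.0, 1.0):
                raise ValidationError(
                    f"{meta_path}: os_event for {p} must be 0 or 1, got {ev!r}"
                )
            survival[p] = SurvivalRecord(os_time=float(meta.at[p, "os_time"]), os_event=int(ev))
    return ExpressionCohort(expr=expr, subgroup=subgroup, survival=survival, scale=scale)


def read_dose_response(path: str | Path) -> DoseResponseSurface:
    """Read a long-format combination assay CSV into a full-grid surface.

    Replicate rows for the same ``(dose_a, dose_b)`` cell are averaged.
    Every combination of the observed dose levels must be present;
    responses may range over [-20, 120] to admit modest assay noise
    outside the nominal 0-100 window.
    """
    df = pd.read_csv(path)
    required = {"dose_a", "dose_b", "response_pct"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    if (df["dose_a"] < 0).any() or (df["dose_b"] < 0).any():
        raise ValidationError(f"{path}: negative doses are not allowed")
    bad = df[(df["response_pct"] < -20) | (df["response_pct"] > 120)]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValidationError(
            f"{path}: response_pct {r['response_pct']} at "
            f"({r['dose_a']}, {r['dose_b']}) outside [-20, 120]"
        )
    kind = "inhibition"
    if "response_kind" in df.columns:
        kinds = set(df["response_kind"].astype(str))
        if len(kinds) != 1:
            raise ValidationError(f"{path}: response_kind column is not constant: {kinds}")
        kind = kinds.pop()
    doses_a = np.array(sorted(df["dose_a"].unique()), dtype=float)
    doses_b = np.array(sorted(df["dose_b"].unique()), dtype=float)
    cell_means = df.groupby(["dose_a", "dose_b"])["response_pct"].mean()
    response = np.empty((len(doses_a), len(doses_b)))
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            try:
                response[i, j] = cell_means[(da, db)]
            except KeyError:
                raise ValidationError(
                    f"{path}: missing grid cell ({da:g},{db:g})"
                ) from None
    return DoseResponseSurface(
        doses_a=doses_a, doses_b=doses_b, response=response, response_kind=kind
    )
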