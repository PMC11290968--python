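"""Combination dose-response surfaces and HSA-reference synergy scoring.

The highest-single-agent (HSA) reference model takes, at every
combination dose pair, the larger of the two single-agent inhibitions as
the expected combination effect.  The synergy score of a surface is the
unweighted mean, over all combination cells, of the observed inhibition
minus this expectation, in percentage points.  Scores above +10 are
called synergistic and below -10 antagonistic; everything in between is
additive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

SYNERGY_THRESHOLD = 10.0
ANTAGONISM_THRESHOLD = -10.0


@dataclass
class DoseResponseSurface:
    """Mean response over a full factorial dose grid for two agents.

    ``response[i, j]`` is the mean response at ``(doses_a[i], doses_b[j])``.
    Both grids are strictly ascending and start at 0 (vehicle), so the
    first row/column hold the single-agent margins and ``response[0, 0]``
    the untreated well.  ``response_kind`` records whether values are
    inhibition (0 = no effect) or viability (100 = no effect).
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    response: np.ndarray
    response_kind: str = "inhibition"

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        for name, grid in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if grid.ndim != 1 or len(grid) < 1:
                raise ValidationError(f"{name} must be a non-empty 1-d grid")
            if np.any(np.diff(grid) <= 0):
                raise ValidationError(f"{name} must be strictly ascending")
            if grid[0] != 0:
                raise ValidationError(f"{name} must start at dose 0")
        if self.response.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValidationError(
                f"response shape {self.response.shape} does not match dose grids "
                f"({len(self.doses_a)} x {len(self.doses_b)})"
            )
        if not np.isfinite(self.response).all():
            raise ValidationError("response matrix contains non-finite values")
        if self.response_kind not in ("inhibition", "viability"):
            raise ValidationError(f"unknown response_kind {self.response_kind!r}")


@dataclass
class SynergyResult:
    """HSA synergy summary of one combination surface."""

    hsa_score: float
    per_cell_excess: np.ndarray  # (len(doses_a)-1, len(doses_b)-1), combo cells only
    classification: str  # synergistic | additive | antagonistic


def to_inhibition(surface: DoseResponseSurface) -> DoseResponseSurface:
    """Convert a viability surface to inhibition (100 - v); a surface
    already on the inhibition scale passes through unchanged."""
    if surface.response_kind == "inhibition":
        return surface
    return DoseResponseSurface(
        doses_a=surface.doses_a.copy(),
        doses_b=surface.doses_b.copy(),
        response=100.0 - surface.response,
        response_kind="inhibition",
    )


def _require_inhibition(surface: DoseResponseSurface) -> None:
    if surface.response_kind != "inhibition":
        raise ValidationError(
            "surface is on the viability scale; apply to_inhibition() first"
        )
    if len(surface.doses_a) < 2 or len(surface.doses_b) < 2:
        raise ValidationError(
            "surface has no combination cells: each agent needs at least one "
            "nonzero dose beyond the vehicle column/row"
        )


def hsa_expected(surface: DoseResponseSurface) -> np.ndarray:
    """Expected combination inhibition under the HSA reference model:
    ``max(single-agent A at dose a, single-agent B at dose b)`` for every
    combination cell (a > 0, b > 0)."""
    _require_inhibition(surface)
    margin_a = surface.response[1:, 0]  # agent A alone, doses_a[1:]
    margin_b = surface.response[0, 1:]  # agent B alone, doses_b[1:]
    return np.maximum.outer(margin_a, margin_b)


def hsa_score(surface: DoseResponseSurface) -> SynergyResult:
    """Score a surface against the HSA expectation.

    The per-cell excess is observed minus expected inhibition over the
    combination block; the summary score is its unweighted mean.
    Classification uses the +/-10 percentage-point convention (the
    boundaries themselves count as additive).
    """
    expected = hsa_expected(surface)
    observed = surface.response[1:, 1:]
    excess = observed - expected
    score = float(np.mean(excess))
    if score > SYNERGY_THRESHOLD:
        classification = "synergistic"
    elif score < ANTAGONISM_THRESHOLD:
        classification = "antagonistic"
    else:
        classification = "additive"
    return SynergyResult(hsa_score=score, per_cell_excess=excess, classification=classification)
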