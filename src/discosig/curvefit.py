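"""Nonlinear dose-response and decay curve fits.

Two least-squares models:

* four-parameter logistic (4PL) inhibition curve
  ``y = bottom + (top - bottom) / (1 + (ec50 / x)^hill)``,
  whose EC50 is the dose of half-maximal effect; and
* one-phase exponential decay
  ``y(t) = (y0 - plateau) * exp(-k t) + plateau``,
  whose half-life is ``ln 2 / k`` (the standard protein-turnover model
  for cycloheximide-chase time courses).

Both use multi-start Levenberg-Marquardt-style optimisation
(``scipy.optimize.least_squares``) with positivity enforced through log
parameterisation of EC50 and k.  Fit failures are returned as values
(``converged=False``), never raised, so batch scoring of many curves
keeps going.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ValidationError

LN2 = math.log(2.0)
# dose used for vehicle (x = 0) wells in the log-dose 4PL model
ZERO_DOSE_SURROGATE_FACTOR = 1e-2


@dataclass
class CurveFit:
    """Result of one nonlinear curve fit."""

    model: str  # "fourPL" | "one_phase_decay"
    params: dict[str, float] = field(default_factory=dict)
    derived: dict[str, float] = field(default_factory=dict)
    rss: float = math.inf
    converged: bool = False


def _four_pl(logx: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float) -> np.ndarray:
    # exp overflow saturates the logistic to its asymptote; that is the
    # intended limit, so silence the spurious warning
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_ec50 - logx)))


def fit_4pl(doses: np.ndarray, responses: np.ndarray) -> CurveFit:
    """Fit a 4PL curve and report its EC50.

    Zero-dose (vehicle) points are kept in the fit at a surrogate dose
    of ``min(nonzero dose) / 100`` so they anchor the curve's bottom
    asymptote; the model itself is evaluated on log dose.  Multi-start
    initialisation places the EC50 guess at each distinct nonzero dose
    with Hill slopes in {0.5, 1, 2}, and the best residual sum of
    squares wins.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValidationError("doses and responses must be equal-length 1-d vectors")
    if len(doses) < 5:
        raise ValidationError(f"need at least 5 dose points, got {len(doses)}")
    if np.any(doses < 0):
        raise ValidationError("doses must be >= 0")
    nonzero = np.unique(doses[doses > 0])
    if len(nonzero) < 3:
        raise ValidationError(f"need >= 3 distinct nonzero doses, got {len(nonzero)}")
    if np.ptp(responses) == 0:
        return CurveFit(model="fourPL", converged=False)

    surrogate = nonzero.min() * ZERO_DOSE_SURROGATE_FACTOR
    x = np.where(doses > 0, doses, surrogate)
    logx = np.log(x)
    lo, hi = float(responses.min()), float(responses.max())
    span = hi - lo

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _four_pl(logx, *theta) - responses

    best: CurveFit = CurveFit(model="fourPL", converged=False)
    for ec50_guess in nonzero:
        for hill_guess in (0.5, 1.0, 2.0):
            theta0 = np.array([lo, hi, math.log(ec50_guess), hill_guess])
            try:
                sol = least_squares(residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14)
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if sol.success and rss < best.rss:
                bottom, top, log_ec50, hill = sol.x
                if hill == 0 or not np.isfinite(log_ec50):
                    continue
                ec50 = math.exp(log_ec50)
                best = CurveFit(
                    model="fourPL",
                    params={
                        "bottom": float(bottom),
                        "top": float(top),
                        "ec50": float(ec50),
                        "hill": float(hill),
                    },
                    derived={"EC50": float(ec50)},
                    rss=rss,
                    converged=True,
                )
    # a "fit" explaining less than machine-level structure of a flat
    # response is degenerate even when the optimiser reports success
    if best.converged and abs(best.params["top"] - best.params["bottom"]) < 1e-9 * max(1.0, span):
        best.converged = False
    return best


def _decay(t: np.ndarray, y0: float, plateau: float, logk: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        return (y0 - plateau) * np.exp(-np.exp(logk) * t) + plateau


def fit_one_phase_decay(
    times: np.ndarray,
    levels: np.ndarray,
    plateau_fixed: float | None = None,
) -> CurveFit:
    """Fit one-phase exponential decay and report the half-life.

    ``plateau_fixed`` pins the asymptote (common choice: 0 for complete
    degradation); otherwise the plateau is a free parameter.  The decay
    rate is optimised on the log scale, so it is positive by
    construction; a rate collapsing to ~0 (non-decaying data) is
    flagged ``converged=False`` rather than yielding a nonsensical
    negative half-life.
    """
    times = np.asarray(times, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if times.shape != levels.shape or times.ndim != 1:
        raise ValidationError("times and levels must be equal-length 1-d vectors")
    if len(times) < 4:
        raise ValidationError(f"need at least 4 time points, got {len(times)}")
    if np.any(times < 0):
        raise ValidationError("times must be >= 0")
    t_span = float(np.ptp(times))
    if t_span == 0 or np.ptp(levels) == 0:
        return CurveFit(model="one_phase_decay", converged=False)

    free_plateau = plateau_fixed is None

    def residuals(theta: np.ndarray) -> np.ndarray:
        if free_plateau:
            y0, plateau, logk = theta
        else:
            y0, logk = theta
            plateau = plateau_fixed
        return _decay(times, y0, plateau, logk) - levels

    y0_guess = float(levels[np.argmin(times)])
    plateau_guess = float(levels[np.argmax(times)]) if free_plateau else float(plateau_fixed)
    best = CurveFit(model="one_phase_decay", converged=False)
    for frac in (0.1, 0.3, 1.0, 3.0):
        k_guess = LN2 / (t_span * frac)
        if free_plateau:
            theta0 = np.array([y0_guess, plateau_guess, math.log(k_guess)])
        else:
            theta0 = np.array([y0_guess, math.log(k_guess)])
        try:
            sol = least_squares(residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if sol.success and rss < best.rss:
            if free_plateau:
                y0, plateau, logk = sol.x
            else:
                y0, logk = sol.x
                plateau = float(plateau_fixed)
            k = math.exp(float(logk))
            best = CurveFit(
                model="one_phase_decay",
                params={"y0": float(y0), "plateau": float(plateau), "k": k},
                derived={"half_life": LN2 / k},
                rss=rss,
                converged=True,
            )
    # k indistinguishable from zero on the observed time span means the
    # data do not decay; report the fit but mark it unconverged
    if best.converged and best.params["k"] * t_span < 1e-6:
        best.converged = False
    return best
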