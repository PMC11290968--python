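"""Independent brute-force reimplementations used as oracles.

These deliberately use naive per-element loops and textbook formulas,
sharing no code with the package, so agreement with the library is a
genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def naive_consensus(
    row_ids: list[str], z: np.ndarray, tau: float, z_min: float
) -> dict[str, tuple[float, str, float]]:
    """Per-gene loop re-derivation of the consensus retention rule.

    Returns gene -> (mean z over available lines, direction, agreement).
    """
    out: dict[str, tuple[float, str, float]] = {}
    for i, gene in enumerate(row_ids):
        vals = [v for v in z[i] if not math.isnan(v)]
        if not vals:
            continue
        n = len(vals)
        n_up = sum(1 for v in vals if v >= z_min)
        n_down = sum(1 for v in vals if v <= -z_min)
        up_ok = n_up / n >= tau
        down_ok = n_down / n >= tau
        if up_ok == down_ok:  # neither, or direction-conflicted
            continue
        direction = "up" if up_ok else "down"
        agreement = (n_up if up_ok else n_down) / n
        out[gene] = (sum(vals) / n, direction, agreement)
    return out


def naive_rank(values: list[float]) -> list[float]:
    """Average ranks (1-based) with ties sharing the mean rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def naive_spearman(x: list[float], y: list[float]) -> float:
    """Rank both vectors then compute Pearson's r by the definition."""
    rx, ry = naive_rank(list(x)), naive_rank(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def naive_logrank_chi2(
    group_a: list[tuple[float, int]], group_b: list[tuple[float, int]]
) -> float:
    """Explicit 2x2 hypergeometric table at each distinct event time."""
    everyone = [(t, e, "A") for t, e in group_a] + [(t, e, "B") for t, e in group_b]
    event_times = sorted({t for t, e, _ in everyone if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in everyone if tt >= t]
        n = len(at_risk)
        n_a = sum(1 for _, _, g in at_risk if g == "A")
        d = sum(1 for tt, ee, _ in at_risk if tt == t and ee == 1)
        d_a = sum(1 for tt, ee, g in at_risk if tt == t and ee == 1 and g == "A")
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * ((n - n_a) / n) * ((n - d) / (n - 1))
    return o_minus_e**2 / var


def naive_hsa_score(response: np.ndarray) -> float:
    """Cell-by-cell loop over the combination block of an inhibition
    surface (row 0 / column 0 are the single-agent margins)."""
    excesses = []
    for i in range(1, response.shape[0]):
        for j in range(1, response.shape[1]):
            expected = max(response[i, 0], response[0, j])
            excesses.append(response[i, j] - expected)
    return sum(excesses) / len(excesses)
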