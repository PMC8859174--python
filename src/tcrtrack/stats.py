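"""Paired cohort statistics: exact Wilcoxon signed-rank and Bonferroni.

The Wilcoxon test uses the exact null distribution (by convolution over
signed ranks) for n <= 15 pairs after dropping zero differences, and a
normal approximation with continuity and tie corrections for larger n.
Ties receive average ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

EXACT_LIMIT = 15


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int
    n_zero_dropped: int
    exact: bool


def _exact_wplus_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of W+ over all 2^n sign assignments.

    Ranks may be tied (average ranks), so W+ lives on a grid of half-integer
    values; we convolve on a doubled-integer grid.
    """
    doubled = np.round(ranks * 2).astype(int)
    total = doubled.sum()
    probs = np.zeros(total + 1)
    probs[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(probs)
        shifted[r:] = probs[: len(probs) - r]
        probs = 0.5 * (probs + shifted)
    support = np.arange(total + 1) / 2.0
    return support, probs


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped (their count is reported); requires at
    least 3 informative pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    n = len(d)
    if n == 0:
        raise ValueError("degenerate pairing: all differences are zero")
    if n < 3:
        raise ValueError(f"need >= 3 nonzero differences (got {n})")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_LIMIT:
        support, probs = _exact_wplus_distribution(ranks)
        p_low = probs[support <= w_plus + 1e-9].sum()
        p_high = probs[support >= w_plus - 1e-9].sum()
        p = min(1.0, 2.0 * min(p_low, p_high))
        return WilcoxonResult(w_plus, float(p), n, n_zero, exact=True)

    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(w_plus, min(1.0, p), n, n_zero, exact=False)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: multiply by m (default the list length), cap at 1."""
    p = list(p_values)
    if any(not (0.0 <= v <= 1.0) for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return [min(1.0, v * m) for v in p]
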