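"""Shannon-entropy diversity and its longitudinal trend.

Entropy is computed on UMI-weighted amino-acid clonotype frequencies for
consistency with tracking; natural log is the default base with base 2 and
a normalized variant (H / ln K) exposed.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .core import RepertoireSample, frequencies


def shannon_entropy(freqs: Mapping, base: float = math.e) -> float:
    """H = -sum p log p over clone frequencies (0 log 0 = 0)."""
    p = np.asarray(list(freqs.values()), dtype=float)
    if np.any(p < 0):
        raise ValueError("negative frequency")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1 (got {total})")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / math.log(base)


def sample_entropy(
    sample: RepertoireSample, base: float = math.e, normalized: bool = False
) -> float:
    """Shannon entropy of one sample's UMI-weighted AA clone frequencies."""
    f = frequencies(sample, level="aa", weight="auto")
    h = shannon_entropy(f, base=base)
    if normalized:
        k = len(f)
        return h / (math.log(k) / math.log(base)) if k > 1 else 0.0
    return h


def entropy_trend(
    series: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """OLS fit of entropy on months across subjects.

    Returns (slope, adjusted R^2, two-sided slope p-value).  Needs at least
    three points over at least two distinct timepoints.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 (timepoint, entropy) points")
    t = np.array([x for x, _ in series], dtype=float)
    h = np.array([y for _, y in series], dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("degenerate design: all timepoints identical")
    X = sm.add_constant(t)
    fit = sm.OLS(h, X).fit()
    return float(fit.params[1]), float(fit.rsquared_adj), float(fit.pvalues[1])
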