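"""Paired z-tests, Bonferroni adjustment, and quartile summaries.

Feature changes are validated with large-sample paired z-tests (no
distributional assumption on the underlying populations), adjusted for the
two hypotheses per feature (raw vs Wiener, raw vs RLS-family) with the
Bonferroni rule p_bonf = min(1, k*p), k = 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedTestResult",
    "DeltaSummary",
    "paired_z_test",
    "bonferroni",
    "summarize_deltas",
]


@dataclass
class PairedTestResult:
    feature_name: str
    group: str
    n: int
    mean_diff: float
    z: float
    p: float
    p_bonf: float


@dataclass
class DeltaSummary:
    """Quartiles/mean of percent feature changes plus boxplot whiskers."""

    feature_name: str
    group: str
    quartile1: float
    median: float
    quartile3: float
    mean: float
    whisker_lo: float
    whisker_hi: float
    n: int


def paired_z_test(x, y) -> tuple[float, float]:
    """Two-sided paired z-test on the mean of d = x - y.

    z = mean(d) / (sd(d)/sqrt(n)) with the n-1 sample standard deviation;
    the p-value is the two-sided standard-normal tail probability.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    if n < 30:
        warnings.warn(
            f"n = {n} < 30: the normal approximation of the paired z-test is weak",
            stacklevel=2,
        )
    d = x - y
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: degenerate pairing")
    z = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def bonferroni(p: float, k: int = 2) -> float:
    """Bonferroni adjustment min(1, k*p) for k hypotheses."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    if k < 1:
        raise ValueError("k must be >= 1")
    return min(1.0, k * p)


def summarize_deltas(values, feature_name: str = "", group: str = "") -> DeltaSummary:
    """Type-7 (linear interpolation) quartiles, mean, and 1.5*IQR whiskers."""
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to summarise")
    if v.size < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # numpy default = type 7
    iqr = q3 - q1
    in_lo = v[v >= q1 - 1.5 * iqr]
    in_hi = v[v <= q3 + 1.5 * iqr]
    return DeltaSummary(
        feature_name=feature_name,
        group=group,
        quartile1=float(q1),
        median=float(med),
        quartile3=float(q3),
        mean=float(np.mean(v)),
        whisker_lo=float(np.min(in_lo)),
        whisker_hi=float(np.max(in_hi)),
        n=int(v.size),
    )
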