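"""Self-contained nonparametric tests, correlation, line fits and kernel
density estimation used throughout the analysis pipeline.

These are deliberately hand-authored (and cross-checked against independent
oracles in the test suite); only reference distribution functions
(chi-square, Student t, Kolmogorov) come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import special
from scipy.stats import chi2 as _chi2
from scipy.stats import t as _t

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "TestResult", "kruskal_wallis", "pearson_corr", "ks_two_sample",
    "dunn_sidak", "polyfit1", "GaussianKDE", "gaussian_kde",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``df`` follows the (k-1, N-k) display convention for the Kruskal-Wallis
    test (the chi-square reference itself uses k-1 degrees of freedom),
    n-2 for the Pearson correlation, and None for the KS test.
    """

    method: str
    statistic: float
    p_value: float
    n: Tuple[int, ...]
    df: Union[int, Tuple[int, int], None] = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")


def _average_ranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks (1-based, ties get the average of their rank span)."""
    uniq, inv, counts = np.unique(values, return_inverse=True,
                                  return_counts=True)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    avg = starts + (counts + 1) / 2.0
    return avg[inv]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank ANOVA with tie correction.

    The H statistic is computed on mid-ranks of the pooled sample and divided
    by the tie-correction factor ``1 - sum(t^3 - t) / (N^3 - N)``; the
    p-value comes from the chi-square distribution with k-1 df.  Amplitude
    and frequency data here are heavily tied (a handful of discrete levels),
    so the correction matters.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ParameterError("need at least two groups")
    if any(a.size == 0 for a in arrs):
        raise ParameterError("every group must be non-empty")
    sizes = [a.size for a in arrs]
    n = int(sum(sizes))
    if n < 3:
        raise ParameterError("need a total sample size of at least 3")
    pooled = np.concatenate(arrs)
    k = len(arrs)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, tuple(sizes),
                          df=(k - 1, n - k))
    ranks = _average_ranks(pooled)
    h = 0.0
    offset = 0
    for m in sizes:
        rsum = ranks[offset:offset + m].sum()
        h += rsum * rsum / m
        offset += m
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(np.sum(counts ** 3 - counts))
    h /= 1.0 - ties / (n ** 3 - n)
    h = max(h, 0.0)
    p = float(_chi2.sf(h, k - 1))
    return TestResult("kruskal_wallis", float(h), p, tuple(sizes),
                      df=(k - 1, n - k))


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson linear correlation with two-sided p from the exact
    t-transform ``t = r sqrt((n-2) / (1-r^2))`` on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ParameterError("need at least 3 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc * xc).sum()))
    sy = float(np.sqrt((yc * yc).sum()))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateDataError(
            "correlation undefined: one input has zero variance")
    r = float((xc * yc).sum() / (sx * sy))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _t.sf(abs(tstat), n - 2))
    return TestResult("pearson", r, min(p, 1.0), (n,), df=n - 2)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; the two-sided
    p-value uses the asymptotic Kolmogorov distribution evaluated at
    ``sqrt(mn/(m+n)) * D``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ParameterError("both samples must be non-empty")
    pts = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pts, side="right") / m
    cdf_y = np.searchsorted(y, pts, side="right") / n
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = np.sqrt(m * n / (m + n))
    p = float(np.clip(special.kolmogorov(en * d), 0.0, 1.0))
    return TestResult("ks_two_sample", d, p, (m, n), df=None)


def dunn_sidak(p_values: Sequence[float], m: int) -> np.ndarray:
    """Dunn-Sidak correction for *m* comparisons:
    ``p_adj = 1 - (1 - p)^m``, clipped to [0, 1] and monotone in p."""
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ParameterError("m must be >= 1")
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        adj = -np.expm1(m * np.log1p(-p))
    adj = np.where(p >= 1.0, 1.0, adj)
    return np.clip(adj, 0.0, 1.0)


def polyfit1(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Ordinary least-squares line fit; returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ParameterError("need >= 2 paired observations")
    xc = x - x.mean()
    sxx = float((xc * xc).sum())
    if sxx == 0.0:
        raise DegenerateDataError("all x values identical: line fit degenerate")
    slope = float((xc * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


@dataclass
class GaussianKDE:
    """Gaussian-kernel density estimate with Silverman's rule-of-thumb
    bandwidth ``0.9 min(sd, IQR/1.34) n^{-1/5}`` (falling back to the sample
    SD when the IQR is zero)."""

    values: np.ndarray
    bandwidth: float

    @classmethod
    def fit(cls, values: Sequence[float],
            bandwidth: Optional[float] = None) -> "GaussianKDE":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ParameterError("need at least 2 values for a KDE")
        sd = float(v.std(ddof=1))
        if sd == 0.0:
            raise DegenerateDataError(
                "constant sample: bandwidth undefined; supply an explicit "
                "bandwidth or add variability")
        if bandwidth is None:
            q75, q25 = np.percentile(v, [75, 25])
            iqr = float(q75 - q25)
            spread = min(sd, iqr / 1.34) if iqr > 0 else sd
            bandwidth = 0.9 * spread * v.size ** (-0.2)
        if bandwidth <= 0:
            raise ParameterError("bandwidth must be positive")
        return cls(values=v, bandwidth=float(bandwidth))

    def evaluate(self, grid: Sequence[float]) -> np.ndarray:
        g = np.asarray(grid, dtype=float)
        z = (g[:, None] - self.values[None, :]) / self.bandwidth
        k = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
        return k.mean(axis=1) / self.bandwidth

    def grid(self, n: int = 256, pad: float = 5.0):
        """Evaluation grid spanning the data ± pad bandwidths, with density."""
        lo = self.values.min() - pad * self.bandwidth
        hi = self.values.max() + pad * self.bandwidth
        xs = np.linspace(lo, hi, n)
        return xs, self.evaluate(xs)


def gaussian_kde(values: Sequence[float],
                 bandwidth: Optional[float] = None) -> GaussianKDE:
    """Convenience constructor for :class:`GaussianKDE`."""
    return GaussianKDE.fit(values, bandwidth=bandwidth)
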