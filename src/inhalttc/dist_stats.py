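"""Distributional machinery for the derivation pipeline.

log10 ECDFs, empirical percentiles, a normal-CDF overlay, QQ data,
Shapiro-Wilk and two-sample Kolmogorov-Smirnov tests, and the
bootstrapped 5th percentile.  Percentiles are computed on the raw value
scale; log10 is used only for plotting/normality diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence
import warnings

import numpy as np
from scipy import stats

QuantileMethod = Literal["linear", "nearest"]
_NP_METHOD = {"linear": "linear", "nearest": "closest_observation"}


@dataclass(frozen=True)
class ECDF:
    """Empirical CDF over log10-transformed values: p_i = i/n at the i-th
    order statistic."""

    log10_values: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.probabilities) > 0):
            raise ValueError("probabilities must be strictly increasing")
        if not np.isclose(self.probabilities[-1], 1.0):
            raise ValueError("final probability must be 1")


@dataclass(frozen=True)
class PercentileEstimate:
    group: str
    n: int
    p: float
    value: float
    method: str


@dataclass(frozen=True)
class BootstrapResult:
    n_replicates: int
    seed: int
    replicates: np.ndarray
    median: float
    ci_low: float
    ci_high: float


def ecdf(values: Sequence[float]) -> ECDF:
    """ECDF of the log10-transformed sample (values must be positive).

    Ties collapse to the highest step at each distinct point, but the
    returned arrays keep one entry per distinct sorted value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    if np.any(arr <= 0):
        raise ValueError("values must be positive to take log10")
    logs = np.sort(np.log10(arr))
    n = logs.size
    probs = np.arange(1, n + 1) / n
    # keep the last (highest) probability at each tied point
    _, last_idx = np.unique(logs[::-1], return_index=True)
    keep = np.sort(n - 1 - last_idx)
    return ECDF(log10_values=logs[keep], probabilities=probs[keep])


def empirical_percentile(
    values: Sequence[float],
    p: float = 5.0,
    group: str = "",
    method: QuantileMethod = "linear",
) -> PercentileEstimate:
    """Empirical percentile of the raw values (linear interpolation default)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    if not 0 < p < 100:
        raise ValueError(f"percentile level must be in (0, 100), got {p!r}")
    value = float(np.percentile(arr, p, method=_NP_METHOD[method]))
    return PercentileEstimate(group=group, n=int(arr.size), p=p, value=value, method=method)


def normal_overlay(values: Sequence[float], sample_n: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Normal-CDF curve fitted by moments to the log10 data.

    Returns ``sample_n`` evaluation points spanning the data range and
    Phi((x - m) / s) at each.
    """
    logs = np.log10(np.asarray(values, dtype=float))
    if logs.size < 2:
        raise ValueError("need at least 2 values for an overlay")
    m, s = logs.mean(), logs.std(ddof=1)
    if s == 0:
        warnings.warn("zero variance: degenerate overlay", stacklevel=2)
        x = np.full(sample_n, m)
        return x, np.where(x >= m, 1.0, 0.0)
    x = np.linspace(logs.min(), logs.max(), sample_n)
    return x, stats.norm.cdf(x, loc=m, scale=s)


def qq_points(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal theoretical quantiles vs. sorted standardized data."""
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n < 3:
        raise ValueError("need at least 3 values for a QQ plot")
    s = arr.std(ddof=1)
    if s == 0:
        raise ValueError("zero variance data has no QQ representation")
    standardized = (arr - arr.mean()) / s
    theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theoretical, standardized


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston approximation via scipy)."""
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise ValueError(f"Shapiro-Wilk supports 3 <= n <= 5000, got n={arr.size}")
    res = stats.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Two-sample K-S test: D = sup |ECDF_x - ECDF_y|.

    Exact p-value when the smaller sample has n <= 25, asymptotic
    otherwise; the method used is returned alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if min(x.size, y.size) <= 25 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue), method


def bootstrap_percentile(
    values: Sequence[float],
    p: float = 5.0,
    n_replicates: int = 10_000,
    seed: int = 0,
    method: QuantileMethod = "linear",
) -> BootstrapResult:
    """Bootstrap distribution of the empirical percentile.

    Each replicate resamples n values with replacement and recomputes the
    percentile with the same quantile method.  Replicate r draws from a
    deterministic stream seeded by (seed, r), so the result is
    reproducible and independent of any parallel scheduling.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    n = arr.size
    reps = np.empty(n_replicates)
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        sample = arr[rng.integers(0, n, size=n)]
        reps[r] = np.percentile(sample, p, method=_NP_METHOD[method])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapResult(
        n_replicates=n_replicates,
        seed=seed,
        replicates=reps,
        median=float(np.median(reps)),
        ci_low=float(lo),
        ci_high=float(hi),
    )
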