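"""Resampling statistics: permutation tests, bootstrap intervals, Bonferroni.

The permutation test uses the add-one convention p = (1 + #{|T*| >= |T|}) /
(1 + R) so a Monte Carlo p-value is never zero; at R = 10,000 the smallest
reportable value is about 1e-4, below which results are best stated as a
bound. When the number of distinct relabelings is small the test switches
to exhaustive enumeration and the p-value is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as _scipy_stats

__all__ = ["TestResult", "IntervalResult", "permutation_test",
           "bootstrap_ci", "bonferroni_adjust"]

EXHAUSTIVE_LIMIT = 100_000


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    observed: float
    p_value: float
    n_resamples: int
    tails: int
    seed: int | None
    mode: str = "monte_carlo"        # or "exhaustive"
    degenerate: bool = False


@dataclass(frozen=True)
class IntervalResult:
    statistic_name: str
    estimate: float
    lower: float
    upper: float
    level: float
    n_resamples: int
    seed: int | None


def _stat_func(statistic):
    if callable(statistic):
        return statistic, getattr(statistic, "__name__", "custom")
    if statistic in ("mean", "mean-difference"):
        return (lambda v, axis=-1: np.mean(v, axis=axis)), "mean-difference"
    if statistic in ("median", "median-difference"):
        return (lambda v, axis=-1: np.median(v, axis=axis)), "median-difference"
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_test(
    a,
    b,
    statistic: str = "mean",
    n_resamples: int = 10_000,
    tails: int = 2,
    rng: np.random.Generator | int | None = None,
    exhaustive: bool | None = None,
) -> TestResult:
    """Two-sample permutation test of a difference in mean or median.

    Pooled observations are randomly relabeled into groups of the original
    sizes; the two-tailed p-value counts resampled |T*| at least as large as
    the observed |T|. ``exhaustive=None`` switches to full enumeration
    automatically when the number of distinct splits is at most 1e5; the
    enumerated p-value is the exact fraction of splits. When cluster-level
    observations share a sampling unit (e.g., a nucleus or a simulation),
    aggregate per unit before calling, so relabeling respects the unit.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    func, name = _stat_func(statistic)
    observed = float(func(a) - func(b))
    pooled = np.concatenate([a, b])
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)

    if np.all(pooled == pooled[0]):
        return TestResult(name, observed, 1.0, 0, tails, seed,
                          mode="degenerate", degenerate=True)

    def extremity(t_star: np.ndarray) -> np.ndarray:
        if tails == 2:
            return np.abs(t_star) >= abs(observed) - 1e-12
        if tails == 1:
            return t_star >= observed - 1e-12
        raise ValueError("tails must be 1 or 2")

    n_a, n = a.size, pooled.size
    if exhaustive is None:
        exhaustive = math.comb(n, n_a) <= EXHAUSTIVE_LIMIT
    if exhaustive:
        t_star = []
        idx_all = np.arange(n)
        for combo in combinations(range(n), n_a):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            t_star.append(func(pooled[sel]) - func(pooled[~sel]))
        t_star = np.asarray(t_star)
        p = float(np.mean(extremity(t_star)))
        return TestResult(name, observed, p, len(t_star), tails, seed,
                          mode="exhaustive")

    if tails == 2:
        # canonical split: permute the sorted pool into (smaller, rest)
        # groups; |mean_S - mean_Sc| is invariant under complementation, so
        # the two-tailed p-value is exactly label-exchange symmetric
        k = min(n_a, n - n_a)
        base = np.sort(pooled)
    else:
        k = n_a
        base = pooled
    perm = rng.permuted(np.tile(base, (n_resamples, 1)), axis=1)
    t_star = func(perm[:, :k], axis=1) - func(perm[:, k:], axis=1)
    p = float((1 + np.count_nonzero(extremity(t_star))) / (1 + n_resamples))
    return TestResult(name, observed, p, n_resamples, tails, seed)


def bootstrap_ci(
    sample,
    statistic: str = "median",
    n_resamples: int = 10_000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
    method: str = "percentile",
) -> IntervalResult:
    """Bootstrap confidence interval (percentile method by default).

    The sample is resampled with replacement ``n_resamples`` times and the
    interval is read off the percentiles of the resampled statistic. The
    bias-corrected accelerated variant is available via ``method='bca'``.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size == 0:
        raise ValueError("sample must be non-empty")
    func, name = _stat_func(statistic)
    name = name.replace("-difference", "")
    estimate = float(func(sample))
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)
    if method == "bca":
        res = _scipy_stats.bootstrap(
            (sample,), lambda v, axis=-1: func(v, axis=axis),
            n_resamples=n_resamples, confidence_level=level,
            method="BCa", rng=rng)
        lo, hi = float(res.confidence_interval.low), \
            float(res.confidence_interval.high)
    elif method == "percentile":
        idx = rng.integers(0, sample.size, size=(n_resamples, sample.size))
        t_star = func(sample[idx], axis=1)
        alpha = (1 - level) / 2
        lo = float(np.quantile(t_star, alpha))
        hi = float(np.quantile(t_star, 1 - alpha))
    else:
        raise ValueError(f"unknown method {method!r}")
    lo = min(lo, estimate)
    hi = max(hi, estimate)
    return IntervalResult(name, estimate, lo, hi, level, n_resamples, seed)


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m
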