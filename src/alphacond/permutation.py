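"""Per-sample paired t-tests with tmax/tmin permutation FWER control.

The contrast is the per-subject difference of the CS+ and CS− alpha
time series (both members of each contingency level averaged first).
In a paired design the only exchangeable relabeling is an independent
per-subject swap of the two conditions, i.e. a sign flip of that
subject's whole difference series.  Each permutation's t-series extrema
feed a t_min and a t_max null distribution; the 2.5th percentile of
t_min and the 97.5th percentile of t_max are the two-sided critical
values at α = 0.05, controlling the family-wise error rate across all
time samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PermutationResult:
    t_series: np.ndarray = field(repr=False)
    t_crit_low: float
    t_crit_high: float
    n_perm: int
    alpha: float
    sig_mask: np.ndarray = field(repr=False)
    windows: list[tuple[float, float]]
    seed: int | None = None


def samplewise_t(diffs: np.ndarray) -> np.ndarray:
    """One-sample t statistic per time sample of (subjects, time) diffs.

    Zero-variance samples yield ±inf (or NaN when the mean is also 0);
    they are flagged with a warning rather than raising.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for a t statistic")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    if np.any(sd == 0):
        warnings.warn("zero-variance time samples produced non-finite t",
                      RuntimeWarning, stacklevel=2)
        with np.errstate(invalid="ignore"):
            t = np.where(sd == 0,
                         np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)
    return t


def _t_from_signs(signs: np.ndarray, diffs: np.ndarray) -> np.ndarray:
    """t-series for many sign patterns at once.

    Sign flips leave each subject's squared value unchanged, so the
    per-permutation variance follows from the permuted mean alone:
    Σ(s_i d_i − m)² = Σ d_i² − n m².
    """
    n = diffs.shape[0]
    sumsq = np.sum(diffs**2, axis=0)  # (time,)
    means = signs @ diffs / n         # (perm, time)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (sumsq[None, :] - n * means**2) / (n - 1)
        var = np.maximum(var, 0.0)
        t = means / np.sqrt(var / n)
    return np.where(var == 0, np.where(means == 0, 0.0,
                                       np.inf * np.sign(means)), t)


def tmax_null(diffs: np.ndarray, n_perm: int = 1000,
              seed: int | None = None,
              include_identity: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Sign-flip null distributions of the t-series extrema.

    Returns ``(tmin_dist, tmax_dist)`` of length ``n_perm``.  With
    ``include_identity`` the first permutation is the observed labeling.
    """
    diffs = np.asarray(diffs, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = diffs.shape[0]
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
    if include_identity:
        signs[0] = 1.0
    t = _t_from_signs(signs, diffs)
    finite = np.isfinite(t)
    if not finite.all():
        warnings.warn("non-finite permutation t values excluded from extrema",
                      RuntimeWarning, stacklevel=2)
        t = np.where(finite, t, np.nan)
        return np.nanmin(t, axis=1), np.nanmax(t, axis=1)
    return t.min(axis=1), t.max(axis=1)


def exhaustive_signflip_oracle(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distributions from all 2^n sign patterns (n <= 20)."""
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n > 20:
        raise ValueError(f"exhaustive enumeration infeasible for n={n} (> 20)")
    bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
    signs = bits * 2.0 - 1.0
    t = _t_from_signs(signs, diffs)
    return t.min(axis=1), t.max(axis=1)


def critical_values(tmin_dist: np.ndarray, tmax_dist: np.ndarray,
                    alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided critical t values: α/2-tail percentiles of the extrema.

    Percentiles use linear interpolation between order statistics.
    """
    tmin_dist = np.asarray(tmin_dist, float)
    tmax_dist = np.asarray(tmax_dist, float)
    if tmin_dist.size == 0 or tmax_dist.size == 0:
        raise ValueError("empty null distribution")
    lo = float(np.nanpercentile(tmin_dist, 100 * alpha / 2))
    hi = float(np.nanpercentile(tmax_dist, 100 * (1 - alpha / 2)))
    return lo, hi


def significant_windows(t_series: np.ndarray, crits: tuple[float, float],
                        times: np.ndarray) -> tuple[np.ndarray, list]:
    """Mask of samples beyond the critical values and maximal runs in ms."""
    t_series = np.asarray(t_series, float)
    times = np.asarray(times, float)
    if len(t_series) != len(times):
        raise ValueError("t_series and times lengths differ")
    lo, hi = crits
    mask = (t_series < lo) | (t_series > hi)
    windows = []
    in_run = False
    for i, m in enumerate(mask):
        if m and not in_run:
            start = i
            in_run = True
        elif not m and in_run:
            windows.append((float(times[start]), float(times[i - 1])))
            in_run = False
    if in_run:
        windows.append((float(times[start]), float(times[-1])))
    return mask, windows


def permutation_test(diffs: np.ndarray, times: np.ndarray,
                     n_perm: int = 1000, alpha: float = 0.05,
                     seed: int | None = None,
                     include_identity: bool = False) -> PermutationResult:
    """Full per-sample tmax/tmin permutation test on paired differences."""
    t_obs = samplewise_t(diffs)
    tmin_d, tmax_d = tmax_null(diffs, n_perm=n_perm, seed=seed,
                               include_identity=include_identity)
    lo, hi = critical_values(tmin_d, tmax_d, alpha=alpha)
    mask, windows = significant_windows(t_obs, (lo, hi), times)
    return PermutationResult(t_obs, lo, hi, n_perm, alpha, mask, windows, seed)
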