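"""Intensity estimation, trend testing and single change-point detection.

The daily intensity lambda(t) (expected events/day) is estimated by a
centred moving average of the daily counts; the first and last s/2 days
are trimmed because the window does not fit there.  Trend is assessed
with the Cox-Stuart sign test and the location of a single change in
mean and variance with an at-most-one-change (AMOC) Gaussian
likelihood-ratio scan with an asymptotic penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_events import DailyCountSeries
from .result import TestResult

__all__ = [
    "IntensityEstimate",
    "ChangePointResult",
    "moving_average_intensity",
    "cox_stuart_test",
    "amoc_changepoint",
]

MA_WINDOWS = (30, 60, 90, 180, 365, 730)


@dataclass(frozen=True)
class IntensityEstimate:
    """Smoothed rate lambda-hat(t) with its trimming convention.

    ``values[i]`` estimates the intensity on original day
    ``first_day + i``; the estimate covers days s//2+1 .. T-s//2 (up to
    the half-day centring of an even window) of a series of length T.
    """

    values: np.ndarray
    window_s: int
    source_T: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any():
            raise ValueError("intensity values must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def first_day(self) -> int:
        return (self.window_s + 1) // 2 + 1

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    def cumulative(self) -> np.ndarray:
        """Integrated intensity Lambda(t) over the trimmed range."""
        return np.cumsum(self.values)

    def to_original_day(self, i: int) -> int:
        """Map a 1-based index of ``values`` back to the raw day axis."""
        return i + (self.window_s + 1) // 2


@dataclass(frozen=True)
class ChangePointResult:
    tau: int
    pre_mean: float
    post_mean: float
    significant: bool
    statistic: float = float("nan")
    threshold: float = float("nan")


def moving_average_intensity(s: DailyCountSeries, window_s: int) -> IntensityEstimate:
    """Centred moving average of the daily counts, trimmed at both ends.

    ``window_s`` must be smaller than the series length.  The result has
    length T - window_s: day t in s//2+1 .. T-s//2 averages the window
    of ``window_s`` days around t (for odd windows the window is
    symmetric; for even ones it extends one day further forward).
    """
    if window_s < 2:
        raise ValueError("window_s must be at least 2")
    if window_s >= s.T:
        raise ValueError(f"window {window_s} >= series length {s.T}")
    ma = np.convolve(s.counts.astype(float),
                     np.ones(window_s) / window_s, mode="valid")
    # 'valid' yields T - s + 1 values; dropping the first aligns value i
    # (0-based) with original day s/2 + 1 + i, i.e. days s/2+1 .. T-s/2.
    return IntensityEstimate(values=ma[1:], window_s=window_s, source_T=s.T)


def cox_stuart_test(x: np.ndarray,
                    alternative: str = "decreasing") -> TestResult:
    """Cox-Stuart sign test for monotone trend.

    Pairs x_i with x_{i + ceil(n/2)} (the middle element is dropped for
    odd n), counts the sign of each difference and applies an exact
    binomial(m, 1/2) test on the non-tied pairs.  Smoothed inputs are
    serially correlated, which makes the reported p-value conservative
    rather than exact; it is reported as-is.
    """
    if alternative not in ("decreasing", "increasing", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    c = (n + 1) // 2
    first = x[: n // 2]
    second = x[c: c + n // 2]
    diffs = second - first
    signs = np.sign(diffs)
    m = int((signs != 0).sum())
    if m == 0:
        raise ValueError("all pairs tied; trend test undefined")
    n_neg = int((signs < 0).sum())
    alt = {"decreasing": "greater", "increasing": "less",
           "two_sided": "two-sided"}[alternative]
    bt = stats.binomtest(n_neg, m, 0.5, alternative=alt)
    return TestResult(
        method="cox_stuart",
        statistic=float(n_neg),
        p_value=float(bt.pvalue),
        n=n,
        extras={"n_pairs": m, "alternative": alternative},
    )


def _segment_cost(csum: np.ndarray, csum2: np.ndarray,
                  lo: int, hi: int) -> float:
    """-2 x Gaussian profile log-likelihood (up to constants) of x[lo:hi]."""
    n = hi - lo
    s1 = csum[hi] - csum[lo]
    s2 = csum2[hi] - csum2[lo]
    var = s2 / n - (s1 / n) ** 2
    var = max(var, 1e-300)
    return n * np.log(var)


def amoc_changepoint(x: np.ndarray, alpha: float = 0.05,
                     min_seg: int = 2) -> ChangePointResult:
    """At-most-one-change scan for a joint shift in mean and variance.

    For every admissible split point tau the Gaussian likelihood-ratio
    gain of modelling x[1..tau] and x[tau+1..n] with separate means and
    variances is computed; the maximising tau is reported.  Significance
    uses the extreme-value asymptotic threshold for the mean+variance
    likelihood-ratio statistic at confidence 1 - alpha.

    ``min_seg`` excludes split points leaving either segment shorter
    than that many observations.  On smoothed series this matters: a
    stretch shorter than the smoothing window is built from almost
    wholly shared data, so its near-zero sample variance would otherwise
    dominate the likelihood-ratio scan.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0.0:
        return ChangePointResult(tau=0, pre_mean=float(x[0]),
                                 post_mean=float(x[0]), significant=False)
    lo = max(2, min_seg)
    if n - 2 * lo < 1:
        raise ValueError("min_seg leaves no admissible split point")
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x * x)))
    full = _segment_cost(csum, csum2, 0, n)
    taus = np.arange(lo, n - lo + 1)
    gains = np.empty(taus.shape[0])
    for j, t in enumerate(taus):
        gains[j] = full - (_segment_cost(csum, csum2, 0, t)
                           + _segment_cost(csum, csum2, t, n))
    best = int(np.argmax(gains))
    tau = int(taus[best])
    lr = float(gains[best])  # 2 x log-likelihood gain

    # Asymptotic critical value for the max-LR statistic with p = 2
    # changing parameters (Gumbel limit of the scan maximum).
    loglog = np.log(np.log(n))
    a_n = np.sqrt(2.0 * loglog)
    b_n = 2.0 * loglog + np.log(loglog)
    x_alpha = -np.log(-0.5 * np.log(1.0 - alpha))
    threshold = ((x_alpha + b_n) / a_n) ** 2

    return ChangePointResult(
        tau=tau,
        pre_mean=float(x[:tau].mean()),
        post_mean=float(x[tau:].mean()),
        significant=bool(lr > threshold),
        statistic=lr,
        threshold=float(threshold),
    )


def changepoint_on_intensity(est: IntensityEstimate,
                             alpha: float = 0.05) -> ChangePointResult:
    """AMOC on a smoothed intensity, with tau on the original day axis.

    Candidate splits leaving a segment shorter than the smoothing
    window are excluded (see ``amoc_changepoint``).
    """
    res = amoc_changepoint(est.values, alpha=alpha, min_seg=est.window_s)
    return ChangePointResult(
        tau=est.to_original_day(res.tau),
        pre_mean=res.pre_mean,
        post_mean=res.post_mean,
        significant=res.significant,
        statistic=res.statistic,
        threshold=res.threshold,
    )
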