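"""Homogeneous Poisson model fit and its goodness-of-fit battery.

Under a day-discretized homogeneous Poisson process the daily counts
are i.i.d. Poisson(lambda) and the whole-day inter-arrival gaps are
geometric on {0, 1, 2, ...} with p = 1 - exp(-lambda).  This module
estimates lambda, tabulates observed vs expected daily-count
frequencies, and tests the Poisson count distribution (Pearson chi2 and
a Cameron-Trivedi dispersion test) and the geometric gap distribution
(chi2 with tail pooling, optionally merging the 0- and 1-day categories
to soften the daily-discretization artifact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_events import DailyCountSeries, InterArrivalSeries
from .result import TestResult

__all__ = [
    "RateEstimate",
    "FrequencyTable",
    "GeometricFit",
    "estimate_rate",
    "poisson_expected_frequencies",
    "poisson_chisq_gof",
    "dispersion_test",
    "geometric_gof",
]


@dataclass(frozen=True)
class RateEstimate:
    """Maximum-likelihood event rate: sample mean of the daily counts."""

    lambda_hat: float
    n_events: int
    n_days: int


@dataclass(frozen=True)
class FrequencyTable:
    """Observed vs expected number of days with k events, k = 0..k_max."""

    ks: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    tail_expected: float  # expected mass at k > k_max

    def as_rows(self) -> list[dict]:
        return [{"k": int(k), "observed": int(o), "expected": float(e)}
                for k, o, e in zip(self.ks, self.observed, self.expected)]


@dataclass(frozen=True)
class GeometricFit:
    """Geometric gap model with p = 1 - exp(-lambda)."""

    p: float
    merge_first_two: bool = False

    @classmethod
    def from_rate(cls, lam: float, merge_first_two: bool = False) -> "GeometricFit":
        if lam < 0:
            raise ValueError("rate must be non-negative")
        return cls(p=float(1.0 - np.exp(-lam)), merge_first_two=merge_first_two)


def estimate_rate(s: DailyCountSeries) -> RateEstimate:
    """ML rate estimate: total events / total days."""
    if s.T < 1:
        raise ValueError("empty series")
    return RateEstimate(lambda_hat=s.total / s.T, n_events=s.total, n_days=s.T)


def poisson_expected_frequencies(r: RateEstimate, k_max: int = 4) -> FrequencyTable:
    """Expected number of days with exactly k events, k = 0..k_max."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    ks = np.arange(k_max + 1)
    pmf = stats.poisson.pmf(ks, r.lambda_hat)
    expected = r.n_days * pmf
    return FrequencyTable(
        ks=ks,
        observed=np.zeros_like(ks),
        expected=expected,
        tail_expected=float(r.n_days * stats.poisson.sf(k_max, r.lambda_hat)),
    )


def observed_frequencies(s: DailyCountSeries, k_max: int | None = None) -> FrequencyTable:
    """Observed and Poisson-expected daily-count frequency table."""
    r = estimate_rate(s)
    km = int(s.counts.max()) if k_max is None else k_max
    km = max(km, 1)
    obs = np.bincount(s.counts, minlength=km + 1)[: km + 1]
    tab = poisson_expected_frequencies(r, km)
    return FrequencyTable(ks=tab.ks, observed=obs, expected=tab.expected,
                          tail_expected=tab.tail_expected)


def _pool_tail(observed: np.ndarray, expected: np.ndarray,
               min_expected: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Merge the highest categories until every expected cell >= min_expected.

    The last expected cell is an open tail (already includes the mass
    above the largest tabulated value)."""
    obs = observed.astype(float).copy()
    exp = expected.copy()
    while exp.shape[0] > 1 and exp.min() < min_expected:
        obs[-2] += obs[-1]
        exp[-2] += exp[-1]
        obs, exp = obs[:-1], exp[:-1]
    return obs, exp


def poisson_chisq_gof(s: DailyCountSeries) -> TestResult:
    """Pearson chi2 of daily-count frequencies against Poisson(ML lambda).

    The open tail beyond the largest observed count is folded into the
    top category; high categories are pooled until every expected cell
    is at least 1.  Degrees of freedom subtract one for the estimated
    rate: df = (#cells - 1) - 1.
    """
    if np.unique(s.counts).shape[0] < 2:
        raise ValueError("degenerate series: fewer than 2 distinct counts")
    r = estimate_rate(s)
    kmax = int(s.counts.max())
    obs = np.bincount(s.counts, minlength=kmax + 1).astype(float)
    exp = r.n_days * stats.poisson.pmf(np.arange(kmax + 1), r.lambda_hat)
    exp[-1] += r.n_days * stats.poisson.sf(kmax, r.lambda_hat)  # open tail
    obs, exp = _pool_tail(obs, exp)
    if obs.shape[0] < 3:
        raise ValueError("fewer than 3 cells after pooling; chi2 undefined "
                         "with an estimated rate")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.shape[0] - 2
    return TestResult(method="chisq_poisson", statistic=chi2,
                      p_value=float(stats.chi2.sf(chi2, df)), n=s.T,
                      extras={"df": df, "n_cells": obs.shape[0],
                              "lambda_hat": r.lambda_hat})


def dispersion_test(s: DailyCountSeries) -> TestResult:
    """Cameron-Trivedi test of Poisson equidispersion.

    Tests H0: Var = mu against Var = mu + alpha*mu via the auxiliary
    statistic z_i = ((y_i - ybar)^2 - y_i) / ybar under a constant-mean
    model; the test statistic is sqrt(n) * mean(z) / sd(z), asymptotically
    standard normal.  Two-sided p-value (over- or under-dispersion).
    """
    if s.T < 30:
        raise ValueError("need at least 30 days")
    y = s.counts.astype(float)
    mu = y.mean()
    if mu == 0:
        raise ValueError("all-zero series")
    aux = ((y - mu) ** 2 - y) / mu
    z = np.sqrt(s.T) * aux.mean() / aux.std(ddof=1)
    return TestResult(method="poisson_dispersion", statistic=float(z),
                      p_value=float(2.0 * stats.norm.sf(abs(z))), n=s.T,
                      extras={"mean": mu, "variance": float(y.var(ddof=1))})


def geometric_gof(t: InterArrivalSeries, fit: GeometricFit) -> TestResult:
    """Chi2 goodness of fit of the whole-day gaps to geom(p) on {0,1,2,...}.

    The open tail is pooled so every expected cell is at least 1.  When
    ``fit.merge_first_two`` the 0- and 1-day categories are combined
    before testing (two events recorded one day apart may be only hours
    apart, so the daily grid piles extra mass on those two cells).
    One degree of freedom is subtracted for the rate estimated from the
    same series.
    """
    if t.n < 20:
        raise ValueError("need at least 20 gaps")
    p = fit.p
    if not 0.0 < p < 1.0:
        raise ValueError("geometric parameter must be in (0, 1)")
    gaps = t.gaps
    kmax = int(gaps.max())
    obs = np.bincount(gaps, minlength=kmax + 1).astype(float)
    # geom on {0,1,...}: pmf(k) = p (1-p)^k
    pmf = p * (1.0 - p) ** np.arange(kmax + 1)
    exp = t.n * pmf
    exp[-1] += t.n * (1.0 - p) ** (kmax + 1)  # open tail
    if fit.merge_first_two and obs.shape[0] >= 2:
        obs = np.concatenate(([obs[0] + obs[1]], obs[2:]))
        exp = np.concatenate(([exp[0] + exp[1]], exp[2:]))
    obs, exp = _pool_tail(obs, exp)
    if obs.shape[0] < 3:
        raise ValueError("fewer than 3 cells after pooling")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.shape[0] - 2
    return TestResult(method="chisq_geometric_times", statistic=chi2,
                      p_value=float(stats.chi2.sf(chi2, df)), n=t.n,
                      extras={"df": df, "n_cells": obs.shape[0], "p": p,
                              "merged_first_two": fit.merge_first_two})
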