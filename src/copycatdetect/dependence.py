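"""Autocorrelation diagnostics and Ljung-Box portmanteau tests.

Applied to the daily count series ("events") and to the whole-day gap
sequence ("times").  Lags 7 and 14 correspond to one and two weekly
periods and cover the contagion windows considered in the imitation
literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import acf as _sm_acf, pacf as _sm_pacf

from .result import TestResult

__all__ = ["Correlogram", "acf", "ljung_box"]

DEFAULT_LAGS = (7, 14)


@dataclass(frozen=True)
class Correlogram:
    """Sample (partial) autocorrelations at lags 1..L with a white-noise
    confidence band +/- z_{1-alpha/2} / sqrt(n)."""

    lags: np.ndarray
    values: np.ndarray
    band: float
    partial: bool

    def exceedances(self) -> np.ndarray:
        """Lags whose autocorrelation falls outside the band."""
        return self.lags[np.abs(self.values) > self.band]


def acf(x: np.ndarray, L: int, partial: bool = False,
        alpha: float = 0.05) -> Correlogram:
    """Sample ACF (denominator-n convention) or PACF at lags 1..L."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= L:
        raise ValueError(f"need more than L={L} observations")
    if np.ptp(x) == 0.0:
        raise ValueError("autocorrelation undefined for a constant series")
    if partial:
        vals = _sm_pacf(x, nlags=L, method="ldb")[1:]
    else:
        vals = _sm_acf(x, nlags=L, adjusted=False)[1:]
    band = float(stats.norm.ppf(1.0 - alpha / 2.0) / np.sqrt(n))
    return Correlogram(lags=np.arange(1, L + 1), values=np.asarray(vals),
                       band=band, partial=partial)


def ljung_box(x: np.ndarray, L: int) -> TestResult:
    """Ljung-Box portmanteau test that the first L autocorrelations are 0.

    Q = n(n+2) sum_{k<=L} r_k^2 / (n-k), referred to chi2(L); no degrees
    of freedom are subtracted (fitdf = 0, raw-series screening).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= L:
        raise ValueError(f"need more than L={L} observations")
    if np.ptp(x) == 0.0:
        raise ValueError("constant series")
    r = _sm_acf(x, nlags=L, adjusted=False)[1:]
    q = float(n * (n + 2) * np.sum(r ** 2 / (n - np.arange(1, L + 1))))
    return TestResult(method="ljung_box", statistic=q,
                      p_value=float(stats.chi2.sf(q, L)), n=n,
                      extras={"lags": L})
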