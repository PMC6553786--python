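"""Uniformity, runs and rank-based group-comparison tests.

Event times (day indices with multiplicity) are tested against a
continuous Uniform(0, T] null with the classical one-sample
Kolmogorov-Smirnov, Cramer-von Mises and Anderson-Darling statistics.
Daily discretization induces ties; the continuous-case p-values are
then conservative, which is documented rather than corrected (an
optional seeded within-day jitter is available).  Randomness of the
binarized series is checked with a Wald-Wolfowitz runs test, and
calendar groups are compared with Dunn's rank-based multiple
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .core_events import BinarySeries, EventCalendar, DailyCountSeries, GroupedSamples
from .result import TestResult

__all__ = [
    "uniformity_test",
    "runs_test",
    "dunn_test",
    "PairwiseComparisonTable",
    "anderson_darling_uniform",
]

UNIFORMITY_METHODS = ("KS", "CVM", "AD")


def _ad_pvalue_asymptotic(z: float) -> float:
    """P(A2 > z) from the asymptotic null distribution of the one-sample
    Anderson-Darling statistic with fully specified null (Marsaglia &
    Marsaglia's rational approximation to the limit law)."""
    if z <= 0.0:
        return 1.0
    if z < 2.0:
        cdf = (np.exp(-1.2337141 / z) / np.sqrt(z)
               * (2.00012 + (0.247105 - (0.0649821 - (0.0347962
                  - (0.011672 - 0.00168691 * z) * z) * z) * z) * z))
    else:
        cdf = np.exp(-np.exp(1.0776 - (2.30695 - (0.43424 - (0.082433
                     - (0.008056 - 0.0003146 * z) * z) * z) * z) * z))
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


def anderson_darling_uniform(u: np.ndarray) -> tuple[float, float]:
    """A2 statistic and asymptotic p-value for u ~ Uniform(0, 1)."""
    u = np.sort(np.asarray(u, dtype=float))
    n = u.shape[0]
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(u) + np.log(1.0 - u[::-1])))
    return float(a2), _ad_pvalue_asymptotic(float(a2))


def uniformity_test(cal: EventCalendar | DailyCountSeries,
                    method: str = "KS",
                    jitter_seed: int | None = None) -> TestResult:
    """Goodness of fit of event times against Uniform(0, T].

    ``method`` is one of KS, CVM, AD.  By default the raw integer day
    indices are used; passing ``jitter_seed`` adds a seeded uniform
    within-day offset in (-1, 0] to break the daily ties.
    """
    if method not in UNIFORMITY_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {UNIFORMITY_METHODS}")
    if isinstance(cal, DailyCountSeries):
        days, T = cal.event_days().astype(float), cal.T
    else:
        days, T = cal.day_indices().astype(float), cal.n_days
    n = days.shape[0]
    if n < 5:
        raise ValueError("need at least 5 events")
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        days = days - rng.uniform(0.0, 1.0, size=n)
    u = days / T
    if method == "KS":
        res = stats.kstest(u, stats.uniform.cdf)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "CVM":
        res = stats.cramervonmises(u, stats.uniform.cdf)
        stat, p = float(res.statistic), float(min(res.pvalue, 1.0))
    else:
        stat, p = anderson_darling_uniform(u)
    return TestResult(method=f"uniformity_{method}", statistic=stat,
                      p_value=p, n=n, extras={"T": T, "jittered": jitter_seed is not None})


def runs_test(b: BinarySeries, continuity_correction: bool = False) -> TestResult:
    """Wald-Wolfowitz runs test for randomness of a 0/1 sequence.

    Normal approximation: z = (R - E[R]) / sd[R] with
    E[R] = 1 + 2 n0 n1 / n.  No continuity correction by default.
    """
    bits = b.bits
    n = bits.shape[0]
    n1 = int(bits.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("runs test needs both symbols present")
    runs = int(1 + (np.diff(bits) != 0).sum())
    mu = 1.0 + 2.0 * n0 * n1 / n
    var = 2.0 * n0 * n1 * (2.0 * n0 * n1 - n) / (n ** 2 * (n - 1))
    dev = runs - mu
    if continuity_correction and abs(dev) > 0.5:
        dev -= 0.5 * np.sign(dev)
    z = dev / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(method="runs", statistic=float(z), p_value=float(min(p, 1.0)),
                      n=n, extras={"runs": runs, "expected_runs": mu,
                                   "n0": n0, "n1": n1})


@dataclass(frozen=True)
class PairwiseComparisonTable:
    """One row per unordered group pair of a Dunn multiple comparison."""

    pairs: tuple[tuple[str, str, float, float, float], ...]
    adjustment: str
    kruskal_p: float

    def significant_pairs(self, alpha: float = 0.05,
                          adjusted: bool = True) -> list[tuple[str, str]]:
        return [(a, b) for (a, b, _, pu, pa) in self.pairs
                if (pa if adjusted else pu) < alpha]

    def as_rows(self) -> list[dict]:
        return [
            {"group_a": a, "group_b": b, "z": z,
             "p_unadjusted": pu, "p_adjusted": pa}
            for (a, b, z, pu, pa) in self.pairs
        ]


def dunn_test(g: GroupedSamples, adjustment: str = "bonferroni") -> PairwiseComparisonTable:
    """Dunn's post-hoc pairwise comparison on jointly ranked daily counts.

    All observations are ranked together (mid-ranks for ties); for each
    pair of groups

        z_ij = (Rbar_i - Rbar_j) /
               sqrt((N(N+1)/12 - sum(t^3 - t)/(12(N-1))) (1/n_i + 1/n_j))

    with a two-sided normal p-value.  Family-wise adjustment is
    Bonferroni by default; unadjusted p-values are always reported too.
    """
    labels = list(g.groups.keys())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g.groups[k], dtype=float) for k in labels]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    N = pooled.shape[0]
    ranks = stats.rankdata(pooled)
    # tie correction sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    var_factor = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    mean_ranks, sizes = {}, {}
    pos = 0
    for k, a in zip(labels, arrays):
        mean_ranks[k] = float(ranks[pos:pos + a.size].mean())
        sizes[k] = a.size
        pos += a.size
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(var_factor * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        p_adj = {"bonferroni": min(1.0, p * n_pairs), "none": p}[adjustment]
        rows.append((a, b, float(z), p, p_adj))
    kw = stats.kruskal(*arrays) if len(set(map(float, pooled))) > 1 else None
    return PairwiseComparisonTable(
        pairs=tuple(rows),
        adjustment=adjustment,
        kruskal_p=float(kw.pvalue) if kw is not None else 1.0,
    )
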