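import numpy as np
import pytest
from scipy import stats

from copycatdetect import (
    CopycatParams,
    count_filter,
    simulate_batch,
    simulate_copycat,
    simulate_homogeneous,
    simulate_nonhomogeneous,
)
from copycatdetect.intensity_trend import IntensityEstimate
from copycatdetect.simulate import calibrated_copycat_params, copycat_mean_rate


class TestHomogeneous:
    def test_zero_rate(self):
        assert simulate_homogeneous(0.0, 100, seed=0).total == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_homogeneous(-0.1, 10, seed=0)

    def test_seeded_reproducibility(self):
        a = simulate_homogeneous(0.2, 1000, seed=42)
        b = simulate_homogeneous(0.2, 1000, seed=42)
        c = simulate_homogeneous(0.2, 1000, seed=43)
        assert a.counts.tolist() == b.counts.tolist()
        assert a.counts.tolist() != c.counts.tolist()

    def test_total_within_poisson_interval(self):
        # P_H1 configuration: mean total 338, sd ~ sqrt(338)
        rng = np.random.default_rng(1)
        lam, T = 0.18664, 1811
        mean = lam * T
        inside = sum(
            abs(simulate_homogeneous(lam, T, rng).total - mean) <= 2 * np.sqrt(mean)
            for _ in range(500))
        assert inside / 500 >= 0.93

    def test_count_distribution_matches_poisson_pmf(self):
        s = simulate_homogeneous(0.3, 10**6, seed=2)
        obs = np.bincount(s.counts)
        exp = 10**6 * stats.poisson.pmf(np.arange(len(obs)), 0.3)
        exp[-1] += 10**6 * stats.poisson.sf(len(obs) - 1, 0.3)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, len(obs) - 1) > 0.001


class TestNonHomogeneous:
    def test_constant_intensity_matches_homogeneous_mean(self):
        est = IntensityEstimate(values=np.full(2000, 0.25), window_s=30,
                                source_T=2030)
        rng = np.random.default_rng(3)
        totals = [simulate_nonhomogeneous(est, rng).total for _ in range(300)]
        assert np.mean(totals) == pytest.approx(500, rel=0.02)

    def test_expected_total_is_cumulative_intensity(self):
        values = np.abs(np.sin(np.linspace(0, 7, 1500))) * 0.3
        est = IntensityEstimate(values=values, window_s=30, source_T=1530)
        rng = np.random.default_rng(4)
        totals = [simulate_nonhomogeneous(est, rng).total for _ in range(300)]
        assert np.mean(totals) == pytest.approx(values.sum(), rel=0.03)

    def test_step_intensity_recovered(self):
        values = np.concatenate([np.full(1000, 0.3), np.full(1000, 0.1)])
        est = IntensityEstimate(values=values, window_s=30, source_T=2030)
        rng = np.random.default_rng(5)
        first = np.mean([simulate_nonhomogeneous(est, rng).counts[:1000].mean()
                         for _ in range(500)])
        second = np.mean([simulate_nonhomogeneous(est, rng).counts[1000:].mean()
                          for _ in range(500)])
        assert first == pytest.approx(0.3, rel=0.05)
        assert second == pytest.approx(0.1, rel=0.05)


class TestCopycat:
    def test_delta_zero_law_equals_homogeneous(self):
        rng = np.random.default_rng(6)
        p = CopycatParams(delta=0.0, r=7, base_lambda=0.18664, T=1811)
        tot_c = [simulate_copycat(p, rng).total for _ in range(1000)]
        tot_h = [simulate_homogeneous(0.18664, 1811, rng).total
                 for _ in range(1000)]
        assert stats.ks_2samp(tot_c, tot_h).pvalue > 0.01

    def test_boosted_mean_rate_bounded(self):
        p = CopycatParams(delta=1.0, r=14, base_lambda=0.18664, T=1811)
        rate = copycat_mean_rate(p, n_pilot=50, seed=7)
        assert 0.18664 < rate <= 2 * 0.18664

    def test_lag1_autocorrelation_increases_with_delta(self):
        rng = np.random.default_rng(8)

        def mean_r1(delta):
            p = CopycatParams(delta=delta, r=3, base_lambda=0.18664, T=1811)
            r1 = []
            for _ in range(200):
                c = simulate_copycat(p, rng).counts.astype(float)
                c = c - c.mean()
                r1.append((c[:-1] * c[1:]).sum() / (c * c).sum())
            return np.mean(r1)

        r_small, r_large = mean_r1(0.1), mean_r1(1.0)
        assert 0 < r_small < r_large

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            CopycatParams(delta=-0.1, r=7, base_lambda=0.2, T=100)
        with pytest.raises(ValueError):
            CopycatParams(delta=0.5, r=0, base_lambda=0.2, T=100)


class TestCountFilter:
    def test_central_value_accepted_zero_rejected(self):
        from copycatdetect.core_events import DailyCountSeries
        lam, T = 0.18664, 1811
        counts = np.zeros(T, dtype=int)
        counts[: round(lam * T)] = 1  # total at the centre of Poisson(lam*T)
        assert count_filter(DailyCountSeries(counts=counts), lam)
        assert not count_filter(
            DailyCountSeries(counts=np.zeros(T, dtype=int)), lam)

    def test_acceptance_rate_near_95_percent(self):
        rng = np.random.default_rng(10)
        lam, T = 0.163, 4018
        kept = sum(count_filter(simulate_homogeneous(lam, T, rng), lam)
                   for _ in range(1000))
        assert 0.93 <= kept / 1000 <= 0.97


class TestBatch:
    def test_filtered_batch_all_pass(self):
        b = simulate_batch("homogeneous", 50, seed=11, filter_rate=0.163,
                           lam=0.163, T=4018)
        assert b.n_runs == 50
        assert all(count_filter(s, 0.163) for s in b.replicates)

    def test_resample_cap_raises(self):
        with pytest.raises(RuntimeError):
            simulate_batch("homogeneous", 10, seed=12, filter_rate=10.0,
                           max_attempts_factor=2, lam=0.1, T=500)

    def test_calibrated_copycat_matches_target_rate(self):
        target = 0.18664
        cp = calibrated_copycat_params(1.0, 14, target, 1811, seed=13)
        assert cp.base_lambda < target  # base deflated below the target
        rate = copycat_mean_rate(cp, n_pilot=100, seed=14)
        assert rate == pytest.approx(target, rel=0.05)
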