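import numpy as np
import pytest
from scipy import stats

from copycatdetect import (
    DailyCountSeries,
    ad2_events,
    chisq2_times,
    energy_test,
    inter_arrival_times,
    ks2_events,
    run_comparison_battery,
    simulate_homogeneous,
)
from copycatdetect.compare import batch_versus_medians, energy_statistic
from copycatdetect.core_events import InterArrivalSeries
from copycatdetect.simulate import simulate_batch


def brute_energy(x, y):
    n, m = len(x), len(y)
    dxy = np.abs(x[:, None] - y[None, :]).mean()
    dxx = np.abs(x[:, None] - x[None, :]).mean()
    dyy = np.abs(y[:, None] - y[None, :]).mean()
    return n * m / (n + m) * (2 * dxy - dxx - dyy)


class TestTwoSampleEvents:
    def test_series_vs_itself(self, homogeneous_series):
        res = ks2_events(homogeneous_series, homogeneous_series)
        assert res.statistic == 0.0 and res.p_value == 1.0
        ad = ad2_events(homogeneous_series, homogeneous_series)
        assert ad.p_value == 1.0

    def test_matched_null_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            a = simulate_homogeneous(0.163, 4018, rng)
            b = simulate_homogeneous(0.163, 4018, rng)
            ps.append(ks2_events(a, b).p_value)
        assert 0.4 <= np.median(ps) <= 0.6

    def test_shifted_samples_rejected(self):
        counts_a = np.zeros(1000, dtype=int)
        counts_b = np.zeros(1000, dtype=int)
        counts_a[:100] = 1
        counts_b[-100:] = 1
        a, b = DailyCountSeries(counts=counts_a), DailyCountSeries(counts=counts_b)
        assert ks2_events(a, b).p_value < 1e-6
        assert ad2_events(a, b).p_value == pytest.approx(0.001)

    def test_length_mismatch(self, homogeneous_series):
        short = DailyCountSeries(counts=homogeneous_series.counts[:100])
        with pytest.raises(ValueError):
            ks2_events(homogeneous_series, short)

    def test_ad_pvalue_unclipped_above_quarter(self):
        # scipy clips the AD p-value at 0.25; the extrapolated value must
        # be able to exceed it for clearly similar samples
        rng = np.random.default_rng(1)
        ps = [ad2_events(simulate_homogeneous(0.163, 4018, rng),
                         simulate_homogeneous(0.163, 4018, rng)).p_value
              for _ in range(50)]
        assert np.median(ps) > 0.3


class TestChisqTimes:
    def test_identical_gap_multisets(self):
        g = InterArrivalSeries(gaps=np.tile([0, 1, 2, 5, 9], 8))
        res = chisq2_times(g, g)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_power_on_different_geometrics(self):
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(40):
            a = InterArrivalSeries(gaps=rng.geometric(0.17, 300) - 1)
            b = InterArrivalSeries(gaps=rng.geometric(0.05, 300) - 1)
            rejections += chisq2_times(a, b).p_value < 0.05
        assert rejections >= 36

    def test_too_few_gaps(self):
        g = InterArrivalSeries(gaps=np.arange(5))
        with pytest.raises(ValueError):
            chisq2_times(g, g)


class TestEnergy:
    def test_zero_statistic_on_identical_samples(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert energy_statistic(x, x.copy()) == pytest.approx(0.0, abs=1e-12)
        res = energy_test(x, x.copy(), n_perm=99, seed=0)
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_statistic_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=15), rng.normal(1.0, 2.0, size=9)
        assert energy_statistic(x, y) == pytest.approx(
            brute_energy(x, y), abs=1e-9)

    def test_separated_normals_always_detected(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            x, y = rng.normal(size=50), rng.normal(3.0, 1.0, size=50)
            assert energy_test(x, y, n_perm=199, seed=rng).p_value <= 0.01

    def test_perm_count_floor(self):
        with pytest.raises(ValueError):
            energy_test(np.arange(5.0), np.arange(5.0), n_perm=10)


class TestBatteryProtocols:
    def test_matched_null_medians_central(self):
        rng = np.random.default_rng(4)
        real = simulate_homogeneous(0.18664, 1811, rng)
        batch = simulate_batch("homogeneous", 100, rng, lam=0.18664, T=1811)
        rep = batch_versus_medians(real, batch, "null", n_perm=99, seed=rng)
        meds = {r["test"]: r["median_p"] for r in rep.rows}
        for test, p in meds.items():
            assert 0.05 < p < 0.95, (test, p)

    def test_copycat_delta_zero_reproduces_homogeneous_row(self):
        rng = np.random.default_rng(5)
        rep_c = run_comparison_battery(
            None, {"generator": "copycat", "delta": 0.0, "r_grid": (3,),
                   "base_lambda": 0.18664, "T": 1811},
            n_runs=60, seed=rng, mode="self", lb_lags=(7,))
        rep_h = run_comparison_battery(
            None, {"generator": "homogeneous", "lam": 0.18664, "T": 1811,
                   "filter_rate": 0.18664},
            n_runs=60, seed=rng, mode="self", lb_lags=(7,))
        med_c = {r["test"]: r["median_p"] for r in rep_c.rows}
        med_h = {r["test"]: r["median_p"] for r in rep_h.rows}
        for test in ("uniformity_KS", "ljung_box_events_7", "runs"):
            assert med_c[test] == pytest.approx(med_h[test], abs=0.2)

    def test_versus_mode_needs_real_series(self):
        with pytest.raises(ValueError):
            run_comparison_battery(
                None, {"generator": "homogeneous", "lam": 0.2, "T": 300},
                n_runs=5, seed=0, mode="versus")
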