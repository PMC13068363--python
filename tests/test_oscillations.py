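import math

import numpy as np
import pytest
from scipy import stats as sp_stats

from protomorph.oscillations import (
    acf_spectrum,
    detrend,
    event_statistics,
    find_extrema,
    ks_shifted_exponential,
    poisson_chi2,
)
from protomorph.signals import TimeSeries
from protomorph.synth import (
    BurstSeriesParams,
    EventTrain,
    gen_burst_potential_series,
    gen_event_train,
)

#: prominence matched to the generator noise floor (5 x noise sd of 0.02 mV)
RECOVERY_PROMINENCE_MV = 0.1


class TestDetrend:
    def test_polynomial_degree_one_removes_ramp_exactly(self):
        t = np.arange(500.0)
        s = TimeSeries(t, 0.3 * t - 7.0)
        resid, baseline = detrend(s, "polynomial", 1)
        assert np.max(np.abs(resid.values)) < 1e-9
        assert np.allclose(baseline.values, s.values)

    def test_rolling_median_preserves_fast_sine_amplitude(self):
        t = np.arange(5000.0)
        sine = 2.0 * np.sin(2 * np.pi * t / 50.0)
        s = TimeSeries(t, sine + 0.01 * t)
        resid, _ = detrend(s, "rolling_median", 501)
        interior = resid.values[500:-500]
        assert np.max(interior) == pytest.approx(2.0, rel=0.05)

    def test_none_is_identity(self):
        s = TimeSeries(np.arange(10.0), np.random.default_rng(0).random(10))
        resid, baseline = detrend(s, "none")
        assert np.array_equal(resid.values, s.values)
        assert not baseline.values.any()

    def test_invalid_window_or_degree_raise(self):
        s = TimeSeries(np.arange(100.0), np.zeros(100))
        with pytest.raises(ValueError):
            detrend(s, "rolling_median", 10)  # even
        with pytest.raises(ValueError):
            detrend(s, "polynomial", 9)


class TestFindExtrema:
    def test_sinusoid_peak_count_and_periods(self):
        t = np.arange(1000.0)
        s = TimeSeries(t, np.sin(2 * np.pi * t / 100.0))
        ev = find_extrema(s, min_prominence_mv=0.5, min_separation_s=5.0)
        assert ev.n_peaks == 10
        assert ev.trough_times_s.size == 10
        assert np.allclose(ev.periods_s, 100.0)
        assert np.allclose(ev.frequencies_hz, 0.01)

    def test_monotone_ramp_has_no_peaks(self):
        s = TimeSeries(np.arange(100.0), np.arange(100.0))
        ev = find_extrema(s, min_prominence_mv=0.1)
        assert ev.n_peaks == 0

    def test_planted_bursts_recovered(self, burst_run_seed7):
        resid, _ = detrend(burst_run_seed7.series)
        ev = find_extrema(resid, RECOVERY_PROMINENCE_MV, 5.0)
        planted = burst_run_seed7.event_times_s
        d = np.abs(planted[:, None] - ev.peak_times_s[None, :]).min(axis=1)
        assert np.mean(d <= 5.0) >= 0.90

    @pytest.mark.parametrize("seed", [7, 11, 23])
    def test_counting_identities_on_burst_runs(self, seed):
        res = gen_burst_potential_series(BurstSeriesParams(seed=seed))
        resid, _ = detrend(res.series)
        ev = find_extrema(resid, RECOVERY_PROMINENCE_MV, 5.0)
        assert ev.periods_s.size == ev.n_peaks - 1
        assert ev.amplitudes_mv.size == ev.n_peaks - 2
        assert np.allclose(ev.frequencies_hz, 1.0 / ev.periods_s)

    def test_peaks_and_troughs_alternate(self, burst_run_seed7):
        resid, _ = detrend(burst_run_seed7.series)
        ev = find_extrema(resid, RECOVERY_PROMINENCE_MV, 5.0)
        merged = np.concatenate([ev.peak_times_s, ev.trough_times_s])
        kinds = np.concatenate([np.ones(ev.n_peaks),
                                -np.ones(ev.trough_times_s.size)])
        order = np.argsort(merged)
        assert np.all(np.abs(np.diff(kinds[order])) == 2)


class TestEventStatistics:
    def _events_from_periods(self, periods):
        # build a synthetic alternating saw signal with the desired periods
        peak_times = np.concatenate([[0.0], np.cumsum(periods)])
        t = np.arange(peak_times[-1] + 10.0)
        vals = np.zeros_like(t)
        for pt in peak_times:
            vals += np.exp(-((t - pt) ** 2) / 2.0)
        s = TimeSeries(t, vals)
        return find_extrema(s, min_prominence_mv=0.2, min_separation_s=1.0)

    def test_constant_periods_give_zero_spread(self):
        ev = self._events_from_periods(np.full(20, 10.0))
        stats = event_statistics(ev)
        assert stats["period"].mean == pytest.approx(10.0)
        assert stats["period"].std == pytest.approx(0.0, abs=1e-12)
        assert stats["frequency"].mean == pytest.approx(0.1)

    def test_mean_period_176s_implies_0057_hz(self):
        ev = self._events_from_periods(np.full(12, 176.361))
        stats = event_statistics(ev)
        assert stats["frequency"].mean == pytest.approx(0.0057, abs=5e-5)

    def test_lognormal_sample_is_right_skewed(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0, 1, 500)
        # oracle via direct sample moments
        assert sp_stats.skew(x) > 2
        ev_stats_skew = sp_stats.skew(x, bias=True)
        assert ev_stats_skew == pytest.approx(sp_stats.skew(x))

    def test_kurtosis_uses_pearson_convention_by_default(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200_00)
        from protomorph.oscillations import _dist_stats
        st = _dist_stats(x, fisher_kurtosis=False)
        assert st.kurtosis == pytest.approx(3.0, abs=0.1)


class TestShiftedExponentialKS:
    def test_fitted_scale_and_rate_from_moments(self):
        rng = np.random.default_rng(0)
        periods = 5.0 + rng.exponential(171.36, 509)
        periods[0] = 5.0  # pin the minimum
        res = ks_shifted_exponential(periods)
        assert res.params["loc_s"] == pytest.approx(5.0)
        assert res.params["scale_s"] == pytest.approx(
            periods.mean() - 5.0)
        assert res.params["lambda_hz"] == pytest.approx(
            1.0 / res.params["scale_s"])

    def test_gamma_intervals_are_rejected(self):
        train = gen_event_train("gamma", 0.01, 5e4, shape=3.0, seed=11)
        periods = np.diff(train.event_times_s)
        res = ks_shifted_exponential(periods)
        assert res.p_value < 0.01
        assert res.reject

    def test_degenerate_sample_raises(self):
        with pytest.raises(ValueError):
            ks_shifted_exponential(np.full(20, 10.0))


class TestPoissonChi2:
    def test_poisson_train_is_not_rejected_typically(self):
        train = gen_event_train("poisson", 0.01, 1e5, seed=3)
        res = poisson_chi2(train, bin_width_s=2.0)
        assert res.p_value > 0.05

    def test_clustered_train_is_rejected(self):
        train = gen_event_train("clustered", 0.002, 1e5, seed=3)
        res = poisson_chi2(train, bin_width_s=2.0)
        assert res.p_value < 0.01

    def test_lambda_hat_matches_event_density(self):
        # 511 events over 93,000 s in 2 s bins implies lambda-hat near 0.011
        train = gen_event_train("poisson", 511 / 93_000, 93_000.0, seed=2)
        res = poisson_chi2(train, bin_width_s=2.0)
        expected = len(train) * 2.0 / 93_000
        assert res.params["lambda_per_bin"] == pytest.approx(expected, rel=1e-6)
        assert res.params["lambda_per_bin"] == pytest.approx(0.011, abs=2e-3)

    def test_too_few_bins_raise(self):
        train = gen_event_train("poisson", 1.0, 30.0, seed=0)
        with pytest.raises(ValueError):
            poisson_chi2(train, bin_width_s=10.0)


class TestAcfSpectrum:
    def test_constant_series_is_pure_dc(self):
        s = TimeSeries(np.arange(200.0), np.full(200, 5.0))
        out = acf_spectrum(s, 50.0)
        assert out.dominant_freq_hz == 0.0

    def test_sine_dominant_frequency_within_one_bin(self):
        t = np.arange(10_000.0)
        s = TimeSeries(t, np.sin(2 * np.pi * 0.01 * t))
        out = acf_spectrum(s, 1000.0)
        assert abs(out.dominant_freq_hz - 0.01) <= 1.0 / t.size

    def test_ar1_decay_timescale_matches_closed_form(self):
        rng = np.random.default_rng(8)
        phi = 0.99
        n = 200_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        s = TimeSeries(np.arange(float(n)), x)
        out = acf_spectrum(s, 2000.0)
        expected = -1.0 / math.log(phi)
        assert out.decay_timescale_s == pytest.approx(expected, rel=0.2)

    def test_nonuniform_sampling_raises(self):
        s = TimeSeries(np.array([0.0, 1.0, 3.0, 7.0]), np.zeros(4))
        with pytest.raises(ValueError):
            acf_spectrum(s, 1.0)
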