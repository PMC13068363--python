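import math

import numpy as np
import pytest

from protomorph.synth import gen_voltammetry_fixtures
from protomorph.voltammetry import (
    CVCycleMetrics,
    cv_cycle_metrics,
    conditioning_report,
    dpv_metrics,
    dpv_theoretical_peak,
    entropy_rate,
    fit_auc_quadratic,
    fit_peak_decay,
    transfer_entropy,
)


def metrics_from_fixture(fx):
    return [
        cv_cycle_metrics(g["potential_v"].to_numpy(),
                         g["current_ua"].to_numpy(), int(c))
        for c, g in fx.cv_sweeps.groupby("cycle")
    ]


class TestCvCycleMetrics:
    def test_constant_current_closed_sweep_has_zero_area(self):
        e = np.concatenate([np.linspace(0.5, -0.5, 50),
                            np.linspace(-0.5, 0.5, 50)])
        m = cv_cycle_metrics(e, np.full(100, 3.0))
        assert m.auc_ua_v == pytest.approx(0.0, abs=1e-12)
        assert not m.open_loop

    def test_rectangular_loop_area(self):
        # +I0 forward over dV, -I0 backward: enclosed area 2 I0 dV
        e = np.concatenate([np.linspace(0, 1, 100), np.linspace(1, 0, 100)])
        i = np.concatenate([np.full(100, 2.0), np.full(100, -2.0)])
        m = cv_cycle_metrics(e, i)
        assert abs(m.auc_ua_v) == pytest.approx(2 * 2.0 * 1.0, rel=1e-2)

    def test_planted_extrema_recovered_from_sweep(self, voltammetry_noiseless):
        ms = metrics_from_fixture(voltammetry_noiseless)
        truth = voltammetry_noiseless.cv_truth
        assert ms[0].i_min_ua == pytest.approx(truth.i_min_ua.iloc[0])
        assert ms[0].i_max_ua == pytest.approx(truth.i_max_ua.iloc[0])
        assert ms[0].i_peak_abs_ua == pytest.approx(
            truth.i_peak_abs_ua.iloc[0])

    def test_open_loop_is_flagged(self):
        e = np.linspace(0, 1, 50)
        m = cv_cycle_metrics(e, np.sin(e))
        assert m.open_loop


class TestFitPeakDecay:
    def test_noiseless_constants_recovered(self, voltammetry_noiseless):
        y = voltammetry_noiseless.cv_truth.i_peak_abs_ua.to_numpy()
        fit = fit_peak_decay(y)
        assert fit.converged
        assert fit.amplitude_ua == pytest.approx(1531.22, rel=1e-3)
        assert fit.rate_per_cycle == pytest.approx(0.1889, rel=1e-3)
        assert fit.offset_ua == pytest.approx(58.43, rel=1e-3)

    def test_one_percent_noise_recovers_within_five_percent(self):
        fx = gen_voltammetry_fixtures(cv={"noise_frac": 0.01}, seed=5)
        fit = fit_peak_decay(fx.cv_truth.i_peak_abs_ua.to_numpy())
        assert fit.amplitude_ua == pytest.approx(1531.22, rel=0.05)
        assert fit.rate_per_cycle == pytest.approx(0.1889, rel=0.05)
        assert fit.offset_ua == pytest.approx(58.43, rel=0.05)

    def test_refit_of_own_model_is_fixed_point(self):
        cycles = np.arange(1, 41, dtype=float)
        y = 100.0 * np.exp(-0.3 * cycles) + 7.0
        fit = fit_peak_decay(y, cycles)
        refit = fit_peak_decay(
            fit.amplitude_ua * np.exp(-fit.rate_per_cycle * cycles)
            + fit.offset_ua, cycles)
        assert refit.amplitude_ua == pytest.approx(fit.amplitude_ua, abs=1e-8)
        assert refit.rate_per_cycle == pytest.approx(fit.rate_per_cycle,
                                                     abs=1e-8)

    def test_asymptote_equals_offset(self):
        cycles = np.arange(1, 31, dtype=float)
        y = 50.0 * np.exp(-0.4 * cycles) + 3.0
        fit = fit_peak_decay(y, cycles)
        limit = fit.amplitude_ua * math.exp(-fit.rate_per_cycle * 1e6) \
            + fit.offset_ua
        assert limit == pytest.approx(fit.offset_ua)

    def test_too_few_cycles_raise(self):
        with pytest.raises(ValueError):
            fit_peak_decay(np.array([3.0, 2.0, 1.5]))


class TestInformationMetrics:
    def test_constant_series_has_zero_entropy_rate(self):
        assert entropy_rate(np.full(1000, 4.2)) == 0.0

    def test_alternating_series_is_fully_predictable(self):
        x = np.tile([0.0, 1.0], 5000)
        assert entropy_rate(x, n_bins=2) == pytest.approx(0.0, abs=1e-12)

    def test_iid_uniform_entropy_rate_near_log2_bins(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 8, 100_000).astype(float)
        assert entropy_rate(x, n_bins=8) == pytest.approx(3.0, abs=0.02)

    def test_entropy_rate_bounded_by_log2_bins(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(5000)
        assert 0.0 <= entropy_rate(x, n_bins=8) <= 3.0

    def test_independent_series_report_zero_flow(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(100_000)
        x = rng.standard_normal(100_000)
        reported, raw, floor = transfer_entropy(y, x, n_bins=8, seed=1)
        assert raw <= 0.01
        assert reported == 0.0

    def test_copy_channel_carries_one_bit(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 100_000).astype(float)
        y = np.roll(x, 1)  # y_t = x_{t-1}
        reported, raw, _ = transfer_entropy(x, y, n_bins=2, seed=1)
        assert reported == pytest.approx(1.0, abs=0.02)

    def test_transfer_entropy_nonnegative_and_bounded(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(5000)
        x = 0.5 * np.roll(y, 1) + 0.5 * rng.standard_normal(5000)
        _, raw, _ = transfer_entropy(y, x, n_bins=4, seed=2)
        assert 0.0 <= raw <= entropy_rate(x, n_bins=4) + 1e-9

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            transfer_entropy(np.zeros(10), np.zeros(11))


class TestConditioningReport:
    def test_identical_channels_have_unit_correlation(self):
        cycles = np.arange(1, 31)
        peak = 100.0 * np.exp(-0.2 * cycles) + 10.0
        ms = [CVCycleMetrics(int(c), -p, p, p, p)
              for c, p in zip(cycles, peak)]
        fit, info = conditioning_report(ms)
        assert info.pearson_r == pytest.approx(1.0)
        assert info.lag1_autocorr > 0.99

    def test_independent_auc_reports_no_directed_flow(self):
        rng = np.random.default_rng(9)
        cycles = np.arange(1, 101)
        peak = 100.0 * np.exp(-0.1 * cycles) + 10.0
        ms = [CVCycleMetrics(int(c), -p, p, p, float(rng.standard_normal()))
              for c, p in zip(cycles, peak)]
        _, info = conditioning_report(ms, seed=3)
        assert info.transfer_entropy_bits == 0.0
        assert info.transfer_entropy_floor_bits > 0.0

    def test_too_few_cycles_raise(self):
        ms = [CVCycleMetrics(i, -1.0, 1.0, 1.0, 1.0) for i in range(5)]
        with pytest.raises(ValueError):
            conditioning_report(ms)


class TestDpv:
    def test_gaussian_bump_metrics(self):
        e = np.linspace(-4, 4, 801)
        i = 0.5 * np.exp(-((e + 0.3) ** 2) / (2 * 0.1**2))
        m = dpv_metrics(e, i, pulse_amplitude_v=0.5)
        assert m.peak_current_ma == pytest.approx(0.5, rel=1e-6)
        assert m.peak_potential_v == pytest.approx(-0.3, abs=0.011)
        assert not m.no_peak

    def test_flat_curve_is_flagged(self):
        e = np.linspace(-4, 4, 100)
        m = dpv_metrics(e, np.zeros(100), 0.1)
        assert m.no_peak
        assert m.auc_ma_v == 0.0

    def test_planted_endpoint_currents_recovered(self):
        fx = gen_voltammetry_fixtures(dpv={"amplitudes": [0.1, 1.0]})
        rows = [
            dpv_metrics(g["potential_v"].to_numpy(),
                        g["current_ma"].to_numpy(), a)
            for a, g in fx.dpv_curves.groupby("pulse_amplitude_v")
        ]
        truth = fx.dpv_truth
        for row, (_, tr) in zip(rows, truth.iterrows()):
            assert row.peak_current_ma == pytest.approx(tr.peak_current_ma,
                                                        rel=1e-6)
            assert row.auc_ma_v == pytest.approx(tr.auc_ma_v, rel=1e-3)


class TestQuadraticFit:
    def test_exact_parabola_recovered(self):
        x = np.linspace(0.1, 1.0, 10)
        y = 0.0725 * x**2 + 0.5165 * x + 0.0070
        fit = fit_auc_quadratic(x, y)
        assert fit.coeffs[0] == pytest.approx(0.0725, abs=1e-10)
        assert fit.coeffs[1] == pytest.approx(0.5165, abs=1e-10)
        assert fit.coeffs[2] == pytest.approx(0.0070, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_r_squared_identity(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 1, 20)
        y = x**2 + rng.normal(0, 0.1, 20)
        fit = fit_auc_quadratic(x, y)
        assert fit.r_squared == pytest.approx(1 - fit.rss / fit.tss)

    def test_noisy_coefficients_within_three_sd(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0.1, 1.0, 10)
        sigma = 0.02
        y = 0.0725 * x**2 + 0.5165 * x + 0.0070 + rng.normal(0, sigma, 10)
        fit = fit_auc_quadratic(x, y)
        # oracle: OLS coefficient sds from (X'X)^-1 sigma^2
        design = np.column_stack([x**2, x, np.ones_like(x)])
        cov = sigma**2 * np.linalg.inv(design.T @ design)
        sds = np.sqrt(np.diag(cov))
        truth = (0.0725, 0.5165, 0.0070)
        for c, t, sd in zip(fit.coeffs, truth, sds):
            assert abs(c - t) < 3 * sd

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_auc_quadratic(np.arange(3.0), np.arange(3.0))


class TestTheoreticalPeak:
    AREA = math.pi * (5e-6) ** 2

    def test_zero_pulse_amplitude_gives_zero_current(self):
        assert dpv_theoretical_peak(1, self.AREA, 1.0, 1e-9, 0.05, 0.0) == 0.0

    def test_linear_in_pulse_amplitude(self):
        i1 = dpv_theoretical_peak(1, self.AREA, 1.0, 1e-9, 0.05, 0.2)
        i2 = dpv_theoretical_peak(1, self.AREA, 1.0, 1e-9, 0.05, 0.4)
        assert i2 == pytest.approx(2 * i1)

    def test_10_micron_disc_area(self):
        # electrode diameter 0.01 mm -> radius 5e-6 m
        assert self.AREA == pytest.approx(7.85e-11, rel=1e-3)

    def test_invalid_pulse_width_raises(self):
        with pytest.raises(ValueError):
            dpv_theoretical_peak(1, self.AREA, 1.0, 1e-9, 0.0, 0.1)
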