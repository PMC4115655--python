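"""Autocorrelograms, the two-cosine skipping model fit, and derived indices."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import hdtheta as ht
from hdtheta.errors import InvalidArgumentError, UndefinedMetricError
from hdtheta.skipping import (Autocorrelogram, SkippingFit, model_curve,
                              oscillation_noise_floor)


def brute_force_autocorr(times, max_lag_ms=1000.0, bin_ms=1.0):
    """O(n^2) pair-count oracle."""
    times = np.asarray(times)
    n_half = int(round(max_lag_ms / bin_ms))
    counts = np.zeros(2 * n_half + 1)
    for i in range(times.size):
        for j in range(times.size):
            if i == j:
                continue
            lag = (times[j] - times[i]) * 1000.0
            idx = int(round(lag / bin_ms)) + n_half
            if 0 <= idx <= 2 * n_half and abs(lag) <= max_lag_ms + bin_ms / 2:
                k = int(round(lag / bin_ms))
                if abs(k) <= n_half:
                    counts[k + n_half] += 1
    return counts


def make_fit(**kw):
    base = dict(a1=10.0, a2=5.0, b=2.0, c1=1.0, c2=1.0,
                omega1=2 * math.pi * 8.0, omega2=2 * math.pi * 4.0,
                tau1=5000.0, tau2=20.0, tau3=3.0,
                residual_norm=0.0, converged=True, n_peak=100.0)
    base.update(kw)
    return SkippingFit(**base)


class TestISIHistogram:
    def test_point_mass_at_ten_ms(self):
        sp = ht.SpikeTrain("u", np.array([0.0, 0.010, 0.020]), 1.0)
        h = ht.isi_histogram(sp)
        assert h.counts[10] == 2 and h.counts.sum() == 2
        assert h.refractory_fraction == 0.0
        assert h.refractory_clean

    def test_refractory_violation_detected(self):
        sp = ht.SpikeTrain("u", np.array([0.0, 0.001, 0.050]), 1.0)
        h = ht.isi_histogram(sp)
        assert h.refractory_fraction == pytest.approx(0.5)
        assert not h.refractory_clean

    def test_poisson_isi_mean(self):
        sp = ht.generate_theta_skipping_train(
            600.0, ht.GroundTruth.poisson_cell(rate_hz=5.0), seed=3)
        isi_ms = np.diff(sp.spike_times) * 1000.0
        se = 200.0 / np.sqrt(isi_ms.size)       # exponential: sd = mean
        assert abs(isi_ms.mean() - 200.0) <= 3 * se

    def test_too_few_spikes_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ht.isi_histogram(ht.SpikeTrain("u", np.array([1.0]), 2.0))


class TestAutocorrelogram:
    def test_two_spike_pair(self):
        sp = ht.SpikeTrain("u", np.array([0.5, 0.510]), 1.0)
        ac = ht.autocorrelogram(sp)
        centre = ac.n_bins // 2
        assert ac.counts[centre + 10] == 1 and ac.counts[centre - 10] == 1
        assert ac.counts.sum() == 2

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        times = np.sort(rng.uniform(0, 3.0, size=50))
        sp = ht.SpikeTrain("u", times, 3.0)
        ac = ht.autocorrelogram(sp)
        assert np.array_equal(ac.counts, brute_force_autocorr(times))

    @given(st.lists(st.floats(0, 5), min_size=2, max_size=40))
    def test_symmetry_property(self, raw):
        times = np.sort(np.asarray(raw))
        sp = ht.SpikeTrain("u", times, 6.0)
        ac = ht.autocorrelogram(sp)
        assert np.array_equal(ac.counts, ac.counts[::-1])
        assert ac.n_bins == 2001

    def test_bad_arguments(self):
        sp = ht.SpikeTrain("u", np.array([0.1, 0.2]), 1.0)
        with pytest.raises(InvalidArgumentError):
            ht.autocorrelogram(sp, bin_ms=0.0)
        with pytest.raises(InvalidArgumentError):
            ht.autocorrelogram(ht.SpikeTrain("u", np.array([0.1]), 1.0))


class TestModelFit:
    def test_noiseless_round_trip(self):
        true = np.array([50.0, 30.0, 10.0, 40.0, 40.0,
                         2 * math.pi * 8.67, 2 * math.pi * 4.33, 300.0, 20.0, 3.0])
        lags = np.arange(-1000.0, 1001.0)
        ac = Autocorrelogram(lags_ms=lags, counts=model_curve(true, lags))
        fit = ht.fit_skipping_model(ac)
        assert fit.converged
        rel = np.abs(fit.params() - true) / np.abs(true)
        assert rel.max() < 0.01

    def test_parameters_respect_bounds(self, skipping_fit):
        ac, fit = skipping_fit
        n = ac.peak
        for v in (fit.a1, fit.a2, fit.b, fit.c1, fit.c2):
            assert 0.0 <= v <= n
        assert 12 * math.pi <= fit.omega1 <= 24 * math.pi
        assert 6 * math.pi <= fit.omega2 <= 12 * math.pi
        assert 0 < fit.tau1 <= 5000 and 0 < fit.tau2 <= 100 and 0 < fit.tau3 <= 10

    def test_generator_frequency_recovery(self, skipping_fit):
        _, fit = skipping_fit
        assert abs(fit.f_high_hz - 8.67) <= 0.3
        assert abs(fit.f_low_hz - 4.335) <= 0.3

    def test_homogeneous_poisson_not_skipping(self):
        sp = ht.generate_theta_skipping_train(
            600.0, ht.GroundTruth.poisson_cell(rate_hz=5.0), seed=5)
        ac = ht.autocorrelogram(sp)
        fit = ht.fit_skipping_model(ac)
        ind = ht.skipping_indices(fit, ac)
        assert not ht.classify_theta_skipping(fit, ind, ac)

    def test_empty_autocorrelogram_rejected(self):
        ac = Autocorrelogram(lags_ms=np.arange(-1000.0, 1001.0),
                             counts=np.zeros(2001))
        with pytest.raises(InvalidArgumentError):
            ht.fit_skipping_model(ac)


class TestIndices:
    def test_jump_factor_arithmetic(self):
        assert ht.jump_factor(make_fit(a1=10.0, a2=0.0)) == 0.0
        assert ht.jump_factor(make_fit(a1=7.0, a2=7.0)) == pytest.approx(0.5)
        assert ht.jump_factor(make_fit(a1=50.0, a2=30.0)) == pytest.approx(0.375)
        with pytest.raises(UndefinedMetricError):
            ht.jump_factor(make_fit(a1=0.0, a2=0.0))

    def test_frequency_ratio(self):
        assert ht.frequency_ratio(make_fit(omega1=16 * math.pi,
                                           omega2=8 * math.pi)) == pytest.approx(2.0)
        assert ht.frequency_ratio(make_fit(omega1=24 * math.pi,
                                           omega2=6 * math.pi)) == pytest.approx(4.0)
        with pytest.raises(UndefinedMetricError):
            ht.frequency_ratio(make_fit(omega2=0.0))

    def test_ts_equal_peaks_is_zero(self):
        # amplitudes chosen so the first two envelope peaks are equal (the
        # half-frequency term exactly offsets the envelope decay): TS = 0
        w1 = 2 * math.pi * 8.0
        tau1 = 5000.0
        d1 = math.exp(-125.0 / tau1)
        d2 = math.exp(-250.0 / tau1)
        a_minus, a_plus = 2.5 / d1, 2.5 / d2
        fit = make_fit(a1=(a_plus + a_minus) / 2, a2=(a_plus - a_minus) / 2,
                       b=0.0, omega1=w1, omega2=w1 / 2, tau1=tau1)
        ac = Autocorrelogram(np.arange(-1000.0, 1001.0), np.ones(2001))
        ts = ht.theta_skipping_index(fit, ac)
        assert ts == pytest.approx(0.0, abs=5e-3)

    def test_ts_formula_on_known_peaks(self):
        # solve for amplitudes so the first two envelope peaks are exactly
        # 2 and 3 (omega2 = omega1/2, decay compensated): TS = 1/3
        w1 = 2 * math.pi * 8.0
        tau1 = 5000.0
        x1, x2 = 125.0, 250.0
        d1, d2 = math.exp(-x1 / tau1), math.exp(-x2 / tau1)
        a_minus = 2.0 / d1     # a1 - a2 at the low peak
        a_plus = 3.0 / d2      # a1 + a2 at the high peak
        fit = make_fit(a1=(a_plus + a_minus) / 2, a2=(a_plus - a_minus) / 2,
                       b=0.0, omega1=w1, omega2=w1 / 2, tau1=tau1)
        ac = Autocorrelogram(np.arange(-1000.0, 1001.0), np.ones(2001))
        ts = ht.theta_skipping_index(fit, ac)
        assert ts == pytest.approx(1.0 / 3.0, abs=5e-3)

    def test_ts_undefined_without_two_peaks(self):
        fit = make_fit(a1=0.0, a2=0.0)
        ac = Autocorrelogram(np.arange(-1000.0, 1001.0), np.ones(2001))
        with pytest.raises(UndefinedMetricError):
            ht.theta_skipping_index(fit, ac)

    def test_skipping_cell_positive_ts_and_classification(self, skipping_fit):
        ac, fit = skipping_fit
        ind = ht.skipping_indices(fit, ac)
        assert ind.ts_index is not None and 0.0 < ind.ts_index <= 1.0
        assert ind.frequency_ratio == pytest.approx(2.0, abs=0.05)
        assert ht.classify_theta_skipping(fit, ind, ac)

    def test_pure_theta_cell_not_skipping(self):
        sp = ht.generate_theta_skipping_train(
            600.0, ht.GroundTruth.theta_cell(seed=6), seed=6)
        ac = ht.autocorrelogram(sp)
        fit = ht.fit_skipping_model(ac)
        ind = ht.skipping_indices(fit, ac)
        assert not ht.classify_theta_skipping(fit, ind, ac)
        # but the theta oscillation itself is clearly above the noise floor
        assert fit.a1 > oscillation_noise_floor(ac)
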