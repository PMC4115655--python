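"""Directional tuning curves, CW/CCW split, Rayleigh stats, condition tests."""

import numpy as np
import pytest
from scipy import special, stats

import hdtheta as ht
from hdtheta._circular import circ_diff_deg
from hdtheta.errors import InvalidArgumentError, UndefinedMetricError
from hdtheta.hd import HDMetrics
from hdtheta.tracking import AngularVelocitySeries, HeadDirectionSeries


def hd_from_theta(theta_deg, rate=50.0):
    theta_deg = np.asarray(theta_deg, dtype=float)
    return HeadDirectionSeries(timestamps=np.arange(theta_deg.size) / rate,
                               theta_deg=theta_deg, sample_rate=rate)


class TestTuningCurve:
    def test_zero_spikes_all_zero(self, hd_series, docc):
        sp = ht.SpikeTrain("u0", np.empty(0), 1200.0)
        curve = ht.tuning_curve(sp, hd_series, docc)
        assert np.all(curve.rate == 0)

    def test_refuses_unsampled_bins(self):
        hd = hd_from_theta(np.linspace(0, 90, 200))
        docc = ht.directional_occupancy(hd)
        sp = ht.SpikeTrain("u0", np.array([1.0]), 4.0)
        with pytest.raises(InvalidArgumentError):
            ht.tuning_curve(sp, hd, docc)

    def test_preferred_direction_recovery(self, hd_train, hd_series, docc):
        curve = ht.tuning_curve(hd_train, hd_series, docc)
        assert abs(circ_diff_deg(curve.peak_direction_deg, 90.0)) <= 5.0

    def test_uniform_symmetry(self):
        # one sample per bin centre, one spike on each sample: equal rates
        theta = np.arange(2.5, 360, 5.0)
        hd = hd_from_theta(theta)
        docc = ht.directional_occupancy(hd)
        sp = ht.SpikeTrain("u0", hd.timestamps.copy(), hd.timestamps[-1] + 0.01)
        curve = ht.tuning_curve(sp, hd, docc)
        assert np.allclose(curve.rate, curve.rate[0])

    def test_spike_mass_conserved(self, hd_train, hd_series, docc):
        curve = ht.tuning_curve(hd_train, hd_series, docc)
        assert curve.spike_count.sum() == hd_train.n_spikes


class TestNormalizeAndAlign:
    def test_peak_moves_to_180(self, hd_train, hd_series, docc):
        curve = ht.tuning_curve(hd_train, hd_series, docc)  # peak near 90
        aligned = ht.normalize_and_align(curve)
        assert aligned.rate.max() == pytest.approx(1.0)
        assert np.all((aligned.rate >= 0) & (aligned.rate <= 1.0))
        assert 180.0 // 5 == np.argmax(aligned.rate)

    def test_already_aligned_curve_unchanged(self, hd_series, docc):
        rate = np.exp(-0.5 * ((np.arange(72) - 36.1) / 5) ** 2)
        curve = ht.DirectionalTuningCurve(
            bin_centers_deg=(np.arange(72) + 0.5) * 5.0, rate=rate,
            spike_count=rate, dwell_s=np.ones(72))
        aligned = ht.normalize_and_align(curve)
        assert np.allclose(aligned.rate, rate / rate.max())

    def test_cyclic_shift_preserves_multiset(self, hd_train, hd_series, docc):
        curve = ht.tuning_curve(hd_train, hd_series, docc)
        aligned = ht.normalize_and_align(curve)
        assert sorted(np.round(aligned.rate * curve.peak_rate, 9)) == \
            pytest.approx(sorted(np.round(curve.rate, 9)))

    def test_all_zero_curve_rejected(self):
        curve = ht.DirectionalTuningCurve(
            bin_centers_deg=(np.arange(72) + 0.5) * 5.0, rate=np.zeros(72),
            spike_count=np.zeros(72), dwell_s=np.ones(72))
        with pytest.raises(UndefinedMetricError):
            ht.normalize_and_align(curve)


class TestSplitCwCcw:
    def test_no_fast_turns_flags_both(self):
        hd = hd_from_theta(np.linspace(0, 359, 720) % 360)
        av = AngularVelocitySeries(hd.timestamps, np.zeros(720))
        sp = ht.SpikeTrain("u0", np.array([1.0]), 14.4)
        cw, ccw, res = ht.split_cw_ccw(sp, hd, av)
        assert not cw.complete and not ccw.complete
        assert res["separation_angle_deg"] is None

    def test_threshold_boundary_sample_counts_as_cw(self):
        theta = np.tile(np.arange(2.5, 360, 5.0), 3)
        hd = hd_from_theta(theta)
        omega = np.full(theta.size, 120.0)           # exactly at threshold
        av = AngularVelocitySeries(hd.timestamps, omega)
        sp = ht.SpikeTrain("u0", np.array([0.0]), hd.timestamps[-1] + 0.01)
        cw, ccw, _ = ht.split_cw_ccw(sp, hd, av)
        assert cw.complete                            # every bin visited
        assert cw.spike_count.sum() == 1
        assert ccw.spike_count.sum() == 0

    def test_separation_angle_recovery(self, hd_train, hd_series, angvel):
        # generator truth: CW/CCW offset of 20 degrees
        _, _, res = ht.split_cw_ccw(hd_train, hd_series, angvel)
        assert res["separation_angle_deg"] is not None
        assert abs(res["separation_angle_deg"] - 20.0) <= 7.5

    def test_sample_partition(self, hd_series, angvel):
        omega = angvel.omega_deg_per_s
        n_cw = np.sum(omega >= 120.0)
        n_ccw = np.sum(omega <= -120.0)
        n_mid = np.sum(np.abs(omega) < 120.0)
        assert n_cw + n_ccw + n_mid == omega.size


class TestRayleigh:
    def test_point_mass(self):
        mean, r, p = ht.rayleigh_statistics([90.0] * 20)
        assert r == pytest.approx(1.0)
        assert mean == pytest.approx(90.0)
        assert p < 1e-6

    def test_uniform_bin_centres(self):
        _, r, _ = ht.rayleigh_statistics(np.arange(2.5, 360, 5.0))
        assert r < 1e-10

    def test_von_mises_resultant_matches_bessel_ratio(self):
        rng = np.random.default_rng(0)
        draws = np.rad2deg(rng.vonmises(0.0, 2.0, size=10000)) % 360.0
        _, r, _ = ht.rayleigh_statistics(draws)
        oracle = special.iv(1, 2.0) / special.iv(0, 2.0)
        assert r == pytest.approx(oracle, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ht.rayleigh_statistics([])


class TestDistributivePrediction:
    def test_constant_map_predicts_constant(self, traj20, hd_series):
        occ = ht.spatial_occupancy(traj20, 5.0)
        joint, _, _ = ht.joint_occupancy(traj20, hd_series, 5.0, 5.0)
        rate = np.where(occ.dwell_s > 0, 3.0, np.nan)
        rmap = ht.RateMap(rate_hz=rate, spike_count=rate, bin_cm=5.0,
                          in_arena=occ.in_arena, x_edges_cm=occ.x_edges_cm,
                          y_edges_cm=occ.y_edges_cm)
        pred = ht.distributive_predicted_tuning(rmap, joint)
        assert np.nanmax(np.abs(pred.rate - 3.0)) < 1e-9

    def test_place_cell_tuning_is_occupancy_artefact(self, traj20, hd_series):
        # a purely place-modulated unit's directional curve should match the
        # distributive prediction (coarse 45-deg bins to beat shot noise)
        truth = ht.GroundTruth.place_cell(field_center_xy=(12.0, 0.0),
                                          peak_rate_hz=20.0, seed=3)
        sp = ht.generate_place_spike_train(traj20, truth, seed=3)
        occ = ht.spatial_occupancy(traj20, 5.0)
        rmap = ht.rate_map(sp, traj20, occ)
        joint, _, _ = ht.joint_occupancy(traj20, hd_series, 5.0, 45.0)
        pred = ht.distributive_predicted_tuning(rmap, joint)
        obs = ht.tuning_curve(sp, hd_series, ht.directional_occupancy(hd_series, 45.0))
        assert np.corrcoef(obs.rate, pred.rate)[0, 1] > 0.8
        assert np.max(np.abs(obs.rate - pred.rate)) < 0.3 * obs.rate.mean()

    def test_hd_cell_exceeds_prediction_at_preferred(self, traj20, hd_series,
                                                     hd_train, docc):
        occ = ht.spatial_occupancy(traj20, 5.0)
        rmap = ht.rate_map(hd_train, traj20, occ)
        joint, _, _ = ht.joint_occupancy(traj20, hd_series, 5.0, 5.0)
        pred = ht.distributive_predicted_tuning(rmap, joint)
        obs = ht.tuning_curve(hd_train, hd_series, docc)
        k = int(np.nanargmax(obs.rate))
        assert obs.rate[k] > 1.5 * pred.rate[k]


def metrics(peak_rate, mean_dir=10.0, **kw):
    base = dict(mean_direction_deg=mean_dir, peak_direction_deg=mean_dir,
                peak_rate_hz=peak_rate, rayleigh_r=0.8, rayleigh_p=1e-5,
                n_spikes=1000, mean_dir_cw_deg=mean_dir + 5,
                mean_dir_ccw_deg=mean_dir - 5, separation_angle_deg=10.0)
    base.update(kw)
    return HDMetrics(**base)


class TestCompareConditions:
    def test_identical_conditions(self):
        a = [metrics(10.0 + i) for i in range(5)]
        rep = ht.compare_conditions(a, a)
        assert np.allclose(rep["t"], 0.0)
        assert np.allclose(rep["p"], 1.0)
        assert not rep["significant"].any()
        assert np.allclose(rep["alpha_adjusted"], 0.05 / 5)

    def test_three_pair_example_matches_paired_t_oracle(self):
        rates_a = [12.0, 15.0, 9.0]
        rates_b = [10.0, 14.5, 8.0]
        a = [metrics(r) for r in rates_a]
        b = [metrics(r) for r in rates_b]
        rep = ht.compare_conditions(a, b).set_index("measure")
        t_o, p_o = stats.ttest_rel(rates_a, rates_b)
        assert rep.loc["peak_rate_hz", "t"] == pytest.approx(t_o)
        assert rep.loc["peak_rate_hz", "p"] == pytest.approx(p_o)

    def test_angular_measures_use_circular_difference(self):
        # a consistent 4-degree shift across the 0/360 wrap must register as
        # a small, highly significant difference; linear differencing would
        # see one ~356-degree outlier and lose it
        dirs_a = [358.0, 2.0, 6.0, 354.0]
        jitter = [4.05, 3.95, 4.02, 3.98]
        dirs_b = [(a - j) % 360.0 for a, j in zip(dirs_a, jitter)]
        a = [metrics(10.0, mean_dir=d) for d in dirs_a]
        b = [metrics(10.0, mean_dir=d) for d in dirs_b]
        rep = ht.compare_conditions(a, b).set_index("measure")
        assert rep.loc["mean_direction_deg", "t"] > 10.0
        assert rep.loc["mean_direction_deg", "p"] < 0.01
        assert np.allclose(circ_diff_deg(dirs_a, dirs_b), jitter)

    def test_mismatched_units_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ht.compare_conditions([metrics(1.0)], [metrics(1.0), metrics(2.0)])
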