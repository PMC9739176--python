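"""Error/repeatability metrics, sweep analyses and Kalman smoothing."""

import math

import numpy as np
import pandas as pd
import pytest

from fohtrack.evaluate import (
    elevation_analysis,
    angle_analysis,
    grid_metrics,
    kalman_smooth,
    label_offset_correction,
    repeat_average,
    repeatability,
    spatial_summary,
    tracking_error,
    uncertainty_correlation,
)
from fohtrack.scan_convert import CartesianEstimate


class TestTrackingError:
    def test_perfect_tracking_zero_error(self):
        tracked = np.tile([3.0, 100.0], (18, 1))
        np.testing.assert_allclose(tracking_error(tracked, [3.0, 100.0]), [0.0, 0.0])

    def test_constant_offset(self):
        tracked = np.tile([1.0, -2.0], (5, 1)) + np.array([10.0, 50.0])
        e = tracking_error(tracked, [10.0, 50.0])
        np.testing.assert_allclose(e, [1.0, -2.0])
        assert np.linalg.norm(e) == pytest.approx(math.sqrt(5.0))

    def test_matches_direct_mean_oracle(self, rng):
        tracked = rng.normal(size=(18, 2))
        truth = rng.normal(size=2)
        expected = np.array(
            [sum(t[i] for t in tracked) / 18 - truth[i] for i in range(2)]
        )
        np.testing.assert_allclose(tracking_error(tracked, truth), expected, atol=1e-12)


class TestRepeatability:
    def test_identical_positions_zero(self):
        assert np.all(repeatability(np.tile([1.0, 2.0], (10, 1))) == 0.0)

    def test_alternating_closed_form(self):
        n = 18
        x = np.array([1.0, -1.0] * (n // 2))
        tracked = np.column_stack([x, np.zeros(n)])
        expected = 1.0 * math.sqrt(n / (n - 1))
        assert repeatability(tracked)[0] == pytest.approx(expected)

    def test_matches_formula_oracle(self, rng):
        tracked = rng.normal(size=(18, 2))
        mean = tracked.mean(axis=0)
        expected = np.sqrt(((tracked - mean) ** 2).sum(axis=0) / 17)
        np.testing.assert_allclose(repeatability(tracked), expected, atol=1e-12)


class TestRepeatAverage:
    def test_identical_repeats_zero_uncertainty(self):
        mean, unc = repeat_average(np.tile(0.7, (5, 1)))
        assert mean[0] == pytest.approx(0.7)
        assert unc[0] == 0.0

    def test_two_repeats_arithmetic(self):
        mean, unc = repeat_average(np.array([[0.0], [1.0]]))
        assert mean[0] == pytest.approx(0.5)
        assert unc[0] == pytest.approx(math.sqrt(0.5) / math.sqrt(2.0))

    def test_five_repeats_oracle(self, rng):
        v = rng.normal(size=(5, 3))
        mean, unc = repeat_average(v)
        np.testing.assert_allclose(mean, v.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(unc, v.std(axis=0, ddof=1) / math.sqrt(5), atol=1e-12)


class TestSpatialSummary:
    def test_identical_locations(self):
        out = spatial_summary(np.full(10, 0.4))
        assert out["mean"] == pytest.approx(0.4)
        assert out["std"] == 0.0

    def test_small_table_hand_computed(self):
        out = spatial_summary(np.array([0.2, 0.4, 0.9]))
        assert out["mean"] == pytest.approx(0.5)
        assert out["std"] == pytest.approx(np.std([0.2, 0.4, 0.9], ddof=1))

    def test_percentile_of_uniform_values(self):
        vals = np.linspace(0.0, 1.0, 1001)
        out = spatial_summary(vals, percentiles=(95.0,))
        assert out["p95"] == pytest.approx(0.95, abs=1e-3)


class TestLabelOffsetCorrection:
    def test_zero_offset_is_identity(self, rng):
        pts = rng.normal(size=(6, 2))
        np.testing.assert_allclose(label_offset_correction(pts, 0.0, 55.0), pts)

    def test_horizontal_shaft(self):
        out = label_offset_correction(np.array([[10.0, 20.0]]), 3.5, 0.0)
        np.testing.assert_allclose(out, [[6.5, 20.0]])

    def test_55_degree_shaft(self):
        out = label_offset_correction(np.array([[0.0, 0.0]]), 3.5, 55.0)
        np.testing.assert_allclose(
            out,
            [[-3.5 * math.cos(math.radians(55.0)), -3.5 * math.sin(math.radians(55.0))]],
        )


class TestUncertaintyCorrelation:
    def test_proportional_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert uncertainty_correlation(x, 2 * x) == pytest.approx(1.0)

    def test_anti_proportional_is_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert uncertainty_correlation(x, -0.5 * x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        assert uncertainty_correlation(x, y) == pytest.approx(expected, abs=1e-12)


def _track(points, cov=1e-10):
    return [
        CartesianEstimate(x, y, np.diag([cov, cov]), valid=True) for x, y in points
    ]


class TestKalmanSmooth:
    def test_stationary_noiseless_track_is_unchanged(self):
        track = _track([(5.0, 80.0)] * 40)
        out = kalman_smooth(track, "constant_velocity", process_noise=1.0)
        for est in out[10:]:
            assert est.x_mm == pytest.approx(5.0, abs=1e-6)
            assert est.y_mm == pytest.approx(80.0, abs=1e-6)

    @pytest.mark.parametrize("model", ["constant_velocity", "constant_acceleration"])
    def test_constant_velocity_line_recovered(self, model):
        dt = 1.0 / 18.0
        pts = [(0.5 * i * dt, 100.0 - 0.2 * i * dt) for i in range(60)]
        out = kalman_smooth(_track(pts), model, process_noise=1.0, dt=dt)
        for est, (x, y) in list(zip(out, pts))[30:]:
            assert est.x_mm == pytest.approx(x, abs=1e-6)
            assert est.y_mm == pytest.approx(y, abs=1e-6)

    def test_jitter_variance_reduced(self, rng):
        jitter = rng.normal(0.0, 0.5, size=(200, 2))
        pts = [(3.0 + jx, 90.0 + jy) for jx, jy in jitter]
        track = [
            CartesianEstimate(x, y, np.diag([0.25, 0.25]), valid=True) for x, y in pts
        ]
        out = kalman_smooth(track, "constant_velocity", process_noise=0.5)
        xs_in = np.array([p[0] for p in pts[50:]])
        xs_out = np.array([e.x_mm for e in out[50:]])
        assert xs_out.var() < xs_in.var()

    def test_invalid_frames_are_predicted_through(self):
        pts = [(1.0, 50.0)] * 30
        track = _track(pts)
        track[15] = CartesianEstimate.invalid()
        out = kalman_smooth(track, "constant_velocity", process_noise=1.0)
        assert out[15].valid
        assert out[15].x_mm == pytest.approx(1.0, abs=1e-3)

    def test_too_few_valid_estimates_rejected(self):
        with pytest.raises(ValueError):
            kalman_smooth(_track([(0.0, 1.0)]), "constant_velocity")


class TestGridMetricsTable:
    def test_matches_hand_computation(self):
        est = pd.DataFrame(
            {
                "position_id": [0, 0, 1, 1],
                "frame": [0, 1, 0, 1],
                "x_mm": [1.0, 2.0, 10.0, 10.0],
                "y_mm": [100.0, 102.0, 120.0, 120.0],
                "r_mm": [100.0, 102.0, 120.4, 120.4],
                "theta_deg": [0.5, 1.0, 4.0, 4.0],
                "valid": [True, True, True, False],
            }
        )
        truth = pd.DataFrame(
            {"position_id": [0, 1], "x_mm": [1.0, 9.0], "y_mm": [101.0, 119.0]}
        )
        m = grid_metrics(est, truth).set_index("position_id")
        assert m.loc[0, "error_x_mm"] == pytest.approx(0.5)
        assert m.loc[0, "error_y_mm"] == pytest.approx(0.0)
        assert m.loc[0, "rep_x_mm"] == pytest.approx(np.std([1.0, 2.0], ddof=1))
        assert m.loc[1, "n_valid"] == 1
        assert m.loc[1, "error_x_mm"] == pytest.approx(1.0)


class TestSweepAnalyses:
    def test_elevation_curves(self, small_geometry, pulse_model):
        from fohtrack.pipeline import track_dataset
        from fohtrack.simulator import generate_elevation_sweep

        ds = generate_elevation_sweep(
            small_geometry, pulse_model, depth_mm=120.0, z_min_mm=-8.0, z_max_mm=8.0,
            step_mm=4.0, n_frames_per_position=2, snr_db=60.0, seed=5,
        )
        est = track_dataset(ds)
        curves = elevation_analysis(est, ds.truth)
        assert len(curves) == 5
        mid = curves[curves["z_mm"] == 0.0].iloc[0]
        assert abs(mid["lateral_displacement_mm"]) < 0.5
        assert abs(mid["axial_displacement_mm"]) < 0.5
        # SNR decays away from the imaging plane
        assert mid["snr_db"] >= curves["snr_db"].min()

    def test_angle_sweep_amplitudes(self, small_geometry, pulse_model, template):
        from fohtrack.simulator import generate_angle_sweep

        ds = generate_angle_sweep(
            small_geometry, pulse_model, depth_mm=80.0,
            angles_deg=np.array([0.0, 40.0]), n_frames_per_position=2,
            snr_db=math.inf,
        )
        df = angle_analysis(ds, template)
        assert df["raw_relative"].iloc[1] == pytest.approx(1.67, abs=0.08)
        assert df["processed_relative"].iloc[1] == pytest.approx(1.0, abs=0.10)
        assert (df["raw_amplitude_std"] >= 0).all()
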