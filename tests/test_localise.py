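"""Centre-of-mass angle, cumulative-energy time of arrival and the full
single-frame localiser."""

import math

import numpy as np
import pytest

from fohtrack.framing import FOHFrame
from fohtrack.geometry import ProbeGeometry, cartesian_to_polar, scan_line_angles
from fohtrack.localise import (
    ColumnEnergies,
    NoSignalError,
    PreTransmitError,
    TrackerOptions,
    column_energies,
    localise_frame,
    radial_position,
    time_of_arrival,
    weighted_angle_spread,
    weighted_mean_angle,
)
from fohtrack.pipeline import dataset_noise_level, make_template, processed_noise_level
from fohtrack.simulator import (
    SimulationScene,
    generate_frame,
    generate_grid_dataset,
    generate_noise_frames,
    GridSpec,
)

FS = 1.0e7


def _frame_from_energies(energies, angles):
    """Single-sample frame whose column energies equal the given values."""
    return FOHFrame(
        samples=np.sqrt(np.asarray(energies, dtype=float))[None, :],
        sample_rate_hz=FS,
        line_angles_deg=np.asarray(angles, dtype=float),
    )


def _ce(energies, angles):
    e = np.asarray(energies, dtype=float)
    return ColumnEnergies(
        energies=e,
        angles_deg=np.asarray(angles, dtype=float),
        n_total=len(e),
        n_nonzero=int(np.count_nonzero(e)),
    )


class TestColumnEnergies:
    def test_single_nonzero_column_survives_alone(self):
        ce = column_energies(_frame_from_energies([0, 0, 4.0, 0], [-1, 0, 1, 2]))
        np.testing.assert_array_equal(ce.energies, [0, 0, 4.0, 0])
        assert ce.n_nonzero == 1

    def test_minus_6db_threshold_zeroes_weak_column(self):
        # 0.20 < 10^(-6/10) = 0.2512, so the second column is zeroed
        ce = column_energies(_frame_from_energies([1.0, 0.20], [0, 1]))
        np.testing.assert_array_equal(ce.energies, [1.0, 0.0])

    def test_uniform_energies_all_survive(self):
        ce = column_energies(_frame_from_energies([0.5] * 6, np.arange(6)))
        assert ce.n_nonzero == 6

    def test_all_zero_frame_degenerate(self):
        ce = column_energies(_frame_from_energies([0, 0], [0, 1]))
        assert ce.degenerate


class TestWeightedMeanAngle:
    @pytest.mark.parametrize(
        "energies, angles, expected",
        [
            ([0, 1, 0], [-1.0, 0.0, 1.0], 0.0),
            ([1, 1], [10.0, 20.0], 15.0),
            ([1, 3], [0.0, 4.0], 3.0),
        ],
    )
    def test_centre_of_mass(self, energies, angles, expected):
        assert weighted_mean_angle(_ce(energies, angles)) == pytest.approx(expected)

    def test_all_zero_raises(self):
        with pytest.raises(NoSignalError):
            weighted_mean_angle(_ce([0, 0], [0, 1]))

    def test_invariant_to_amplitude_scaling(self, rng):
        e = rng.uniform(0.1, 1.0, 16)
        a = np.linspace(-5, 5, 16)
        assert weighted_mean_angle(_ce(e, a)) == pytest.approx(
            weighted_mean_angle(_ce(7.3 * e, a)), abs=1e-12
        )


class TestWeightedAngleSpread:
    def test_single_column_spread_is_zero(self):
        assert weighted_angle_spread(_ce([0, 5.0, 0], [-1, 0, 1]), 0.0) == 0.0

    def test_equal_energies_at_plus_minus_one_degree(self):
        # corrected form: sqrt(1) * sqrt(2/1) = sqrt(2)
        s = weighted_angle_spread(_ce([1.0, 1.0], [-1.0, 1.0]), 0.0)
        assert s == pytest.approx(math.sqrt(2.0))

    def test_printed_variant_is_corrected_over_nprime(self):
        ce = _ce([1.0, 2.0, 3.0], [-1.0, 0.0, 2.0])
        tb = weighted_mean_angle(ce)
        assert weighted_angle_spread(ce, tb, "printed") == pytest.approx(
            weighted_angle_spread(ce, tb, "corrected") / 3.0
        )

    def test_scaling_invariance(self, rng):
        e = rng.uniform(0.1, 1.0, 8)
        a = np.arange(8.0)
        tb = weighted_mean_angle(_ce(e, a))
        assert weighted_angle_spread(_ce(e, a), tb) == pytest.approx(
            weighted_angle_spread(_ce(4.2 * e, a), tb)
        )


class TestTimeOfArrival:
    def test_rectangular_envelope_is_exact(self):
        """For a flat pulse, t0.1 = t0 + 0.1 T, so t_start = t0 and the
        1.25 dt duration equals T exactly."""
        t0, T = 200, 400  # samples
        w = np.zeros(1000)
        w[t0 : t0 + T] = 0.5
        t_start, dt = time_of_arrival(w, FS)
        assert t_start == pytest.approx(t0 / FS, rel=1e-12)
        assert 1.25 * dt == pytest.approx(T / FS, rel=1e-12)

    def test_shift_equivariance(self):
        w = np.zeros(1000)
        w[100:300] = np.hanning(200)
        t1, dt1 = time_of_arrival(w, FS)
        t2, dt2 = time_of_arrival(np.roll(w, 250), FS)
        assert t2 - t1 == pytest.approx(250 / FS, abs=1e-12)
        assert dt1 == pytest.approx(dt2, abs=1e-12)

    def test_gaussian_envelope_matches_oversampled_oracle(self):
        """Onset from the sampled pulse agrees with a 100x-oversampled
        numeric evaluation within one sample."""
        sigma = 5e-7
        centre = 50e-6

        def onset(fs):
            t = np.arange(int(100e-6 * fs)) / fs
            w = np.exp(-((t - centre) ** 2) / (2 * sigma**2))
            return time_of_arrival(w, fs)[0]

        assert abs(onset(FS) - onset(100 * FS)) < 1.0 / FS

    def test_zero_energy_raises(self):
        with pytest.raises(NoSignalError):
            time_of_arrival(np.zeros(100), FS)


class TestRadialPosition:
    def test_start_at_delay_gives_probe_face(self):
        geo = ProbeGeometry(radius_of_curvature_mm=40.0)
        r, _ = radial_position(2e-5, 0.0, geo, delay_s=2e-5)
        assert r == pytest.approx(40.0)

    def test_arithmetic_example(self):
        # c = 1540 m/s, corrected t = 64.935 us, rho = 40 mm -> 140.0 mm
        geo = ProbeGeometry(radius_of_curvature_mm=40.0, sound_speed_mps=1540.0)
        r, _ = radial_position(64.935e-6, 0.0, geo)
        assert r == pytest.approx(140.0, abs=1e-2)

    def test_sigma_r_is_pulse_length(self):
        geo = ProbeGeometry(sound_speed_mps=1540.0)
        _, sr = radial_position(1e-4, 1e-6, geo)
        assert sr == pytest.approx(1.925, abs=1e-6)

    def test_pre_transmit_rejected(self):
        geo = ProbeGeometry()
        with pytest.raises(PreTransmitError):
            radial_position(1e-6, 0.0, geo, delay_s=2e-6)


class TestLocaliseFrame:
    def test_noise_free_on_axis_round_trip(self, small_geometry, pulse_model, template):
        scene = SimulationScene(tip_x_mm=0.0, tip_y_mm=100.0 + 68.0)
        frame = generate_frame(scene, small_geometry, pulse_model, FS)
        est = localise_frame(frame, template, None, small_geometry)
        truth = cartesian_to_polar(scene.tip)
        spacing = small_geometry.field_of_view_deg / (small_geometry.n_scan_lines - 1)
        assert est.valid and est.method == "centre_of_mass"
        assert abs(est.theta_deg - truth.theta_deg) < spacing / 2
        c_mm = small_geometry.sound_speed_mps * 1e3
        assert abs(est.r_mm - truth.r_mm) < 1.5 / FS * c_mm

    def test_pure_noise_frame_invalid(self, small_geometry, template, rng):
        frames = generate_noise_frames(small_geometry, FS, 0.02, n_frames=3, rng=rng)
        noise = processed_noise_level(frames[:2], template)
        est = localise_frame(frames[2], template, noise, small_geometry)
        assert not est.valid

    def test_symmetric_two_line_energy_splits_difference(self, small_geometry, template):
        angles = scan_line_angles(small_geometry)
        window = 1600
        cols = np.zeros((window, small_geometry.n_scan_lines))
        for k in (30, 31):
            cols[800 : 800 + len(template.waveform), k] = template.waveform
        frame = FOHFrame(samples=cols, sample_rate_hz=FS, line_angles_deg=angles)
        est = localise_frame(frame, template, None, small_geometry)
        assert est.method == "centre_of_mass"
        assert est.theta_deg == pytest.approx((angles[30] + angles[31]) / 2, abs=1e-9)

    def test_theta_invariant_to_global_scaling(self, small_geometry, pulse_model, template):
        scene = SimulationScene(tip_x_mm=15.0, tip_y_mm=120.0)
        frame = generate_frame(scene, small_geometry, pulse_model, FS)
        est1 = localise_frame(frame, template, None, small_geometry)
        est2 = localise_frame(
            frame.copy_with(frame.samples * 37.0), template, None, small_geometry
        )
        assert est1.theta_deg == pytest.approx(est2.theta_deg, abs=1e-9)
        assert est1.r_mm == pytest.approx(est2.r_mm, abs=1e-9)

    def test_repeatability_degrades_and_sigma_tracks_it(self, small_geometry, pulse_model):
        """Average repeatability does not improve as SNR drops, and the
        estimated angular width correlates with measured repeatability."""
        template = make_template(pulse_model, FS)
        reps, sigmas = [], []
        for snr in (60.0, 40.0, 20.0):
            ds = generate_grid_dataset(
                small_geometry,
                pulse_model,
                GridSpec(depth_min_mm=90.0, depth_max_mm=90.0, spacing_mm=200.0),
                n_frames_per_position=25,
                snr_db=snr,
                seed=3,
                sample_rate_hz=FS,
            )
            noise = dataset_noise_level(ds, template)
            ests = []
            sig = []
            for pid, fi, fr in ds.iter_frames():
                e = localise_frame(fr, template, noise, small_geometry)
                if e.valid:
                    ests.append([e.r_mm, e.theta_deg])
                    sig.append(e.sigma_theta_deg)
            ests = np.array(ests)
            reps.append(float(np.std(ests[:, 1], ddof=1)))
            sigmas.append(float(np.mean(sig)))
        assert reps[0] <= reps[2]  # 60 dB at least as repeatable as 20 dB
        r = np.corrcoef(sigmas, reps)[0, 1]
        assert r > 0.5
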