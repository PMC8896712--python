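"""Synthetic trajectory generators and perturbations."""

import numpy as np
import pytest

from gazeflow import calib, synth
from gazeflow.synth import (
    OverlappingPerturbationError,
    Perturbation,
    Scenario,
    ScenarioError,
    apply_perturbation,
    corkscrew_trajectory,
    gait_head_trajectory,
    sinusoid_trajectory,
    straight_approach,
    synth_calibration_session,
)


class TestStraightApproach:
    def test_zero_offset_is_collinear_every_frame(self):
        sc = straight_approach(duration=1.0, fps=30, fixation_offset_angle=0.0)
        # fixation on the ground track: x = 0 throughout
        assert np.all(sc.fixations[:, 0] == 0.0)
        v = sc.velocities()
        cross = v[:, 0] * (sc.fixations[:, 1] - sc.centers[:, 1])
        assert np.allclose(cross, 0.0)

    def test_opposite_offsets_mirror(self):
        a = straight_approach(duration=0.5, fps=30, fixation_offset_angle=7.0)
        b = straight_approach(duration=0.5, fps=30, fixation_offset_angle=-7.0)
        assert np.allclose(a.fixations[:, 0], -b.fixations[:, 0])
        assert np.allclose(a.fixations[:, 1], b.fixations[:, 1])
        assert np.allclose(a.centers, b.centers)

    def test_declination_crosses_45_at_closed_form_time(self):
        """h = 1.25, v = 1.25, start 5 m out: atan(h / (5 - 1.25 t)) reaches
        45 degrees when the remaining ground distance equals the eye
        height, i.e. at t = (5 - 1.25) / 1.25 = 3.0 s."""
        sc = straight_approach(eye_height=1.25, speed=1.25, duration=3.2, fps=60,
                               start_distance=5.0)
        d = sc.fixations[:, 1] - sc.centers[:, 1]
        decl = np.degrees(np.arctan2(sc.centers[:, 2], d))
        i = int(np.argmin(np.abs(decl - 45.0)))
        assert sc.t[i] == pytest.approx(3.0, abs=1.0 / 60)

    def test_bad_speed_rejected(self):
        with pytest.raises(ScenarioError):
            straight_approach(speed=0.0)


class TestSinusoidAndCorkscrew:
    def test_zero_amplitude_equals_straight_path(self):
        sin0 = sinusoid_trajectory(amplitude=0.0, duration=0.5, fps=30)
        straight = straight_approach(duration=0.5, fps=30)
        assert np.allclose(sin0.centers, straight.centers)

    @pytest.mark.parametrize("axis, col", [("vertical", 2), ("horizontal", 0)])
    def test_peak_velocity_is_two_pi_f_a(self, axis, col):
        amp, freq = 0.07, 1.5
        sc = sinusoid_trajectory(axis=axis, amplitude=amp, frequency=freq,
                                 duration=4.0, fps=200)
        v = sc.velocities()
        assert np.abs(v[1:, col]).max() == pytest.approx(2 * np.pi * freq * amp, rel=0.01)

    def test_zero_radius_corkscrew_is_straight(self):
        cs = corkscrew_trajectory(radius=0.0, duration=0.5, fps=30)
        straight = straight_approach(duration=0.5, fps=30)
        assert np.allclose(cs.centers[:, [0, 1]], straight.centers[:, [0, 1]])

    def test_corkscrew_quadrature_is_exact(self):
        r, f = 0.1, 1.2
        cs = corkscrew_trajectory(radius=r, angular_rate=f, duration=1.0, fps=60)
        phase = 2 * np.pi * f * cs.t
        assert np.allclose(cs.centers[:, 0], r * np.cos(phase), atol=1e-12)
        assert np.allclose(cs.centers[:, 2] - cs.eye_height, r * np.sin(phase), atol=1e-12)


class TestGaitTrajectory:
    @pytest.mark.parametrize("walk_speed", [0.8, 1.2, 1.6, 2.0])
    def test_vertical_peak_velocity_is_half_walk_speed(self, walk_speed):
        sc = gait_head_trajectory(walk_speed=walk_speed, duration=5.0, fps=100)
        v = sc.velocities()
        ratio = np.abs(v[1:, 2]).max() / walk_speed
        assert ratio == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("walk_speed", [0.8, 1.4, 2.0])
    def test_vertical_velocity_spectrum_peaks_at_step_frequency(self, walk_speed):
        sc = gait_head_trajectory(walk_speed=walk_speed, duration=20.0, fps=100)
        vz = sc.velocities()[1:, 2]
        power = np.abs(np.fft.rfft(vz)) ** 2
        freqs = np.fft.rfftfreq(vz.size, 1.0 / 100)
        peak = freqs[1:][np.argmax(power[1:])]
        assert peak == pytest.approx(2.0, abs=0.1)

    def test_lateral_sway_at_half_step_frequency(self):
        sc = gait_head_trajectory(duration=20.0, fps=100)
        vx = sc.velocities()[1:, 0]
        power = np.abs(np.fft.rfft(vx)) ** 2
        freqs = np.fft.rfftfreq(vx.size, 1.0 / 100)
        peak = freqs[1:][np.argmax(power[1:])]
        assert peak == pytest.approx(1.0, abs=0.1)

    def test_integer_cycles_return_to_height(self):
        sc = gait_head_trajectory(duration=3.0, fps=100, phase_jitter=0.0)
        # 2 Hz: one full cycle every 0.5 s = 50 frames
        assert sc.centers[100, 2] == pytest.approx(sc.centers[0, 2], abs=1e-12)

    def test_bit_identical_for_same_seed(self):
        a = gait_head_trajectory(seed=42, phase_jitter=0.02, duration=2.0)
        b = gait_head_trajectory(seed=42, phase_jitter=0.02, duration=2.0)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.fixations, b.fixations)
        c = gait_head_trajectory(seed=43, phase_jitter=0.02, duration=2.0)
        assert not np.array_equal(a.centers, c.centers)


class TestScenarioValidation:
    def test_generators_emit_valid_scenarios_for_random_draws(self, rng):
        """Invariant checks pass across 1000 random parameter draws inside
        the documented ranges."""
        gens = [
            lambda r: straight_approach(
                eye_height=r.uniform(1.0, 1.8), speed=r.uniform(0.5, 2.5),
                fixation_offset_angle=r.uniform(-25, 25),
                duration=0.1, fps=r.choice([30, 60, 120]),
                start_distance=r.uniform(2, 10),
            ),
            lambda r: sinusoid_trajectory(
                axis=r.choice(["vertical", "horizontal"]),
                amplitude=r.uniform(0, 0.3), frequency=r.uniform(0.2, 3),
                base_speed=r.uniform(0.5, 2.5), duration=0.1, fps=60,
            ),
            lambda r: corkscrew_trajectory(
                radius=r.uniform(0, 0.3), angular_rate=r.uniform(0.2, 3),
                base_speed=r.uniform(0.5, 2.5), duration=0.1, fps=60,
            ),
            lambda r: gait_head_trajectory(
                walk_speed=r.uniform(0.8, 2.0), duration=0.2, fps=60,
                phase_jitter=r.uniform(0, 0.05), seed=int(r.integers(0, 2**31)),
            ),
        ]
        for i in range(1000):
            sc = gens[i % len(gens)](rng)
            sc.validate()  # raises on any invariant violation

    def test_uneven_frame_times_rejected(self):
        t = np.array([0.0, 0.03, 0.07])
        c = np.tile([0, 0, 1.25], (3, 1))
        f = np.tile([0, 5, 0.0], (3, 1))
        with pytest.raises(ScenarioError):
            Scenario(t=t, centers=c, fixations=f, fps=30.0)

    def test_below_ground_eye_rejected(self):
        t = np.arange(3) / 30
        c = np.tile([0, 0, -0.1], (3, 1))
        f = np.tile([0, 5, 0.0], (3, 1))
        with pytest.raises(ScenarioError):
            Scenario(t=t, centers=c, fixations=f, fps=30.0)


class TestPerturbations:
    def test_zero_magnitude_slip_leaves_scenario_unchanged(self):
        sc = straight_approach(duration=1.0, fps=30)
        p = Perturbation(kind="slip", onset=0.3, duration=0.2,
                         direction=(0, -1), magnitude_deg=0.0)
        out = apply_perturbation(sc, p)
        assert np.allclose(out.fixations, sc.fixations, atol=1e-12)

    def test_slip_sweeps_stated_retinal_magnitude(self):
        from gazeflow.eyemodel import orient_to_fixation, project_point

        sc = straight_approach(duration=1.0, fps=40)
        p = Perturbation(kind="slip", onset=0.3, duration=0.25,
                         direction=(0, -1), magnitude_deg=1.0)
        out = apply_perturbation(sc, p)
        i = int(round((p.onset + p.duration) * 40))  # last window frame
        pose = orient_to_fixation(out.centers[i], out.fixations[i])
        rc = project_point(pose, sc.fixations[i])
        assert rc.rho == pytest.approx(1.0, abs=1e-6)

    def test_overlapping_same_kind_rejected(self):
        sc = straight_approach(duration=1.0, fps=30)
        p1 = Perturbation(kind="slip", onset=0.2, duration=0.3, magnitude_deg=0.5)
        p2 = Perturbation(kind="slip", onset=0.4, duration=0.3, magnitude_deg=0.5)
        out = apply_perturbation(sc, p1)
        with pytest.raises(OverlappingPerturbationError):
            apply_perturbation(out, p2)

    def test_window_outside_duration_rejected(self):
        sc = straight_approach(duration=0.5, fps=30)
        p = Perturbation(kind="saccade", onset=0.4, duration=0.3, rate_deg_s=100.0)
        with pytest.raises(ScenarioError):
            apply_perturbation(sc, p)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ScenarioError):
            Perturbation(kind="blink", onset=0.0, duration=0.1)


class TestCalibrationSessionGenerator:
    def test_no_misalignment_intersects_at_calib_point(self):
        s = synth_calibration_session(true_misalignment=(0, 0, 0), noise_deg=0.0)
        pts = calib.gaze_ground_intersections(s, [0.0, 0.0, 0.0])
        assert np.allclose(pts[:, :2], s.calib_point[:2], atol=1e-9)

    def test_true_rotation_restores_alignment(self):
        mis = (4.0, -2.5, 1.5)
        s = synth_calibration_session(true_misalignment=mis, noise_deg=0.0)
        pts = calib.gaze_ground_intersections(s, mis)
        assert calib.calibration_error(pts, s.calib_point) == pytest.approx(0.0, abs=1e-9)

    def test_single_axis_sweep_flagged_degenerate(self):
        s = synth_calibration_session(sweep=((0.0, 20.0),))
        assert s.degenerate_sweep
        s2 = synth_calibration_session()
        assert not s2.degenerate_sweep

    def test_seeded_noise_is_reproducible(self):
        a = synth_calibration_session(noise_deg=0.5, seed=3)
        b = synth_calibration_session(noise_deg=0.5, seed=3)
        assert np.array_equal(a.raw_gaze, b.raw_gaze)
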