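"""Synthetic eye trajectories, fixation schedules, and perturbations.

These generators stand in for recorded gaze/kinematic sessions: they emit
:class:`Scenario` objects (frame-by-frame eye center and fixated ground
point) with the statistical structure of natural locomotion — constant
velocity approaches with lateral fixation offsets, sinusoidal and
corkscrew trajectories, gait-like head oscillation whose vertical velocity
peaks at the step frequency (~2 Hz) with peak magnitude about half the
walking speed, fixation-slip and saccade perturbations, and head-sweep
calibration sessions with a known sensor misalignment.

World frame: x right, y forward, z up; ground plane z = 0.  All
stochastic elements are driven by an explicit integer seed; identical
seeds and parameters reproduce bit-identical scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.spatial.transform import Rotation

from . import calib as _calib
from .eyemodel import orient_to_fixation

DEFAULT_EYE_HEIGHT = 1.25  # m; order of leg length plus trunk, configurable
DEFAULT_FPS = 60.0


class ScenarioError(ValueError):
    """Invalid scenario or perturbation configuration."""


class OverlappingPerturbationError(ScenarioError):
    """Same-kind perturbation windows overlap."""


@dataclass
class Perturbation:
    """A fixation imperfection injected into a scenario window.

    kind = "slip": the gaze ray sweeps ``magnitude_deg`` of visual angle
    uniformly over the window, so the fixated image slips across the fovea
    in retinal ``direction`` (chart convention: +x right, +y up).
    kind = "saccade": the gaze rotates at ``rate_deg_s`` in ``direction``
    for the window duration, overriding fixation.
    """

    kind: str
    onset: float
    duration: float
    direction: tuple = (0.0, -1.0)
    magnitude_deg: float = 0.0  # slip: total retinal sweep
    rate_deg_s: float = 0.0  # saccade: rotation rate

    def __post_init__(self) -> None:
        if self.kind not in ("slip", "saccade"):
            raise ScenarioError(f"unknown perturbation kind {self.kind!r}")
        if self.duration <= 0:
            raise ScenarioError("perturbation duration must be positive")
        d = np.hypot(*self.direction)
        if d < 1e-12:
            raise ScenarioError("perturbation direction must be non-zero")

    @property
    def window(self) -> tuple[float, float]:
        return (self.onset, self.onset + self.duration)


@dataclass
class Scenario:
    """Time series of eye positions and fixated ground points driving the
    whole retinal-flow pipeline."""

    t: np.ndarray
    centers: np.ndarray  # (n, 3)
    fixations: np.ndarray  # (n, 3), z = 0
    fps: float
    walk_speed: float | None = None
    eye_height: float | None = None
    perturbations: list = dataclass_field(default_factory=list)
    seed: int | None = None
    kind: str = "custom"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.fixations = np.asarray(self.fixations, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.t.size
        if self.centers.shape != (n, 3) or self.fixations.shape != (n, 3):
            raise ScenarioError("centers/fixations must be (n_frames, 3)")
        if self.fps <= 0:
            raise ScenarioError("fps must be positive")
        dt = np.diff(self.t)
        if n > 1 and not np.all(dt > 0):
            raise ScenarioError("t must be strictly increasing")
        if n > 1 and not np.allclose(dt, 1.0 / self.fps, rtol=1e-6, atol=1e-9):
            raise ScenarioError("t must be spaced at 1/fps")
        if np.any(self.centers[:, 2] <= 0):
            raise ScenarioError("eye center must stay above the ground plane")
        if np.any(np.abs(self.fixations[:, 2]) > 1e-9):
            raise ScenarioError("fixation points must lie on the ground plane")

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def velocities(self) -> np.ndarray:
        """Per-frame eye velocity (m/s) by backward difference, matching the
        frame-pair convention of the flow computation; the first frame
        repeats the second."""
        v = np.empty_like(self.centers)
        v[1:] = (self.centers[1:] - self.centers[:-1]) * self.fps
        v[0] = v[1] if self.n_frames > 1 else 0.0
        return v

    def replace_fixations(self, fixations: np.ndarray, perturbations: list) -> "Scenario":
        return Scenario(
            t=self.t.copy(), centers=self.centers.copy(), fixations=fixations,
            fps=self.fps, walk_speed=self.walk_speed, eye_height=self.eye_height,
            perturbations=perturbations, seed=self.seed, kind=self.kind,
        )


def _frame_times(duration: float, fps: float) -> np.ndarray:
    n = int(round(duration * fps)) + 1
    return np.arange(n) / fps


def straight_approach(
    eye_height: float = DEFAULT_EYE_HEIGHT,
    speed: float = 1.25,
    fixation_offset_angle: float = 0.0,
    duration: float = 2.0,
    fps: float = DEFAULT_FPS,
    start_distance: float = 5.0,
    seed: int | None = None,
) -> Scenario:
    """Constant-velocity, constant-height straight path along +Y.

    The fixation point sits ``start_distance`` m from the eye's initial
    ground position, placed so that the signed angle from the velocity
    direction to the fixation direction at t = 0 equals
    ``fixation_offset_angle`` (degrees; positive = the eye will pass to the
    right of the fixation point, i.e. fixation to the left of the track).
    """
    if speed <= 0:
        raise ScenarioError("speed must be positive")
    t = _frame_times(duration, fps)
    centers = np.column_stack([
        np.zeros_like(t), speed * t, np.full_like(t, eye_height)
    ])
    a = math.radians(fixation_offset_angle)
    fix = np.array([-start_distance * math.sin(a), start_distance * math.cos(a), 0.0])
    fixations = np.tile(fix, (t.size, 1))
    return Scenario(
        t=t, centers=centers, fixations=fixations, fps=fps,
        walk_speed=speed, eye_height=eye_height, seed=seed, kind="straight_approach",
    )


def sinusoid_trajectory(
    axis: str = "vertical",
    amplitude: float = 0.1,
    frequency: float = 1.0,
    base_speed: float = 1.25,
    duration: float = 2.0,
    fps: float = DEFAULT_FPS,
    eye_height: float = DEFAULT_EYE_HEIGHT,
    fixation_distance: float = 5.0,
    seed: int | None = None,
) -> Scenario:
    """Straight base path plus a sinusoidal displacement on one axis,
    fixating a fixed ground point ahead."""
    if axis not in ("vertical", "horizontal"):
        raise ScenarioError("axis must be 'vertical' or 'horizontal'")
    if amplitude < 0:
        raise ScenarioError("amplitude must be >= 0")
    t = _frame_times(duration, fps)
    wave = amplitude * np.sin(2 * np.pi * frequency * t)
    x = wave if axis == "horizontal" else np.zeros_like(t)
    z = np.full_like(t, eye_height) + (wave if axis == "vertical" else 0.0)
    centers = np.column_stack([x, base_speed * t, z])
    fixations = np.tile([0.0, fixation_distance, 0.0], (t.size, 1))
    return Scenario(
        t=t, centers=centers, fixations=fixations, fps=fps,
        walk_speed=base_speed, eye_height=eye_height, seed=seed,
        kind=f"sinusoid_{axis}",
    )


def corkscrew_trajectory(
    radius: float = 0.1,
    angular_rate: float = 1.0,
    base_speed: float = 1.25,
    duration: float = 2.0,
    fps: float = DEFAULT_FPS,
    eye_height: float = DEFAULT_EYE_HEIGHT,
    fixation_distance: float = 5.0,
    seed: int | None = None,
) -> Scenario:
    """Forward motion with circular displacement in the frontal plane:
    vertical and horizontal sinusoids in exact quadrature at
    ``angular_rate`` (Hz)."""
    if radius < 0:
        raise ScenarioError("radius must be >= 0")
    t = _frame_times(duration, fps)
    phase = 2 * np.pi * angular_rate * t
    centers = np.column_stack([
        radius * np.cos(phase),
        base_speed * t,
        np.full_like(t, eye_height) + radius * np.sin(phase),
    ])
    fixations = np.tile([0.0, fixation_distance, 0.0], (t.size, 1))
    return Scenario(
        t=t, centers=centers, fixations=fixations, fps=fps,
        walk_speed=base_speed, eye_height=eye_height, seed=seed, kind="corkscrew",
    )


def gait_head_trajectory(
    walk_speed: float = 1.25,
    step_frequency: float = 2.0,
    vertical_peak_vel_fraction: float = 0.5,
    lateral_peak_vel_fraction: float = 0.15,
    duration: float = 4.0,
    fps: float = DEFAULT_FPS,
    eye_height: float = DEFAULT_EYE_HEIGHT,
    fixation_distance: float = 5.0,
    phase_jitter: float = 0.0,
    seed: int | None = None,
) -> Scenario:
    """Gait-like head oscillation during forward walking.

    Vertical velocity oscillates at the step frequency (default 2 Hz, the
    natural footstep period) with peak magnitude
    ``vertical_peak_vel_fraction * walk_speed`` (default one half of the
    walking speed); a smaller lateral sway oscillates at half the step
    frequency (alternating feet).  ``phase_jitter`` adds a random-walk
    phase wander (radians per sqrt-frame) controlled by ``seed``.
    """
    if walk_speed <= 0:
        raise ScenarioError("walk_speed must be positive")
    t = _frame_times(duration, fps)
    phase_v = 2 * np.pi * step_frequency * t
    phase_l = np.pi * step_frequency * t  # half frequency
    if phase_jitter > 0:
        rng = np.random.default_rng(seed)
        wander = np.cumsum(rng.normal(0.0, phase_jitter, t.size))
        phase_v = phase_v + wander
        phase_l = phase_l + 0.5 * wander
    v_peak = vertical_peak_vel_fraction * walk_speed
    l_peak = lateral_peak_vel_fraction * walk_speed
    # displacement amplitudes giving the requested peak velocities
    amp_v = v_peak / (2 * np.pi * step_frequency)
    amp_l = l_peak / (np.pi * step_frequency)
    centers = np.column_stack([
        amp_l * np.sin(phase_l),
        walk_speed * t,
        np.full_like(t, eye_height) - amp_v * np.cos(phase_v),
    ])
    fixations = np.tile([0.0, fixation_distance, 0.0], (t.size, 1))
    return Scenario(
        t=t, centers=centers, fixations=fixations, fps=fps,
        walk_speed=walk_speed, eye_height=eye_height, seed=seed, kind="gait_head",
    )


def apply_perturbation(scenario: Scenario, pert: Perturbation) -> Scenario:
    """Inject a slip or saccade by redirecting the gaze ray frame by frame.

    The perturbed gaze direction is the unperturbed (fixating) direction
    rotated by the accumulated perturbation angle toward the retinal
    direction in which the gaze moves; the stored fixation point becomes
    the rotated ray's ground intersection.  For slip the *image* of the
    previously fixated point drifts in ``pert.direction``, so the gaze ray
    rotates opposite to it; a saccade rotates the gaze in
    ``pert.direction`` at ``rate_deg_s``.
    """
    lo, hi = pert.window
    if lo < scenario.t[0] - 1e-9 or hi > scenario.t[-1] + 1e-9:
        raise ScenarioError("perturbation window outside scenario duration")
    for other in scenario.perturbations:
        if other.kind == pert.kind:
            olo, ohi = other.window
            if lo < ohi and olo < hi:
                raise OverlappingPerturbationError(
                    f"overlapping {pert.kind} windows {other.window} and {pert.window}"
                )
    u = np.asarray(pert.direction, dtype=float)
    u = u / np.linalg.norm(u)
    if pert.kind == "slip":
        u = -u  # gaze moves opposite to the image slip

    fixations = scenario.fixations.copy()
    prev_pose = None
    for i in range(scenario.n_frames):
        ti = scenario.t[i]
        if ti < lo - 1e-9 or ti > hi + 1e-9:
            continue
        if pert.kind == "slip":
            ang = pert.magnitude_deg * (ti - lo) / pert.duration
        else:
            ang = pert.rate_deg_s * (ti - lo)
        pose = orient_to_fixation(scenario.centers[i], scenario.fixations[i], prev_pose)
        prev_pose = pose
        ang_rad = np.radians(ang)
        d_ret = u[0] * pose.right_dir + u[1] * pose.up_dir
        new_dir = np.cos(ang_rad) * pose.gaze_dir + np.sin(ang_rad) * d_ret
        origin = pose.center
        if new_dir[2] >= -1e-12:
            raise ScenarioError(
                "perturbed gaze ray does not intersect the ground "
                f"(frame {i}, angle {ang:.2f} deg)"
            )
        t_hit = -origin[2] / new_dir[2]
        fixations[i] = origin + t_hit * new_dir
        fixations[i, 2] = 0.0
    return scenario.replace_fixations(fixations, scenario.perturbations + [pert])


DEFAULT_SWEEP = ((0.0, 20.0), (20.0, 0.0), (15.0, 15.0))


def synth_calibration_session(
    true_misalignment=(0.0, 0.0, 0.0),
    sweep=DEFAULT_SWEEP,
    calib_distance: float = 1.4,
    noise_deg: float = 0.0,
    seed: int | None = None,
    eye_height: float = 1.6,
    frames_per_segment: int = 200,
    fps: float = 120.0,
):
    """Synthesize a head-sweep calibration session with a known sensor
    misalignment.

    The subject stands with the calibration point ``calib_distance`` m
    ahead of the vertical projection of the eye on the ground, holds gaze
    on it, and sweeps the head through the ``sweep`` segments (each a
    ``(yaw_amplitude_deg, pitch_amplitude_deg)`` sinusoidal excursion:
    up/down, left/right, diagonal).  Per frame the true eye-in-head gaze is
    corrupted by the *inverse* of ``true_misalignment`` (intrinsic X-Y-Z
    Euler degrees) plus optional per-axis Gaussian angular noise, so
    recovering the misalignment re-aligns the rays with the point.

    Returns a :class:`gazeflow.calib.CalibrationSession`; sessions with a
    single-axis sweep are flagged ``degenerate_sweep`` (rotation about the
    gaze axis is unobservable).
    """
    if len(sweep) < 1:
        raise ScenarioError("sweep must contain at least one segment")
    rng = np.random.default_rng(seed)
    eye_center = np.array([0.0, 0.0, eye_height])
    calib_point = np.array([0.0, calib_distance, 0.0])
    g_world = calib_point - eye_center
    g_world = g_world / np.linalg.norm(g_world)

    yaws, pitches = [], []
    for yaw_amp, pitch_amp in sweep:
        s = np.sin(2 * np.pi * np.arange(frames_per_segment) / frames_per_segment)
        yaws.append(yaw_amp * s)
        pitches.append(pitch_amp * s)
    yaw = np.concatenate(yaws)
    pitch = np.concatenate(pitches)
    n = yaw.size
    head = Rotation.from_euler("ZX", np.column_stack([yaw, pitch]), degrees=True)

    gaze_in_head = head.inv().apply(g_world)
    r_mis = Rotation.from_euler("XYZ", true_misalignment, degrees=True)
    raw = r_mis.inv().apply(gaze_in_head)
    if noise_deg > 0:
        noise = Rotation.from_rotvec(np.radians(rng.normal(0.0, noise_deg, (n, 3))))
        raw = np.einsum("nij,nj->ni", noise.as_matrix(), raw)
    raw = raw / np.linalg.norm(raw, axis=1, keepdims=True)

    # a sweep is degenerate when head rotation explores (nearly) one axis only
    active = [(abs(ya) > 1e-9, abs(pa) > 1e-9) for ya, pa in sweep]
    axes_used = {ax for pair in active for ax, on in zip(("yaw", "pitch"), pair) if on}
    degenerate = len(axes_used) < 2

    return _calib.CalibrationSession(
        head_rotations=head,
        eye_centers=np.tile(eye_center, (n, 1)),
        raw_gaze=raw,
        calib_point=calib_point,
        t=np.arange(n) / fps,
        degenerate_sweep=degenerate,
    )
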