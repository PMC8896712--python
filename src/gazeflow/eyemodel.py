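"""Geometry of the fixating spherical pinhole eye.

The eye is a sphere (anatomical radius 12 mm) with a pinhole pupil at one
pole and the fovea at the opposite pole.  It sits at a 3D position above a
flat ground plane (z = 0) and is oriented so that the optic axis (the line
through fovea and pupil) passes through a fixated ground point, with
minimal torsion about the optic axis: the eye's transverse axis (the
retinal equator direction) stays horizontal, so the orientation is a yaw
to the gaze azimuth followed by a pure pitch -- the rotation that carries
the horizontal-forward reference gaze to the gaze direction with zero
twist.  This horizon-fixed frame makes projection equivariant under
ground-plane isometries; its one degenerate configuration is gaze
straight down (no azimuth), resolved by carrying the equator over from
the previous frame's pose.

Because the pupil is a single point, projection preserves ray angles, so
a ground point's retinal position reduces to the spherical direction of
the incoming ray.  Ray directions are anchored at the eye *centre* (the
nodal-point convention), which makes the retinal coordinates exactly
independent of eye radius; anchoring at the pole pupil instead would
shift angles by O(radius / distance) ~ 0.5% at metre-scale distances.

* ``rho``   -- angular eccentricity (degrees of visual angle): the angle
  between the incoming ray and the optic axis; equals the great-circle
  distance from the fovea of the ray's second intersection with the eye
  sphere.
* ``theta`` -- polar angle measured from the eye's transverse-plane
  equator, stored in *visual-field* convention (upper visual field at
  +pi/2, right visual field at theta 0), i.e. the 180-degree retinal flip
  is applied once here, not at plot time.

World frame: x right, y forward, z up; ground plane z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

REFERENCE_GAZE = np.array([0.0, 1.0, 0.0])
DEFAULT_EYE_RADIUS_MM = 12.0
DEFAULT_FOV_DEG = 60.0
DEFAULT_MAX_GROUND_DISTANCE = 50.0


class EyeModelError(ValueError):
    """Base error for eye-model geometry."""


class GazeDegenerateError(EyeModelError):
    """Gaze points straight down (no azimuth) and no prior pose is
    available to define the equator direction."""


class DegenerateRayError(EyeModelError):
    """Ground point coincides with the pupil point."""


@dataclass
class EyePose:
    """Position and minimal-torsion orientation of the fixating eye."""

    center: np.ndarray
    gaze_rotation: Rotation
    fixation: np.ndarray
    radius_mm: float = DEFAULT_EYE_RADIUS_MM

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.fixation = np.asarray(self.fixation, dtype=float)
        if self.center[2] <= 0:
            raise EyeModelError("eye center must be above the ground plane")

    @property
    def gaze_dir(self) -> np.ndarray:
        """Unit optic-axis direction, from fovea through pupil to fixation."""
        return self.gaze_rotation.apply(REFERENCE_GAZE)

    @property
    def right_dir(self) -> np.ndarray:
        """Unit vector toward the right visual field (transverse equator)."""
        return self.gaze_rotation.apply([1.0, 0.0, 0.0])

    @property
    def up_dir(self) -> np.ndarray:
        """Unit vector toward the upper visual field."""
        return self.gaze_rotation.apply([0.0, 0.0, 1.0])

    @property
    def radius_m(self) -> float:
        return self.radius_mm * 1e-3

    @property
    def pupil_pos(self) -> np.ndarray:
        """The pinhole pupil: the scene-ward pole of the eye sphere."""
        return self.center + self.radius_m * self.gaze_dir

    @property
    def fovea_pos(self) -> np.ndarray:
        return self.center - self.radius_m * self.gaze_dir

    @property
    def declination_deg(self) -> float:
        """Gaze angle below the horizontal, in degrees."""
        g = self.gaze_dir
        return float(np.degrees(np.arctan2(-g[2], np.hypot(g[0], g[1]))))

    @property
    def ground_pos(self) -> np.ndarray:
        """Vertical projection of the eye center onto the ground plane."""
        return np.array([self.center[0], self.center[1], 0.0])


@dataclass
class RetinalCoord:
    """Polar retinal position: ``theta`` (radians, from the transverse
    equator, visual-field convention) and ``rho`` (degrees of visual angle
    from the fovea)."""

    theta: float
    rho: float


@dataclass
class GroundGrid:
    """Evenly spaced points on the ground plane (z = 0)."""

    points: np.ndarray  # (n, 3), all z = 0
    spacing: float
    extent: tuple  # (xmin, xmax, ymin, ymax)

    @classmethod
    def from_bbox(cls, xmin, xmax, ymin, ymax, spacing: float = 0.25) -> "GroundGrid":
        if spacing <= 0:
            raise EyeModelError("spacing must be positive")
        gx = np.arange(xmin, xmax + spacing / 2, spacing)
        gy = np.arange(ymin, ymax + spacing / 2, spacing)
        xx, yy = np.meshgrid(gx, gy)
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        return cls(pts, spacing, (float(xmin), float(xmax), float(ymin), float(ymax)))

    @classmethod
    def covering_scenario(
        cls,
        scenario,
        fov_deg: float = DEFAULT_FOV_DEG,
        spacing: float = 0.25,
        max_ground_distance: float = DEFAULT_MAX_GROUND_DISTANCE,
        frame_stride: int = 10,
    ) -> "GroundGrid":
        """Grid whose extent covers the eye's field-of-view footprint over
        the scenario (sampled frames plus endpoints), with one spacing of
        margin."""
        idx = sorted(set(range(0, scenario.n_frames, frame_stride)) | {scenario.n_frames - 1})
        lo = np.array([np.inf, np.inf])
        hi = np.array([-np.inf, -np.inf])
        prev = None
        for i in idx:
            pose = orient_to_fixation(scenario.centers[i], scenario.fixations[i], prev)
            prev = pose
            curve, _ = fov_ground_boundary(
                pose, fov_deg, max_ground_distance=max_ground_distance
            )
            lo = np.minimum(lo, curve.min(axis=0))
            hi = np.maximum(hi, curve.max(axis=0))
        lo -= spacing
        hi += spacing
        return cls.from_bbox(lo[0], hi[0], lo[1], hi[1], spacing)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def orient_to_fixation(
    center, fixation, prev_pose: EyePose | None = None,
    radius_mm: float = DEFAULT_EYE_RADIUS_MM,
) -> EyePose:
    """Minimal-torsion pose fixating a ground point.

    Zero torsion is defined against the horizon: the eye's transverse
    (equator) axis stays horizontal, perpendicular to the gaze azimuth,
    so the rotation is the geodesic carrying the horizontal-forward
    reference gaze to the gaze direction with no twist about the optic
    axis.  For gaze straight down the azimuth is undefined; the equator
    direction is then taken from the previous frame's pose (an error when
    no prior pose is given).
    """
    center = np.asarray(center, dtype=float)
    fixation = np.asarray(fixation, dtype=float)
    if center[2] <= 0:
        raise EyeModelError("eye center must be above the ground plane")
    if abs(fixation[2]) > 1e-9:
        raise EyeModelError("fixation point must lie on the ground plane")
    g = fixation - center
    norm = np.linalg.norm(g)
    if norm < 1e-12:
        raise EyeModelError("fixation coincides with the eye center")
    g = g / norm
    horiz = np.hypot(g[0], g[1])
    if horiz < 1e-12:
        if prev_pose is None:
            raise GazeDegenerateError(
                "gaze is straight down and no prior pose defines the equator"
            )
        r = prev_pose.right_dir
        r = np.array([r[0], r[1], 0.0])
        rn = np.linalg.norm(r)
        if rn < 1e-12:
            raise GazeDegenerateError("prior pose equator is vertical")
        right = r / rn
    else:
        # horizontal, 90 degrees clockwise (viewed from above) of the azimuth
        right = np.array([g[1], -g[0], 0.0]) / horiz
    up = np.cross(right, g)
    rot = Rotation.from_matrix(np.column_stack([right, g, up]))
    return EyePose(center=center, gaze_rotation=rot, fixation=fixation, radius_mm=radius_mm)


def fov_ground_boundary(
    pose: EyePose,
    fov_radius_deg: float = DEFAULT_FOV_DEG,
    n_samples: int = 360,
    max_ground_distance: float = DEFAULT_MAX_GROUND_DISTANCE,
) -> tuple[np.ndarray, bool]:
    """Sampled intersection of the field-of-view cone with the ground plane.

    Returns ``(curve, bounded)`` where ``curve`` is an (n, 2) array of
    ground x, y and ``bounded`` is False when the cone's upper edge reaches
    the horizontal (the intersection is then unbounded and rays that miss
    the ground -- or strike it beyond ``max_ground_distance`` -- are clipped
    at ``max_ground_distance``)."""
    half = np.radians(fov_radius_deg)
    phi = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    g, r, u = pose.gaze_dir, pose.right_dir, pose.up_dir
    dirs = (
        np.cos(half) * g[None, :]
        + np.sin(half) * (np.cos(phi)[:, None] * r[None, :] + np.sin(phi)[:, None] * u[None, :])
    )
    origin = pose.center
    dz = dirs[:, 2]
    bounded = bool(np.all(dz < -1e-12))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -origin[2] / dz
    horiz = np.linalg.norm(dirs[:, :2], axis=1)
    t_clip = np.where(horiz > 1e-12, max_ground_distance / np.maximum(horiz, 1e-12), 0.0)
    miss = (dz >= -1e-12) | (t < 0) | (t * horiz > max_ground_distance)
    t = np.where(miss, t_clip, t)
    pts = origin[None, :2] + t[:, None] * dirs[:, :2]
    return pts, bounded


def project_points(
    pose: EyePose, points: np.ndarray, fov_deg: float = DEFAULT_FOV_DEG
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project many ground points; returns ``(in_view, theta, rho)`` arrays.

    ``in_view`` is a boolean mask (within the field-of-view cone and in
    front of the pupil plane); theta/rho are NaN where not in view.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    v = pts - pose.center
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateRayError("a point coincides with the pupil")
    vn = v / norms[:, None]
    c = vn @ pose.gaze_dir
    a = vn @ pose.right_dir
    b = vn @ pose.up_dir
    # arctan2 keeps rho well-conditioned at the fovea (arccos loses ~8
    # digits there, which would alias into spurious foveal flow)
    rho = np.degrees(np.arctan2(np.hypot(a, b), c))
    theta = np.arctan2(b, a)
    in_view = (rho <= fov_deg) & (c > 0)
    theta = np.where(in_view, theta, np.nan)
    rho = np.where(in_view, rho, np.nan)
    return in_view, theta, rho


def project_point(
    pose: EyePose, p, fov_deg: float = DEFAULT_FOV_DEG
) -> RetinalCoord | None:
    """Project one ground point to retinal polar coordinates, or None when
    the point is out of view."""
    in_view, theta, rho = project_points(pose, np.asarray(p, float)[None, :], fov_deg)
    if not in_view[0]:
        return None
    return RetinalCoord(theta=float(theta[0]), rho=float(rho[0]))


def project_grid(
    pose: EyePose,
    grid: GroundGrid,
    fov_deg: float = DEFAULT_FOV_DEG,
    extra_points: np.ndarray | None = None,
):
    """Project a ground grid (plus optional extra anchor points) keeping
    stable point ids.

    Returns a :class:`FrameProjection` with ids into the concatenated
    point array (grid points first, then extras); out-of-view points are
    omitted but ids are preserved for re-entry bookkeeping.
    """
    pts = grid.points
    if extra_points is not None and len(extra_points):
        pts = np.vstack([pts, np.atleast_2d(extra_points)])
    in_view, theta, rho = project_points(pose, pts, fov_deg)
    ids = np.flatnonzero(in_view)
    return FrameProjection(ids=ids, theta=theta[ids], rho=rho[ids])


@dataclass
class FrameProjection:
    """Per-frame retinal positions of visible points, keyed by stable id."""

    ids: np.ndarray
    theta: np.ndarray
    rho: np.ndarray

    def __len__(self) -> int:
        return self.ids.size


def retinal_to_direction(pose: EyePose, theta, rho_deg) -> np.ndarray:
    """World-frame unit ray direction(s) for retinal coordinates."""
    theta = np.asarray(theta, dtype=float)
    rho = np.radians(np.asarray(rho_deg, dtype=float))
    g, r, u = pose.gaze_dir, pose.right_dir, pose.up_dir
    d = (
        np.cos(rho)[..., None] * g
        + np.sin(rho)[..., None] * (np.cos(theta)[..., None] * r + np.sin(theta)[..., None] * u)
    )
    return d


def retinal_to_ground(pose: EyePose, theta, rho_deg) -> np.ndarray:
    """Inverse projection: cast the retinal ray back to the ground plane.

    Returns (…, 2) ground x, y; NaN where the ray does not descend."""
    d = retinal_to_direction(pose, theta, rho_deg)
    origin = pose.center
    dz = d[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -origin[2] / dz
    ok = (dz < -1e-12) & (t > 0)
    t = np.where(ok, t, np.nan)
    return origin[:2] + t[..., None] * d[..., :2]


def poses_for_scenario(scenario, radius_mm: float = DEFAULT_EYE_RADIUS_MM) -> list:
    """Minimal-torsion pose per scenario frame (prior pose threaded through
    for degenerate gazes)."""
    poses = []
    prev = None
    for i in range(scenario.n_frames):
        pose = orient_to_fixation(
            scenario.centers[i], scenario.fixations[i], prev, radius_mm=radius_mm
        )
        poses.append(pose)
        prev = pose
    return poses


def write_pose_table(scenario, path) -> None:
    """Trajectory table: t, cx, cy, cz, fx, fy (one row per frame)."""
    df = pd.DataFrame(
        {
            "t": scenario.t,
            "cx": scenario.centers[:, 0],
            "cy": scenario.centers[:, 1],
            "cz": scenario.centers[:, 2],
            "fx": scenario.fixations[:, 0],
            "fy": scenario.fixations[:, 1],
        }
    )
    df.to_csv(path, index=False)
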