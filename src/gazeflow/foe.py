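"""Head-centered focus-of-expansion detection on dense 2D flow fields.

The FoE of an expanding flow field is a repellor node.  Negating the field
turns it into an attractor: a uniform grid of particles advected along the
negated field piles up at the FoE.  Endpoints are histogrammed into square
bins; if the winning bin captures at least a majority fraction (default
50%) of the particles, the FoE is present and located at the centroid of
that bin's endpoints (sub-bin accuracy), otherwise it is out of view.

FoE per-frame displacement is converted to deg/s by scaling field units to
degrees with the camera field of view and multiplying by the frame rate.

:func:`head_frame_flow` generates head-centered flow from the geometric
scenario model — projecting the ground grid into a head-fixed,
non-fixating pinhole camera and differencing consecutive frames — so the
tracker is testable without any recorded video.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import vfield
from .eyemodel import GroundGrid
from .vfield import VectorField2D


class FoeError(ValueError):
    """Invalid FoE-tracker input."""


@dataclass
class FoeResult:
    """Outcome of FoE detection on one flow field."""

    present: bool
    location: np.ndarray | None  # field coordinates, None when absent
    fraction: float  # endpoint share of the winning bin
    n_particles: int

    def __repr__(self) -> str:
        loc = None if self.location is None else tuple(np.round(self.location, 3))
        return (
            f"FoeResult(present={self.present}, location={loc}, "
            f"fraction={self.fraction:.3f}, n_particles={self.n_particles})"
        )


def track_foe(
    field: VectorField2D,
    seeds_per_axis: int = 20,
    bin_size: float | None = None,
    majority: float = 0.5,
    step: float | None = None,
    max_steps: int = 600,
) -> FoeResult:
    """Detect the focus of expansion by negated-field particle drift.

    Parameters
    ----------
    seeds_per_axis : uniform seed grid resolution across the field.
    bin_size : endpoint histogram bin edge length in field units
        (default 1/20 of the field width).
    majority : minimum endpoint fraction for a present FoE.
    """
    if field.x.size < 2 or field.y.size < 2 or not field.mask.any():
        raise FoeError("flow field is empty")
    neg = VectorField2D(field.x, field.y, -field.vel_x, -field.vel_y, field.mask)
    width = float(field.x[-1] - field.x[0])
    height = float(field.y[-1] - field.y[0])
    if bin_size is None:
        bin_size = width / 20.0
    sx = np.linspace(field.x[0], field.x[-1], seeds_per_axis + 2)[1:-1]
    sy = np.linspace(field.y[0], field.y[-1], seeds_per_axis + 2)[1:-1]
    xx, yy = np.meshgrid(sx, sy)
    seeds = np.column_stack([xx.ravel(), yy.ravel()])
    lines = vfield.advect_streamlines(neg, seeds, step=step, max_steps=max_steps)
    ends = lines.endpoints
    ok = np.all(np.isfinite(ends), axis=1)
    ends = ends[ok]
    n = seeds.shape[0]
    if ends.shape[0] == 0:
        return FoeResult(False, None, 0.0, n)
    bx = np.arange(field.x[0], field.x[-1] + bin_size, bin_size)
    by = np.arange(field.y[0], field.y[-1] + bin_size, bin_size)
    hist, _, _ = np.histogram2d(ends[:, 0], ends[:, 1], bins=(bx, by))
    ix, iy = np.unravel_index(np.argmax(hist), hist.shape)
    in_bin = (
        (ends[:, 0] >= bx[ix]) & (ends[:, 0] < bx[ix] + bin_size)
        & (ends[:, 1] >= by[iy]) & (ends[:, 1] < by[iy] + bin_size)
    )
    if not in_bin.any():
        return FoeResult(False, None, 0.0, n)
    # merge endpoint clusters that straddle a bin edge: count everything
    # within one bin radius of the winning bin's provisional centroid
    seed_loc = ends[in_bin].mean(axis=0)
    near = np.linalg.norm(ends - seed_loc, axis=1) <= bin_size
    fraction = float(near.sum()) / n
    if fraction < majority:
        return FoeResult(False, None, fraction, n)
    location = ends[near].mean(axis=0)
    return FoeResult(True, location, fraction, n)


def foe_velocity(
    loc_t: np.ndarray | None,
    loc_t1: np.ndarray | None,
    fov_deg: float,
    field_width: float,
    fps: float,
) -> float:
    """FoE speed in deg/s between two consecutive present frames.

    Euclidean displacement in field units, scaled to degrees by
    ``fov_deg / field_width``, times the frame rate.  NaN when either
    frame has no FoE.
    """
    if loc_t is None or loc_t1 is None:
        return float("nan")
    d = float(np.linalg.norm(np.asarray(loc_t1, float) - np.asarray(loc_t, float)))
    return d * (fov_deg / field_width) * fps


@dataclass
class CameraSpec:
    """Head-fixed pinhole camera: full horizontal field of view in degrees,
    image resolution (odd node count per axis, 1-"pixel" node spacing),
    fixed pitch/yaw (degrees; positive pitch looks up) and an optional yaw
    rate for pure-rotation scenarios."""

    fov_deg: float = 100.0
    resolution: int = 41
    pitch_deg: float = 0.0
    yaw_deg: float = 0.0
    yaw_rate_deg_s: float = 0.0

    def orientation(self, t: float) -> Rotation:
        yaw = self.yaw_deg + self.yaw_rate_deg_s * t
        return Rotation.from_euler("ZX", [yaw, self.pitch_deg], degrees=True)

    def axes(self) -> np.ndarray:
        half = self.resolution // 2
        return np.arange(-half, half + 1, dtype=float)

    @property
    def width(self) -> float:
        return float(self.resolution - 1)


def _project_camera(cam: CameraSpec, rot: Rotation, pos: np.ndarray, pts: np.ndarray):
    fwd = rot.apply([0.0, 1.0, 0.0])
    right = rot.apply([1.0, 0.0, 0.0])
    up = rot.apply([0.0, 0.0, 1.0])
    d = pts - pos
    depth = d @ fwd
    with np.errstate(divide="ignore", invalid="ignore"):
        xt = (d @ right) / depth
        yt = (d @ up) / depth
    half_tan = np.tan(np.radians(cam.fov_deg / 2.0))
    scale = (cam.width / 2.0) / half_tan
    px = xt * scale
    py = yt * scale
    half = cam.width / 2.0
    ok = (depth > 1e-9) & (np.abs(px) <= half) & (np.abs(py) <= half)
    return ok, px, py


def _backdrop_points(scenario, distance: float, spacing: float) -> np.ndarray:
    """Static frontal plane of scene points far ahead of the whole
    trajectory, standing in for the above-horizon structure (trees,
    buildings) of a natural scene; without it the synthetic flow field
    would be empty above the horizon."""
    y_wall = float(scenario.centers[:, 1].max()) + distance
    x = np.arange(-distance, distance + spacing, spacing)
    z = np.arange(spacing / 2, distance + spacing, spacing)
    xx, zz = np.meshgrid(x, z)
    return np.column_stack([xx.ravel(), np.full(xx.size, y_wall), zz.ravel()])


def head_frame_flow(
    scenario,
    frame_index: int,
    camera: CameraSpec | None = None,
    grid: GroundGrid | None = None,
    ground_spacing: float = 0.5,
    ground_extent: float = 20.0,
    backdrop_distance: float = 40.0,
    backdrop_spacing: float = 1.0,
) -> VectorField2D:
    """Head-centered flow for one scenario frame pair.

    Projects the scene points (ground grid plus a static far backdrop
    plane) into the head-fixed camera on frames ``frame_index - 1`` and
    ``frame_index``, differences the image positions of points visible on
    both, and interpolates onto the regular camera grid (units: pixels per
    frame).  Set ``backdrop_distance`` to 0 to disable the backdrop.
    """
    if frame_index < 1 or frame_index >= scenario.n_frames:
        raise FoeError("frame_index must address a consecutive frame pair")
    camera = camera or CameraSpec()
    if grid is None:
        c = scenario.centers[frame_index]
        grid = GroundGrid.from_bbox(
            c[0] - ground_extent, c[0] + ground_extent,
            c[1] - ground_extent, c[1] + ground_extent,
            ground_spacing,
        )
    pts = grid.points
    if backdrop_distance > 0:
        pts = np.vstack([pts, _backdrop_points(scenario, backdrop_distance, backdrop_spacing)])
    res = []
    for j in (frame_index - 1, frame_index):
        rot = camera.orientation(float(scenario.t[j]))
        res.append(_project_camera(camera, rot, scenario.centers[j], pts))
    (ok0, x0, y0), (ok1, x1, y1) = res
    both = ok0 & ok1
    pos = np.column_stack([x1[both], y1[both]])
    disp = np.column_stack([x1[both] - x0[both], y1[both] - y0[both]])
    ax = camera.axes()
    return vfield.interpolate_scattered(pos, disp, ax, ax)


def track_scenario(
    scenario,
    camera: CameraSpec | None = None,
    majority: float = 0.5,
    **flow_kwargs,
) -> pd.DataFrame:
    """Per-frame FoE track for a scenario: frame, present, x, y, fraction,
    velocity_deg_s (deg/s between consecutive present frames)."""
    camera = camera or CameraSpec()
    rows = []
    prev_loc = None
    for i in range(1, scenario.n_frames):
        field = head_frame_flow(scenario, i, camera, **flow_kwargs)
        r = track_foe(field, majority=majority)
        vel = foe_velocity(prev_loc, r.location, camera.fov_deg, camera.width, scenario.fps)
        rows.append({
            "frame": i,
            "present": r.present,
            "x": np.nan if r.location is None else r.location[0],
            "y": np.nan if r.location is None else r.location[1],
            "fraction": r.fraction,
            "velocity_deg_s": vel,
        })
        prev_loc = r.location
    return pd.DataFrame(rows)
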