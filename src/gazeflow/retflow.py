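"""Per-frame retinal flow and its curl/divergence features.

Successive projections of the ground grid through the fixating pinhole eye
yield per-point retinal displacements; these are interpolated onto a
regular grid on the azimuthal-equidistant retinal chart, where planar
divergence and z-curl are computed.  From those fields come the features
of interest:

* **foveal curl** — mean curl in a small window around the fovea; its sign
  says on which side of the path the fixated point lies (positive =
  fixation left, the body passes to its right), its magnitude grows with
  the offset angle.
* **point of maximum divergence** — the peak of the divergence "hill";
  back-projected to the ground it lies on the line through the eye's
  ground position along the ground-projected velocity, so it encodes the
  instantaneous over-ground velocity vector in retinotopic coordinates.
* **foveal iso-contour** — the divergence level set through the foveal
  value; during a straight approach to the fixated point it starts in the
  lower visual field, constricts to a point when the eye is one eye height
  from the fixation point (45 degree gaze declination), then reopens into
  the upper field.

The planar calculus on the chart ignores the spherical metric distortion
of the azimuthal-equidistant map (< 5% at 60 degrees eccentricity).
Velocities are deg/s (per-frame chart displacement times fps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from skimage import measure

from . import vfield
from .eyemodel import (
    DEFAULT_FOV_DEG,
    EyePose,
    FrameProjection,
    GroundGrid,
    project_grid,
    poses_for_scenario,
    retinal_to_ground,
)
from .vfield import ScalarField2D, VectorField2D


class RetinalFlowError(ValueError):
    """Invalid retinal-flow input."""


class ZeroVelocityError(RetinalFlowError):
    """Heading angles are undefined for zero horizontal velocity."""


class EmptyFovealWindowError(RetinalFlowError):
    """No valid grid nodes inside the foveal window."""


def chart(theta, rho):
    """Azimuthal-equidistant chart of retinal polar coordinates.

    x = rho*cos(theta), y = rho*sin(theta); rho in degrees, theta in the
    visual-field convention (upper field at +pi/2, right field at 0)."""
    theta = np.asarray(theta, dtype=float)
    rho = np.asarray(rho, dtype=float)
    return rho * np.cos(theta), rho * np.sin(theta)


def unchart(x, y):
    """Inverse chart; defined for rho < 180 degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.arctan2(y, x), np.hypot(x, y)


@dataclass
class RetinalGridSpec:
    """Regular grid on the retinal chart: rho <= fov_deg, node spacing in
    degrees (default 1 degree over a 60-degree field)."""

    fov_deg: float = DEFAULT_FOV_DEG
    spacing_deg: float = 1.0

    def axes(self) -> np.ndarray:
        n = int(round(self.fov_deg / self.spacing_deg))
        return np.arange(-n, n + 1) * self.spacing_deg

    def fovea_index(self) -> int:
        return int(round(self.fov_deg / self.spacing_deg))


def point_flow(prev: FrameProjection, curr: FrameProjection, fps: float):
    """Per-point retinal displacement between consecutive frames.

    Only ids visible on both frames carry flow (newly visible points are
    undefined on their first frame).  Returns ``(ids, pos, disp, vel)``:
    current chart positions (deg), displacements (deg/frame) and
    velocities (deg/s).
    """
    if fps <= 0:
        raise RetinalFlowError("fps must be positive")
    shared, i_prev, i_curr = np.intersect1d(
        prev.ids, curr.ids, assume_unique=True, return_indices=True
    )
    px, py = chart(prev.theta[i_prev], prev.rho[i_prev])
    cx, cy = chart(curr.theta[i_curr], curr.rho[i_curr])
    pos = np.column_stack([cx, cy])
    disp = np.column_stack([cx - px, cy - py])
    return shared, pos, disp, disp * fps


@dataclass
class RetinalFlowFrame:
    """Scattered point flow for one frame plus its regular-grid
    interpolation and derived curl/divergence fields."""

    t: float
    fps: float
    point_ids: np.ndarray
    point_pos: np.ndarray  # chart deg
    point_vel: np.ndarray  # deg/s
    grid_flow: VectorField2D
    curl_field: ScalarField2D
    div_field: ScalarField2D
    spec: RetinalGridSpec

    def flow_at_fovea(self) -> np.ndarray:
        """Grid-flow velocity (deg/s) at the fovea node."""
        i = self.spec.fovea_index()
        return np.array([self.grid_flow.vel_x[i, i], self.grid_flow.vel_y[i, i]])


def flow_frame(
    point_ids: np.ndarray,
    point_pos: np.ndarray,
    point_vel: np.ndarray,
    spec: RetinalGridSpec,
    fps: float,
    t: float = 0.0,
) -> RetinalFlowFrame:
    """Interpolate scattered point velocities onto the retinal grid and
    compute curl and divergence."""
    ax = spec.axes()
    grid = vfield.interpolate_scattered(point_pos, point_vel, ax, ax)
    xx, yy = grid.meshgrid()
    inside = np.hypot(xx, yy) <= spec.fov_deg + 1e-9
    mask = grid.mask & inside
    grid = VectorField2D(
        grid.x, grid.y,
        np.where(mask, grid.vel_x, np.nan),
        np.where(mask, grid.vel_y, np.nan),
        mask,
    )
    return RetinalFlowFrame(
        t=t, fps=fps, point_ids=point_ids, point_pos=point_pos, point_vel=point_vel,
        grid_flow=grid, curl_field=vfield.curl_z(grid), div_field=vfield.divergence(grid),
        spec=spec,
    )


def foveal_curl(frame: RetinalFlowFrame, window_deg: float = 2.0) -> float:
    """Mean curl (1/s) over valid grid nodes within ``window_deg`` of the
    fovea, reported in the retinal-surface sign convention: positive when
    the trajectory passes to the *right* of the fixated point (fixation on
    the left of the path), negative for fixation on the right, zero when
    fixation is aligned with the velocity vector.

    The curl field itself is computed on the visual-field chart, where the
    mathematical (counter-clockwise positive) convention gives the
    opposite sign: the chart and the physical retinal surface are mirror
    images, and mirroring flips curl.  The walker-facing feature uses the
    retinal-surface sign so that its sign directly encodes the fixation
    side.
    """
    xx, yy = frame.curl_field.meshgrid()
    sel = (np.hypot(xx, yy) <= window_deg + 1e-9) & frame.curl_field.mask
    if not sel.any():
        raise EmptyFovealWindowError(
            f"no valid curl nodes within {window_deg} deg of the fovea"
        )
    return float(-frame.curl_field.value[sel].mean())


@dataclass
class MaxDivergence:
    """Location of the divergence peak, on the retina and on the ground."""

    chart_xy: np.ndarray  # refined chart position, deg
    coord: "tuple"  # (theta, rho)
    ground_xy: np.ndarray  # inverse-projected ground point (NaN above horizon)
    value: float
    on_boundary: bool


def _quadratic_refine(values: np.ndarray, iy: int, ix: int, dx: float, dy: float):
    """Sub-node refinement of an argmax by a least-squares quadratic fit
    over the 3x3 neighbourhood; returns (offset_x, offset_y) clamped to one
    cell, or (0, 0) when the fit is not a proper maximum."""
    patch = values[iy - 1 : iy + 2, ix - 1 : ix + 2]
    if patch.shape != (3, 3) or not np.all(np.isfinite(patch)):
        return 0.0, 0.0
    gx, gy = np.meshgrid([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0])
    a = np.column_stack([
        np.ones(9), gx.ravel(), gy.ravel(),
        gx.ravel() ** 2, (gx * gy).ravel(), gy.ravel() ** 2,
    ])
    coef, *_ = np.linalg.lstsq(a, patch.ravel(), rcond=None)
    _, c1, c2, c3, c4, c5 = coef
    h = np.array([[2 * c3, c4], [c4, 2 * c5]])
    det = np.linalg.det(h)
    if det <= 0 or h[0, 0] >= 0:  # not a local maximum
        return 0.0, 0.0
    off = np.linalg.solve(h, -np.array([c1, c2]))
    off = np.clip(off, -1.0, 1.0)
    return float(off[0] * dx), float(off[1] * dy)


def max_divergence(frame: RetinalFlowFrame, pose: EyePose) -> MaxDivergence:
    """Argmax of the divergence field, refined by a quadratic fit and
    back-projected to the ground plane.

    Ties at the maximum break toward the fovea (the foveal iso-contour
    encloses the peak).  A peak on the valid-mask or grid boundary is
    flagged ``on_boundary``.
    """
    f = frame.div_field
    if not f.mask.any():
        raise RetinalFlowError("divergence field has no valid nodes")
    vals = np.where(f.mask, f.value, -np.inf)
    vmax = vals.max()
    ties = np.argwhere(vals >= vmax - 1e-15)
    xx, yy = f.meshgrid()
    ecc = np.hypot(xx[ties[:, 0], ties[:, 1]], yy[ties[:, 0], ties[:, 1]])
    iy, ix = ties[np.argmin(ecc)]
    ny, nx = f.shape
    on_edge = iy in (0, ny - 1) or ix in (0, nx - 1)
    if not on_edge:
        neigh = f.mask[iy - 1 : iy + 2, ix - 1 : ix + 2]
        on_edge = not neigh.all()
    dx = float(f.x[1] - f.x[0])
    dy = float(f.y[1] - f.y[0])
    offx, offy = (0.0, 0.0)
    if not on_edge:
        offx, offy = _quadratic_refine(f.value, iy, ix, dx, dy)
    cx = float(f.x[ix]) + offx
    cy = float(f.y[iy]) + offy
    theta, rho = unchart(cx, cy)
    ground = retinal_to_ground(pose, theta, rho)
    return MaxDivergence(
        chart_xy=np.array([cx, cy]),
        coord=(float(theta), float(rho)),
        ground_xy=np.asarray(ground, dtype=float),
        value=float(vmax),
        on_boundary=bool(on_edge),
    )


@dataclass
class IsoContour:
    """Divergence level set through the foveal value.

    ``state``: "closed" (closed curve near the fovea, enclosed area >=
    one grid cell), "degenerate" (enclosed area below one grid cell — the
    contour has constricted to a point), "open" (the component reaches the
    field-of-view boundary), or "absent" (no component found)."""

    state: str
    curve: np.ndarray | None  # (n, 2) chart points
    area: float  # enclosed area, deg^2 (0 when open/absent)
    level: float


def _shoelace(curve: np.ndarray) -> float:
    x, y = curve[:, 0], curve[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def foveal_isocontour(frame: RetinalFlowFrame) -> IsoContour:
    """Extract the divergence iso-contour at the foveal divergence value
    (marching squares), keeping the connected component nearest the fovea."""
    f = frame.div_field
    i = frame.spec.fovea_index()
    if not f.mask[i, i]:
        raise RetinalFlowError("fovea node is masked; iso-contour undefined")
    level = float(f.value[i, i])
    values = np.where(f.mask, f.value, np.nan)
    try:
        contours = measure.find_contours(values, level)
    except ValueError:
        contours = []
    if not contours:
        # a level set at the field maximum is a single point: the contour
        # has constricted onto the fovea
        vmax = np.nanmax(values)
        state = "degenerate" if level >= vmax - 1e-12 else "absent"
        return IsoContour(state=state, curve=None, area=0.0, level=level)
    dx = float(f.x[1] - f.x[0])
    dy = float(f.y[1] - f.y[0])
    best, best_dist = None, np.inf
    for c in contours:
        # rows are y indices, cols are x indices -> chart coordinates
        pts = np.column_stack([f.x[0] + c[:, 1] * dx, f.y[0] + c[:, 0] * dy])
        d = np.hypot(pts[:, 0], pts[:, 1]).min()
        if d < best_dist:
            best, best_dist = pts, d
    closed = np.allclose(best[0], best[-1], atol=1e-9)
    if not closed:
        return IsoContour(state="open", curve=best, area=0.0, level=level)
    area = _shoelace(best)
    cell = abs(dx * dy)
    state = "degenerate" if area < cell else "closed"
    return IsoContour(state=state, curve=best, area=float(area), level=level)


def signed_ground_angle(origin_xy, direction_xy, target_xy) -> float:
    """Signed degrees from a ground direction to the direction of a target
    point; positive when the target lies to the left of the direction
    (i.e. the path passes to the right of the target)."""
    v = np.asarray(direction_xy, dtype=float)
    if np.hypot(*v) < 1e-12:
        raise ZeroVelocityError("zero horizontal velocity: heading angle undefined")
    f = np.asarray(target_xy, dtype=float) - np.asarray(origin_xy, dtype=float)
    cross = v[0] * f[1] - v[1] * f[0]
    dot = v[0] * f[0] + v[1] * f[1]
    return float(np.degrees(np.arctan2(cross, dot)))


def heading_angles(
    pose: EyePose, velocity: np.ndarray, maxdiv_ground_xy
) -> tuple[float, float]:
    """Heading-angle pair, both with vertex at the eye's ground
    position and positive = the eye passes to the right of the fixated
    point:

    * ``velocity_fixation_angle`` — from the ground-projected velocity
      direction to the direction of the fixation point;
    * ``maxdiv_fixation_angle``  — the same construction with the
      direction to the max-divergence ground point in place of the
      velocity direction.

    Because the velocity line always passes through the max-divergence
    ground point, the two angles agree (up to grid resolution)."""
    v = np.asarray(velocity, dtype=float)[:2]
    origin = pose.ground_pos[:2]
    vel_fix = signed_ground_angle(origin, v, pose.fixation[:2])
    md = np.asarray(maxdiv_ground_xy, dtype=float)
    if np.all(np.isfinite(md)):
        md_dir = md - origin
        md_fix = signed_ground_angle(origin, md_dir, pose.fixation[:2])
    else:
        md_fix = float("nan")
    return vel_fix, md_fix


def backproject_scalar(sfield: ScalarField2D, pose: EyePose) -> tuple[pd.DataFrame, int]:
    """Map each valid retinal node through the inverse projection to the
    ground plane, carrying its scalar value.

    Returns (table with gx, gy, value, x, y) and the count of nodes
    dropped for lying above the horizon."""
    xx, yy = sfield.meshgrid()
    sel = sfield.mask
    theta, rho = unchart(xx[sel], yy[sel])
    ground = retinal_to_ground(pose, theta, rho)
    ok = np.all(np.isfinite(ground), axis=-1)
    dropped = int((~ok).sum())
    df = pd.DataFrame(
        {
            "gx": ground[ok, 0],
            "gy": ground[ok, 1],
            "value": sfield.value[sel][ok],
            "x": xx[sel][ok],
            "y": yy[sel][ok],
        }
    )
    return df, dropped


# ---------------------------------------------------------------------------
# scenario-level pipeline


def _fixation_anchors(scenario) -> np.ndarray:
    """Static fixation targets: fixation positions held for at least two
    consecutive frames are added to the projected scatter so the fovea
    carries an exact zero-flow datum during perfect fixation."""
    fx = scenario.fixations
    anchors = []
    for i in range(scenario.n_frames - 1):
        if np.allclose(fx[i], fx[i + 1], atol=1e-12):
            anchors.append(fx[i])
    if not anchors:
        return np.empty((0, 3))
    uniq = np.unique(np.round(np.asarray(anchors), 9), axis=0)
    return uniq


def _disc_patch(center_xy, radius: float, spacing: float) -> np.ndarray:
    """Static fine ground-point disc (z = 0) centred on a ground location."""
    r = np.arange(-radius, radius + spacing / 2, spacing)
    xx, yy = np.meshgrid(center_xy[0] + r, center_xy[1] + r)
    keep = np.hypot(xx - center_xy[0], yy - center_xy[1]) <= radius + 1e-12
    return np.column_stack([xx[keep], yy[keep], np.zeros(keep.sum())])


def spherical_divergence(field: VectorField2D) -> ScalarField2D:
    """Divergence of a retinal chart field with the spherical metric.

    The azimuthal-equidistant chart stretches the tangential direction by
    ``rho / sin(rho)``; for a field with radial/tangential physical
    components ``F_r`` and ``F_t = F_t_chart * sin(rho)/rho`` the surface
    divergence is

        dF_r/drho + cot(rho) F_r + (1/sin rho) dF_t/dtheta.

    Input units deg (chart) and deg/s (velocity); output 1/s.  Within half
    a degree of the fovea the planar value is used (the two agree to
    O(rho^2) there and the polar terms are numerically singular).
    """
    deg = np.pi / 180.0
    xx, yy = field.meshgrid()
    rho = np.hypot(xx, yy) * deg
    theta = np.arctan2(yy, xx)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    vx = np.where(field.mask, field.vel_x, np.nan) * deg
    vy = np.where(field.mask, field.vel_y, np.nan) * deg
    f_r = vx * cos_t + vy * sin_t
    f_t_chart = -vx * sin_t + vy * cos_t
    with np.errstate(invalid="ignore", divide="ignore"):
        stretch = np.where(rho > 1e-12, np.sin(rho) / rho, 1.0)
    f_t = f_t_chart * stretch
    # chart-cartesian gradients (per radian of chart distance)
    x_rad = field.x * deg
    y_rad = field.y * deg
    dfr_dx = np.gradient(f_r, x_rad, axis=1)
    dfr_dy = np.gradient(f_r, y_rad, axis=0)
    dft_dx = np.gradient(f_t, x_rad, axis=1)
    dft_dy = np.gradient(f_t, y_rad, axis=0)
    dfr_drho = cos_t * dfr_dx + sin_t * dfr_dy
    # (1/sin rho) d(F_t)/dtheta = (rho/sin rho) * tangential derivative
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_stretch = np.where(rho > 1e-12, rho / np.sin(rho), 1.0)
        cot = np.where(rho > 1e-12, np.cos(rho) / np.sin(rho), 0.0)
    div_s = dfr_drho + cot * f_r + inv_stretch * (-sin_t * dft_dx + cos_t * dft_dy)
    planar = np.gradient(vx, x_rad, axis=1) + np.gradient(vy, y_rad, axis=0)
    near_pole = rho < 0.5 * deg
    value = np.where(near_pole, planar, div_s)
    mask = np.isfinite(value) & field.mask
    return ScalarField2D(field.x, field.y, value, mask)


def _quadratic_peak(
    xx: np.ndarray, yy: np.ndarray, vals: np.ndarray, sel: np.ndarray,
    center: np.ndarray, radius: float,
):
    """Least-squares 2D quadratic peak fit over nodes within ``radius`` of
    ``center``; returns the stationary point or None when the fit is not a
    proper maximum."""
    near = sel & (np.hypot(xx - center[0], yy - center[1]) <= radius)
    if near.sum() < 8:
        return None
    px = xx[near] - center[0]
    py = yy[near] - center[1]
    a = np.column_stack([np.ones(px.size), px, py, px**2, px * py, py**2])
    coef, *_ = np.linalg.lstsq(a, vals[near], rcond=None)
    _, c1, c2, c3, c4, c5 = coef
    h = np.array([[2 * c3, c4], [c4, 2 * c5]])
    if np.linalg.det(h) <= 0 or h[0, 0] >= 0:
        return None
    off = np.linalg.solve(h, -np.array([c1, c2]))
    if np.hypot(*off) > radius:
        return None
    return center + off


def exact_local_flow(
    prev_pose: EyePose, pose: EyePose, fps: float, ax: np.ndarray, ay: np.ndarray
) -> VectorField2D:
    """Model-exact retinal flow on a chart window.

    The ground plane of the model is continuous, so the flow at any chart
    node can be evaluated without scatter interpolation: invert the node's
    retinal ray to its ground point at the current frame, project that
    (static) ground point at the previous frame, and difference the chart
    positions.  Nodes whose ray misses the ground are masked."""
    from .eyemodel import project_points

    xx, yy = np.meshgrid(ax, ay)
    theta, rho = unchart(xx.ravel(), yy.ravel())
    g = retinal_to_ground(pose, theta, rho)
    ok = np.all(np.isfinite(g), axis=-1)
    pts = np.column_stack([np.nan_to_num(g[:, 0]), np.nan_to_num(g[:, 1]), np.zeros(g.shape[0])])
    ok0, th0, rh0 = project_points(prev_pose, pts, fov_deg=179.0)
    x0, y0 = chart(th0, rh0)
    vx = (xx.ravel() - x0) * fps
    vy = (yy.ravel() - y0) * fps
    bad = ~(ok & ok0)
    vx[bad] = np.nan
    vy[bad] = np.nan
    return VectorField2D(ax, ay, vx.reshape(xx.shape), vy.reshape(xx.shape))


def refine_max_divergence(
    prev_pose: EyePose,
    pose: EyePose,
    fps: float,
    coarse: MaxDivergence,
    fine_spacing_deg: float = 0.2,
    fine_radius_deg: float = 6.0,
    fit_radius_deg: float = 1.5,
    n_iter: int = 2,
) -> MaxDivergence:
    """Two-stage localisation of the divergence peak.

    The divergence hill is extremely flat near its top (relative variation
    of order 1e-4 over a degree), so the argmax of the scatter-interpolated
    global field carries degrees of localisation noise.  Each refinement
    pass evaluates the *model-exact* flow (:func:`exact_local_flow`) on a
    fine chart window around the current estimate, takes the argmax of the
    metric-corrected (spherical) divergence, and fits a quadratic over a
    neighbourhood to place the peak sub-node.  The spherical correction
    matters here: the flat-chart divergence peak is displaced by the
    chart's tangential stretching at eccentricities of tens of degrees,
    which would bias the peak off the velocity line; the surface
    divergence peak lies on it.  Falls back to the incoming estimate when
    the peak is on a boundary or the local problem is degenerate."""
    best = coarse
    if best.on_boundary or not np.all(np.isfinite(best.ground_xy)):
        return best
    for _ in range(n_iter):
        n = int(round(fine_radius_deg / fine_spacing_deg))
        ax = best.chart_xy[0] + np.arange(-n, n + 1) * fine_spacing_deg
        ay = best.chart_xy[1] + np.arange(-n, n + 1) * fine_spacing_deg
        try:
            local = exact_local_flow(prev_pose, pose, fps, ax, ay)
            div = spherical_divergence(local)
        except vfield.VectorFieldError:
            return best
        if not div.mask.any():
            return best
        vals = np.where(div.mask, div.value, -np.inf)
        iy, ix = np.unravel_index(np.argmax(vals), vals.shape)
        peak = np.array([ax[ix], ay[iy]])
        xx, yy = div.meshgrid()
        fitted = _quadratic_peak(xx, yy, div.value, div.mask, peak, fit_radius_deg)
        if fitted is not None:
            peak = fitted
        theta, rho = unchart(peak[0], peak[1])
        ground = retinal_to_ground(pose, theta, rho)
        if not np.all(np.isfinite(ground)):
            return best
        best = MaxDivergence(
            chart_xy=peak,
            coord=(float(theta), float(rho)),
            ground_xy=np.asarray(ground, dtype=float),
            value=float(vals[iy, ix]),
            on_boundary=False,
        )
    return best


@dataclass
class FrameFeatures:
    """Scalar feature row extracted from one retinal-flow frame."""

    t: float
    declination_deg: float
    foveal_curl: float
    foveal_speed: float
    anchor_speed: float  # image speed (deg/s) of the static fixation target
    maxdiv_theta: float
    maxdiv_rho: float
    maxdiv_gx: float
    maxdiv_gy: float
    vel_fix_angle: float
    maxdiv_fix_angle: float
    isocontour_state: str
    isocontour_area: float


def analyze_scenario(
    scenario,
    spec: RetinalGridSpec | None = None,
    ground_spacing: float = 0.25,
    max_ground_distance: float = 15.0,
    foveal_window_deg: float = 2.0,
    fixation_patch_radius: float = 0.6,
    fixation_patch_spacing: float = 0.02,
    refine_maxdiv: bool = True,
    keep_frames: bool = False,
    grid: GroundGrid | None = None,
):
    """Run the full retinal-flow pipeline over a scenario.

    Per frame: orient the eye to the fixation point, project the ground
    grid (plus static fixation anchors), difference consecutive
    projections, interpolate to the retinal grid, and extract the feature
    row.  The flow on the first frame is defined to be zero, so its
    features are zeros with the max-divergence entries undefined.

    A uniform ground grid is retinally coarse near the eye, so two static
    refinements keep the foveal features resolution-limited by the retinal
    grid rather than by the ground sampling: a fine ground-point disc
    around each static fixation target (``fixation_patch_*``), and a
    two-stage local re-localisation of the divergence peak
    (``refine_maxdiv``; see :func:`refine_max_divergence`).

    Returns ``(features_df, frames)`` where ``frames`` is a list of
    :class:`RetinalFlowFrame` when ``keep_frames`` else an empty list.
    """
    spec = spec or RetinalGridSpec()
    if grid is None:
        grid = GroundGrid.covering_scenario(
            scenario, fov_deg=spec.fov_deg, spacing=ground_spacing,
            max_ground_distance=max_ground_distance,
            frame_stride=max(1, min(5, scenario.n_frames - 1)),
        )
    anchors = _fixation_anchors(scenario)
    extras = [anchors] if len(anchors) else []
    if fixation_patch_radius > 0 and fixation_patch_spacing > 0:
        for a in anchors:
            extras.append(_disc_patch(a[:2], fixation_patch_radius, fixation_patch_spacing))
    extra_pts = np.vstack(extras) if extras else np.empty((0, 3))
    anchor_id = grid.n_points if len(anchors) else None
    poses = poses_for_scenario(scenario)
    velocities = scenario.velocities()

    rows = []
    frames = []
    prev_proj = None
    for i, pose in enumerate(poses):
        proj = project_grid(pose, grid, fov_deg=spec.fov_deg, extra_points=extra_pts)
        if i == 0:
            rows.append(FrameFeatures(
                t=float(scenario.t[0]), declination_deg=pose.declination_deg,
                foveal_curl=0.0, foveal_speed=0.0, anchor_speed=0.0,
                maxdiv_theta=np.nan, maxdiv_rho=np.nan,
                maxdiv_gx=np.nan, maxdiv_gy=np.nan,
                vel_fix_angle=np.nan, maxdiv_fix_angle=np.nan,
                isocontour_state="zero-flow", isocontour_area=0.0,
            ))
            prev_proj = proj
            continue
        ids, pos, _, vel = point_flow(prev_proj, proj, scenario.fps)
        frame = flow_frame(ids, pos, vel, spec, scenario.fps, t=float(scenario.t[i]))
        try:
            fc = foveal_curl(frame, foveal_window_deg)
        except EmptyFovealWindowError:
            fc = np.nan
        fspeed = float(np.hypot(*frame.flow_at_fovea()))
        a_speed = np.nan
        if anchor_id is not None:
            hit = np.flatnonzero(ids == anchor_id)
            if hit.size:
                a_speed = float(np.hypot(*vel[hit[0]]))
        md = max_divergence(frame, pose)
        if refine_maxdiv:
            md = refine_max_divergence(poses[i - 1], pose, scenario.fps, md)
        try:
            iso = foveal_isocontour(frame)
        except RetinalFlowError:
            iso = IsoContour(state="undefined", curve=None, area=0.0, level=np.nan)
        try:
            vel_fix, md_fix = heading_angles(pose, velocities[i], md.ground_xy)
        except ZeroVelocityError:
            vel_fix, md_fix = np.nan, np.nan
        rows.append(FrameFeatures(
            t=float(scenario.t[i]), declination_deg=pose.declination_deg,
            foveal_curl=fc, foveal_speed=fspeed, anchor_speed=a_speed,
            maxdiv_theta=md.coord[0], maxdiv_rho=md.coord[1],
            maxdiv_gx=float(md.ground_xy[0]), maxdiv_gy=float(md.ground_xy[1]),
            vel_fix_angle=vel_fix, maxdiv_fix_angle=md_fix,
            isocontour_state=iso.state, isocontour_area=iso.area,
        ))
        if keep_frames:
            frames.append(frame)
        prev_proj = proj

    df = pd.DataFrame([r.__dict__ for r in rows])
    return df, frames
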