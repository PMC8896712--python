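"""Planar vector-field calculus on regular grids.

Canonical expansion/rotation/spiral field generators, numerical divergence
and z-curl, scattered-to-grid interpolation, and streamline particle
advection.  These primitives are shared by the retinal-flow feature
extraction (:mod:`gazeflow.retflow`) and the head-centered
focus-of-expansion tracker (:mod:`gazeflow.foe`).

Conventions
-----------
Grids are rectangular with strictly monotone, evenly spaced axes.  Velocity
and scalar arrays are indexed ``[iy, ix]`` (row = y, column = x).  Positive
z-curl means counter-clockwise rotation with x pointing right and y
pointing up.  Divergence and curl are evaluated with central differences on
interior nodes and one-sided differences at the boundary, which is exact
for fields linear in position (so the canonical unit-strength fields have
divergence/curl exactly 2 at *every* node, edges included).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator
from scipy.spatial import QhullError


class VectorFieldError(ValueError):
    """Base error for vector-field operations."""


class UnknownFieldKindError(VectorFieldError):
    """Requested canonical field kind is not recognised."""


class GridTooSmallError(VectorFieldError):
    """Differential operators need at least 3 nodes per axis."""


class DegenerateScatterError(VectorFieldError):
    """Scattered points are too few or collinear to triangulate."""


class NonPositiveStepError(VectorFieldError):
    """Advection step must be positive."""


CANONICAL_KINDS = ("expansion", "rotation_ccw", "rotation_cw", "spiral")


@dataclass
class VectorField2D:
    """A 2D velocity field sampled on a regular rectangular grid.

    Parameters
    ----------
    x, y : 1D arrays of node coordinates (strictly monotone, evenly spaced).
    vel_x, vel_y : velocity components, shape ``(len(y), len(x))``.
    mask : boolean validity flags, same shape; invalid nodes carry no
        finite-velocity requirement.
    """

    x: np.ndarray
    y: np.ndarray
    vel_x: np.ndarray
    vel_y: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.vel_x = np.asarray(self.vel_x, dtype=float)
        self.vel_y = np.asarray(self.vel_y, dtype=float)
        shape = (self.y.size, self.x.size)
        if self.vel_x.shape != shape or self.vel_y.shape != shape:
            raise VectorFieldError(
                f"velocity arrays must have shape {shape}, got "
                f"{self.vel_x.shape} / {self.vel_y.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise VectorFieldError("mask shape must match grid shape")
        for axis in (self.x, self.y):
            if axis.size < 2:
                continue
            d = np.diff(axis)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise VectorFieldError("grid axes must be strictly monotone")
            if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
                raise VectorFieldError("grid axes must be evenly spaced")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y.size, self.x.size)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    @property
    def spacing(self) -> float:
        """Smallest axis spacing (magnitude)."""
        return float(min(abs(self.dx), abs(self.dy)))

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)

    def speed(self) -> np.ndarray:
        return np.hypot(self.vel_x, self.vel_y)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a table with columns x, y, vx, vy, valid."""
        xx, yy = self.meshgrid()
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "vx": self.vel_x.ravel(),
                "vy": self.vel_y.ravel(),
                "valid": self.mask.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VectorField2D":
        x = np.unique(df["x"].to_numpy())
        y = np.unique(df["y"].to_numpy())
        shape = (y.size, x.size)
        if len(df) != shape[0] * shape[1]:
            raise VectorFieldError("table does not cover a full regular grid")
        order = np.lexsort((df["x"].to_numpy(), df["y"].to_numpy()))
        vx = df["vx"].to_numpy()[order].reshape(shape)
        vy = df["vy"].to_numpy()[order].reshape(shape)
        valid = df["valid"].to_numpy()[order].reshape(shape).astype(bool)
        return cls(x, y, vx, vy, valid)


@dataclass
class ScalarField2D:
    """A scalar (e.g. divergence or curl, units 1/time) on the same grid
    layout as its source :class:`VectorField2D`."""

    x: np.ndarray
    y: np.ndarray
    value: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.value)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y.size, self.x.size)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)

    def to_frame(self) -> pd.DataFrame:
        xx, yy = self.meshgrid()
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "value": self.value.ravel(),
                "valid": self.mask.ravel(),
            }
        )


@dataclass
class StreamlineSet:
    """Particle paths advected along a vector field.

    ``paths[i]`` is the ordered point sequence for ``seeds[i]``; it always
    starts at the seed and terminates on grid exit, on convergence (particle
    trapped near an attractor), or at the step budget.
    """

    seeds: np.ndarray
    paths: list
    endpoints: np.ndarray
    n_steps: np.ndarray
    terminated: np.ndarray  # True where the particle stopped before max_steps


def make_canonical_field(kind: str, extent: int, spacing: float = 1.0) -> VectorField2D:
    """Build one of the canonical linear flow fields on [-extent, extent]^2.

    ``expansion``     v = ( x,  y)   (uniform divergence 2, curl 0)
    ``rotation_ccw``  v = (-y,  x)   (uniform curl +2, divergence 0)
    ``rotation_cw``   v = ( y, -x)   (uniform curl -2, divergence 0)
    ``spiral``        v = (x-y, y+x) (expansion + ccw rotation; both 2)
    """
    if kind not in CANONICAL_KINDS:
        raise UnknownFieldKindError(
            f"unknown canonical field kind {kind!r}; expected one of {CANONICAL_KINDS}"
        )
    if extent < 1:
        raise VectorFieldError("extent must be >= 1")
    if spacing <= 0:
        raise VectorFieldError("spacing must be positive")
    ax = np.arange(-extent, extent + spacing / 2, spacing, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    if kind == "expansion":
        vx, vy = xx, yy
    elif kind == "rotation_ccw":
        vx, vy = -yy, xx
    elif kind == "rotation_cw":
        vx, vy = yy, -xx
    else:  # spiral
        vx, vy = xx - yy, yy + xx
    return VectorField2D(ax, ax.copy(), vx.copy(), vy.copy())


def _check_differentiable(field: VectorField2D) -> None:
    if field.x.size < 3 or field.y.size < 3:
        raise GridTooSmallError(
            "divergence/curl need at least 3 nodes per axis, got "
            f"{field.y.size} x {field.x.size}"
        )


def _masked_components(field: VectorField2D) -> tuple[np.ndarray, np.ndarray]:
    vx = np.where(field.mask, field.vel_x, np.nan)
    vy = np.where(field.mask, field.vel_y, np.nan)
    return vx, vy


def divergence(field: VectorField2D) -> ScalarField2D:
    """Numerical divergence d(vx)/dx + d(vy)/dy.

    Central differences on interior nodes, one-sided at the boundary
    (exact for fields linear in position).  Nodes whose stencil touches an
    invalid node are masked in the result.
    """
    _check_differentiable(field)
    vx, vy = _masked_components(field)
    div = np.gradient(vx, field.x, axis=1) + np.gradient(vy, field.y, axis=0)
    mask = np.isfinite(div) & field.mask
    return ScalarField2D(field.x, field.y, div, mask)


def curl_z(field: VectorField2D) -> ScalarField2D:
    """Numerical z-curl d(vy)/dx - d(vx)/dy; positive = counter-clockwise."""
    _check_differentiable(field)
    vx, vy = _masked_components(field)
    curl = np.gradient(vy, field.x, axis=1) - np.gradient(vx, field.y, axis=0)
    mask = np.isfinite(curl) & field.mask
    return ScalarField2D(field.x, field.y, curl, mask)


def interpolate_scattered(
    points: np.ndarray,
    velocities: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
) -> VectorField2D:
    """Piecewise-linear interpolation of scattered 2D velocities onto a grid.

    Nodes outside the convex hull of ``points`` are masked invalid rather
    than extrapolated (flow is undefined where no data constrain it).

    Raises
    ------
    DegenerateScatterError
        If fewer than 3 points are given or all points are collinear.
    """
    points = np.asarray(points, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise DegenerateScatterError("need at least 3 scattered 2D points")
    try:
        interp = LinearNDInterpolator(points, velocities)
    except QhullError as exc:
        raise DegenerateScatterError(f"degenerate point set: {exc}") from exc
    xx, yy = np.meshgrid(np.asarray(grid_x, float), np.asarray(grid_y, float))
    vals = interp(np.column_stack([xx.ravel(), yy.ravel()]))
    vx = vals[:, 0].reshape(xx.shape)
    vy = vals[:, 1].reshape(xx.shape)
    mask = np.isfinite(vx) & np.isfinite(vy)
    vx = np.where(mask, vx, np.nan)
    vy = np.where(mask, vy, np.nan)
    return VectorField2D(np.asarray(grid_x, float), np.asarray(grid_y, float), vx, vy, mask)


def interpolate_at(field: VectorField2D, points: np.ndarray) -> np.ndarray:
    """Bilinear velocity lookup at arbitrary positions; NaN outside the grid
    or next to invalid nodes."""
    vx, vy = _masked_components(field)
    stacked = np.stack([vx, vy], axis=-1)
    interp = RegularGridInterpolator(
        (field.y, field.x), stacked, method="linear",
        bounds_error=False, fill_value=np.nan,
    )
    pts = np.asarray(points, dtype=float)
    return interp(pts[..., ::-1])  # (x, y) -> (row=y, col=x)


def advect_streamlines(
    field: VectorField2D,
    seeds: np.ndarray,
    step: float | None = None,
    max_steps: int = 1000,
    settle_window: int = 16,
) -> StreamlineSet:
    """Advect particles along the field with fixed-step midpoint (RK2)
    integration and bilinear field lookup.

    Each step moves a particle ``step`` units along the locally normalised
    flow direction.  A particle terminates when it leaves the grid (or
    enters a masked region), when its net displacement over the last
    ``settle_window`` steps drops below half a step (trapped at an
    attractor), or at ``max_steps``.

    Parameters
    ----------
    step : arc-length step in field units; default 0.25 grid spacings.
    """
    if step is not None and step <= 0:
        raise NonPositiveStepError(f"step must be positive, got {step}")
    if step is None:
        step = 0.25 * field.spacing
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    n = seeds.shape[0]

    vx, vy = _masked_components(field)
    stacked = np.stack([vx, vy], axis=-1)
    interp = RegularGridInterpolator(
        (field.y, field.x), stacked, method="linear",
        bounds_error=False, fill_value=np.nan,
    )

    def velocity(p: np.ndarray) -> np.ndarray:
        return interp(p[:, ::-1])

    pos = seeds.copy()
    trail = np.full((max_steps + 1, n, 2), np.nan)
    trail[0] = pos
    active = np.ones(n, dtype=bool)
    n_steps = np.zeros(n, dtype=int)
    terminated = np.zeros(n, dtype=bool)
    anchor = pos.copy()  # position settle_window steps ago

    tiny = 1e-30
    for k in range(1, max_steps + 1):
        if not active.any():
            break
        p = pos[active]
        v1 = velocity(p)
        s1 = np.linalg.norm(v1, axis=1, keepdims=True)
        d1 = v1 / np.maximum(s1, tiny)
        mid = p + 0.5 * step * d1
        v2 = velocity(mid)
        s2 = np.linalg.norm(v2, axis=1, keepdims=True)
        d2 = np.where(s2 > tiny, v2 / np.maximum(s2, tiny), d1)
        new = p + step * d2

        ok = np.isfinite(v1).all(axis=1) & np.isfinite(new).all(axis=1)
        # zero-velocity particles are at an equilibrium: stop them in place
        stalled = s1[:, 0] <= tiny
        ok &= ~stalled

        idx = np.flatnonzero(active)
        dead = idx[~ok]
        terminated[dead] = True
        active[dead] = False
        alive = idx[ok]
        pos[alive] = new[ok]
        trail[k, alive] = new[ok]
        n_steps[alive] = k

        if k % settle_window == 0 and alive.size:
            moved = np.linalg.norm(pos[alive] - anchor[alive], axis=1)
            settled = alive[moved < 0.5 * step]
            terminated[settled] = True
            active[settled] = False
            anchor[alive] = pos[alive]

    paths = [trail[: n_steps[i] + 1, i, :].copy() for i in range(n)]
    return StreamlineSet(
        seeds=seeds, paths=paths, endpoints=pos.copy(),
        n_steps=n_steps, terminated=terminated,
    )


def read_vector_field(path) -> VectorField2D:
    """Read a vector field from a delimited table (columns x, y, vx, vy, valid)."""
    return VectorField2D.from_frame(pd.read_csv(path))


def write_vector_field(field: VectorField2D, path) -> None:
    field.to_frame().to_csv(path, index=False)


def write_scalar_field(sfield: ScalarField2D, path) -> None:
    sfield.to_frame().to_csv(path, index=False)
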