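"""VOR-based gaze-alignment calibration.

During calibration the subject fixates a known ground point while sweeping
the head; the vestibulo-ocular reflex counter-rotates the eye, so the true
world gaze is constant while eye-in-head gaze varies.  A fixed rotation
(the sensor misalignment) maps raw eye-in-sensor gaze vectors to
eye-in-head gaze.  It is recovered by minimising the mean distance between
the gaze/ground-plane intersections and the calibration point: only the
correct alignment makes head rotation and eye counter-rotation cancel.

Rotations are parameterised as intrinsic X-Y-Z Euler angles in degrees
(any consistent convention works; the same one is used by the synthetic
session generator).  Rays that do not intersect the ground plane are
truncated at ``truncation_distance`` (default 10 m) and their endpoints
enter the error as-is, which keeps the cost surface finite for large
misalignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

EULER_CONVENTION = "XYZ"  # intrinsic


class CalibrationError(ValueError):
    """Invalid calibration input."""


class OptimizerDidNotConvergeError(RuntimeError):
    """Alignment optimisation failed to converge; carries the final iterate."""

    def __init__(self, message: str, final_euler: np.ndarray):
        super().__init__(message)
        self.final_euler = final_euler


class DegenerateSweepWarning(UserWarning):
    """Head sweep covers a single rotation axis; rotation about the gaze
    axis is unobservable."""


@dataclass
class CalibrationSession:
    """Per-frame head orientations, eye centers and raw (sensor-frame)
    gaze directions, plus the known calibration point."""

    head_rotations: Rotation  # stacked, length n
    eye_centers: np.ndarray  # (n, 3) m
    raw_gaze: np.ndarray  # (n, 3) unit vectors, sensor frame
    calib_point: np.ndarray  # (3,), on the ground plane
    truncation_distance: float = 10.0
    t: np.ndarray | None = None
    degenerate_sweep: bool = False

    def __post_init__(self) -> None:
        self.eye_centers = np.asarray(self.eye_centers, dtype=float)
        self.raw_gaze = np.asarray(self.raw_gaze, dtype=float)
        self.calib_point = np.asarray(self.calib_point, dtype=float)
        n = len(self.head_rotations)
        if self.eye_centers.shape != (n, 3) or self.raw_gaze.shape != (n, 3):
            raise CalibrationError("eye_centers/raw_gaze must be (n, 3)")
        norms = np.linalg.norm(self.raw_gaze, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise CalibrationError("raw gaze directions must be unit length")
        if abs(self.calib_point[2]) > 1e-9:
            raise CalibrationError("calibration point must lie on the ground plane")

    @property
    def n_frames(self) -> int:
        return len(self.head_rotations)

    def to_frame(self) -> pd.DataFrame:
        q = self.head_rotations.as_quat()  # (x, y, z, w)
        t = self.t if self.t is not None else np.arange(self.n_frames, dtype=float)
        return pd.DataFrame(
            {
                "t": t,
                "qw": q[:, 3], "qx": q[:, 0], "qy": q[:, 1], "qz": q[:, 2],
                "cx": self.eye_centers[:, 0],
                "cy": self.eye_centers[:, 1],
                "cz": self.eye_centers[:, 2],
                "gx": self.raw_gaze[:, 0],
                "gy": self.raw_gaze[:, 1],
                "gz": self.raw_gaze[:, 2],
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, calib_point, truncation_distance: float = 10.0
    ) -> "CalibrationSession":
        quat = df[["qx", "qy", "qz", "qw"]].to_numpy()
        return cls(
            head_rotations=Rotation.from_quat(quat),
            eye_centers=df[["cx", "cy", "cz"]].to_numpy(),
            raw_gaze=df[["gx", "gy", "gz"]].to_numpy(),
            calib_point=np.asarray(calib_point, dtype=float),
            truncation_distance=truncation_distance,
            t=df["t"].to_numpy() if "t" in df else None,
        )


@dataclass
class AlignmentResult:
    """Recovered alignment rotation with residual diagnostics."""

    euler_deg: np.ndarray
    residual_error: float  # mean distance to calibration point, m
    scatter_rms: float  # RMS distance of intersections from their centroid, m
    intersections: np.ndarray
    n_frames: int
    n_iterations: int
    converged: bool

    def summary(self) -> str:
        e = self.euler_deg
        lines = [
            "VOR gaze-alignment calibration",
            "==============================",
            f"frames:               {self.n_frames}",
            f"euler X-Y-Z (deg):    [{e[0]: .4f}, {e[1]: .4f}, {e[2]: .4f}]",
            f"residual error (m):   {self.residual_error:.6f}",
            f"scatter RMS (m):      {self.scatter_rms:.6f}",
            f"iterations:           {self.n_iterations}",
            f"converged:            {self.converged}",
        ]
        return "\n".join(lines)


def _world_gaze_dirs(session: CalibrationSession, euler_deg) -> np.ndarray:
    r_align = Rotation.from_euler(EULER_CONVENTION, euler_deg, degrees=True)
    aligned = r_align.apply(session.raw_gaze)
    return session.head_rotations.apply(aligned)


def gaze_ground_intersections(session: CalibrationSession, euler_deg) -> np.ndarray:
    """Ground intersections of the aligned gaze rays.

    Each raw gaze is rotated by the candidate Euler alignment, then by the
    frame's head orientation, and cast from the eye center to z = 0.  Rays
    that do not descend to the ground are truncated at the session's
    truncation distance (the truncated endpoint is used as-is).
    """
    dirs = _world_gaze_dirs(session, euler_deg)
    origins = session.eye_centers
    dz = dirs[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -origins[:, 2] / dz
    hits = (dz < -1e-12) & (t > 0)
    t = np.where(hits, t, session.truncation_distance)
    return origins + t[:, None] * dirs


def calibration_error(points: np.ndarray, calib_point) -> float:
    """Mean Euclidean distance between intersection points and the
    calibration point (m)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise CalibrationError("no intersection points")
    return float(np.mean(np.linalg.norm(points - np.asarray(calib_point, float), axis=1)))


def vor_consistency_check(session: CalibrationSession, euler_deg) -> float:
    """Root-mean-square distance of the gaze/ground intersections from
    their centroid: a correct alignment yields a tight cluster around the
    calibration point."""
    pts = gaze_ground_intersections(session, euler_deg)
    centroid = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))


def fit_alignment(
    session: CalibrationSession,
    method: str = "Nelder-Mead",
    xatol: float = 1e-6,
    fatol: float = 1e-10,
    max_iter: int = 2000,
) -> AlignmentResult:
    """Recover the sensor-to-head alignment rotation.

    Minimises :func:`calibration_error` over the Euler triple by local
    unconstrained optimisation from the [0, 0, 0] start.
    """
    if session.degenerate_sweep:
        warnings.warn(
            "head sweep covers a single rotation axis; the component about "
            "the gaze axis is unobservable",
            DegenerateSweepWarning,
            stacklevel=2,
        )

    def cost(euler):
        pts = gaze_ground_intersections(session, euler)
        return calibration_error(pts, session.calib_point)

    options = {"maxiter": max_iter}
    if method == "Nelder-Mead":
        options.update({"xatol": xatol, "fatol": fatol})
    res = minimize(cost, np.zeros(3), method=method, options=options)
    if not res.success:
        raise OptimizerDidNotConvergeError(
            f"alignment optimisation did not converge: {res.message}", res.x
        )
    euler = np.asarray(res.x, dtype=float)
    euler = (euler + 180.0) % 360.0 - 180.0
    pts = gaze_ground_intersections(session, euler)
    centroid = pts.mean(axis=0)
    scatter = float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
    return AlignmentResult(
        euler_deg=euler,
        residual_error=calibration_error(pts, session.calib_point),
        scatter_rms=scatter,
        intersections=pts,
        n_frames=session.n_frames,
        n_iterations=int(res.nit),
        converged=bool(res.success),
    )
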