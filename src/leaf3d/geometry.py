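"""Pinhole projection, depth-consistency gating and view-angle scoring.

A 3D point ``p`` in world coordinates is mapped into a view by the calibrated
pinhole model: ``x_cam = R p + T`` and ``(u, v) = (fx x/Zc + cx, fy y/Zc + cy)``
with ``Zc`` the camera-frame depth.  The rendered/estimated depth map then acts
as a visibility reference: a point is accepted at its pixel only when the
relative depth error ``e = (d - Zc) / d`` is small, which excludes points that
fall in the pixel's view frustum but lie on an occluded surface.

Pixel convention: 0-based, pixel centers at integer coordinates; raster lookup
rounds ``(u, v)`` to the nearest integer.  Points behind the camera or
projecting outside the raster yield no hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "CameraModel",
    "Pose",
    "PixelHit",
    "GateStatus",
    "project_point",
    "project_points",
    "depth_error",
    "depth_gate",
    "view_angle_cos",
]

#: sentinel for "no data" in depth maps (COLMAP writes 0 for unreconstructed)
DEPTH_NO_DATA = 0.0


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics (COLMAP PINHOLE dialect: fx, fy, cx, cy, no distortion)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the raster")

    @property
    def K(self) -> np.ndarray:
        """3x3 intrinsic matrix."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class Pose:
    """World-to-camera rigid transform ``x_cam = R x_world + t``."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=np.float64)
        t = np.asarray(self.t, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("R must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("R must be a proper rotation (det = +1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates, ``C = -R^T t``."""
        return -self.R.T @ self.t

    @property
    def matrix(self) -> np.ndarray:
        """3x4 extrinsic matrix ``[R | t]``."""
        return np.hstack([self.R, self.t[:, None]])


@dataclass(frozen=True)
class PixelHit:
    """A successful projection: continuous pixel coordinates and camera depth."""

    u: float
    v: float
    zc: float


class GateStatus(Enum):
    PASS = "pass"
    FAIL = "fail"
    NO_DATA = "no_data"


def project_point(p, cam: CameraModel, pose: Pose) -> PixelHit | None:
    """Project one world point; ``None`` if behind the camera or off-raster."""
    p = np.asarray(p, dtype=np.float64).reshape(3)
    if not np.isfinite(p).all():
        raise ValueError("point coordinates must be finite")
    x = pose.R @ p + pose.t
    zc = x[2]
    if zc <= 0:
        return None
    u = cam.fx * x[0] / zc + cam.cx
    v = cam.fy * x[1] / zc + cam.cy
    ui, vi = int(np.rint(u)), int(np.rint(v))
    if not (0 <= ui < cam.width and 0 <= vi < cam.height):
        return None
    return PixelHit(u=float(u), v=float(v), zc=float(zc))


def project_points(points: np.ndarray, cam: CameraModel, pose: Pose):
    """Vectorized projection of ``(N, 3)`` points.

    Returns
    -------
    u, v : float arrays of continuous pixel coordinates
    zc : float array of camera depths
    valid : bool array, True where the point is in front of the camera and its
        rounded pixel falls inside the raster
    """
    points = np.asarray(points, dtype=np.float64)
    if not np.isfinite(points).all():
        raise ValueError("point coordinates must be finite")
    x = points @ pose.R.T + pose.t
    zc = x[:, 2]
    front = zc > 0
    safe_z = np.where(front, zc, 1.0)
    u = cam.fx * x[:, 0] / safe_z + cam.cx
    v = cam.fy * x[:, 1] / safe_z + cam.cy
    ui = np.rint(u).astype(np.int64)
    vi = np.rint(v).astype(np.int64)
    valid = front & (ui >= 0) & (ui < cam.width) & (vi >= 0) & (vi < cam.height)
    return u, v, zc, valid


def depth_error(d: float, zc: float) -> float:
    """Relative depth error ``e = (d - Zc) / d`` of Eq. (2)-style gating."""
    return (d - zc) / d


def depth_gate(
    hit: PixelHit, depth_map: np.ndarray, e_threshold: float, no_data: float = DEPTH_NO_DATA
) -> tuple[GateStatus, float]:
    """Check one hit against the view's depth map.

    Returns the gate status and the signed relative error (NaN when the depth
    map has no data at the pixel).
    """
    vi, ui = int(np.rint(hit.v)), int(np.rint(hit.u))
    d = float(depth_map[vi, ui])
    if d <= no_data:
        return GateStatus.NO_DATA, float("nan")
    e = depth_error(d, hit.zc)
    return (GateStatus.PASS if abs(e) < e_threshold else GateStatus.FAIL), e


def view_angle_cos(p, n, camera_center) -> float:
    """Cosine of the angle between the viewing ray and the surface normal.

    ``v = p - C`` points from the camera toward the surface; a front-facing
    surface (normal toward the camera) gives ``cos φ < 0``, a grazing view 0,
    and a backside view ``cos φ > 0``.
    """
    p = np.asarray(p, dtype=np.float64).reshape(3)
    n = np.asarray(n, dtype=np.float64).reshape(3)
    c = np.asarray(camera_center, dtype=np.float64).reshape(3)
    if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-6):
        raise ValueError("normal must be unit length")
    v = p - c
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("point coincides with the camera center")
    return float(np.clip(v @ n / nv, -1.0, 1.0))
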