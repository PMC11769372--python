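"""Point-cloud cleanup for turntable MVS reconstructions.

MVS point clouds come out in an arbitrary normalized frame and include the
turntable, pot, soil and stray background points.  The chain here mirrors the
standard cleanup: voxel downsampling, RANSAC 3D circle fit of the turntable
rim to recover metric scale and a gravity-aligned frame, pass-through / RGB /
statistical filtering, and an exact inverse transform to return to the
original frame so the camera poses stay valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud

__all__ = [
    "CircleFit",
    "ScaleCalibration",
    "voxel_downsample",
    "ransac_circle_fit",
    "calibrate_scale",
    "passthrough_filter",
    "rgb_filter",
    "statistical_filter",
]


@dataclass
class CircleFit:
    """A 3D circle: center, radius, unit plane normal, and its RANSAC support."""

    center: np.ndarray
    radius: float
    normal: np.ndarray
    inliers: np.ndarray
    inlier_fraction: float


@dataclass
class ScaleCalibration:
    """Metric scale plus the rigid transform taking the turntable plane to Z=0.

    ``scale`` is world units (e.g. meters) per model unit.  ``apply`` maps
    model coordinates into the turntable frame (circle center at the origin,
    plane normal along +Z); ``invert`` restores the original frame exactly.
    """

    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) + self.translation) @ self.rotation.T

    def invert(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation - self.translation


def voxel_downsample(cloud: PointCloud, voxel_size: float) -> PointCloud:
    """One centroid per occupied voxel; attributes taken from the first member."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    pts = cloud.points
    keys = np.floor(pts / voxel_size).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    n_vox = len(first)
    sums = np.zeros((n_vox, 3))
    np.add.at(sums, inverse, pts)
    counts = np.bincount(inverse, minlength=n_vox).astype(np.float64)
    centroids = sums / counts[:, None]
    return PointCloud(
        points=centroids,
        rgb=None if cloud.rgb is None else cloud.rgb[first],
        labels=None if cloud.labels is None else cloud.labels[first],
        normals=None if cloud.normals is None else cloud.normals[first],
    )


def _circumcircle_3d(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Circumcircle of 3 points in 3D: (center, radius, unit normal) or None."""
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    nn = np.linalg.norm(n)
    if nn < 1e-12 * max(np.linalg.norm(ab), np.linalg.norm(ac), 1e-300):
        return None
    n = n / nn
    # solve for the center in the plane: equidistant from a, b, c
    rhs = np.array([ab @ ab / 2.0, ac @ ac / 2.0, 0.0])
    mat = np.vstack([ab, ac, n])
    center = a + np.linalg.solve(mat, rhs)
    return center, float(np.linalg.norm(center - a)), n


def _circle_distance(points: np.ndarray, center: np.ndarray, radius: float, normal: np.ndarray):
    """3D distance of each point to the circle curve."""
    rel = points - center
    h = rel @ normal
    radial = np.linalg.norm(rel - h[:, None] * normal, axis=1)
    return np.hypot(radial - radius, h)


def ransac_circle_fit(
    points: np.ndarray,
    n_iter: int = 1000,
    inlier_tol: float | None = None,
    seed: int = 0,
) -> CircleFit:
    """Fit a 3D circle to noisy turntable-rim points by RANSAC.

    Hypotheses are circumcircles of random 3-point samples; a point is an
    inlier when its 3D distance to the circle curve is below ``inlier_tol``
    (default 0.5 % of the hypothesized radius).  The best-consensus circle is
    refined by a least-squares fit on its inliers (plane by SVD, then a Kåsa
    circle fit in the plane).
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    best = None
    best_count = -1
    for _ in range(n_iter):
        sample = rng.choice(len(points), size=3, replace=False)
        hyp = _circumcircle_3d(*points[sample])
        if hyp is None:
            continue
        center, radius, normal = hyp
        tol = inlier_tol if inlier_tol is not None else 0.005 * radius
        dist = _circle_distance(points, center, radius, normal)
        count = int((dist < tol).sum())
        if count > best_count:
            best_count = count
            best = (center, radius, normal, tol)
    if best is None:
        raise ValueError("all 3-point samples were collinear")
    center, radius, normal, tol = best
    inliers = np.nonzero(_circle_distance(points, center, radius, normal) < tol)[0]
    if len(inliers) >= 3:
        center, radius, normal = _refine_circle(points[inliers], normal)
        inliers = np.nonzero(_circle_distance(points, center, radius, normal) < tol)[0]
    return CircleFit(
        center=center,
        radius=float(radius),
        normal=normal,
        inliers=inliers,
        inlier_fraction=len(inliers) / len(points),
    )


def _refine_circle(pts: np.ndarray, normal_hint: np.ndarray):
    """Least-squares circle through ``pts``: SVD plane + Kåsa fit in-plane."""
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    normal = vt[2]
    if normal @ normal_hint < 0:
        normal = -normal
    # in-plane orthonormal basis
    e1 = vt[0]
    e2 = np.cross(normal, e1)
    x, y = rel @ e1, rel @ e2
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    sol, *_ = np.linalg.lstsq(A, x * x + y * y, rcond=None)
    cx, cy, c0 = sol
    radius = float(np.sqrt(c0 + cx * cx + cy * cy))
    center = centroid + cx * e1 + cy * e2
    return center, radius, normal


def _rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the unit vector ``normal`` onto +Z."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    c = float(normal @ z)
    s = np.linalg.norm(v)
    if s < 1e-15:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def calibrate_scale(fit: CircleFit, real_diameter: float) -> ScaleCalibration:
    """Metric scale from the known turntable diameter plus the plane-to-Z=0 transform."""
    if real_diameter <= 0:
        raise ValueError("real_diameter must be positive")
    return ScaleCalibration(
        scale=real_diameter / (2.0 * fit.radius),
        rotation=_rotation_to_z(fit.normal),
        translation=-np.asarray(fit.center, dtype=np.float64),
    )


def passthrough_filter(cloud: PointCloud, axis: int, lo: float, hi: float) -> PointCloud:
    """Keep points with coordinate ``lo ≤ x_axis ≤ hi`` (bounds inclusive)."""
    coord = cloud.points[:, axis]
    return cloud.select((coord >= lo) & (coord <= hi))


def rgb_filter(cloud: PointCloud, max_chroma: int = 25) -> PointCloud:
    """Drop near-gray background points.

    A point is background when ``max(R,G,B) − min(R,G,B) < max_chroma`` on the
    8-bit scale (the low-saturation white/gray studio box); the boundary value
    itself is kept.
    """
    if cloud.rgb is None:
        raise ValueError("cloud has no RGB attribute")
    rgb = cloud.rgb.astype(np.int64)
    chroma = rgb.max(axis=1) - rgb.min(axis=1)
    return cloud.select(chroma >= max_chroma)


def statistical_filter(cloud: PointCloud, k: int = 20, std_mult: float = 2.0) -> PointCloud:
    """Statistical outlier removal by the k-nearest-neighbour mean-distance test."""
    n = len(cloud)
    if n <= k:
        return cloud.select(np.ones(n, dtype=bool))
    tree = cKDTree(cloud.points)
    dist, _ = tree.query(cloud.points, k=k + 1)
    mean_d = dist[:, 1:].mean(axis=1)
    cutoff = mean_d.mean() + std_mult * mean_d.std()
    return cloud.select(mean_d <= cutoff)
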