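"""Synthetic turntable scenes standing in for camera + MVS + 2D segmenter.

A scene is a set of leaf-like elliptical surface patches sampled to points
around a central stem axis, with per-point ground-truth instance labels,
colors and surface normals.  A ring of pinhole cameras (32 views at 11.25°
azimuth spacing, 30–45° elevation, matching a turntable capture) observes the
scene, and a point-splat z-buffer renderer produces mutually consistent depth
maps, normal maps and ground-truth instance-mask rasters — exactly the inputs
the lifting and fusion stages consume.  Controlled mask corruption (merge,
split, dropout, boundary morphology) emulates the error modes of an automatic
2D segmenter.

Leaves are placed at distinct stem heights and staggered azimuths so the
patches do not intersect; the renderer stores normals flipped toward the
rendering camera, as MVS normal estimators do, so every rendered surface is
front-facing in its own view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import binary_dilation, binary_erosion, disk

from .cloud import PointCloud
from .geometry import CameraModel, Pose, project_points
from .lifting import ViewBundle

__all__ = [
    "SyntheticScene",
    "CorruptionSpec",
    "generate_scene",
    "camera_ring",
    "default_camera",
    "render_view",
    "render_ring",
    "corrupt_masks",
    "turntable_rim_points",
]

BACKGROUND_RGB = np.array([235, 235, 235], dtype=np.uint8)  # low-saturation studio


@dataclass
class SyntheticScene:
    """A labeled leaf point cloud plus its turntable geometry."""

    cloud: PointCloud
    n_leaves: int
    turntable_center: np.ndarray
    turntable_radius: float
    seed: int

    @property
    def centroid(self) -> np.ndarray:
        return self.cloud.points.mean(axis=0)


@dataclass(frozen=True)
class CorruptionSpec:
    """Per-mask corruption probabilities emulating 2D segmenter errors."""

    merge_prob: float = 0.0
    split_prob: float = 0.0
    dropout_prob: float = 0.0
    boundary_radius: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.merge_prob, self.split_prob, self.dropout_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


def generate_scene(
    n_leaves: int = 8,
    points_per_leaf: int = 600,
    seed: int = 0,
    scale: float = 0.3,
) -> SyntheticScene:
    """Random non-coplanar elliptical leaf patches around a stem axis.

    ``scale`` is the overall plant size in world units (meters at the
    default); leaves attach at distinct heights and staggered azimuths so
    patches are disjoint in space.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    pts, labels, normals, rgb = [], [], [], []
    heights = np.linspace(0.25 * scale, 1.0 * scale, n_leaves)
    az_step = 2 * np.pi / n_leaves
    azimuths = (np.arange(n_leaves) * az_step + rng.uniform(-0.2, 0.2, n_leaves) * az_step) % (
        2 * np.pi
    )
    order = rng.permutation(n_leaves)
    for lab in range(n_leaves):
        az = azimuths[order[lab]]
        h = heights[lab]
        out = np.array([np.cos(az), np.sin(az), 0.0])
        petiole = rng.uniform(0.25, 0.45) * scale
        a = rng.uniform(0.15, 0.28) * scale  # semi-major axis
        b = rng.uniform(0.5, 0.7) * a
        pitch = rng.uniform(np.deg2rad(15), np.deg2rad(55))  # tilt from horizontal
        # leaf plane basis: major axis points outward and up by `pitch`
        e1 = out * np.cos(pitch) + np.array([0, 0, np.sin(pitch)])
        normal = np.array([0, 0, np.cos(pitch)]) - out * np.sin(pitch)
        e2 = np.cross(normal, e1)
        roll = rng.uniform(-0.3, 0.3)
        e1r = np.cos(roll) * e1 + np.sin(roll) * e2
        e2r = -np.sin(roll) * e1 + np.cos(roll) * e2
        normal = np.cross(e1r, e2r)
        normal /= np.linalg.norm(normal)
        center = out * petiole + np.array([0, 0, h])
        r = np.sqrt(rng.uniform(0, 1, points_per_leaf))
        th = rng.uniform(0, 2 * np.pi, points_per_leaf)
        local = (a * r * np.cos(th))[:, None] * e1r + (b * r * np.sin(th))[:, None] * e2r
        pts.append(center + local)
        labels.append(np.full(points_per_leaf, lab))
        normals.append(np.tile(normal, (points_per_leaf, 1)))
        base = np.array([40, 150, 50]) + rng.integers(-20, 21, 3)
        jitter = rng.integers(-12, 13, (points_per_leaf, 3))
        rgb.append(np.clip(base + jitter, 0, 255).astype(np.uint8))
    cloud = PointCloud(
        points=np.vstack(pts),
        rgb=np.vstack(rgb),
        labels=np.concatenate(labels),
        normals=np.vstack(normals),
    )
    return SyntheticScene(
        cloud=cloud,
        n_leaves=n_leaves,
        turntable_center=np.zeros(3),
        turntable_radius=0.6 * scale,
        seed=seed,
    )


def default_camera(width: int = 640, height: int = 480, focal: float = 600.0) -> CameraModel:
    """Desk-scale raster; all downstream algorithms are resolution-independent."""
    return CameraModel(fx=focal, fy=focal, cx=width / 2.0, cy=height / 2.0, width=width, height=height)


def _look_at(center: np.ndarray, target: np.ndarray) -> Pose:
    """World-to-camera pose with +z toward ``target`` and image-v pointing down."""
    f = target - center
    f = f / np.linalg.norm(f)
    up = np.array([0.0, 0.0, 1.0])
    x = np.cross(f, up)
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        x = np.array([1.0, 0.0, 0.0])
    else:
        x = x / nx
    y = np.cross(f, x)
    R = np.vstack([x, y, f])
    return Pose(R=R, t=-R @ center)


def camera_ring(
    n_views: int = 32,
    elevation_deg: tuple[float, float] = (30.0, 45.0),
    radius: float = 1.2,
    target: np.ndarray | None = None,
) -> list[Pose]:
    """Turntable ring: azimuths at 360/n° spacing, elevations ramping through the band.

    Every camera sits at ``radius`` from ``target`` and looks at it; the
    default 32 views give the 11.25° spacing of a turntable capture.
    """
    if target is None:
        target = np.zeros(3)
    target = np.asarray(target, dtype=np.float64)
    az = np.arange(n_views) * (2 * np.pi / n_views)
    lo, hi = np.deg2rad(elevation_deg[0]), np.deg2rad(elevation_deg[1])
    # triangle ramp lo -> hi -> lo keeps adjacent views adjacent in elevation
    u = np.arange(n_views) / max(n_views - 1, 1)
    el = lo + (hi - lo) * (1 - np.abs(2 * u - 1))
    poses = []
    for a, e in zip(az, el):
        offset = radius * np.array([np.cos(a) * np.cos(e), np.sin(a) * np.cos(e), np.sin(e)])
        poses.append(_look_at(target + offset, target))
    return poses


def render_view(
    scene: SyntheticScene,
    camera: CameraModel,
    pose: Pose,
    view_id: int = 0,
    splat_radius: int = 2,
) -> ViewBundle:
    """Point-splat z-buffer render: depth, world normals, labels, RGB.

    Each point paints a disc of ``splat_radius`` pixels; the nearest point
    wins every pixel, so for every rendered pixel the winning point's depth
    error against the depth map is exactly zero.  Stored normals are flipped
    toward the camera.
    """
    cloud = scene.cloud
    h, w = camera.height, camera.width
    u, v, zc, valid = project_points(cloud.points, camera, pose)
    idx = np.nonzero(valid)[0]
    ui = np.rint(u[idx]).astype(np.int64)
    vi = np.rint(v[idx]).astype(np.int64)
    # painter's algorithm: draw far-to-near, the last (nearest) write wins
    order = np.argsort(-zc[idx], kind="stable")
    idx, ui, vi = idx[order], ui[order], vi[order]
    z_sorted = zc[idx]

    offsets = [
        (dy, dx)
        for dy in range(-splat_radius, splat_radius + 1)
        for dx in range(-splat_radius, splat_radius + 1)
        if dy * dy + dx * dx <= splat_radius * splat_radius
    ]
    depth = np.zeros((h, w), dtype=np.float64)
    normal = np.zeros((h, w, 3), dtype=np.float64)
    label = np.zeros((h, w), dtype=np.int32)
    rgb = np.tile(BACKGROUND_RGB, (h, w, 1))

    cam_center = pose.center
    to_point = cloud.points[idx] - cam_center
    n_world = cloud.normals[idx]
    flip = np.einsum("ij,ij->i", to_point, n_world) > 0
    n_store = np.where(flip[:, None], -n_world, n_world)
    col = cloud.rgb[idx] if cloud.rgb is not None else np.zeros((len(idx), 3), np.uint8)
    lab = cloud.labels[idx] + 1

    all_v, all_u, sel = [], [], []
    for dy, dx in offsets:
        vv, uu = vi + dy, ui + dx
        ok = (vv >= 0) & (vv < h) & (uu >= 0) & (uu < w)
        all_v.append(vv[ok])
        all_u.append(uu[ok])
        sel.append(np.nonzero(ok)[0])
    vv = np.concatenate(all_v)
    uu = np.concatenate(all_u)
    sel = np.concatenate(sel)
    # global far-to-near order across all splat fragments
    frag_order = np.argsort(-z_sorted[sel], kind="stable")
    vv, uu, sel = vv[frag_order], uu[frag_order], sel[frag_order]
    depth[vv, uu] = z_sorted[sel]
    normal[vv, uu] = n_store[sel]
    label[vv, uu] = lab[sel]
    rgb[vv, uu] = col[sel]

    return ViewBundle(
        view_id=view_id,
        camera=camera,
        pose=pose,
        depth=depth,
        normals=normal,
        label_raster=label,
        rgb=rgb,
    )


def render_ring(
    scene: SyntheticScene,
    camera: CameraModel | None = None,
    poses: list[Pose] | None = None,
    n_views: int = 32,
    splat_radius: int = 2,
) -> list[ViewBundle]:
    """Render the full turntable ring around the scene centroid."""
    camera = camera or default_camera()
    if poses is None:
        radius = 4.0 * scene.turntable_radius / 0.6
        poses = camera_ring(n_views=n_views, radius=radius, target=scene.centroid)
    return [
        render_view(scene, camera, pose, view_id=i, splat_radius=splat_radius)
        for i, pose in enumerate(poses)
    ]


def corrupt_masks(bundle: ViewBundle, spec: CorruptionSpec) -> ViewBundle:
    """Apply segmenter-style errors to the view's label raster.

    Merge unifies a mask with its nearest neighbor (by raster centroid),
    split bisects a mask with a random line, dropout removes it, and boundary
    morphology erodes or dilates it (dilation only claims background pixels).
    Depth and normal rasters are untouched — these are 2D labeling errors,
    not geometry errors.  Deterministic given ``spec.seed`` and the view id.
    """
    rng = np.random.default_rng([spec.seed, bundle.view_id])
    raster = bundle.label_raster.copy()
    labels = [int(k) for k in np.unique(raster) if k > 0]

    cent = {}
    for k in labels:
        ys, xs = np.nonzero(raster == k)
        cent[k] = np.array([ys.mean(), xs.mean()])

    for k in labels:
        if len(cent) > 1 and rng.random() < spec.merge_prob and k in cent:
            others = [m for m in cent if m != k]
            target = min(others, key=lambda m: float(np.linalg.norm(cent[m] - cent[k])))
            keep, drop = min(k, target), max(k, target)
            raster[raster == drop] = keep
            cent[keep] = (cent[keep] + cent[drop]) / 2.0
            del cent[drop]

    next_label = int(raster.max()) + 1
    for k in list(np.unique(raster)):
        k = int(k)
        if k <= 0:
            continue
        if rng.random() < spec.split_prob:
            ys, xs = np.nonzero(raster == k)
            theta = rng.uniform(0, np.pi)
            side = (ys - ys.mean()) * np.cos(theta) + (xs - xs.mean()) * np.sin(theta) > 0
            if side.any() and (~side).any():
                raster[ys[side], xs[side]] = next_label
                next_label += 1

    for k in list(np.unique(raster)):
        k = int(k)
        if k <= 0:
            continue
        if rng.random() < spec.dropout_prob:
            raster[raster == k] = 0

    if spec.boundary_radius > 0:
        footprint = disk(spec.boundary_radius)
        for k in list(np.unique(raster)):
            k = int(k)
            if k <= 0:
                continue
            m = raster == k
            if rng.random() < 0.5:
                eroded = binary_erosion(m, footprint)
                raster[m & ~eroded] = 0
            else:
                grown = binary_dilation(m, footprint) & (raster == 0)
                raster[grown] = k

    return ViewBundle(
        view_id=bundle.view_id,
        camera=bundle.camera,
        pose=bundle.pose,
        depth=bundle.depth,
        normals=bundle.normals,
        label_raster=raster,
        rgb=bundle.rgb,
    )


def turntable_rim_points(
    center: np.ndarray,
    radius: float,
    normal: np.ndarray,
    n: int = 500,
    noise: float = 0.0,
    outlier_frac: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Points on (and around) a 3D circle — a synthetic turntable rim.

    ``noise`` is the isotropic Gaussian σ in world units; ``outlier_frac`` of
    the points are replaced by uniform points in a box around the circle.
    """
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=np.float64)
    normal = np.asarray(normal, dtype=np.float64)
    normal = normal / np.linalg.norm(normal)
    tmp = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    th = rng.uniform(0, 2 * np.pi, n)
    pts = center + radius * (np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2)
    if noise > 0:
        pts = pts + rng.normal(0, noise, pts.shape)
    n_out = int(round(outlier_frac * n))
    if n_out > 0:
        which = rng.choice(n, size=n_out, replace=False)
        pts[which] = center + rng.uniform(-2 * radius, 2 * radius, (n_out, 3))
    return pts
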