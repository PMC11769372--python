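"""Lift 2D instance-mask labels onto the 3D cloud, one view at a time.

Each cloud point is projected into the view; it inherits the mask label at its
pixel only when (a) it projects inside the raster in front of the camera,
(b) the depth map agrees with its camera depth within a relative threshold
(occlusion / frustum-ambiguity gate), (c) the surface is front-facing for this
camera (``cos φ < 0``), and (d) the pixel carries a mask label at all.
Accepted points also receive a confidence score

    s = λ · max(0, −cos φ) + (1 − λ) · d_n

combining viewpoint quality (how perpendicular the viewing ray is to the leaf
surface) with the normalized imaging depth ``d_n`` (min–max normalized over
the view's valid depth pixels).  λ weighs the two factors; scores live in
[0, 1] per view and are later summed or differenced during fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .geometry import CameraModel, Pose, project_points

__all__ = ["ViewBundle", "ViewLabeling", "FusionConfig", "lift_view", "confidence", "prefilter_groups"]


@dataclass
class ViewBundle:
    """One calibrated view: camera, pose, rasters, instance labels.

    ``label_raster`` uses 0 for background/no-mask and k ≥ 1 for mask k.
    ``depth`` uses 0 (or negative) as the no-data sentinel.  ``normals`` is an
    (H, W, 3) world-frame unit-normal raster.
    """

    view_id: int
    camera: CameraModel
    pose: Pose
    depth: np.ndarray
    normals: np.ndarray
    label_raster: np.ndarray
    rgb: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (self.camera.height, self.camera.width)
        if self.depth.shape != shape:
            raise ValueError("depth raster does not match camera size")
        if self.normals.shape != shape + (3,):
            raise ValueError("normal raster does not match camera size")
        if self.label_raster.shape != shape:
            raise ValueError("label raster does not match camera size")
        if self.rgb is not None and self.rgb.shape[:2] != shape:
            raise ValueError("rgb raster does not match camera size")


@dataclass
class ViewLabeling:
    """Per-point labels (−1 = no grouping information) and confidences for one view."""

    view_id: int
    labels: np.ndarray
    conf: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.conf = np.asarray(self.conf, dtype=np.float64)
        if self.labels.shape != self.conf.shape:
            raise ValueError("labels and conf must have equal length")
        if np.any(self.conf[self.labels < 0] != 0):
            raise ValueError("conf must be 0 where label is -1")


@dataclass(frozen=True)
class FusionConfig:
    """Tunables for lifting and merging.

    e_threshold : relative depth-error gate (default 0.005, i.e. e < 0.5 %).
    lam : viewpoint-vs-distance weight λ of the confidence score (default 0.9).
    tau_match : mutual overlap ratio above which two groups are the same leaf.
    tau_unmatched : γ mass on −1 above which an incoming group is "new".
    distance_mode : "literal" rewards larger normalized depth, "proximity"
        rewards smaller ((1 − λ)(1 − d_n)).
    """

    e_threshold: float = 0.005
    lam: float = 0.9
    tau_match: float = 0.5
    tau_unmatched: float = 0.8
    distance_mode: str = "literal"

    def __post_init__(self) -> None:
        if not 0 < self.e_threshold < 1:
            raise ValueError("e_threshold must be in (0, 1)")
        if not 0 < self.lam < 1:
            raise ValueError("lambda must be in (0, 1)")
        if not (0 < self.tau_match < 1 and 0 < self.tau_unmatched < 1):
            raise ValueError("tau_match and tau_unmatched must be in (0, 1)")
        if self.distance_mode not in ("literal", "proximity"):
            raise ValueError("distance_mode must be 'literal' or 'proximity'")


def confidence(
    cos_phi: float | np.ndarray,
    dn: float | np.ndarray,
    lam: float = 0.9,
    distance_mode: str = "literal",
):
    """Per-point confidence ``s = λ·max(0, −cos φ) + (1 − λ)·d_n``.

    ``dn`` must already be normalized to [0, 1].  In ``proximity`` mode the
    distance term is ``(1 − λ)(1 − d_n)`` so that nearer surfaces score higher.
    """
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    view_term = lam * np.maximum(0.0, -np.asarray(cos_phi, dtype=np.float64))
    dn = np.asarray(dn, dtype=np.float64)
    if distance_mode == "literal":
        dist_term = (1.0 - lam) * dn
    elif distance_mode == "proximity":
        dist_term = (1.0 - lam) * (1.0 - dn)
    else:
        raise ValueError("distance_mode must be 'literal' or 'proximity'")
    s = view_term + dist_term
    return float(s) if np.isscalar(cos_phi) or np.ndim(cos_phi) == 0 else s


def lift_view(cloud: PointCloud, view: ViewBundle, cfg: FusionConfig) -> ViewLabeling:
    """Transfer the view's 2D mask labels to the cloud with depth gating."""
    n = len(cloud)
    labels = np.full(n, -1, dtype=np.int64)
    conf = np.zeros(n, dtype=np.float64)

    u, v, zc, valid = project_points(cloud.points, view.camera, view.pose)
    if not valid.any():
        return ViewLabeling(view.view_id, labels, conf)
    idx = np.nonzero(valid)[0]
    ui = np.rint(u[idx]).astype(np.int64)
    vi = np.rint(v[idx]).astype(np.int64)

    d = view.depth[vi, ui]
    has_depth = d > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (d - zc[idx]) / np.where(has_depth, d, 1.0)
    gate = has_depth & (np.abs(e) < cfg.e_threshold)

    pix_label = view.label_raster[vi, ui]
    gate &= pix_label > 0

    # backside test with the normal-map normal at the pixel
    nrm = view.normals[vi, ui]
    vvec = cloud.points[idx] - view.pose.center
    vnorm = np.linalg.norm(vvec, axis=1)
    gate &= vnorm > 0
    with np.errstate(invalid="ignore"):
        cos_phi = np.einsum("ij,ij->i", vvec, nrm) / np.where(vnorm > 0, vnorm, 1.0)
    cos_phi = np.clip(cos_phi, -1.0, 1.0)
    gate &= cos_phi < 0

    if not gate.any():
        return ViewLabeling(view.view_id, labels, conf)

    # normalized depth over this view's valid depth pixels
    valid_depths = view.depth[view.depth > 0]
    dmin, dmax = float(valid_depths.min()), float(valid_depths.max())
    span = dmax - dmin
    dn = np.clip((zc[idx] - dmin) / span, 0.0, 1.0) if span > 0 else np.zeros(len(idx))

    keep = idx[gate]
    labels[keep] = pix_label[gate]
    conf[keep] = confidence(cos_phi[gate], dn[gate], cfg.lam, cfg.distance_mode)
    return ViewLabeling(view.view_id, labels, conf)


def prefilter_groups(
    vl: ViewLabeling,
    cloud: PointCloud,
    k: int = 10,
    std_mult: float = 2.0,
    min_group_size: int = 5,
) -> ViewLabeling:
    """Remove spatial outliers from each lifted group.

    Within each label group, a point whose mean distance to its ``k`` nearest
    group-mates exceeds the group mean by ``std_mult`` standard deviations is
    unlabeled.  Groups smaller than ``min_group_size`` (before or after the
    test) are dissolved entirely.  Removing a label zeroes the confidence; the
    point itself stays in the cloud.
    """
    labels = vl.labels.copy()
    conf = vl.conf.copy()
    for lab in np.unique(labels[labels >= 0]):
        member = np.nonzero(labels == lab)[0]
        if len(member) < min_group_size:
            labels[member] = -1
            conf[member] = 0.0
            continue
        pts = cloud.points[member]
        kk = min(k, len(member) - 1)
        tree = cKDTree(pts)
        dist, _ = tree.query(pts, k=kk + 1)
        mean_d = dist[:, 1:].mean(axis=1)
        cutoff = mean_d.mean() + std_mult * mean_d.std()
        out = member[mean_d > cutoff]
        labels[out] = -1
        conf[out] = 0.0
        if (labels == lab).sum() < min_group_size:
            rest = np.nonzero(labels == lab)[0]
            labels[rest] = -1
            conf[rest] = 0.0
    return ViewLabeling(vl.view_id, labels, conf)
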