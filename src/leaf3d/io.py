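"""Readers and writers for the on-disk dialects the pipeline consumes.

Formats: ASCII PLY for point clouds (with optional ``red/green/blue`` uint8
colors and an integer ``label`` vertex property, the dialect CloudCompare
exports for manual segmentations), COLMAP text camera models
(``cameras.txt`` PINHOLE entries + ``images.txt`` quaternion poses), NPZ
float32 rasters keyed ``depth`` and ``normal``, 16-bit indexed PNG mask
rasters, and JSON for labelings, calibrations and metric reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.spatial.transform import Rotation

from .cloud import PointCloud
from .fusion import FusionState
from .geometry import CameraModel, Pose
from .lifting import ViewLabeling

__all__ = [
    "read_ply",
    "write_ply",
    "read_colmap_model",
    "write_colmap_model",
    "read_rasters_npz",
    "write_rasters_npz",
    "read_mask_png",
    "write_mask_png",
    "read_labeling_json",
    "write_labeling_json",
    "write_colored_ply",
]

_PLY_DTYPES = {
    "float": np.float32,
    "float32": np.float32,
    "double": np.float64,
    "float64": np.float64,
    "uchar": np.uint8,
    "uint8": np.uint8,
    "int": np.int32,
    "int32": np.int32,
    "short": np.int16,
    "ushort": np.uint16,
}


def read_ply(path: str | Path) -> PointCloud:
    """Read an ASCII PLY point cloud; recognizes RGB and ``label`` properties."""
    path = Path(path)
    with open(path, "r") as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path} is not a PLY file")
        fmt = fh.readline().split()
        if fmt[1] != "ascii":
            raise ValueError("only ASCII PLY is supported")
        n_vertex = 0
        props: list[tuple[str, type]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unterminated PLY header")
            tok = line.split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                props.append((tok[2], _PLY_DTYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
        names = [p[0] for p in props]
        data = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
    if data.shape[0] != n_vertex:
        raise ValueError("vertex count mismatch")
    col = {name: data[:, i] for i, (name, _) in enumerate(props)}
    points = np.column_stack([col["x"], col["y"], col["z"]])
    rgb = None
    if {"red", "green", "blue"} <= set(names):
        rgb = np.column_stack([col["red"], col["green"], col["blue"]]).astype(np.uint8)
    labels = col["label"].astype(np.int64) if "label" in names else None
    return PointCloud(points=points, rgb=rgb, labels=labels)


def write_ply(path: str | Path, cloud: PointCloud) -> None:
    """Write an ASCII PLY point cloud with whatever attributes are present."""
    path = Path(path)
    n = len(cloud)
    header = ["ply", "format ascii 1.0", f"element vertex {n}"]
    header += [f"property double {ax}" for ax in "xyz"]
    cols: list[np.ndarray] = [cloud.points]
    fmts = ["%.17g %.17g %.17g"]
    if cloud.rgb is not None:
        header += [f"property uchar {c}" for c in ("red", "green", "blue")]
        cols.append(cloud.rgb.astype(np.float64))
        fmts.append("%d %d %d")
    if cloud.labels is not None:
        header.append("property int label")
        cols.append(cloud.labels[:, None].astype(np.float64))
        fmts.append("%d")
    header.append("end_header")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, np.hstack(cols), fmt=" ".join(fmts))


def write_colored_ply(path: str | Path, cloud: PointCloud, labels: np.ndarray, seed: int = 0) -> None:
    """Export a segmentation as a colored PLY (one random color per label)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    palette = {int(k): rng.integers(30, 256, 3).astype(np.uint8) for k in np.unique(labels) if k >= 0}
    rgb = np.full((len(cloud), 3), 80, dtype=np.uint8)
    for k, c in palette.items():
        rgb[labels == k] = c
    write_ply(path, PointCloud(points=cloud.points, rgb=rgb, labels=labels))


def write_colmap_model(
    directory: str | Path, camera: CameraModel, poses: list[Pose], names: list[str] | None = None
) -> None:
    """Write a single-camera COLMAP text model (cameras.txt + images.txt)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "cameras.txt", "w") as fh:
        fh.write("# Camera list: CAMERA_ID MODEL WIDTH HEIGHT PARAMS[]\n")
        fh.write(
            f"1 PINHOLE {camera.width} {camera.height} "
            f"{camera.fx:.17g} {camera.fy:.17g} {camera.cx:.17g} {camera.cy:.17g}\n"
        )
    with open(directory / "images.txt", "w") as fh:
        fh.write("# Image list: IMAGE_ID QW QX QY QZ TX TY TZ CAMERA_ID NAME\n")
        for i, pose in enumerate(poses):
            name = names[i] if names else f"view_{i:03d}.png"
            qx, qy, qz, qw = Rotation.from_matrix(pose.R).as_quat()
            t = pose.t
            fh.write(
                f"{i + 1} {qw:.17g} {qx:.17g} {qy:.17g} {qz:.17g} "
                f"{t[0]:.17g} {t[1]:.17g} {t[2]:.17g} 1 {name}\n\n"
            )


def read_colmap_model(directory: str | Path) -> tuple[dict[int, CameraModel], dict[str, tuple[int, Pose]]]:
    """Parse a COLMAP text model.

    Returns ``(cameras, images)`` where ``cameras`` maps camera id to
    :class:`CameraModel` and ``images`` maps image name to
    ``(camera_id, Pose)``.  Only the PINHOLE model is supported.
    """
    directory = Path(directory)
    cameras: dict[int, CameraModel] = {}
    for line in open(directory / "cameras.txt"):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        cam_id, model = int(tok[0]), tok[1]
        if model != "PINHOLE":
            raise ValueError(f"unsupported camera model {model!r}; only PINHOLE is handled")
        w, h = int(tok[2]), int(tok[3])
        fx, fy, cx, cy = map(float, tok[4:8])
        cameras[cam_id] = CameraModel(fx=fx, fy=fy, cx=cx, cy=cy, width=w, height=h)
    images: dict[str, tuple[int, Pose]] = {}
    skip_points2d = False
    for line in open(directory / "images.txt"):
        stripped = line.strip()
        if stripped.startswith("#"):
            continue
        if skip_points2d:  # the POINTS2D line that follows every pose (may be empty)
            skip_points2d = False
            continue
        if not stripped:
            continue
        tok = stripped.split()
        qw, qx, qy, qz = map(float, tok[1:5])
        t = np.array(list(map(float, tok[5:8])))
        cam_id = int(tok[8])
        name = tok[9]
        R = Rotation.from_quat([qx, qy, qz, qw]).as_matrix()
        images[name] = (cam_id, Pose(R=R, t=t))
        skip_points2d = True
    return cameras, images


def write_rasters_npz(path: str | Path, depth: np.ndarray, normal: np.ndarray) -> None:
    np.savez_compressed(path, depth=depth.astype(np.float32), normal=normal.astype(np.float32))


def read_rasters_npz(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    with np.load(path) as data:
        return data["depth"].astype(np.float64), data["normal"].astype(np.float64)


def write_mask_png(path: str | Path, raster: np.ndarray) -> None:
    """Indexed 16-bit PNG: 0 = background, k = mask k."""
    raster = np.asarray(raster)
    if raster.min() < 0 or raster.max() > np.iinfo(np.uint16).max:
        raise ValueError("mask labels must fit in uint16")
    Image.fromarray(raster.astype(np.uint16)).save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.int32)


def write_labeling_json(path: str | Path, obj: ViewLabeling | FusionState) -> None:
    payload = {
        "labels": np.asarray(obj.labels).tolist(),
        "conf": np.asarray(obj.conf).tolist(),
    }
    if isinstance(obj, ViewLabeling):
        payload["view_id"] = obj.view_id
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_labeling_json(path: str | Path) -> ViewLabeling:
    with open(path) as fh:
        payload = json.load(fh)
    return ViewLabeling(
        view_id=int(payload.get("view_id", -1)),
        labels=np.asarray(payload["labels"], dtype=np.int64),
        conf=np.asarray(payload["conf"], dtype=np.float64),
    )
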