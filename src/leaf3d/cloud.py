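"""Point-cloud container shared by every stage of the pipeline.

The cloud's point order is the canonical index space: per-view labelings,
fusion states and metric reports all refer to points by their position in
``points``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PointCloud:
    """N world-space points with optional per-point attributes.

    Parameters
    ----------
    points
        ``(N, 3)`` float array of world coordinates.
    rgb
        Optional ``(N, 3)`` uint8 colors.
    labels
        Optional ``(N,)`` integer instance labels (ground truth or
        prediction); ``-1`` means unlabeled.
    normals
        Optional ``(N, 3)`` unit surface normals in the world frame.
    """

    points: np.ndarray
    rgb: np.ndarray | None = None
    labels: np.ndarray | None = None
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if not np.isfinite(self.points).all():
            raise ValueError("points must be finite")
        n = len(self.points)
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb, dtype=np.uint8)
            if self.rgb.shape != (n, 3):
                raise ValueError("rgb must be (N, 3)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (n,):
                raise ValueError("labels must be (N,)")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != (n, 3):
                raise ValueError("normals must be (N, 3)")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Return the sub-cloud at ``index`` (bool mask or integer index)."""
        return PointCloud(
            points=self.points[index],
            rgb=None if self.rgb is None else self.rgb[index],
            labels=None if self.labels is None else self.labels[index],
            normals=None if self.normals is None else self.normals[index],
        )
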