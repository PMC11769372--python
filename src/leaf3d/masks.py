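"""Post-filtering of automatic 2D instance masks down to leaf-only masks.

Automatic mask generators (SAM-family models run without prompts) return masks
for everything in frame: background, pot, soil, whole plant, single leaflets,
stems.  Three filters, applied in order, reduce this to per-leaf masks:

1. **Saturation filter** — keep masks whose mean HSV saturation exceeds a
   threshold; in a low-saturation white/gray studio this isolates the plant.
2. **Overlap filter** — near-duplicate and part-whole mask pairs are resolved
   in favor of the finer-granularity (smaller) mask, so an organ-level rather
   than whole-plant partition survives; after this step every pixel belongs to
   at most one mask.
3. **Shape filter** — stems are elongated while leaves are "full": the ratio
   of the minimum-enclosing-circle area to the mask area is small for leaves
   (≈1–2) and very large for stems, so thresholding the ratio drops stems.

Each filter only removes masks or reassigns pixels; no new mask is created.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely import MultiPoint, minimum_bounding_radius
from skimage.color import rgb2hsv

__all__ = [
    "Mask2D",
    "MaskSet",
    "saturation_filter",
    "overlap_filter",
    "shape_ratio",
    "shape_filter",
    "filter_chain",
]


@dataclass
class Mask2D:
    """A single binary instance mask within one view."""

    mask_id: int
    raster: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.raster.sum())


@dataclass
class MaskSet:
    """Ordered mask collection for one view; ids are unique within the view."""

    view_id: int
    masks: list[Mask2D] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.mask_id for m in self.masks]
        if len(ids) != len(set(ids)):
            raise ValueError("mask_ids must be unique within a view")

    def __len__(self) -> int:
        return len(self.masks)

    def to_label_raster(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Indexed raster: 0 = background, ``mask_id`` elsewhere.

        Later masks in the list win residual overlaps (after
        :func:`overlap_filter` there are none).
        """
        if shape is None:
            if not self.masks:
                raise ValueError("cannot infer shape from an empty MaskSet")
            shape = self.masks[0].raster.shape
        out = np.zeros(shape, dtype=np.int32)
        for m in self.masks:
            out[m.raster] = m.mask_id
        return out

    @classmethod
    def from_label_raster(cls, view_id: int, raster: np.ndarray) -> "MaskSet":
        raster = np.asarray(raster)
        ids = np.unique(raster)
        masks = [Mask2D(int(k), raster == k) for k in ids if k != 0]
        return cls(view_id=view_id, masks=masks)


def saturation_filter(masks: MaskSet, image: np.ndarray, s_min: float = 40.0) -> MaskSet:
    """Keep masks whose mean 8-bit HSV saturation exceeds ``s_min``.

    ``image`` is an (H, W, 3) RGB raster (uint8 or float in [0, 1]); the
    saturation channel is scaled to [0, 255] so the default ``s_min = 40``
    means "S > 40 on the 8-bit scale".
    """
    if not 0 <= s_min <= 255:
        raise ValueError("s_min must be on the 8-bit [0, 255] saturation scale")
    img = np.asarray(image)
    sat = rgb2hsv(img)[..., 1] * 255.0
    kept = []
    for m in masks.masks:
        if m.raster.shape != sat.shape:
            raise ValueError("mask and image dimensions differ")
        if m.area == 0:
            warnings.warn(f"mask {m.mask_id} is empty; excluded", stacklevel=2)
            continue
        if sat[m.raster].mean() > s_min:
            kept.append(m)
    return MaskSet(view_id=masks.view_id, masks=kept)


def overlap_filter(masks: MaskSet, iou_min: float = 0.5) -> MaskSet:
    """Resolve overlapping masks in favor of finer granularity.

    For every pair with IoU ≥ ``iou_min`` the larger-area mask is removed
    (ties: the higher ``mask_id`` is removed).  Residual pixel overlaps between
    surviving masks are then assigned to the smaller mask, so the output is a
    pixel partition: a leaflet mask keeps its pixels, a whole-plant mask that
    survived loses the contested region.
    """
    if not 0 < iou_min <= 1:
        raise ValueError("iou_min must be in (0, 1]")
    alive = list(masks.masks)
    removed = True
    while removed:
        removed = False
        areas = [m.area for m in alive]
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                inter = np.logical_and(alive[i].raster, alive[j].raster).sum()
                if inter == 0:
                    continue
                union = areas[i] + areas[j] - inter
                if inter / union >= iou_min:
                    # drop the coarser of the two
                    if areas[i] > areas[j] or (
                        areas[i] == areas[j] and alive[i].mask_id > alive[j].mask_id
                    ):
                        drop = i
                    else:
                        drop = j
                    del alive[drop]
                    removed = True
                    break
            if removed:
                break
    # residual overlaps: shared pixels go to the smaller mask (tie: lower id)
    order = sorted(
        range(len(alive)), key=lambda k: (alive[k].area, alive[k].mask_id)
    )
    claimed = None
    out: list[Mask2D] = []
    for k in order:
        m = alive[k]
        if claimed is None:
            claimed = np.zeros_like(m.raster)
        raster = np.logical_and(m.raster, ~claimed)
        claimed |= raster
        if raster.any():
            out.append(Mask2D(m.mask_id, raster))
    out.sort(key=lambda m: m.mask_id)
    return MaskSet(view_id=masks.view_id, masks=out)


def shape_ratio(mask: Mask2D) -> float:
    """Area of the minimum enclosing circle divided by the mask area.

    Compact shapes (discs) score ≈1, squares ≈π/2, elongated bars ≫1.
    Degenerate masks of fewer than 3 pixels return ``inf``.
    """
    if mask.area < 3:
        return float("inf")
    ys, xs = np.nonzero(mask.raster)
    # the enclosing circle is determined by the boundary; thin the point set
    # to boundary pixels to keep the geometry cheap on large blobs
    interior = (
        mask.raster[:-2, 1:-1]
        & mask.raster[2:, 1:-1]
        & mask.raster[1:-1, :-2]
        & mask.raster[1:-1, 2:]
    )
    boundary = mask.raster.copy()
    boundary[1:-1, 1:-1] &= ~interior
    bys, bxs = np.nonzero(boundary)
    r = minimum_bounding_radius(MultiPoint(np.column_stack([bxs, bys])))
    return float(np.pi * r * r / mask.area)


def shape_filter(masks: MaskSet, r_max: float = 4.0) -> MaskSet:
    """Keep masks with ``shape_ratio ≤ r_max`` (drop elongated stems)."""
    if r_max <= 1:
        raise ValueError("r_max must exceed 1 (a disc already scores ≈1)")
    kept = [m for m in masks.masks if shape_ratio(m) <= r_max]
    return MaskSet(view_id=masks.view_id, masks=kept)


def filter_chain(
    masks: MaskSet,
    image: np.ndarray,
    s_min: float = 40.0,
    iou_min: float = 0.5,
    r_max: float = 4.0,
) -> MaskSet:
    """Full saturation → overlap → shape pipeline in the required order."""
    return shape_filter(overlap_filter(saturation_filter(masks, image, s_min), iou_min), r_max)
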