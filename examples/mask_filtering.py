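"""The three-stage 2D mask filter on programmatically drawn shapes.

An automatic segmenter returns masks for background, whole plant, leaves and
stems alike. The chain keeps leaf-like masks only: saturated (plant, not gray
studio), non-duplicate (finer granularity wins), and compact (the
enclosing-circle/area ratio separates full leaves from elongated stems).
"""

import numpy as np
from skimage.draw import disk

from leaf3d.masks import Mask2D, MaskSet, filter_chain, shape_ratio

shape = (200, 200)
image = np.full(shape + (3,), 200, dtype=np.uint8)  # gray studio backdrop
image[40:160, 20:180] = (30, 160, 40)               # green plant region

leaf = np.zeros(shape, bool)
rr, cc = disk((100, 60), 35, shape=shape)
leaf[rr, cc] = True
leaf_dup = leaf.copy()                 # duplicate detection of the same leaf
stem = np.zeros(shape, bool)
stem[60:140, 118:122] = True           # 80x4 elongated bar on the plant
backdrop = np.zeros(shape, bool)
backdrop[:30, :] = True                # gray studio region

masks = MaskSet(0, [Mask2D(1, leaf), Mask2D(2, leaf_dup), Mask2D(3, stem), Mask2D(4, backdrop)])
for m in masks.masks:
    print(f"mask {m.mask_id}: area={m.area:5d} shape_ratio={shape_ratio(m):6.2f}")

kept = filter_chain(masks, image, s_min=40, iou_min=0.5, r_max=4.0)
print("kept mask ids:", [m.mask_id for m in kept.masks])
# only one copy of the leaf survives: the backdrop fails saturation, the
# duplicate collapses, and the stem's ratio (~40) exceeds r_max=4
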