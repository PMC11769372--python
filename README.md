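# leaf3d

Zero-shot 3D leaf instance segmentation from multi-view images, for plant
phenotyping pipelines that reconstruct a point cloud with multi-view stereo
and segment leaves in 2D with an automatic segmenter (SAM-family models).
`leaf3d` takes the three artifacts such a pipeline already produces — the
point cloud, per-view camera calibrations (COLMAP text model), and per-view
depth/normal rasters with instance-mask rasters — and turns the per-view 2D
masks into a single 3D instance segmentation, with no training and no 3D
annotations.

## Method

For each view, every cloud point **p** = (X<sub>w</sub>, Y<sub>w</sub>,
Z<sub>w</sub>) is projected by the calibrated pinhole model

    [u, v, 1]ᵀ = (1/Z_c) · K [R | T] [X_w, Y_w, Z_w, 1]ᵀ

and inherits the mask label at pixel (u, v) only when the view's depth map
agrees with its camera depth, |e| = |(d(u,v) − Z_c)/d(u,v)| < 0.5 %, which
resolves the view-frustum ambiguity (occluded points are rejected), and when
the surface faces the camera (cos φ < 0, with φ the angle between the
viewing ray and the surface normal). Each lifted label carries a confidence

    s = λ · max(0, −cos φ) + (1 − λ) · d_n,    λ = 0.9,

combining viewpoint quality with the min–max-normalized imaging depth d_n.

Per-view labelings are merged incrementally in capture order. Between the
running state and an incoming view, normalized overlap tables Q_x, Q_y give
the fraction γ of each group's points carrying each label on the other side.
Incoming groups that are mostly unknown to the state (γ on −1 ≥ 0.8) enter
as new groups; mutually overlapping pairs (γ ≥ 0.5 in both tables) are the
same leaf and their confidences are **summed** point by point; partially
overlapping pairs are conflicts, resolved toward the side with the higher
group-mean confidence s̄ = (1/N)Σ sᵢ, the contested points' confidence
becoming |s_x − s_y|.

Around this core the package provides the standard surrounding stages: the
three-step 2D mask filter (mean-saturation, overlap/granularity, enclosing-
circle shape ratio), the point-cloud cleanup chain (voxel downsampling,
RANSAC 3D circle fit of the turntable for metric scale, pass-through / RGB /
statistical filters), the evaluation suite (point-level precision/recall/F1,
instance-matched mIoU and AP@IoU, leaf-count R²/MAPE/RMSE), and a synthetic
turntable-scene generator that emulates the whole capture stack (camera ring
at 11.25° spacing, z-buffer renders, controllable mask corruption) for
testing and benchmarking.

## Worked example

```python
import numpy as np
from leaf3d import FusionConfig, incremental_fuse, lift_view, evaluate
from leaf3d.synthetic import generate_scene, render_ring

scene = generate_scene(n_leaves=8, points_per_leaf=600, seed=42)
views = render_ring(scene, n_views=32)
cfg = FusionConfig()                      # e_threshold=0.005, lambda=0.9

labelings = [lift_view(scene.cloud, v, cfg) for v in views]
visible = np.any([vl.labels >= 0 for vl in labelings], axis=0)
state = incremental_fuse(labelings, cfg)
report = evaluate(state.labels, scene.cloud.labels, conf=state.conf, mask=visible)
```

Running this as `python examples/lift_and_fuse.py` prints (clean renders,
all 4800 points visible in ≥ 1 view):

```
precision=1.000 recall=1.000 f1=1.000
mIoU=1.000 AP50=1.000 AP75=1.000
8 fused groups for 8 true leaves
```

i.e. on geometrically consistent inputs the lift-and-fuse pipeline
reproduces the ground-truth partition exactly. With corrupted masks (10 %
merge/split/dropout per mask, emulating 2D segmenter errors —
`examples/corrupted_benchmark.py`) the per-iteration F1 rises as views
corroborate each other:

```
after 2 views: 0.681   after all 32: 0.779   mean single view: 0.596
```

The `examples/` directory holds one short script per capability
(simulation/rendering, lifting + fusion, mask filtering, turntable scale
calibration, the corrupted benchmark), and the `leaf3d` CLI chains the same
stages over on-disk files: `simulate`, `filter-masks`, `lift`, `fuse`,
`preprocess`, `eval`.

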