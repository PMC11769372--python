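# Methods

## Model and assumptions

`leaf3d` treats 3D leaf instance segmentation as a label-transfer-and-fusion
problem. The inputs are assumed mutually calibrated: a point cloud in the
same world frame as the camera poses, per-view depth maps in the same units
as camera-frame depth, and world-frame unit normal maps. The pinhole model
is the COLMAP PINHOLE dialect (fx, fy, cx, cy, no distortion); undistortion
is assumed done upstream. Pixels are 0-based with centers at integer
coordinates, and raster lookups round (u, v) to the nearest integer — the
symmetric choice for raster sampling. Points behind the camera or projecting
outside the raster produce no hit rather than being clamped, since the
projective division is meaningless there.

Whether a reconstruction pipeline stores normals in world or camera frame
varies; the lifting stage requires world-frame normals and the loader is
responsible for any conversion.

## Lifting and the confidence score

A point inherits a view's mask label only if four gates pass: in-raster
projection, relative depth error |e| < `e_threshold`, front-facing surface
(cos φ < 0), and a nonzero mask label at the pixel. The default
`e_threshold` = 0.005 (e < 0.5 %) balances coverage against occlusion
leakage; the backside test is applied at lift time, removing the label
rather than merely zeroing its confidence, because a backside observation
carries no usable grouping information.

The confidence `s = λ·max(0, −cos φ) + (1 − λ)·d_n` uses λ = 0.9 by
default; end-to-end results are quite insensitive to λ because the 2D shape
filter already removes most badly foreshortened (stem-like) leaf masks, so
surviving masks span a narrow range of view angles. `d_n` is the camera
depth min–max normalized over the view's valid depth pixels, which keeps
s ∈ [0, 1] independent of scene scale. As printed, the distance term rewards
*larger* imaging depth; because one can also argue the opposite reading
(nearer surfaces are imaged better), a `proximity` mode replacing the term
with (1 − λ)(1 − d_n) is provided. `literal` is the default.

An optional per-group pre-filter (k-nearest-neighbour mean-distance test,
k = 10, 2.0 σ, groups under 5 points dissolved) removes spatial outliers
from lifted groups. It is deliberately not wired into `lift_view`: on clean
data a mean+2σ test always trims a tail of legitimate points, trading recall
for precision. Enable it (CLI `--prefilter`) when mask boundaries are noisy.

## Incremental fusion

The running state and each incoming view are reconciled through row-
normalized overlap tables. Defaults: `tau_unmatched` = 0.8 (a group mostly
unknown to the other side is new geometry) and `tau_match` = 0.5 (mutual
majority overlap identifies the same leaf). Design choices where the
procedure is genuinely open:

* The running state plays the X role in the confidence-update rule; the
  incoming view is Y.
* Matched pairs are made one-to-one greedily by combined γ; conflicts are
  processed in descending overlap size and each point is re-resolved at most
  once per merge, which makes the merge deterministic when a group overlaps
  several others.
* Equal group means in a conflict: the state wins — biased toward
  accumulated evidence.
* The conflict confidence update uses |s_x − s_y| (the two observations
  spend their agreement resolving the dispute).
* Confidences are unnormalized reliability masses: matched sums may exceed 1
  and are never renormalized.
* Residue rule: after unmatched/matched/conflict handling, incoming-group
  points still unlabeled in the state join their group's dominant state
  correspondent (argmax γ over real labels), or a fresh group if there is
  none. Without this, a view that extends a known leaf with newly visible
  points — but fails the mutual-γ match because the state group has grown
  much larger than any single view's slice — would fragment that leaf into
  one group per view.

Fusing a view with itself is a fixed point of the partition and doubles all
confidences; on clean data the final partition is invariant (up to label
names) under rotations of the view order.

## Evaluation

Predicted groups are matched one-to-one to ground-truth groups greedily by
descending IoU (the standard instance-segmentation convention), and the same
matching is used for the point-level counts (TP = matched-pair
intersections, FP/FN = the remainders), mIoU (unmatched ground truth counts
zero) and AP. AP ranks predictions by group-mean confidence — the only
ranking signal the fusion state carries — and claims each ground-truth group
at most once at the given IoU threshold (0.50 and 0.75 by default). Points
of never-matched predicted groups count as false positives.

All quantities in a comparison are computed over a single fixed point domain
(by default: points visible in at least one view). Per-view quantities on
each view's own labeled subset are not comparable to fused quantities, since
every view labels a different subset.

Leaf-count agreement uses R², MAPE (%) and RMSE between predicted group
counts and true leaf counts; MAPE is undefined for zero true counts and
errors out rather than guessing.

## Preprocessing

RANSAC circle fitting uses 1000 iterations of 3-point circumcircle
hypotheses with an inlier tolerance of 0.5 % of the hypothesized radius, a
least-squares refinement on the consensus set (SVD plane + Kåsa in-plane
fit), and an explicit seed. The background RGB box for the color filter is
max(R,G,B) − min(R,G,B) < 25 on 8-bit values, matching a low-saturation
white/gray studio; the statistical filter defaults to k = 20, 2.0 σ. The
turntable points are isolated by a user-configured height slab — platform
detection is out of scope. The calibration's rigid transform and its inverse
are exact, so camera poses remain valid after the cleanup round trip.

The mask filter defaults: saturation S > 40 on the 8-bit HSV scale (a 0–1
scale would make a threshold of 40 meaningless), IoU ≥ 0.5 for the overlap
filter (separating near-duplicates from part–whole pairs, whose residual
shared pixels go to the smaller mask; equal areas tie toward the lower mask
id), and shape-ratio ≤ 4.0 (discs score ≈ 1, squares ≈ π/2, elongated stems
≫ 10). The minimum enclosing circle is computed exactly on the mask's
boundary pixels.

## The synthetic generator

The generator emulates a turntable capture of a young plant: 8 (default)
planar elliptical leaf patches sampled to 600 points each, attached at
distinct heights and staggered azimuths around a stem axis (so patches do
not interpenetrate — real leaves don't either), viewed by 32 cameras at
11.25° azimuth spacing and 30–45° elevation, desk-scale rasters of 640×480
(every algorithm is resolution-independent). Rendering is point-splat
z-buffering (splat radius 2 px): the nearest point wins each pixel, so depth
maps, normal maps and label rasters are exactly consistent with the cloud —
the winning point's depth error is identically zero. Stored normals are
flipped toward the rendering camera, as MVS normal estimators behave; with
un-flipped normals the backside gate would discard genuinely visible far
sides of planar patches. Mask corruption (merge with the nearest mask, split
by a random line, dropout, boundary erosion/dilation) models 2D segmenter
error modes — over-/under-segmentation and missed detections — and is
deterministic given its seed and the view id.

What the generator does **not** emulate: MVS depth noise and reconstruction
holes (depth maps are exact; holes only via dropout), photometric effects,
curved or serrated leaves, stems and pots in the cloud, and sub-pixel mask
boundary error. Consequently, passing the clean-identity test shows the
geometry and bookkeeping are exact, not that real reconstructions will fuse
perfectly; and the splat renderer's depth quantization (≈ 2·tan(leaf tilt)/f
relative error across a splat) means depth-gate thresholds well below
≈ 0.5 % reject many valid points on tilted leaves — a regime real MVS depth
maps, which are smooth within a surface, do not enter. The benchmark sizes
used throughout (4800 points, 32 views at 640×480) were chosen as the
smallest scene on which every leaf is repeatedly observed from substantially
different angles.

## Numerical notes and limitations

* Rotations are validated to 1e−9 (orthonormality, det +1); projection
  agrees with the full homogeneous-matrix product to better than 1e−9.
* The depth gate treats no-data pixels (d ≤ 0) as a distinct failure, never
  as agreement.
* Degenerate masks (< 3 px) report an infinite shape ratio and are thus
  always filtered as non-leaves.
* Fusion quality can dip when a late view introduces fresh, not-yet-
  corroborated groups; the trend over iterations is upward but not
  monotone.
* Group identity is purely point-overlap-based: two groups of the same
  physical leaf that share no labeled points (possible under extremely
  sparse lifting) cannot be unified. Global (non-incremental) association
  is out of scope.
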