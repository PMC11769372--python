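"""Metric scale from the turntable rim by RANSAC 3D circle fitting.

MVS reconstructions live in an arbitrary normalized frame. Fitting a circle
to the (noisy, outlier-ridden) turntable rim recovers the platform plane and
radius; the known physical diameter then gives world units per model unit,
and the rigid transform puts the platform at Z=0 for pass-through filtering.
"""

import numpy as np

from leaf3d.preprocess import calibrate_scale, ransac_circle_fit
from leaf3d.synthetic import turntable_rim_points

center, radius = np.array([0.2, -0.1, 0.8]), 0.05  # model units
points = turntable_rim_points(center, radius, normal=np.array([0.1, 0.2, 1.0]),
                              n=500, noise=radius * 0.001, outlier_frac=0.3, seed=3)

fit = ransac_circle_fit(points, seed=11)
print(f"fitted radius: {fit.radius:.6f} model units (true {radius})")
print(f"inlier fraction: {fit.inlier_fraction:.2f} (30% of points are outliers)")

calibration = calibrate_scale(fit, real_diameter=0.30)  # a 30 cm platform
print(f"scale: {calibration.scale:.4f} m per model unit")

moved = calibration.apply(points[: len(points)])
print(f"platform plane after alignment: max |z| of inliers = "
      f"{np.abs(calibration.apply(points[fit.inliers])[:, 2]).max():.2e}")
# apply/invert are exact inverses, so camera poses stay valid afterwards
restored = calibration.invert(calibration.apply(points))
print(f"round-trip error: {np.abs(restored - points).max():.2e}")
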