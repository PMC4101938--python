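"""Estimate a tapering tube's radius profile from the boundary response.

Builds a cylinder whose radius shrinks linearly from 8 to 3 voxels, lays a
curve along its axis, and estimates the radius at every point by maximizing
the boundary response B(O, r) — gradient magnitude on a circle of radius r
in the cross-section plane, weighted by the rectified inward GVF projection.
"""

import numpy as np

from svftrace import (
    OpenCurve, PhantomSpec, RadiusParams, estimate_radius,
    gradient, gvf, make_phantom, normalize, normalize_field,
)

spec = PhantomSpec(kind="cylinder", size=(44, 44, 80), radius=(8.0, 3.0), contrast=0.8)
volume, truth = make_phantom(spec)
volume = normalize(volume)
grad = gradient(volume)
gvf_norm = normalize_field(gvf(grad))

x = np.linspace(8, 72, 65)
curve = OpenCurve(np.column_stack([np.full_like(x, 22.0), np.full_like(x, 22.0), x]))
curve = estimate_radius(curve, grad, gvf_norm, RadiusParams(r_max=12.0))

r_true = 8.0 + (3.0 - 8.0) * x / 79.0
err = np.abs(curve.radii - r_true)
print("x      r_est  r_true")
for i in range(0, 65, 8):
    print(f"{x[i]:5.1f}  {curve.radii[i]:5.2f}  {r_true[i]:5.2f}")
print(f"max |error| {err.max():.2f} voxels; "
      f"monotone: {bool(np.all(np.diff(curve.radii) <= 1e-9))}")
# The estimate tracks the taper to within about half a voxel because the
# boundary gradient of the phantom peaks exactly at the nominal radius.
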