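"""Detect tracing seeds on a noisy helix with the Sliding Volume Filter.

Builds a helical tube phantom with additive noise, runs the SVF, and ranks
seeds; then runs the classical intensity-threshold seeding on the same
volume and compares how many seeds of each method fall outside the true
tube.  The SVF scores gradient *orientation* (boundary gradients converging
on the tube interior), so noise maxima that fool the intensity threshold do
not fool it.
"""

import numpy as np
from scipy.spatial import cKDTree

from svftrace import (
    PhantomSpec, SVFParams, detect_seeds, gradient, make_phantom,
    normalize, svf_volume, threshold_seeds,
)

spec = PhantomSpec(kind="helix", size=(48, 64, 64), radius=3.0,
                   coil_radius=16.0, pitch=16.0, turns=2.0,
                   contrast=0.8, noise_sigma=0.1, seed=1)
volume, truth = make_phantom(spec)
volume = normalize(volume)

params = SVFParams(m_sections=16, pn_lines=16, vt=2, r_min=2.0, r_max=8.0)
response = svf_volume(volume, params, mask_threshold=0.2,
                      gradient_field=gradient(volume))
seeds = detect_seeds(response, volume)

tree = cKDTree(truth.centerline)
d_svf, _ = tree.query(seeds.positions().astype(float))
thr = threshold_seeds(volume)
d_thr, _ = tree.query(thr.astype(float))

print(f"SVF seeds:       {len(seeds):4d}, fraction outside tube "
      f"{(d_svf > spec.radius).mean():.3f}")
print(f"threshold seeds: {len(thr):4d}, fraction outside tube "
      f"{(d_thr > spec.radius).mean():.3f}")
print(f"top seed response {seeds[0].response:.3f} at voxel "
      f"{tuple(int(c) for c in seeds[0].position)}")
# A fraction of 0 means every SVF seed lies on the tube body even at this
# noise level; the intensity threshold picks up noise maxima off the tube.
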