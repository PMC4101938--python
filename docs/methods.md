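# Methods

This note records the model, the numerical choices, and the limits of what
the test phantoms can show. Coordinates are `(z, y, x)`, 0-based, voxel
centers at integer positions; all lengths are in voxels. Anisotropic voxel
spacing is carried as metadata only — the filter and snake mathematics
assume isotropic voxels, and resampling anisotropic stacks is the caller's
responsibility.

## Convergence-index filters

The spatial convergence index (SCI) of a sample point `p` relative to a
center `O` is `cos φ = ĝ(p) · (O − p)/|O − p|`, the cosine between the
interpolated image gradient at `p` and the direction from `p` to the center.
The sign convention is fixed so that a bright structure on dark background
scores +1 at its center: boundary gradients point up-intensity, i.e. inward.
The equivalent 2D convergence index used by the sliding band filter is
`CI = −(ĝ · û)` with `û` the outward ray direction — the same statement in
2D. Zero gradients contribute 0 (the neutral element of the average), as do
out-of-band samples: ray samples falling outside the volume and the
degenerate zero-radius sample count 0 but remain in the band normalization,
which biases boundary responses toward 0 rather than failing.

**Sliding band / sliding volume.** Along each support line the band holds
`Vt + 1` samples at unit radial spacing centered on `r`; `r` steps in
integer units over `[Rmin, Rmax]` (a sub-unit `r_step` is available in the
configuration but falls back to a slower per-direction path). Because band
positions and sample radii share the unit grid, every band mean is a sliding
window over one vector of SCI samples per line, computed with a cumulative
sum — this is the only difference between the vectorized implementation and
the literal triple loop, and the two agree to 1e−10 (checked in the tests
and the acceptance script).

**Support-line geometry.** Section `s` of `M` is the half-turn plane
containing the z-axis at azimuth `ψ_s = π s / M`; line `rad` of `Pn` within
a section has in-plane angle `θ = 2π (rad − 1)/Pn` measured from +z. The
`M` half-planes × full-circle in-plane angles cover the sphere. The polar
directions ±z recur in every section; this is inherent to the
section-by-section construction (the sampling density is higher near the
poles, like a latitude–longitude grid) and the duplicates are kept as
distinct support lines so every section contributes the same line count to
the average. The construction rule is recorded on the `DirectionSet` so it
can be swapped.

**Which gradients the SVF sees.** The SCI is computed on raw image
gradients by default (`svf.gradient_source = raw`), which makes the
response exactly invariant to positive affine intensity rescaling; a
`gvf` setting is provided for experimentation.

## Gradient vector flow

GVF is the standard diffusion `u_t = μ ∇²u − |∇I|² (u − ∇I)` applied to the
*image gradient* (not an edge map): the diffused field carries the
up-intensity direction into flat regions, and inside a bright tube the
normalized field points at the centerline from both sides — the property
the snake and the radius estimator rely on. Defaults μ = 0.1,
50 iterations, dt = 0.5; the explicit Euler step requires dt ≤ 1/(6μ) on the
unit grid and the implementation rejects an unstable dt before iterating.
Normalization maps vectors with magnitude above `zero_tol` (default 1e−8 of
the field maximum, so flat-background numeric noise is not amplified into
unit vectors) to unit length.

## Seeding

Candidates must exceed a response floor and be the strict maximum over the
8 interpolated neighbors in the plane perpendicular to the local tube axis;
the axis is the eigenvector of the Hessian of the Gaussian-smoothed
intensity (σ = 1.5) with the smallest-magnitude eigenvalue. Candidates
closer than `min_spacing` (default 5) to a stronger one are suppressed;
survivors are ranked by descending response with lexicographic `(z, y, x)`
tie-breaking, which makes the list deterministic.

**The floor (default 0.6).** The band-position maximization extracts a
positive bias from disordered gradients: in pure noise, each line's maximum
of ~(Rmax−Rmin+1) band means of ~(Vt+1) roughly uniform cosines sits around
0.4–0.55 for thin bands, and averaging over lines does not remove it. The
floor must sit above this noise ceiling; ideal tube centers score ≥ 0.78
even at noise σ = 0.1, so 0.6 separates the two regimes with margin. A
lower floor admits background maxima wholesale. Pre-smoothing the volume
before gradient computation was evaluated and rejected: smoothing turns
isolated noise spikes into genuinely convex blobs that an orientation-only
filter legitimately detects, so it raises rather than lowers the background
response.

The comparison baseline implemented alongside (`threshold_seeds`) is
intensity local maxima (26-neighborhood) above an Otsu threshold — the
classical seeding that convergence-index seeding improves on.

## Open-curve snake

Internal energy `α|c_s|² + β|c_ss|²` with α = 0 (the open curve must be free
to stretch) and β = 0.1 at interior points, forced to 0 at the endpoints.
Evolution is semi-implicit: `(I + γA) x⁺ = x + γF` per coordinate with
γ = 1, where `A` is the banded stiffness matrix with free-end boundary
conditions and `F` is the normalized GVF sampled along the curve plus
`k_stretch` (default 0.5) times the outward continuation direction at each
growing end. The continuation direction is the weak-curvature Hessian
eigenvector — the Jacobian of the gradient field — oriented away from the
curve body, falling back to the outward tangent when the local
eigen-structure is degenerate (flat background) or perpendicular to the
curve. Curves are resampled to unit arc spacing each iteration; growth
extends an end by `grow_step = 1` while the local intensity stays at or
above `background_floor = 0.05` (the leakage guard that terminates tracing
at a structure's end), the end stays inside the volume, arc length stays
below `max_length`, and the end has not collided with an existing trace.

Two stopping subtleties surfaced during development and are part of the
design:

* **Stall detection.** Near a tube's end cap the normalized GVF has unit
  magnitude and opposes the stretch force, so an end can keep appending a
  point that evolution immediately pulls back. If total arc length gains
  less than 0.1·grow_step over 10 consecutive growing iterations, growth is
  declared stalled and both ends stop.
* **Normal-displacement convergence.** Convergence is judged on the
  displacement component *normal* to the curve (max ≤ 0.05 voxels);
  tangential sliding between the end forces and the resampler is mere
  reparametrization, not shape change, and would otherwise keep the
  iteration alive indefinitely.

`trace_all` processes seeds in rank order, skips seeds within
`coverage_radius = 3` of an existing curve, stops growth on collision
within `merge_radius = 3` and links the new curve as a child at the nearest
parent point — this recovers branch topology without manual input; explicit
branch points in the configuration force links at those locations (with an
ancestor check so links stay acyclic). Curves shorter than
`min_arc_length = 5` (stubs from seeds just outside the covered region) are
dropped. The result is a tree of curves serialized as SWC with fixed-width
floats, so repeated runs produce byte-identical files.

The snake energy monitored in tests discretizes the internal terms with the
same difference operators and uses the negative intensity along the curve
as the image potential (the GVF force drives points up-intensity, so
intensity is the natural quantity to monitor); it is checked on noise-free
fixtures with growth and resampling disabled, where it is non-increasing.

## Radius estimation

At each curve point, `v3` is the central-difference tangent, `v1` the global
axis least aligned with `v3` projected orthogonal, `v2 = v3 × v1`. The
boundary response `B(O, r)` averages, over N = 8 rays in the normal plane,
the raw gradient magnitude times the rectified inward projection of the
normalized GVF; `r` sweeps `[r_min, r_max]` in 0.25-voxel steps and the
first maximum wins (determinism). The 8-ray average makes the result
insensitive to the in-plane phase of `v1`. Points whose responses are all
zero take the neighbor-interpolated radius with a warning; a window-3 median
filter along the curve (toggleable) suppresses single-point outliers.
`grad_source` selects which field supplies the magnitude factor (raw
gradient by default).

## Phantoms and what they show

The generator renders tubes by distance-to-centerline against analytic
curves: straight cylinders (rendered from a centerline extended past the x
faces, so the tube is locally infinite with no end caps), helices
(`x = c + R cos t`, `y = c + R sin t`, `z` linear in `t`; axis = z),
Y-branches (trunk along z splitting into two 36° arms), and spherical
blobs. The default cross-section profile is flat with a 1-voxel cosine
taper *centered on the nominal radius*: full intensity for `d ≤ r − 1`,
zero beyond `r + 1`, so the boundary-gradient peak sits exactly at `d = r`
— the quantity the radius estimator measures. A Gaussian profile
(σ = r/2) is available for blob and energy tests. Noise is additive
Gaussian, clipped to [0, 1], from a seeded generator (fixed seed ⇒
bit-identical volumes). Ground truth is the generating centerline at
≤ 1-voxel spacing with per-point radius and branch points.

Reference test conditions used throughout the suite and the acceptance
script: a 40×40×60 cylinder of radius 5 (SVF at M = Pn = 16, Vt = 2,
Rmin = 3, Rmax = 10), a 48×64×64 helix of tube radius 3, coil radius 16,
pitch 16, 2 turns (≈ 204-voxel arc; SVF at M = Pn = 16, Rmin = 2,
Rmax = 8), noise σ = 0.1 at contrast 0.8 for the noisy variant, and
cylinders r ∈ {3, 5, 8} plus an 8→3 taper for radius recovery. These sizes
keep each measurement in seconds-to-minutes while leaving the tube several
support-radii away from any face. The phantoms do **not** emulate
microscope point-spread functions, depth attenuation, uneven illumination,
Poisson noise, or touching/crossing neurites — passing on them shows the
geometry and the statistics of the method are right, not that real
olfactory-axon stacks will reach the same precision.

## Degenerate inputs and tie-breaks

Constant volumes normalize to all-zeros; flat regions give zero gradients,
zero SCI, zero SVF. A degenerate Hessian (isotropic neighborhood) makes the
axis estimate fall back to +z with a warning, and the stretch direction to
the outward tangent. Eigenvector and direction signs are canonicalized
(first nonzero component positive), response ties break lexicographically,
argmax ties take the smallest radius — every path is deterministic under a
fixed configuration.

## Known limitations

* The SVF response is evaluated only where intensity ≥ `mask_threshold`
  (default 0.05; 0 scans every voxel). In noisy stacks a higher mask (0.2
  in the noisy-helix runs) is purely an efficiency choice — separation from
  background is done by the response floor, not the mask.
* Seeding assumes one dominant local axis; at junctions the Hessian axis is
  unreliable, which is why branch recovery is delegated to trace collisions
  rather than to seed-level analysis.
* Snakes stop a few voxels short of rounded tube tips (the stall
  equilibrium between stretch and the cap's GVF); recall on closed-ended
  tubes saturates around 0.95–0.97 at 2-voxel tolerance.
* Radius estimates are circular cross-sections only, quantized to the
  0.25-voxel search step, and capped at `r_max`.
* One structure per volume is assumed; there is no soma segmentation and no
  disentangling of touching neurites.
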