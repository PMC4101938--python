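"""Synthetic tube phantoms with analytically known centerlines and radii.

These volumes emulate the test data used to validate tube filters and
tracers: bright tubular structures (straight cylinders, helices, Y-branches)
and spherical blobs on a dark background, with a chosen cross-section
profile, contrast and additive Gaussian noise.  Every phantom carries its
generating centerline and per-point radius as ground truth, so seed
positions, traced centerlines and estimated radii can all be scored
quantitatively.

The default edge model is a flat profile with a 1-voxel cosine taper centered
on the nominal radius: intensity is full for distance ``d <= r - 1``, falls
as a half-cosine across ``r - 1 < d < r + 1`` and is zero beyond.  This keeps
the boundary gradient finite, well oriented, and peaked exactly at ``d = r``,
which is what a gradient-based radius estimator measures.  Cylinders are
rendered from a centerline extended past the volume faces, so there are no
end-cap gradients and the tube behaves as locally infinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import SpecificationError
from .volume import Volume3D

__all__ = ["PhantomSpec", "GroundTruth", "make_phantom", "write_ground_truth", "read_ground_truth"]

_KINDS = ("cylinder", "helix", "ybranch", "blob")
_PROFILES = ("flat-smooth-edge", "gaussian")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic volume.

    ``radius`` is either a scalar (voxels) or a ``(r_start, r_end)`` pair for
    a linear taper along arc length.  Helix geometry: ``coil_radius`` is the
    coil (not tube) radius, ``pitch`` is the axial rise per full turn, both in
    voxels; the helix axis is z.  ``contrast`` is the peak foreground
    intensity above the zero background, in [0, 1].
    """

    kind: str = "cylinder"
    size: tuple[int, int, int] = (40, 40, 60)  # (Dz, Dy, Dx)
    radius: float | tuple[float, float] = 5.0
    coil_radius: float = 12.0
    pitch: float = 16.0
    turns: float = 1.5
    profile: str = "flat-smooth-edge"
    contrast: float = 0.8
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SpecificationError(f"unknown phantom kind {self.kind!r}; expected one of {_KINDS}")
        if self.profile not in _PROFILES:
            raise SpecificationError(f"unknown profile {self.profile!r}; expected one of {_PROFILES}")
        rmin = min(np.atleast_1d(self.radius))
        if rmin < 1:
            raise SpecificationError(f"radius must be >= 1 voxel, got {self.radius}")
        if not 0 < self.contrast <= 1:
            raise SpecificationError(f"contrast must lie in (0, 1], got {self.contrast}")


@dataclass
class GroundTruth:
    """Analytic centerline, per-point radius, and branch points of a phantom."""

    centerline: np.ndarray          # (n, 3) ordered (z, y, x) points, <=1 voxel apart
    radius_at: np.ndarray           # (n,) radius at each centerline point
    branch_points: list = field(default_factory=list)
    #: parent index per centerline point (-1 = start of a branch chain)
    parents: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=np.float64)
        self.radius_at = np.asarray(self.radius_at, dtype=np.float64)
        if self.parents is None:
            self.parents = np.arange(-1, len(self.centerline) - 1)

    def arc_length(self) -> float:
        """Total polyline arc length (branch chains summed)."""
        total = 0.0
        for i, par in enumerate(self.parents):
            if par >= 0:
                total += float(np.linalg.norm(self.centerline[i] - self.centerline[par]))
        return total


def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(s[-1] / spacing)) + 1, 2)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, points[:, c]) for c in range(3)])


def _arc_fractions(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s / s[-1] if s[-1] > 0 else s


def _radius_along(spec: PhantomSpec, frac: np.ndarray) -> np.ndarray:
    if np.isscalar(spec.radius):
        return np.full(len(frac), float(spec.radius))
    r0, r1 = spec.radius  # linear taper along arc length
    return r0 + (r1 - r0) * frac


def _centerline(spec: PhantomSpec) -> tuple[np.ndarray, list, np.ndarray | None]:
    """Fine-sampled analytic centerline(s); returns (points, branch_points, parents)."""
    dz, dy, dx = spec.size
    if spec.kind == "cylinder":
        cz, cy = dz // 2, dy // 2
        # extend past the x faces so the rendered tube has no end caps
        xs = np.arange(-6.0, dx + 6.0, 0.25)
        pts = np.column_stack([np.full_like(xs, cz), np.full_like(xs, cy), xs])
        return pts, [], None
    if spec.kind == "helix":
        cz, cy, cx = (dz - 1) / 2.0, (dy - 1) / 2.0, (dx - 1) / 2.0
        height = spec.pitch * spec.turns
        t = np.linspace(0.0, 2.0 * np.pi * spec.turns, max(int(40 * spec.turns * spec.coil_radius), 200))
        z = cz - height / 2.0 + spec.pitch * t / (2.0 * np.pi)
        y = cy + spec.coil_radius * np.sin(t)
        x = cx + spec.coil_radius * np.cos(t)
        return np.column_stack([z, y, x]), [], None
    if spec.kind == "ybranch":
        # trunk rises along z to the volume center, then splits into two arms in the z-y plane
        cz, cy, cx = (dz - 1) / 2.0, (dy - 1) / 2.0, (dx - 1) / 2.0
        rmax = max(np.atleast_1d(spec.radius))
        m = rmax + 3.0
        t_trunk = np.arange(m, cz + 0.25, 0.25)
        trunk = np.column_stack([t_trunk, np.full_like(t_trunk, cy), np.full_like(t_trunk, cx)])
        branch = trunk[-1]
        arm_len = min((dz - 1 - m - cz) / np.cos(np.pi / 5), (cy - m) / np.sin(np.pi / 5))
        s = np.arange(0.25, arm_len, 0.25)
        dzdir, dydir = np.cos(np.pi / 5), np.sin(np.pi / 5)
        arm1 = np.column_stack([cz + s * dzdir, cy + s * dydir, np.full_like(s, cx)])
        arm2 = np.column_stack([cz + s * dzdir, cy - s * dydir, np.full_like(s, cx)])
        # chain 1 = trunk + arm1 (contiguous); chain 2 = arm2 rooted at the branch point
        pts = np.vstack([trunk, arm1, arm2])
        parents = np.arange(-1, len(pts) - 1)
        parents[len(trunk) + len(arm1)] = len(trunk) - 1
        return pts, [branch], parents
    # blob: degenerate "centerline" of one point at the center
    c = np.array([[(dz - 1) / 2.0, (dy - 1) / 2.0, (dx - 1) / 2.0]])
    return c, [], np.array([-1])


def _profile_intensity(spec: PhantomSpec, dist: np.ndarray, radius: np.ndarray) -> np.ndarray:
    if spec.profile == "gaussian":
        sigma = radius / 2.0
        out = spec.contrast * np.exp(-(dist ** 2) / (2.0 * sigma ** 2))
        out[out < 1e-4] = 0.0
        return out
    # flat with 1-voxel cosine taper centered at d = radius
    out = np.zeros_like(dist)
    out[dist <= radius - 1.0] = spec.contrast
    ramp = (dist > radius - 1.0) & (dist < radius + 1.0)
    out[ramp] = spec.contrast * 0.5 * (1.0 + np.cos(np.pi * (dist[ramp] - radius[ramp] + 1.0) / 2.0))
    return out


def make_phantom(spec: PhantomSpec) -> tuple[Volume3D, GroundTruth]:
    """Render a phantom volume and its ground truth.

    Foreground intensity is a function of each voxel's distance to the
    analytic centerline; background is zero before noise.  Additive Gaussian
    noise (``noise_sigma``) is applied last and the result clipped to [0, 1].
    """
    pts, branches, parents = _centerline(spec)
    frac = _arc_fractions(pts) if len(pts) > 1 else np.zeros(1)
    radii = _radius_along(spec, frac)
    if spec.kind == "blob":
        radii = np.full(1, float(np.atleast_1d(spec.radius)[0]))

    dz, dy, dx = spec.size
    rmax = float(radii.max())
    if spec.kind == "cylinder":
        # cylinders deliberately extend through the x faces (no end caps): check z, y only
        margins = np.concatenate([pts.min(axis=0)[:2], (np.array(spec.size) - 1 - pts.max(axis=0))[:2]])
    else:
        margins = np.concatenate([pts.min(axis=0), np.array(spec.size) - 1 - pts.max(axis=0)])
    if margins.min() < rmax + 2:
        raise SpecificationError(
            f"tube does not fit: needs a margin of radius+2={rmax + 2:.1f} voxels, "
            f"closest approach to a face is {margins.min():.1f}"
        )

    tree = cKDTree(pts)
    zz, yy, xx = np.meshgrid(
        np.arange(dz, dtype=np.float64),
        np.arange(dy, dtype=np.float64),
        np.arange(dx, dtype=np.float64),
        indexing="ij",
    )
    vox = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    dist, idx = tree.query(vox, workers=-1)
    data = _profile_intensity(spec, dist, radii[idx]).reshape(spec.size)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    data = np.clip(data, 0.0, 1.0)

    # ground truth: resample to <=1 voxel spacing, keep strictly-inside points
    if spec.kind == "blob":
        truth = GroundTruth(pts.copy(), radii.copy(), branches, np.array([-1]))
    elif spec.kind == "ybranch":
        truth = _ybranch_truth(pts, radii, parents, branches)
    else:
        keep = ((pts >= 0.5) & (pts <= np.array(spec.size) - 1.5)).all(axis=1)
        fine, rfine = pts[keep], radii[keep]
        cl = _resample_polyline(fine, 0.8)
        rtree = cKDTree(fine)
        _, ridx = rtree.query(cl)
        truth = GroundTruth(cl, rfine[ridx], branches)
    return Volume3D(data), truth


def _ybranch_truth(pts, radii, parents, branches) -> GroundTruth:
    """Down-sample each branch chain (a contiguous index run) to ~0.8 voxel spacing."""
    starts = [i for i in range(len(pts)) if int(parents[i]) != i - 1 or i == 0]
    starts.append(len(pts))
    cl_pts: list[np.ndarray] = []
    cl_r: list[float] = []
    cl_par: list[int] = []
    for a, b in zip(starts[:-1], starts[1:]):
        chain = np.arange(a, b)
        sub = _resample_polyline(pts[chain], 0.8)
        rtree = cKDTree(pts[chain])
        _, ridx = rtree.query(sub)
        attach = int(parents[a])
        base = len(cl_pts)
        for j in range(len(sub)):
            cl_pts.append(sub[j])
            cl_r.append(float(radii[chain][ridx[j]]))
            if j > 0:
                cl_par.append(base + j - 1)
            elif attach < 0 or base == 0:
                cl_par.append(-1)
            else:
                prev = np.asarray(cl_pts[:base])
                cl_par.append(int(np.argmin(np.linalg.norm(prev - pts[attach], axis=1))))
    return GroundTruth(np.asarray(cl_pts), np.asarray(cl_r), branches, np.asarray(cl_par))


def write_ground_truth(path, truth: GroundTruth) -> None:
    """Plain-text table: index, z, y, x, radius, parent index."""
    with open(path, "w") as fh:
        fh.write("# index z y x radius parent\n")
        for i, (p, r, par) in enumerate(zip(truth.centerline, truth.radius_at, truth.parents)):
            fh.write(f"{i} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f} {r:.3f} {int(par)}\n")


def read_ground_truth(path) -> GroundTruth:
    rows = np.loadtxt(path, comments="#", ndmin=2)
    return GroundTruth(rows[:, 1:4], rows[:, 4], [], rows[:, 5].astype(int))
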