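"""Seed detection: turn an SVF response volume into a ranked list of snake
initialization points.

A voxel becomes a candidate when its response clears a floor AND is the
strict maximum over its 8 neighbors in the local tube cross-section (the
plane perpendicular to the Hessian-estimated tube axis, sampled with
trilinear interpolation).  Candidates closer than ``min_spacing`` to a
stronger candidate are suppressed, and survivors are ranked by descending
response — the tracing order.

The local tube axis at a voxel is the eigenvector of the Hessian of the
Gaussian-smoothed intensity belonging to the smallest-magnitude eigenvalue:
along a bright tube the intensity is flat along the axis and curved across
it, so the weak-curvature eigenvector is the axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .fields import sample_scalar
from .volume import Volume3D

__all__ = ["Seed", "SeedList", "estimate_axis", "detect_seeds", "threshold_seeds"]


@dataclass
class Seed:
    position: np.ndarray      # (3,) lattice point (z, y, x)
    response: float
    axis: np.ndarray          # (3,) unit local tube direction
    rank: int = -1


@dataclass
class SeedList:
    """Seeds ordered by descending response; ties broken by (z, y, x) order."""

    seeds: list[Seed] = field(default_factory=list)
    provenance: object = None

    def __len__(self) -> int:
        return len(self.seeds)

    def __iter__(self):
        return iter(self.seeds)

    def __getitem__(self, i) -> Seed:
        return self.seeds[i]

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.seeds]).reshape(-1, 3)

    def to_table(self, path) -> None:
        """Plain-text table: rank z y x response axis_z axis_y axis_x."""
        with open(path, "w") as fh:
            fh.write("# rank z y x response axis_z axis_y axis_x\n")
            for s in self.seeds:
                p, a = s.position, s.axis
                fh.write(
                    f"{s.rank} {int(p[0])} {int(p[1])} {int(p[2])} {s.response:.6f} "
                    f"{a[0]:.6f} {a[1]:.6f} {a[2]:.6f}\n"
                )

    @classmethod
    def from_table(cls, path) -> "SeedList":
        rows = np.loadtxt(path, comments="#", ndmin=2)
        seeds = [
            Seed(r[1:4].astype(int), float(r[4]), r[5:8], rank=int(r[0]))
            for r in rows
        ]
        return cls(seeds)


def _hessian_at(smoothed: np.ndarray, voxel: np.ndarray) -> np.ndarray:
    """3x3 Hessian by central second differences on a pre-smoothed grid."""
    z, y, x = (int(round(c)) for c in voxel)
    dz, dy, dx = smoothed.shape
    z = min(max(z, 1), dz - 2)
    y = min(max(y, 1), dy - 2)
    x = min(max(x, 1), dx - 2)
    f = smoothed
    h = np.empty((3, 3))
    h[0, 0] = f[z + 1, y, x] - 2 * f[z, y, x] + f[z - 1, y, x]
    h[1, 1] = f[z, y + 1, x] - 2 * f[z, y, x] + f[z, y - 1, x]
    h[2, 2] = f[z, y, x + 1] - 2 * f[z, y, x] + f[z, y, x - 1]
    h[0, 1] = h[1, 0] = (f[z + 1, y + 1, x] - f[z + 1, y - 1, x] - f[z - 1, y + 1, x] + f[z - 1, y - 1, x]) / 4
    h[0, 2] = h[2, 0] = (f[z + 1, y, x + 1] - f[z + 1, y, x - 1] - f[z - 1, y, x + 1] + f[z - 1, y, x - 1]) / 4
    h[1, 2] = h[2, 1] = (f[z, y + 1, x + 1] - f[z, y + 1, x - 1] - f[z, y - 1, x + 1] + f[z, y - 1, x - 1]) / 4
    return h


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip so the first nonzero of (z, y, x) is positive — deterministic."""
    for c in v:
        if abs(c) > 1e-12:
            return v if c > 0 else -v
    return v


def axis_from_smoothed(smoothed: np.ndarray, voxel) -> np.ndarray:
    """Tube axis at a voxel from a pre-smoothed intensity grid (unit vector)."""
    h = _hessian_at(smoothed, np.asarray(voxel, dtype=float))
    w, v = np.linalg.eigh(h)
    if np.ptp(np.abs(w)) < 1e-12:
        warnings.warn("degenerate Hessian: axis undefined, returning +z", stacklevel=2)
        return np.array([1.0, 0.0, 0.0])
    axis = v[:, np.argmin(np.abs(w))]
    return _canonical_sign(axis / np.linalg.norm(axis))


def estimate_axis(volume: Volume3D, voxel, smoothing_sigma: float = 1.5) -> np.ndarray:
    """Local tube direction at ``voxel`` (see module docstring)."""
    smoothed = ndimage.gaussian_filter(volume.data.astype(float), smoothing_sigma)
    return axis_from_smoothed(smoothed, voxel)


def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal in-plane directions perpendicular to ``axis``."""
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(axis)))] = 1.0
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def detect_seeds(
    response_volume: Volume3D,
    source_volume: Volume3D,
    floor: float = 0.6,
    min_spacing: float = 5.0,
    smoothing_sigma: float = 1.5,
    svf_params: object = None,
) -> SeedList:
    """Rank SVF responses into a seed list (normal-plane maxima + spacing NMS)."""
    resp = response_volume.data
    cand = np.argwhere(resp > floor)
    if len(cand) == 0:
        return SeedList([], provenance=svf_params)
    smoothed = ndimage.gaussian_filter(source_volume.data.astype(float), smoothing_sigma)

    in_offsets = np.array([(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)])
    keep: list[tuple[np.ndarray, float, np.ndarray]] = []
    for voxel in cand:
        axis = axis_from_smoothed(smoothed, voxel)
        u, v = _plane_basis(axis)
        nbrs = voxel[None, :] + in_offsets[:, :1] * u[None, :] + in_offsets[:, 1:2] * v[None, :]
        vals = sample_scalar(resp, nbrs, oob_value=-np.inf)
        center = resp[tuple(voxel)]
        if np.all(center > vals):
            keep.append((voxel, float(center), axis))

    # rank by response (descending), ties by (z, y, x); then spacing suppression
    keep.sort(key=lambda t: (-t[1], tuple(t[0])))
    accepted: list[tuple[np.ndarray, float, np.ndarray]] = []
    tree_pts: list[np.ndarray] = []
    for voxel, val, axis in keep:
        if tree_pts:
            d = np.linalg.norm(np.asarray(tree_pts) - voxel, axis=1)
            if d.min() < min_spacing:
                continue
        accepted.append((voxel, val, axis))
        tree_pts.append(voxel)

    seeds = [
        Seed(np.asarray(voxel), val, axis, rank=i)
        for i, (voxel, val, axis) in enumerate(accepted)
    ]
    return SeedList(seeds, provenance=svf_params)


def threshold_seeds(volume: Volume3D, min_spacing: float = 0.0) -> np.ndarray:
    """Baseline seeding: intensity local maxima (26-neighborhood) above Otsu.

    This is the classical intensity-threshold seeding that convergence-index
    seeding is compared against; in noisy data its maxima scatter off the
    tube body.  Returns an (n, 3) array of voxel positions.
    """
    data = volume.data
    thr = threshold_otsu(data)
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = data == ndimage.maximum_filter(data, footprint=footprint)
    cand = np.argwhere(local_max & (data > thr))
    if min_spacing <= 0 or len(cand) == 0:
        return cand
    order = np.argsort(-data[tuple(cand.T)], kind="stable")
    accepted: list[np.ndarray] = []
    for i in order:
        p = cand[i]
        if accepted and cKDTree(np.asarray(accepted)).query(p)[0] < min_spacing:
            continue
        accepted.append(p)
    return np.asarray(accepted).reshape(-1, 3)
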