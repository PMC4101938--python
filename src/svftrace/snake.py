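"""Open-curve snake tracing.

A snake is an ordered point sequence c(s), s in [0, 1], evolved to minimize

    E_total = integral  alpha |c_s|^2 + beta |c_ss|^2  +  E_image + k E_stretch  ds

with free (open) endpoints.  The elasticity weight alpha is 0 by default and
the stiffness beta is forced to 0 at the endpoints, so the curve can bend
freely at its tips and elongate.  The image force is the normalized
gradient-vector-flow field sampled along the curve (it pushes points onto
the tube centerline); the stretching force acts only at the two endpoints,
along the local tube axis (the weak-curvature Hessian eigenvector), oriented
outward so the snake grows along the structure.  Growth at an end stops when
the local intensity falls below ``background_floor`` — the leakage guard
that terminates tracing at the structure's end.

Evolution is the standard semi-implicit scheme: the internal energy yields a
banded matrix A, and each step solves (I + gamma A) x+ = x + gamma F_ext per
coordinate, followed by resampling to uniform arc spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ParameterError
from .fields import VectorField3D, sample_scalar
from .seeding import Seed, SeedList, axis_from_smoothed
from .volume import Volume3D

__all__ = [
    "OpenCurve",
    "SnakeParams",
    "NeuronTrace",
    "init_curve",
    "stretch_direction",
    "evolve",
    "snake_energy",
    "trace_all",
]


@dataclass
class OpenCurve:
    """An ordered continuous 3D point sequence with per-point radii."""

    points: np.ndarray                 # (n, 3) float (z, y, x)
    radii: np.ndarray | None = None    # (n,) voxels; filled by radius estimation
    converged: bool = False
    seed_rank: int = -1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 3:
            raise ParameterError(f"curve needs >= 3 points of dim 3, got shape {self.points.shape}")
        if self.radii is None:
            self.radii = np.zeros(len(self.points))
        self.radii = np.asarray(self.radii, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.points)

    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class SnakeParams:
    """Evolution weights and stopping criteria (lengths in voxels)."""

    alpha: float = 0.0             # elasticity; 0 lets the open curve stretch freely
    beta_interior: float = 0.1     # stiffness at interior points (endpoints always 0)
    k_stretch: float = 0.5         # endpoint stretching weight
    gamma: float = 1.0             # evolution step size
    max_iters: int = 500
    convergence_tol: float = 0.05  # max point displacement to declare convergence
    grow_step: float = 1.0         # endpoint extension per iteration
    background_floor: float = 0.05 # intensity below which growth stops
    max_length: float = 1000.0     # safety cap on arc length
    spacing: float = 1.0           # resampling arc spacing
    smoothing_sigma: float = 1.5   # Gaussian sigma for the Hessian axis estimate

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta_interior < 0 or self.k_stretch <= 0 or self.gamma <= 0:
            raise ParameterError("need alpha, beta >= 0 and k_stretch, gamma > 0")


@dataclass
class NeuronTrace:
    """Traced curves plus branch topology; serializable as SWC.

    ``links`` holds ``(child_curve, parent_curve, parent_point_index,
    child_end)`` tuples; the link graph must stay acyclic, with every
    non-root curve attached to at most one parent.
    """

    curves: list[OpenCurve] = field(default_factory=list)
    links: list[tuple[int, int, int, int]] = field(default_factory=list)
    branch_points: list = field(default_factory=list)
    root: int = 0

    def n_points(self) -> int:
        return sum(len(c) for c in self.curves)

    def parent_of(self) -> dict[int, int]:
        return {child: parent for child, parent, _, _ in self.links}

    def assert_acyclic(self) -> None:
        parent = self.parent_of()
        for start in range(len(self.curves)):
            seen = set()
            cur = start
            while cur in parent:
                if cur in seen:
                    raise ParameterError(f"cycle in trace links through curve {start}")
                seen.add(cur)
                cur = parent[cur]


def _clip_to_bounds(points: np.ndarray, shape) -> np.ndarray:
    return np.clip(points, 0.0, np.asarray(shape, dtype=float) - 1.0)


def resample_curve(points: np.ndarray, spacing: float = 1.0, min_points: int = 3) -> np.ndarray:
    """Resample a polyline to uniform arc spacing close to ``spacing``."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(round(s[-1] / spacing)) + 1, min_points)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, points[:, c]) for c in range(3)])


def init_curve(seed: Seed, shape, half_length: float = 3.0) -> OpenCurve:
    """Straight 5-point segment through the seed along its axis estimate."""
    t = np.linspace(-half_length, half_length, 5)
    pts = np.asarray(seed.position, dtype=float)[None, :] + t[:, None] * np.asarray(seed.axis)[None, :]
    pts = _clip_to_bounds(pts, shape)
    # drop points collapsed onto the clip boundary duplicates
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    pts = pts[keep]
    if len(pts) < 3:
        pts = resample_curve(pts if len(pts) > 1 else np.vstack([pts, pts + 1e-3]), spacing=0.1, min_points=3)
    return OpenCurve(pts, seed_rank=seed.rank)


def stretch_direction(
    curve: OpenCurve,
    end: str,
    volume: Volume3D,
    smoothing_sigma: float = 1.5,
    _smoothed: np.ndarray | None = None,
) -> np.ndarray:
    """Outward continuation direction at one end ('head' = index 0, 'tail' = last).

    The direction is the local tube axis (weak-curvature Hessian eigenvector)
    flipped to point away from the curve body; a degenerate Hessian (flat
    background) falls back to the outward curve tangent.
    """
    if end not in ("head", "tail"):
        raise ParameterError(f"end must be 'head' or 'tail', got {end!r}")
    idx, nbr = (0, 1) if end == "head" else (-1, -2)
    p = curve.points[idx]
    outward = p - curve.points[nbr]
    outward /= np.linalg.norm(outward)
    smoothed = _smoothed
    if smoothed is None:
        smoothed = ndimage.gaussian_filter(volume.data.astype(float), smoothing_sigma)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        axis = axis_from_smoothed(smoothed, p)
    h = _hessian_norm(smoothed, p)
    if h < 1e-10:  # flat neighborhood: no meaningful eigen-structure
        return outward
    if axis @ outward < 0:
        axis = -axis
    if abs(axis @ outward) < 1e-6:  # axis perpendicular to the curve: sign undefined
        return outward
    return axis


def _hessian_norm(smoothed: np.ndarray, p) -> float:
    from .seeding import _hessian_at

    return float(np.abs(_hessian_at(smoothed, np.asarray(p, dtype=float))).max())


def _internal_matrix(n: int, alpha: float, beta_interior: float) -> np.ndarray:
    """Dense (n, n) internal-energy stiffness matrix for an open curve.

    Built as D1' diag(alpha) D1 + D2' diag(beta) D2 with free-end boundary
    conditions; beta is zero at the two endpoints.
    """
    d1 = np.zeros((n - 1, n))
    idx = np.arange(n - 1)
    d1[idx, idx] = -1.0
    d1[idx, idx + 1] = 1.0
    d2 = np.zeros((n - 2, n))
    idx = np.arange(n - 2)
    d2[idx, idx] = 1.0
    d2[idx, idx + 1] = -2.0
    d2[idx, idx + 2] = 1.0
    beta = np.full(n - 2, beta_interior)  # rows correspond to interior points 1..n-2
    return alpha * d1.T @ d1 + d2.T @ (beta[:, None] * d2)


def snake_energy(curve: OpenCurve, volume: Volume3D, params: SnakeParams) -> float:
    """Discretized snake energy: internal bending/elasticity plus image term.

    The image term is the negative intensity along the curve (the GVF force
    drives points up-intensity toward the centerline, so intensity is the
    natural potential to monitor).
    """
    pts = curve.points
    d1 = np.diff(pts, axis=0)
    d2 = np.diff(pts, n=2, axis=0)
    internal = params.alpha * (d1 ** 2).sum() + params.beta_interior * (d2 ** 2).sum()
    image = -sample_scalar(volume.data, pts).mean() * len(pts)
    return float(internal + image)


def evolve(
    curve: OpenCurve,
    gvf_norm: VectorField3D,
    volume: Volume3D,
    params: SnakeParams,
    grow: bool = True,
    resample: bool = True,
    stop_points: np.ndarray | None = None,
    stop_radius: float = 0.0,
) -> OpenCurve:
    """Evolve one snake to convergence (see module docstring).

    Stops when no end can grow and the maximum per-point displacement of an
    iteration is below ``convergence_tol``, or at ``max_iters`` /
    ``max_length``.  Growth at an end also halts when it stalls against an
    opposing image force (arc length stops increasing), or when the end
    collides with ``stop_points`` (existing traces) within ``stop_radius``.
    Deterministic.
    """
    if gvf_norm.kind != "normalized-gvf":
        raise ParameterError(f"evolve expects a normalized-gvf field, got {gvf_norm.kind!r}")
    shape = volume.shape
    smoothed = ndimage.gaussian_filter(volume.data.astype(float), params.smoothing_sigma)
    pts = curve.points.copy()
    grow_head = grow_tail = grow
    converged = False
    solve_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    stop_tree = cKDTree(stop_points) if stop_points is not None and len(stop_points) else None
    prev_length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    stall = 0

    from scipy.linalg import lu_factor, lu_solve

    for _ in range(params.max_iters):
        n = len(pts)
        if n not in solve_cache:
            a = _internal_matrix(n, params.alpha, params.beta_interior)
            solve_cache[n] = lu_factor(np.eye(n) + params.gamma * a)
        lu = solve_cache[n]

        # external force: image (normalized GVF) everywhere, stretch at the free ends
        force = _field_at(gvf_norm, pts)
        if grow_head:
            force[0] += params.k_stretch * stretch_direction(
                OpenCurve(pts), "head", volume, _smoothed=smoothed
            )
        if grow_tail:
            force[-1] += params.k_stretch * stretch_direction(
                OpenCurve(pts), "tail", volume, _smoothed=smoothed
            )

        new = np.column_stack([
            lu_solve(lu, pts[:, c] + params.gamma * force[:, c]) for c in range(3)
        ])
        clipped = _clip_to_bounds(new, shape)
        # convergence is judged on the displacement normal to the curve:
        # tangential sliding is mere reparametrization, not shape change
        delta = clipped - pts
        tang = np.gradient(pts, axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
        normal = delta - (delta * tang).sum(axis=1, keepdims=True) * tang
        disp = float(np.linalg.norm(normal, axis=1).max())
        pts = clipped

        grew = False
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        for end, active in (("head", grow_head), ("tail", grow_tail)):
            if not active:
                continue
            i = 0 if end == "head" else -1
            d = stretch_direction(OpenCurve(pts), end, volume, _smoothed=smoothed)
            cand = pts[i] + params.grow_step * d
            inside = np.all(cand >= 0) and np.all(cand <= np.asarray(shape) - 1)
            if not inside or length >= params.max_length:
                if end == "head":
                    grow_head = False
                else:
                    grow_tail = False
                continue
            if sample_scalar(volume.data, cand) < params.background_floor:
                if end == "head":
                    grow_head = False
                else:
                    grow_tail = False
                continue
            if stop_tree is not None and stop_tree.query(cand)[0] <= stop_radius:
                if end == "head":
                    grow_head = False
                else:
                    grow_tail = False
                continue
            pts = np.vstack([cand[None], pts]) if end == "head" else np.vstack([pts, cand[None]])
            grew = True

        if resample:
            pts = resample_curve(pts, params.spacing)

        # growth stalled against an opposing image force: the end is at the
        # structure's boundary even though the intensity floor never tripped
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        if grew and length - prev_length < 0.1 * params.grow_step:
            stall += 1
            if stall >= 10:
                grow_head = grow_tail = False
        elif grew:
            stall = 0
        prev_length = length

        if not grew and not grow_head and not grow_tail and disp <= params.convergence_tol:
            converged = True
            break
        if not grow and disp <= params.convergence_tol:
            converged = True
            break

    return OpenCurve(pts, converged=converged, seed_rank=curve.seed_rank)


def _field_at(fld: VectorField3D, pts: np.ndarray) -> np.ndarray:
    out = np.empty((len(pts), 3))
    coords = np.clip(pts, 0, np.asarray(fld.grid_shape, dtype=float) - 1).T
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(fld.vectors[c], coords, order=1, mode="nearest")
    return out


def trace_all(
    seeds: SeedList,
    gvf_norm: VectorField3D,
    volume: Volume3D,
    params: SnakeParams,
    branch_points=None,
    coverage_radius: float = 3.0,
    merge_radius: float = 3.0,
    min_arc_length: float = 5.0,
) -> NeuronTrace:
    """Trace snakes from seeds in rank order and assemble the topology.

    Seeds within ``coverage_radius`` of an already-traced curve are skipped
    (their structure is covered).  Growth stops when an end collides with an
    existing curve (within ``merge_radius``) and the new curve is linked as a
    child at the nearest point — this is how junctions are recovered without
    manual input.  Explicit ``branch_points`` force links at those locations.
    Curves shorter than ``min_arc_length`` (stubs from seeds just outside the
    covered region) are discarded.
    """
    trace = NeuronTrace(branch_points=list(branch_points) if branch_points is not None else [])
    all_pts: list[np.ndarray] = []
    owner: list[int] = []

    for seed in seeds:
        stacked_prev = np.vstack(all_pts) if all_pts else None
        if stacked_prev is not None:
            tree = cKDTree(stacked_prev)
            if tree.query(np.asarray(seed.position, dtype=float))[0] <= coverage_radius:
                continue
        curve = evolve(
            init_curve(seed, volume.shape), gvf_norm, volume, params,
            stop_points=stacked_prev, stop_radius=merge_radius,
        )
        if curve.arc_length() < min_arc_length:
            continue
        cidx = len(trace.curves)
        trace.curves.append(curve)
        if all_pts:
            stacked = np.vstack(all_pts)
            tree = cKDTree(stacked)
            best = None
            for end, pt in ((0, curve.points[0]), (1, curve.points[-1])):
                d, j = tree.query(pt)
                if d <= merge_radius and (best is None or d < best[0]):
                    best = (d, j, end)
            if best is not None:
                _, j, end = best
                parent_curve = owner[j]
                offset = j - owner.index(parent_curve)  # index within the parent curve
                trace.links.append((cidx, parent_curve, int(offset), end))
        all_pts.extend(curve.points)
        owner.extend([cidx] * len(curve.points))

    # forced links at user-supplied branch points
    if trace.branch_points and len(trace.curves) >= 2:
        parent_map = trace.parent_of()
        for bp in trace.branch_points:
            bp = np.asarray(bp, dtype=float)
            dists = []
            for ci, c in enumerate(trace.curves):
                d = np.linalg.norm(c.points - bp, axis=1)
                dists.append((float(d.min()), int(d.argmin()), ci))
            dists.sort()
            (d0, j0, parent), (d1, j1, child) = dists[0], dists[1]
            ancestors = set()
            cur = parent
            while cur in parent_map:
                ancestors.add(cur)
                cur = parent_map[cur]
            ancestors.add(cur)
            if child not in parent_map and child not in ancestors:
                end = 0 if j1 < len(trace.curves[child]) / 2 else 1
                trace.links.append((child, parent, j0, end))
                parent_map[child] = parent
    trace.assert_acyclic()
    return trace
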