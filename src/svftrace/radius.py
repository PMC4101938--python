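"""Per-point tube radius estimation along traced curves.

At each curve point ``O`` a local orthonormal frame ``(v1, v2, v3)`` is
built with ``v3`` the curve tangent and ``v1, v2`` spanning the normal
plane.  The boundary response at radius ``r`` is

    B(O, r) = (1/N) * sum_i |grad(O + r v_ai)| * max(-gvf_hat(O + r v_ai) . v_ai, 0)

over ``N`` equally spaced ray directions ``v_ai = cos(a_i) v1 + sin(a_i) v2``
in the normal plane: the raw gradient magnitude (large on the tube wall)
weighted by the rectified inward projection of the normalized GVF (positive
only where the flow points back toward the centerline).  ``B`` peaks when
the sample circle sits on the tube boundary, so the estimated radius is the
argmax of ``B`` over a radius sweep, followed by an optional window-3 median
filter along the curve to suppress single-point outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .fields import VectorField3D
from .snake import OpenCurve

__all__ = ["CrossSectionFrame", "RadiusParams", "make_frame", "boundary_response", "estimate_radius"]


@dataclass
class CrossSectionFrame:
    """Right-handed orthonormal frame at a curve point (components (z, y, x))."""

    origin: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray


@dataclass
class RadiusParams:
    """Radius-search settings (lengths in voxels)."""

    n_rays: int = 8
    r_min: float = 1.0
    r_max: float = 30.0
    r_step: float = 0.25
    median_window: int = 3      # set to 1 to disable the along-curve median filter
    grad_source: str = "raw"    # magnitude field: raw gradient or pre-normalization GVF

    def __post_init__(self) -> None:
        if self.n_rays < 4:
            raise ParameterError(f"n_rays must be >= 4, got {self.n_rays}")
        if not 0 < self.r_min < self.r_max:
            raise ParameterError(f"need 0 < r_min < r_max, got ({self.r_min}, {self.r_max})")
        if self.r_step <= 0:
            raise ParameterError(f"r_step must be positive, got {self.r_step}")


def make_frame(curve: OpenCurve, index: int) -> CrossSectionFrame:
    """Cross-section frame at one curve point.

    ``v3`` is the normalized central-difference tangent (one-sided at the
    ends); ``v1`` is the global axis least aligned with ``v3`` projected
    orthogonal to it, and ``v2 = v3 x v1`` completes a right-handed triple.
    """
    pts = curve.points
    n = len(pts)
    i0, i1 = max(index - 1, 0), min(index + 1, n - 1)
    t = pts[i1] - pts[i0]
    norm = np.linalg.norm(t)
    if norm < 1e-12:
        raise ParameterError(f"zero tangent at curve point {index} (duplicate points)")
    v3 = t / norm
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(v3)))] = 1.0
    v1 = ref - (ref @ v3) * v3
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(v3, v1)
    return CrossSectionFrame(pts[index].copy(), v1, v2, v3)


def _vec_at(fld: VectorField3D, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear vector lookup plus an out-of-bounds mask."""
    shape = np.asarray(fld.grid_shape, dtype=float)
    flat = pts.reshape(-1, 3)
    oob = np.any((flat < 0) | (flat > shape - 1), axis=1).reshape(pts.shape[:-1])
    out = np.empty(pts.shape)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            fld.vectors[c], flat.T, order=1, mode="nearest"
        ).reshape(pts.shape[:-1])
    return out, oob


def boundary_response(
    frame: CrossSectionFrame,
    r: float,
    gradient_field: VectorField3D,
    gvf_norm: VectorField3D,
    params: RadiusParams,
) -> float:
    """Boundary response B(O, r) >= 0; out-of-bounds rays contribute 0."""
    return float(_responses(frame, np.array([r]), gradient_field, gvf_norm, params)[0])


def _responses(frame, radii, gradient_field, gvf_norm, params) -> np.ndarray:
    ai = 2.0 * np.pi * np.arange(params.n_rays) / params.n_rays
    rays = np.cos(ai)[:, None] * frame.v1[None, :] + np.sin(ai)[:, None] * frame.v2[None, :]
    pts = frame.origin[None, None, :] + radii[:, None, None] * rays[None, :, :]  # (R, N, 3)
    g, oob = _vec_at(gradient_field, pts)
    gvf, oob2 = _vec_at(gvf_norm, pts)
    gmag = np.linalg.norm(g, axis=-1)
    inward = np.maximum(-(gvf * rays[None]).sum(axis=-1), 0.0)
    term = gmag * inward
    term[oob | oob2] = 0.0
    return term.mean(axis=1)


def estimate_radius(
    curve: OpenCurve,
    gradient_field: VectorField3D,
    gvf_norm: VectorField3D,
    params: RadiusParams,
) -> OpenCurve:
    """Fill per-point radii by maximizing the boundary response.

    Points where every sampled response is zero (e.g. a point that strayed
    into flat background) get the neighbor-interpolated radius and a logged
    warning.  Deterministic: the first maximum wins on ties.
    """
    radii_grid = np.arange(params.r_min, params.r_max + 1e-9, params.r_step)
    n = len(curve)
    est = np.full(n, np.nan)
    for i in range(n):
        frame = make_frame(curve, i)
        resp = _responses(frame, radii_grid, gradient_field, gvf_norm, params)
        if resp.max() <= 0.0:
            continue
        est[i] = radii_grid[int(np.argmax(resp))]
    bad = np.isnan(est)
    if bad.all():
        warnings.warn("all boundary responses are zero along the curve; radii set to r_min")
        est[:] = params.r_min
    elif bad.any():
        warnings.warn(f"{int(bad.sum())} curve point(s) had zero boundary response; interpolated")
        idx = np.arange(n)
        est[bad] = np.interp(idx[bad], idx[~bad], est[~bad])
    if params.median_window > 1:
        est = ndimage.median_filter(est, size=params.median_window, mode="nearest")
    return OpenCurve(curve.points.copy(), radii=est, converged=curve.converged, seed_rank=curve.seed_rank)
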