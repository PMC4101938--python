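"""SCI / SVF, checked against naive loop oracles with independent trilinear code."""

import numpy as np
import pytest

from svftrace import (
    ParameterError,
    SVFParams,
    VectorField3D,
    Volume3D,
    build_directions,
    gradient,
    sci_point,
    sci_region,
    svf_response,
    svf_volume,
)
from svftrace.svf3d import svf_response_batch


def _trilinear(grid, p):
    z0, y0, x0 = (min(max(int(np.floor(c)), 0), s - 2) for c, s in zip(p, grid.shape))
    fz, fy, fx = p[0] - z0, p[1] - y0, p[2] - x0
    out = 0.0
    for dz, wz in ((0, 1 - fz), (1, fz)):
        for dy, wy in ((0, 1 - fy), (1, fy)):
            for dx, wx in ((0, 1 - fx), (1, fx)):
                out += grid[z0 + dz, y0 + dy, x0 + dx] * wz * wy * wx
    return out


def svf_oracle(grad_field, voxel, params, dirs):
    """Literal triple loop: directions x band centers x band samples."""
    voxel = np.asarray(voxel, dtype=float)
    shape = np.asarray(grad_field.grid_shape, dtype=float)
    total = 0.0
    for d in dirs.directions:
        best = -np.inf
        r = params.r_min
        while r <= params.r_max + 1e-9:
            acc = 0.0
            for k in range(params.vt + 1):
                rr = r - params.vt / 2.0 + k
                p = voxel + rr * d
                if rr == 0 or np.any(p < 0) or np.any(p > shape - 1):
                    continue
                g = np.array([_trilinear(grad_field.vectors[c], p) for c in range(3)])
                mag = np.linalg.norm(g)
                if mag > 0:
                    acc += -(g @ d) / mag
            best = max(best, acc / (params.vt + 1))
            r += 1.0
        total += best
    return total / len(dirs.directions)


# ---------------------------------------------------------------- SCI


def test_sci_point_sign_conventions():
    v = np.zeros((3, 5, 5, 5))
    f = VectorField3D(v.copy(), "raw-gradient")
    f.vectors[2, 2, 2, 1] = 1.0   # at p=(2,2,1): gradient +x, PO = +x
    assert sci_point(f, (2, 2, 1), (2, 2, 2)) == pytest.approx(1.0)
    f.vectors[2, 2, 2, 1] = -1.0  # anti-parallel
    assert sci_point(f, (2, 2, 1), (2, 2, 2)) == pytest.approx(-1.0)
    f.vectors[2, 2, 2, 1] = 0.0
    f.vectors[0, 2, 2, 1] = 1.0   # perpendicular
    assert sci_point(f, (2, 2, 1), (2, 2, 2)) == pytest.approx(0.0)
    assert sci_point(VectorField3D(v, "raw-gradient"), (2, 2, 1), (2, 2, 2)) == 0.0


def test_sci_point_degenerate_direction_rejected(blob):
    with pytest.raises(ParameterError):
        sci_point(blob.grad, (5, 5, 5), (5, 5, 5))


def test_sci_region_blob_center_high(blob):
    assert sci_region(blob.grad, (16, 16, 16), 6.0) >= 0.9


def test_sci_region_flat_background_zero():
    g = gradient(Volume3D(np.full((11, 11, 11), 0.4)))
    assert sci_region(g, (5, 5, 5), 3.0) == 0.0


@pytest.mark.parametrize("seed", range(3))
def test_sci_region_matches_naive_double_loop(seed, blob):
    r = np.random.default_rng(seed)
    g = gradient(Volume3D(r.random((17, 17, 17))))
    o = np.array([8, 8, 8])
    rad = 4.0
    acc, n = 0.0, 0
    for dz in range(-4, 5):
        for dy in range(-4, 5):
            for dx in range(-4, 5):
                rel = np.array([dz, dy, dx], dtype=float)
                dist = np.linalg.norm(rel)
                if dist == 0 or dist > rad:
                    continue
                gv = g.vectors[:, 8 + dz, 8 + dy, 8 + dx]
                mag = np.linalg.norm(gv)
                if mag > 0:
                    acc += (gv @ (-rel)) / (mag * dist)
                n += 1
    assert sci_region(g, o, rad) == pytest.approx(acc / n, abs=1e-12)


# ---------------------------------------------------------------- directions


def test_direction_set_m2_pn4_contains_axes():
    ds = build_directions(2, 4)
    assert ds.directions.shape == (8, 3)
    want = [(1, 0, 0), (-1, 0, 0), (0, 0, 1), (0, 0, -1), (0, 1, 0), (0, -1, 0)]
    for w in want:
        assert np.min(np.linalg.norm(ds.directions - np.array(w), axis=1)) < 1e-12


def test_directions_unit_norm_and_negation_symmetry():
    ds = build_directions(8, 12)
    norms = np.linalg.norm(ds.directions, axis=1)
    assert np.allclose(norms, 1.0, atol=1e-12)
    # every direction's negation is within pi/Pn of some member
    for d in ds.directions:
        cos = ds.directions @ (-d)
        assert np.arccos(np.clip(cos.max(), -1, 1)) <= np.pi / 12 + 1e-9


def test_directions_cover_sphere_evenly():
    ds = build_directions(32, 32)
    assert np.linalg.norm(ds.directions.mean(axis=0)) <= 0.05


# ---------------------------------------------------------------- SVF


def test_flat_background_response_zero():
    g = gradient(Volume3D(np.full((21, 21, 21), 0.5)))
    p = SVFParams(m_sections=4, pn_lines=4, vt=2, r_min=2.0, r_max=5.0)
    assert svf_response(g, (10, 10, 10), p) == 0.0


def test_cylinder_axis_response_strong_and_dominant(cylinder):
    p = SVFParams(m_sections=16, pn_lines=16, vt=2, r_min=3.0, r_max=10.0)
    dirs = build_directions(16, 16)
    on = svf_response(cylinder.grad, (20, 20, 30), p, dirs)
    assert on >= 0.5
    for off in (3, 5, 8):
        assert on >= svf_response(cylinder.grad, (20, 20 + off, 30), p, dirs)


@pytest.mark.parametrize("seed", range(5))
def test_matches_naive_triple_loop_oracle(seed):
    r = np.random.default_rng(seed)
    g = gradient(Volume3D(r.random((17, 17, 17))))
    p = SVFParams(m_sections=4, pn_lines=6, vt=2, r_min=2.0, r_max=5.0)
    dirs = build_directions(4, 6)
    voxels = np.array([[8, 8, 8], [6, 9, 7], [9, 6, 10]], dtype=float)
    fast = svf_response_batch(g, voxels, p, dirs)
    slow = [svf_oracle(g, v, p, dirs) for v in voxels]
    assert np.abs(fast - np.asarray(slow)).max() <= 1e-10


def test_boundary_clipping_keeps_response_finite(cylinder):
    # support extends past the volume faces; clipped samples contribute 0
    p = SVFParams(m_sections=8, pn_lines=8, vt=2, r_min=3.0, r_max=10.0)
    val = svf_response(cylinder.grad, (20, 20, 2), p)
    assert -1.0 <= val <= 1.0


def test_responses_bounded(rng):
    g = gradient(Volume3D(rng.random((17, 17, 17))))
    p = SVFParams(m_sections=4, pn_lines=6, vt=2, r_min=2.0, r_max=5.0)
    vox = rng.integers(6, 11, size=(10, 3)).astype(float)
    vals = svf_response_batch(g, vox, p)
    assert np.all(vals >= -1.0) and np.all(vals <= 1.0)


def test_affine_intensity_invariance(cylinder):
    p = SVFParams(m_sections=8, pn_lines=8, vt=2, r_min=3.0, r_max=10.0)
    dirs = build_directions(8, 8)
    g2 = gradient(Volume3D(3.7 * cylinder.volume.data + 0.2))
    vox = np.array([[20, 20, 30], [20, 23, 30], [18, 20, 25]], dtype=float)
    a = svf_response_batch(cylinder.grad, vox, p, dirs)
    b = svf_response_batch(g2, vox, p, dirs)
    assert np.abs(a - b).max() <= 1e-6


def test_svf_volume_mask_behavior(cylinder):
    p = SVFParams(m_sections=4, pn_lines=4, vt=2, r_min=3.0, r_max=6.0)
    empty = svf_volume(cylinder.volume, p, mask_threshold=1.1)
    assert np.all(empty.data == 0)
    flat = svf_volume(Volume3D(np.zeros((10, 10, 10))), p, mask_threshold=0.0)
    assert np.all(flat.data == 0)


def test_svf_volume_argmax_on_centerline(cylinder, cylinder_response):
    am = np.asarray(np.unravel_index(np.argmax(cylinder_response.data), cylinder_response.data.shape))
    d = np.linalg.norm(am[:2] - np.array([20, 20]))
    assert d <= 1.0


def test_rotation_invariance_90deg_about_z(cylinder):
    p = SVFParams(m_sections=16, pn_lines=16, vt=2, r_min=3.0, r_max=10.0)
    dirs = build_directions(16, 16)
    rot = Volume3D(np.rot90(cylinder.volume.data, axes=(1, 2)).copy())
    grot = gradient(rot)
    # rot90 in the (y, x) plane: old (y=20, x) lands at (y'=59-x, x'=20)
    for x in (20, 30, 40):
        a = svf_response(cylinder.grad, (20, 20, x), p, dirs)
        b = svf_response(grot, (20, 59 - x, 20), p, dirs)
        assert abs(a - b) <= 0.05
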