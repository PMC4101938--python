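import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svftrace import (
    BoundsError,
    ParameterError,
    VectorField3D,
    Volume3D,
    gradient,
    gvf,
    normalize_field,
    sample,
)
from svftrace.fields import gvf_energy


def test_gradient_of_linear_ramp():
    dx = 20
    x = np.arange(dx) / dx
    vol = Volume3D(np.broadcast_to(x, (10, 12, dx)).copy())
    g = gradient(vol)
    interior = g.vectors[:, 1:-1, 1:-1, 1:-1]
    assert np.allclose(interior[0], 0) and np.allclose(interior[1], 0)
    assert np.allclose(interior[2], 1 / dx)


def test_gradient_of_constant_is_zero():
    g = gradient(Volume3D(np.full((5, 5, 5), 0.3)))
    assert np.all(g.vectors == 0)


def test_gradient_points_at_blob_center(blob):
    g = blob.grad
    c = np.array([16.0, 16.0, 16.0])
    zz, yy, xx = np.meshgrid(*[np.arange(33)] * 3, indexing="ij")
    pos = np.stack([zz, yy, xx], axis=-1).astype(float)
    to_center = c - pos
    dist = np.linalg.norm(to_center, axis=-1)
    vec = np.moveaxis(g.vectors, 0, -1)
    mag = np.linalg.norm(vec, axis=-1)
    sel = (dist >= 2) & (dist <= 10) & (mag > 1e-6)
    cos = (vec * to_center).sum(axis=-1)[sel] / (mag[sel] * dist[sel])
    # within 5 degrees of radially inward
    assert cos.min() >= np.cos(np.deg2rad(5.0))


def test_gvf_zero_field_fixed_point():
    zero = VectorField3D(np.zeros((3, 8, 8, 8)), "raw-gradient")
    out = gvf(zero, iterations=25)
    assert np.all(out.vectors == 0)


def test_gvf_zero_iterations_is_identity(rng):
    f = VectorField3D(rng.normal(size=(3, 6, 6, 6)), "raw-gradient")
    out = gvf(f, iterations=0)
    assert np.array_equal(out.vectors, f.vectors)


def test_gvf_extends_edge_attraction_range():
    # step edge at x = 16: the raw gradient vanishes >=3 voxels away, but the
    # diffused field still carries the up-intensity (+x) direction out there,
    # which is what gives the snake its long-range pull onto bright structure
    data = np.zeros((32, 32, 32))
    data[:, :, 16:] = 1.0
    g = gradient(Volume3D(data))
    out = gvf(g, mu=0.1, iterations=200, dt=0.5)
    assert abs(g.vectors[2, 16, 16, 10]) < 1e-12
    assert abs(g.vectors[2, 16, 16, 22]) < 1e-12
    assert out.vectors[2, 16, 16, 10] > 1e-4   # dark side: +x, toward the edge
    assert out.vectors[2, 16, 16, 22] > 1e-4   # bright side: +x, up-intensity


def test_gvf_centers_inside_a_bright_tube(cylinder):
    # inside the tube the normalized flow points at the axis from both sides:
    # the property the open-curve snake relies on
    gn = cylinder.gvf_norm
    assert gn.vectors[1, 20, 17, 30] > 0.5   # below the axis: +y toward it
    assert gn.vectors[1, 20, 23, 30] < -0.5  # above the axis: -y toward it


def test_gvf_energy_non_increasing():
    data = np.zeros((16, 16, 16))
    data[:, :, 8:] = 1.0
    g = gradient(Volume3D(data))
    energies = []
    for iters in (0, 5, 10, 20, 40):
        energies.append(gvf_energy(gvf(g, iterations=iters), g))
    assert np.all(np.diff(energies) <= 1e-9)


def test_gvf_unstable_dt_rejected(rng):
    f = VectorField3D(rng.normal(size=(3, 5, 5, 5)), "raw-gradient")
    with pytest.raises(ParameterError):
        gvf(f, mu=0.5, dt=0.5)  # bound is 1/(6*0.5) = 1/3


def test_normalize_field_unit_magnitudes_and_idempotence(rng):
    f = VectorField3D(rng.normal(size=(3, 6, 6, 6)), "gvf")
    out = normalize_field(f)
    mag = out.magnitude()
    assert np.all((mag < 1e-6) | (np.abs(mag - 1) < 1e-6))
    again = normalize_field(out)
    assert np.allclose(again.vectors, out.vectors)


def test_normalize_field_examples():
    v = np.zeros((3, 1, 1, 2))
    v[:, 0, 0, 0] = [0.0, 3.0, 4.0]
    v[:, 0, 0, 1] = [0.0, 1e-12, 0.0]
    out = normalize_field(VectorField3D(v, "gvf"), zero_tol=1e-9)
    assert np.allclose(out.vectors[:, 0, 0, 0], [0.0, 0.6, 0.8])
    assert np.all(out.vectors[:, 0, 0, 1] == 0)


def test_sample_exact_at_lattice_and_midpoint(rng):
    f = VectorField3D(rng.normal(size=(3, 5, 6, 7)), "raw-gradient")
    assert np.allclose(sample(f, (2.0, 3.0, 4.0)), f.vectors[:, 2, 3, 4])
    mid = sample(f, (2.0, 3.0, 4.5))
    assert np.allclose(mid, (f.vectors[:, 2, 3, 4] + f.vectors[:, 2, 3, 5]) / 2)


def test_sample_out_of_bounds_raises(rng):
    f = VectorField3D(rng.normal(size=(3, 5, 5, 5)), "raw-gradient")
    with pytest.raises(BoundsError):
        sample(f, (4.2, 1.0, 1.0))


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(0.05, 0.95), min_size=3, max_size=3),
       st.integers(0, 2 ** 31 - 1))
def test_sample_reproduces_linear_fields_exactly(frac, seed):
    # trilinear interpolation is exact for fields linear in (z, y, x)
    r = np.random.default_rng(seed)
    coef = r.normal(size=(3, 4))
    zz, yy, xx = np.meshgrid(np.arange(6.0), np.arange(7.0), np.arange(8.0), indexing="ij")
    comps = [c[0] + c[1] * zz + c[2] * yy + c[3] * xx for c in coef]
    f = VectorField3D(np.stack(comps), "raw-gradient")
    p = np.array(frac) * np.array([5.0, 6.0, 7.0])
    expected = [c[0] + c[1] * p[0] + c[2] * p[1] + c[3] * p[2] for c in coef]
    assert np.allclose(sample(f, p), expected, atol=1e-9)
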