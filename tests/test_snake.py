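import numpy as np
import pytest
from scipy.spatial import cKDTree

from svftrace import OpenCurve, SnakeParams, evolve, init_curve, stretch_direction, trace_all
from svftrace.seeding import Seed, SeedList, detect_seeds
from svftrace.snake import resample_curve, snake_energy


def _seed(pos, axis, rank=0):
    return Seed(np.asarray(pos, dtype=float), 0.8, np.asarray(axis, dtype=float), rank=rank)


def test_init_curve_geometry():
    c = init_curve(_seed((20, 20, 30), (0, 0, 1)), (40, 40, 60), half_length=3.0)
    assert len(c) == 5
    assert np.allclose(c.points[0], (20, 20, 27))
    assert np.allclose(c.points[-1], (20, 20, 33))


def test_init_curve_clipped_at_corner_keeps_three_points():
    c = init_curve(_seed((0, 0, 0), (0, 0, 1)), (40, 40, 60), half_length=3.0)
    assert len(c) >= 3
    assert np.all(c.points >= 0)


def test_init_curves_stay_inside_volume(helix, helix_response):
    seeds = detect_seeds(helix_response, helix.volume)
    for s in seeds:
        c = init_curve(s, helix.volume.shape)
        assert np.all(c.points >= 0)
        assert np.all(c.points <= np.array(helix.volume.shape) - 1)


def test_stretch_direction_follows_tube_and_flips(cylinder):
    x = np.linspace(20, 40, 21)
    pts = np.column_stack([np.full_like(x, 20.0), np.full_like(x, 20.0), x])
    c = OpenCurve(pts)
    head = stretch_direction(c, "head", cylinder.volume)
    tail = stretch_direction(c, "tail", cylinder.volume)
    assert np.degrees(np.arccos(np.clip(head @ np.array([0, 0, -1.0]), -1, 1))) <= 15
    assert np.degrees(np.arccos(np.clip(tail @ np.array([0, 0, 1.0]), -1, 1))) <= 15
    rev = OpenCurve(pts[::-1].copy())
    assert np.allclose(stretch_direction(rev, "tail", cylinder.volume), head, atol=1e-9)
    assert np.allclose(stretch_direction(rev, "head", cylinder.volume), tail, atol=1e-9)


def test_stretch_direction_flat_background_falls_back_to_tangent():
    from svftrace import Volume3D

    vol = Volume3D(np.zeros((20, 20, 20)))
    pts = np.column_stack([np.full(5, 10.0), np.full(5, 10.0), np.linspace(8, 12, 5)])
    d = stretch_direction(OpenCurve(pts), "tail", vol)
    assert np.allclose(d, [0, 0, 1])


def test_offset_curve_converges_to_cylinder_axis(cylinder):
    x = np.linspace(20, 40, 21)
    pts = np.column_stack([np.full_like(x, 20.0), np.full_like(x, 23.0), x])
    out = evolve(OpenCurve(pts), cylinder.gvf_norm, cylinder.volume, SnakeParams(), grow=False)
    assert out.converged
    dev = np.linalg.norm(out.points[:, :2] - np.array([20.0, 20.0]), axis=1)
    assert dev.max() <= 1.0


def test_no_stretch_on_axis_means_no_elongation(cylinder):
    x = np.linspace(25, 35, 11)
    pts = np.column_stack([np.full_like(x, 20.0), np.full_like(x, 20.0), x])
    before = OpenCurve(pts).arc_length()
    out = evolve(OpenCurve(pts), cylinder.gvf_norm, cylinder.volume,
                 SnakeParams(max_iters=100), grow=False)
    assert abs(out.arc_length() - before) <= 1.0


def test_energy_non_increasing_during_relaxation(cylinder_gauss):
    params = SnakeParams()
    x = np.linspace(20, 40, 21)
    cur = OpenCurve(np.column_stack([np.full_like(x, 20.0), np.full_like(x, 23.0), x]))
    energies = [snake_energy(cur, cylinder_gauss.volume, params)]
    for _ in range(10):
        cur = evolve(cur, cylinder_gauss.gvf_norm, cylinder_gauss.volume,
                     SnakeParams(max_iters=10), grow=False, resample=False)
        energies.append(snake_energy(cur, cylinder_gauss.volume, params))
    assert np.all(np.diff(energies) <= 1e-9)


def test_helix_traced_from_single_seed(helix):
    mid = len(helix.truth.centerline) // 2
    start = helix.truth.centerline[mid]
    tangent = helix.truth.centerline[mid + 3] - start
    tangent /= np.linalg.norm(tangent)
    out = evolve(
        init_curve(_seed(start, tangent), helix.volume.shape),
        helix.gvf_norm, helix.volume, SnakeParams(),
    )
    assert out.arc_length() >= 0.9 * helix.truth.arc_length()
    d, _ = cKDTree(helix.truth.centerline).query(out.points)
    assert d.mean() <= 1.5


def test_evolution_deterministic(cylinder):
    x = np.linspace(22, 38, 17)
    pts = np.column_stack([np.full_like(x, 20.0), np.full_like(x, 22.0), x])
    a = evolve(OpenCurve(pts), cylinder.gvf_norm, cylinder.volume, SnakeParams())
    b = evolve(OpenCurve(pts), cylinder.gvf_norm, cylinder.volume, SnakeParams())
    assert np.array_equal(a.points, b.points)


def test_point_spacing_after_resampling(helix):
    mid = len(helix.truth.centerline) // 2
    start = helix.truth.centerline[mid]
    out = evolve(
        init_curve(_seed(start, (0, 0, 1.0)), helix.volume.shape),
        helix.gvf_norm, helix.volume, SnakeParams(),
    )
    seg = np.linalg.norm(np.diff(out.points, axis=0), axis=1)
    assert seg.min() >= 0.5 and seg.max() <= 2.0


def test_resample_preserves_endpoints(rng):
    pts = np.cumsum(rng.normal(size=(30, 3)), axis=0)
    out = resample_curve(pts, 1.0)
    assert np.allclose(out[0], pts[0]) and np.allclose(out[-1], pts[-1])


def test_redundant_seeds_trace_single_curve(cylinder):
    seeds = SeedList([
        _seed((20, 20, 5 + 6 * i), (0, 0, 1), rank=i) for i in range(10)
    ])
    trace = trace_all(seeds, cylinder.gvf_norm, cylinder.volume, SnakeParams())
    assert len(trace.curves) == 1


def test_empty_seed_list_gives_empty_trace(cylinder):
    trace = trace_all(SeedList([]), cylinder.gvf_norm, cylinder.volume, SnakeParams())
    assert trace.curves == [] and trace.links == []


def test_trace_links_are_acyclic(helix, helix_response):
    seeds = detect_seeds(helix_response, helix.volume)
    trace = trace_all(seeds, helix.gvf_norm, helix.volume, SnakeParams())
    trace.assert_acyclic()
    parents = trace.parent_of()
    assert all(c != p for c, p in parents.items())
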