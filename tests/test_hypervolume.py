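"""Hypervolume construction: exact geometry, MC estimates, membership."""

import numpy as np
import pytest
from scipy.optimize import linprog
from scipy.spatial import Delaunay

from hyperniche.errors import ConfigurationError, DegenerateGeometryError
from hyperniche.hypervolume import (build_bdw, build_mcp, contains,
                                    load_hypervolume, save_hypervolume)


def grid_count_volume(sources, bandwidth, h=0.04):
    """Independent oracle: count fine-grid cells whose center is within
    Chebyshev `bandwidth` of any source (explicit distance scan)."""
    sources = np.asarray(sources)
    lo = sources.min(axis=0) - bandwidth
    hi = sources.max(axis=0) + bandwidth
    axes = [np.arange(lo[j] + h / 2, hi[j], h) for j in range(sources.shape[1])]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    pts = mesh.reshape(-1, sources.shape[1])
    inside = np.zeros(len(pts), dtype=bool)
    for chunk in np.array_split(np.arange(len(pts)), 40):
        d = np.abs(pts[chunk, None, :] - sources[None, :, :]).max(axis=2)
        inside[chunk] = (d <= bandwidth).any(axis=1)
    return inside.sum() * h ** sources.shape[1]


def rejection_volume(points, n_mc=200_000, seed=0):
    """Independent oracle for hull volume: bounding-box rejection sampling
    with membership by Delaunay simplex lookup."""
    tri = Delaunay(points)
    lo, hi = points.min(axis=0), points.max(axis=0)
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_mc, points.shape[1]))
    frac = (tri.find_simplex(samples) >= 0).mean()
    return frac * np.prod(hi - lo)


def in_hull_lp(vertices, point):
    """LP feasibility: is `point` a convex combination of `vertices`?"""
    n = len(vertices)
    res = linprog(c=np.zeros(n),
                  A_eq=np.vstack([vertices.T, np.ones(n)]),
                  b_eq=np.r_[point, 1.0], bounds=[(0, None)] * n,
                  method="highs")
    return res.success


class TestBdw:
    def test_single_point_d4_volume_exactly_one(self):
        hv = build_bdw(np.zeros((1, 4)), bandwidth=0.5, n_mc=100_000, seed=0)
        assert hv.volume == pytest.approx(1.0)   # one box, multiplicity 1
        assert hv.se == pytest.approx(0.0)

    def test_two_point_union_area_inclusion_exclusion(self):
        """Two d=2 boxes offset 0.5 on one axis: union area 1.5."""
        scores = np.array([[0.0, 0.0], [0.5, 0.0]])
        hv = build_bdw(scores, bandwidth=0.5, n_mc=100_000, seed=1)
        assert abs(hv.volume - 1.5) <= 3 * hv.se

    def test_random_cloud_matches_grid_count_oracle(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(scale=0.8, size=(30, 3))
        hv = build_bdw(scores, bandwidth=0.5, n_mc=200_000, seed=2)
        oracle = grid_count_volume(scores, 0.5)
        assert hv.volume == pytest.approx(oracle, rel=0.02)

    def test_determinism(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(20, 3))
        h1 = build_bdw(scores, n_mc=50_000, seed=11)
        h2 = build_bdw(scores, n_mc=50_000, seed=11)
        assert h1.volume == h2.volume
        np.testing.assert_array_equal(h1.uniform_points, h2.uniform_points)

    def test_adding_point_does_not_shrink_volume(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(15, 3))
        more = np.vstack([scores, rng.normal(size=(1, 3)) + 3.0])
        h1 = build_bdw(scores, n_mc=100_000, seed=3)
        h2 = build_bdw(more, n_mc=100_000, seed=3)
        joint_se = np.hypot(h1.se, h2.se)
        assert h2.volume >= h1.volume - 3 * joint_se

    def test_se_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(25, 3))
        ses = [build_bdw(scores, n_mc=n, seed=4).se
               for n in (1000, 10_000, 100_000)]
        for a, b in zip(ses, ses[1:]):
            assert b < a
            # each tenfold n_mc should cut SE by ~sqrt(10); allow slack
            assert b / a == pytest.approx(10 ** -0.5, rel=0.5)

    def test_low_n_mc_records_warning(self):
        hv = build_bdw(np.zeros((5, 2)), n_mc=200, seed=0, target_points=50)
        assert hv.mc_meta["warnings"]

    def test_empty_scores_error(self):
        with pytest.raises(ConfigurationError):
            build_bdw(np.empty((0, 3)))


class TestMcp:
    def test_unit_4simplex_volume_exact(self):
        simplex = np.vstack([np.zeros(4), np.eye(4)])
        hv = build_mcp(simplex, target_points=100, seed=0)
        assert hv.volume == pytest.approx(1 / 24, abs=1e-12)

    def test_unit_4cube_corners_volume_exact(self):
        corners = np.array([[(i >> j) & 1 for j in range(4)]
                            for i in range(16)], dtype=float)
        hv = build_mcp(corners, target_points=100, seed=0)
        assert hv.volume == pytest.approx(1.0, abs=1e-9)

    def test_volume_matches_rejection_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(50, 3))
        hv = build_mcp(pts, target_points=100, seed=0)
        assert hv.volume == pytest.approx(rejection_volume(pts), rel=0.02)

    def test_volume_matches_qhull(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(60, 4))
        hv = build_mcp(pts, target_points=100, seed=0)
        assert hv.volume == pytest.approx(hv.mc_meta["qhull_volume"], rel=1e-9)

    def test_hull_volume_below_bounding_box(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(40, 3))
        hv = build_mcp(pts, target_points=100, seed=0)
        assert hv.volume <= np.prod(np.ptp(pts, axis=0))

    def test_rank_deficient_cloud_raises_with_rank(self):
        rng = np.random.default_rng(6)
        plane = rng.normal(size=(30, 2))
        pts3 = np.column_stack([plane, plane @ [0.3, -0.7]])  # rank 2 in 3-D
        with pytest.raises(DegenerateGeometryError, match="rank 2"):
            build_mcp(pts3)

    def test_determinism(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(30, 3))
        h1 = build_mcp(pts, seed=9, target_points=500)
        h2 = build_mcp(pts, seed=9, target_points=500)
        np.testing.assert_array_equal(h1.uniform_points, h2.uniform_points)


class TestContains:
    def test_sources_and_vertices_inside(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(25, 3))
        for hv in (build_bdw(pts, n_mc=10_000, seed=0, target_points=100),
                   build_mcp(pts, target_points=100, seed=0)):
            assert contains(hv, pts).all()

    def test_point_beyond_bandwidth_outside(self):
        hv = build_bdw(np.zeros((1, 2)), bandwidth=0.5, n_mc=1000, seed=0,
                       target_points=10)
        assert not contains(hv, np.array([[1.5, 0.0]]))[0]

    def test_uniform_clouds_all_contained(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(30, 3))
        for hv in (build_bdw(pts, n_mc=50_000, seed=1, target_points=2000),
                   build_mcp(pts, target_points=2000, seed=1)):
            assert contains(hv, hv.uniform_points).all()

    def test_dimension_mismatch_error(self):
        hv = build_bdw(np.zeros((1, 3)), n_mc=1000, seed=0, target_points=10)
        with pytest.raises(ConfigurationError):
            contains(hv, np.zeros((2, 2)))

    def test_bdw_membership_matches_brute_force_scan(self):
        rng = np.random.default_rng(10)
        src = rng.normal(size=(20, 3))
        hv = build_bdw(src, n_mc=10_000, seed=0, target_points=100)
        probes = rng.uniform(-2.5, 2.5, size=(1000, 3))
        got = contains(hv, probes)
        cheb = np.abs(probes[:, None, :] - src[None, :, :]).max(axis=2)
        expected = (cheb <= 0.5 + 1e-9).any(axis=1)
        np.testing.assert_array_equal(got, expected)

    def test_mcp_membership_matches_lp_feasibility(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(25, 3))
        hv = build_mcp(pts, target_points=100, seed=0)
        probes = rng.uniform(-2, 2, size=(120, 3))
        got = contains(hv, probes)
        verts = hv.support["vertices"]
        expected = np.array([in_hull_lp(verts, p) for p in probes])
        np.testing.assert_array_equal(got, expected)


def test_serialization_round_trip_exact(tmp_path):
    rng = np.random.default_rng(12)
    pts = rng.normal(size=(30, 3))
    for hv in (build_bdw(pts, n_mc=20_000, seed=5, target_points=500),
               build_mcp(pts, target_points=500, seed=5)):
        base = tmp_path / f"hv_{hv.method}"
        save_hypervolume(hv, base)
        back = load_hypervolume(base)
        assert back.method == hv.method and back.dim == hv.dim
        assert back.volume == hv.volume
        np.testing.assert_array_equal(back.uniform_points, hv.uniform_points)
        for key, val in hv.support.items():
            if isinstance(val, np.ndarray):
                np.testing.assert_array_equal(back.support[key], val)
            else:
                assert back.support[key] == val
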