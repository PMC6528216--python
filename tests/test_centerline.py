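"""Skeletonization, spatial graph, path extraction, smoothing, length."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import otomorph as om
from otomorph.centerline import Polyline3D, SmoothingParams, extract_main_path
from otomorph.grids import BinaryMask
from otomorph.maskops import connected_component_count, contains
from conftest import make_ball_mask


def path_mask(n=10):
    mask = np.zeros((n + 2, 3, 3), bool)
    mask[1 : n + 1, 1, 1] = True
    return BinaryMask(mask, 1.0)


def y_mask(arm=5, short=None):
    """Y-shaped skeleton: two diagonal arms and one straight arm meeting
    at a single voxel (diagonal arms keep the junction unique under
    26-adjacency)."""
    short = arm if short is None else short
    n = 2 * arm + 3
    mask = np.zeros((n, n, 3), bool)
    c = arm + 1
    mask[c, c, 1] = True
    for i in range(1, arm + 1):
        mask[c - i, c - i, 1] = True  # up-left diagonal
        mask[c - i, c + i, 1] = True  # up-right diagonal
    for i in range(1, short + 1):
        mask[c + i, c, 1] = True  # straight down
    return BinaryMask(mask, 1.0)


class TestSkeletonize:
    def test_cylinder_thins_to_unit_width_path(self):
        """Medial thinning of a straight solid cylinder gives a single
        unit-width path along the axis, retracted by at most one tube
        radius at each flat end."""
        r, L = 5, 100
        mask = np.zeros((L + 4, 2 * r + 5, 2 * r + 5), bool)
        yy, zz = np.meshgrid(np.arange(2 * r + 5), np.arange(2 * r + 5), indexing="ij")
        disk = (yy - (r + 2)) ** 2 + (zz - (r + 2)) ** 2 <= r * r
        mask[2 : L + 2, disk] = True
        sk = om.skeletonize(BinaryMask(mask, 1.0))
        g = om.skeleton_to_graph(sk)
        degrees = [d for _, d in g.graph.degree()]
        assert max(degrees) <= 2 and len(g.endpoints) == 2
        coords = np.argwhere(sk.mask)
        span = coords[:, 0].max() - coords[:, 0].min()
        assert span >= L - 2 * r
        assert sk.count() <= L + 2

    def test_single_voxel_is_its_own_skeleton(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        sk = om.skeletonize(BinaryMask(mask, 1.0))
        assert np.array_equal(sk.mask, mask)

    def test_component_count_preserved(self):
        mask = np.zeros((40, 15, 15), bool)
        x, y, z = np.mgrid[0:40, 0:15, 0:15]
        mask |= (x - 8) ** 2 + (y - 7) ** 2 + (z - 7) ** 2 <= 25
        mask |= (x - 30) ** 2 + (y - 7) ** 2 + (z - 7) ** 2 <= 25
        m = BinaryMask(mask, 1.0)
        with pytest.warns(UserWarning, match="component"):
            sk = om.skeletonize(m)
        assert connected_component_count(sk) == 2

    def test_skeleton_is_subset_of_mask(self):
        m = make_ball_mask(8)
        sk = om.skeletonize(m)
        assert contains(m, sk)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            om.skeletonize(BinaryMask(np.zeros((3, 3, 3), bool), 1.0))


class TestSkeletonGraph:
    def test_straight_path_topology(self):
        g = om.skeleton_to_graph(path_mask(10))
        assert g.n_nodes == 10 and g.n_edges == 9
        assert len(g.endpoints) == 2 and len(g.junctions) == 0

    def test_y_shape_has_three_endpoints_one_junction(self):
        g = om.skeleton_to_graph(y_mask(5))
        assert len(g.endpoints) == 3
        assert len(g.junctions) == 1

    def test_empty_skeleton_gives_empty_graph(self):
        g = om.skeleton_to_graph(BinaryMask(np.zeros((3, 3, 3), bool), 1.0))
        assert g.n_nodes == 0

    def test_edge_weights_are_physical(self):
        m = path_mask(5)
        m.spacing_um = np.array([2.0, 3.0, 4.0])
        g = om.skeleton_to_graph(m)
        for _, _, w in g.graph.edges(data="weight"):
            assert w == pytest.approx(2.0)  # steps along axis 0


class TestExtractMainPath:
    def test_path_graph_returned_intact(self):
        g = om.skeleton_to_graph(path_mask(10))
        p = extract_main_path(g)
        assert len(p) == 10
        assert om.polyline_length(p) == pytest.approx(9.0)

    def test_y_shape_keeps_two_longest_arms(self):
        g = om.skeleton_to_graph(y_mask(5, short=3))
        p = extract_main_path(g)
        # Two diagonal arms of physical length 5*sqrt(2); the short straight
        # arm (length 3) is pruned.
        assert om.polyline_length(p) == pytest.approx(10.0 * np.sqrt(2.0))

    def test_largest_component_wins(self):
        mask = np.zeros((50, 3, 3), bool)
        mask[0:13, 1, 1] = True  # length 12
        mask[18:49, 1, 1] = True  # length 30
        g = om.skeleton_to_graph(BinaryMask(mask, 1.0))
        p = extract_main_path(g)
        assert om.polyline_length(p) == pytest.approx(30.0)
        assert p.points[:, 0].min() >= 18.0

    def test_pure_cycle_opened_with_warning(self):
        mask = np.zeros((10, 10, 3), bool)
        mask[2:8, 2, 1] = True
        mask[2:8, 7, 1] = True
        mask[2, 2:8, 1] = True
        mask[7, 2:8, 1] = True
        g = om.skeleton_to_graph(BinaryMask(mask, 1.0))
        with pytest.warns(UserWarning, match="cycle"):
            p = extract_main_path(g)
        assert len(p) >= 10


class TestSmoothPolyline:
    def test_default_parameters(self):
        p = SmoothingParams()
        assert (p.smoothing, p.adhere, p.n_iter) == (0.85, 0.05, 200)

    def test_collinear_points_are_fixed_point(self):
        pts = np.stack([np.arange(10.0), np.zeros(10), np.zeros(10)], axis=1)
        out = om.smooth_polyline(Polyline3D(pts))
        assert np.allclose(out.points, pts, atol=1e-9)

    def test_zigzag_shortens_but_respects_chord(self):
        n = 40
        pts = np.stack(
            [np.arange(n, dtype=float), np.where(np.arange(n) % 2 == 0, 1.0, -1.0), np.zeros(n)],
            axis=1,
        )
        p = Polyline3D(pts)
        out = om.smooth_polyline(p, SmoothingParams(smoothing=0.85, adhere=0.0, n_iter=200))
        chord = np.linalg.norm(pts[-1] - pts[0])
        assert om.polyline_length(out) < om.polyline_length(p)
        assert om.polyline_length(out) >= chord

    def test_zero_parameters_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(15, 3)).cumsum(axis=0)
        out = om.smooth_polyline(Polyline3D(pts), SmoothingParams(0.0, 0.0, 50))
        assert np.allclose(out.points, pts)

    def test_endpoints_exactly_fixed(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 3)).cumsum(axis=0)
        out = om.smooth_polyline(Polyline3D(pts))
        assert np.array_equal(out.points[0], pts[0])
        assert np.array_equal(out.points[-1], pts[-1])

    def test_two_points_returned_unchanged(self):
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        out = om.smooth_polyline(Polyline3D(pts))
        assert np.array_equal(out.points, pts)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), s=st.floats(0.1, 1.0), a=st.floats(0.0, 0.5))
    def test_smoothing_never_moves_endpoints(self, seed, s, a):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(12, 3)).cumsum(axis=0)
        out = om.smooth_polyline(Polyline3D(pts), SmoothingParams(s, a, 50))
        assert np.array_equal(out.points[0], pts[0])
        assert np.array_equal(out.points[-1], pts[-1])


class TestPolylineLength:
    def test_three_four_five(self):
        p = Polyline3D(np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]))
        assert om.polyline_length(p) == 5.0

    def test_collinear_unit_spaced(self):
        pts = np.stack([np.arange(10.0), np.zeros(10), np.zeros(10)], axis=1)
        assert om.polyline_length(Polyline3D(pts)) == pytest.approx(9.0)

    def test_sampled_helix_matches_closed_form(self):
        r, pitch, turns, n = 1000.0, 1000.0, 2.0, 2000
        theta = np.linspace(0, 2 * np.pi * turns, n)
        pts = np.stack(
            [r * np.cos(theta), r * np.sin(theta), pitch * theta / (2 * np.pi)], axis=1
        )
        closed = turns * np.sqrt((2 * np.pi * r) ** 2 + pitch**2)
        assert om.polyline_length(Polyline3D(pts)) == pytest.approx(closed, rel=1e-3)


class TestMeasureDuctLength:
    def test_cylinder_length_within_2pct(self):
        vol, gt = om.make_cylinder_phantom(5000.0, 100.0, 10.0)
        res = om.measure_duct_length(vol, 1)
        assert res.length_um == pytest.approx(5000.0, rel=0.02)

    def test_small_spiral_within_3pct(self, small_spiral_phantom):
        vol, gt = small_spiral_phantom
        res = om.measure_duct_length(vol, 1)
        assert res.length_um == pytest.approx(gt.length_um, rel=0.03)

    def test_pipeline_is_deterministic(self, small_spiral_phantom):
        vol, _ = small_spiral_phantom
        r1 = om.measure_duct_length(vol, 1)
        r2 = om.measure_duct_length(vol, 1)
        assert r1.length_um == r2.length_um
        assert np.array_equal(r1.centerline.points, r2.centerline.points)

    def test_missing_label_raises(self, small_spiral_phantom):
        vol, _ = small_spiral_phantom
        with pytest.raises(ValueError, match="3"):
            om.measure_duct_length(vol, 3)
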