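import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polarfish import errors
from polarfish.cell_geometry import (
    apply_front_mask,
    distance_to_segment,
    measure_all_spots,
    point_in_polygon,
    snap_anchors,
)
from polarfish.spot_detection import Spot, detect_spots
from polarfish.stack_io import ChannelStack, RoiPolygon
from polarfish import synthetic_data as sd

SQUARE = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])


def _spot(x, y, z=0.0, typ=1):
    return Spot(x=x, y=y, z=z, intensity=1.0, type=typ)


class TestSnapAnchors:
    def test_square_vertices_give_single_edge_segments(self, square_polygon):
        part = snap_anchors(square_polygon, SQUARE)
        for role, seg in part.segments.items():
            assert seg.shape == (2, 2), role
        np.testing.assert_array_equal(part.segments["nuclear"],
                                      [[0, 0], [0, 1]])
        np.testing.assert_array_equal(part.segments["invasive"],
                                      [[1, 1], [1, 0]])

    def test_click_snaps_to_nearest_vertex(self, square_polygon):
        clicks = np.array([[0.1, -0.2], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
        part = snap_anchors(square_polygon, clicks)
        np.testing.assert_array_equal(part.segments["nuclear"][0], [0, 0])

    def test_counter_clockwise_clicks_rejected(self, square_polygon):
        with pytest.raises(errors.AnchorOrderError):
            snap_anchors(square_polygon, SQUARE[::-1])

    def test_duplicate_anchor_rejected(self, square_polygon):
        clicks = np.array([[0, 0], [0.1, 0.1], [1, 1], [1, 0]], dtype=float)
        with pytest.raises(errors.DuplicateAnchorError):
            snap_anchors(square_polygon, clicks)

    def test_either_polygon_orientation_accepted(self):
        ccw = RoiPolygon(SQUARE[::-1].copy())
        part = snap_anchors(ccw, SQUARE)
        np.testing.assert_array_equal(part.segments["nuclear"],
                                      [[0, 0], [0, 1]])

    def test_segments_tile_outline_once(self, square_partition):
        segs = square_partition.segments
        # consecutive segments share exactly the anchor vertex
        order = ["nuclear", "side1", "invasive", "side2"]
        for a, b in zip(order, order[1:] + order[:1]):
            np.testing.assert_array_equal(segs[a][-1], segs[b][0])
        total_vertices = sum(len(segs[r]) - 1 for r in order)
        assert total_vertices == len(square_partition.polygon)


class TestPointInPolygon:
    @pytest.mark.parametrize("p,expected", [
        ((0.5, 0.5), True),
        ((2.0, 2.0), False),
        ((0.0, 0.5), True),   # on the edge counts as inside
        ((0.0, 0.0), True),   # vertex
    ])
    def test_square_cases(self, square_polygon, p, expected):
        assert point_in_polygon(p, square_polygon) is expected


class TestDistanceToSegment:
    def test_perpendicular_foot(self):
        assert distance_to_segment((0, 0), np.array([[3, 0], [3, 4]])) \
            == pytest.approx(3.0)

    def test_nearest_endpoint_345(self):
        assert distance_to_segment((0, 0), np.array([[3, 4], [6, 4]])) \
            == pytest.approx(5.0)

    def test_degenerate_segment(self):
        with pytest.raises(errors.DegenerateSegmentError):
            distance_to_segment((0, 0), np.array([[1.0, 1.0]]))
        with pytest.raises(errors.DegenerateSegmentError):
            distance_to_segment((0, 0), np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            seg = np.cumsum(rng.normal(0, 3, (10, 2)), axis=0)
            p = rng.normal(0, 10, 2)
            exact = distance_to_segment(p, seg)
            n = 10_000
            approx = sd.brute_force_distance(p, seg, n_samples=n)
            length = np.sum(np.sqrt(np.sum(np.diff(seg, axis=0) ** 2, 1)))
            assert approx >= exact - 1e-12
            assert approx - exact <= length / n / 2 + 1e-9


class TestMeasureAllSpots:
    def test_square_center_equidistant(self, square_partition):
        recs = measure_all_spots([_spot(0.5, 0.5)], square_partition)
        assert len(recs) == 1
        r = recs[0]
        assert (r.d_nuclear, r.d_side1, r.d_invasive, r.d_side2) \
            == pytest.approx((0.5, 0.5, 0.5, 0.5))

    def test_outside_spot_dropped(self, square_partition):
        assert measure_all_spots([_spot(2.0, 2.0)], square_partition) == []

    def test_on_boundary_spot_kept_with_zero_distance(self, square_partition):
        recs = measure_all_spots([_spot(1.0, 0.5)], square_partition)
        assert len(recs) == 1
        assert recs[0].d_invasive == pytest.approx(0.0)

    def test_matches_brute_force_on_random_spots(self):
        scene = sd.make_scene(shape=(8, 64, 96), n_spots=(25, 25),
                              polarity_bias=(0.4, 0.0), seed=17, render=False)
        recs = measure_all_spots(scene.true_spots, scene.partition())
        oracle = sd.true_distance_table(scene, n_samples=50_000)
        assert len(recs) == len(oracle) == 50
        for a, b in zip(recs, oracle):
            for role in ("d_nuclear", "d_side1", "d_invasive", "d_side2"):
                assert getattr(a, role) == pytest.approx(getattr(b, role),
                                                         abs=1e-6)

    def test_nearest_point_property(self):
        scene = sd.make_scene(shape=(8, 64, 96), n_spots=(20, 0), seed=19,
                              render=False)
        part = scene.partition()
        inv = part.segments["invasive"]
        for r in measure_all_spots(scene.true_spots, part):
            vertex_dists = np.sqrt(np.sum(
                (inv - [r.spot.x, r.spot.y]) ** 2, axis=1))
            assert r.d_invasive <= vertex_dists.min() + 1e-9

    def test_tiling_min_distance_equals_outline_distance(self):
        from shapely.geometry import LineString, Point
        scene = sd.make_scene(shape=(8, 64, 96), n_spots=(30, 0), seed=23,
                              render=False)
        part = scene.partition()
        ring = LineString(np.vstack([part.polygon.vertices,
                                     part.polygon.vertices[:1]]))
        for r in measure_all_spots(scene.true_spots, part):
            d_min = min(r.d_nuclear, r.d_side1, r.d_invasive, r.d_side2)
            assert d_min == pytest.approx(
                ring.distance(Point(r.spot.x, r.spot.y)), abs=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(angle=st.floats(-np.pi, np.pi), tx=st.floats(-50, 50),
           ty=st.floats(-50, 50))
    def test_rigid_motion_invariance(self, angle, tx, ty):
        """Rotating/translating polygon and spots together preserves
        all four distances."""
        scene = sd.make_scene(shape=(8, 64, 96), n_spots=(5, 0), seed=29,
                              render=False)
        part = scene.partition()
        base = measure_all_spots(scene.true_spots, part)
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s], [s, c]])

        def move(xy):
            return xy @ R.T + [tx, ty]

        poly2 = RoiPolygon(move(scene.polygon.vertices))
        part2 = snap_anchors(poly2, move(scene.anchors))
        spots2 = [Spot(x=float(p[0]), y=float(p[1]), z=sp.z, intensity=1.0,
                       type=sp.type)
                  for sp, p in zip(scene.true_spots,
                                   move(np.array([[sp.x, sp.y]
                                                  for sp in scene.true_spots])))]
        moved = measure_all_spots(spots2, part2)
        assert len(base) == len(moved)
        for a, b in zip(base, moved):
            for role in ("d_nuclear", "d_side1", "d_invasive", "d_side2"):
                np.testing.assert_allclose(getattr(a, role),
                                           getattr(b, role), rtol=1e-9,
                                           atol=1e-9)


class TestApplyFrontMask:
    def _stack(self, rng, shape=(4, 4, 16, 16)):
        return ChannelStack(rng.integers(1, 100, shape).astype(float))

    def test_full_frame_polygon_is_identity(self):
        rng = np.random.default_rng(41)
        stack = self._stack(rng)
        poly = RoiPolygon(np.array([[-1, -1], [-1, 16], [16, 16], [16, -1]],
                                   dtype=float))
        out = apply_front_mask(stack, poly)
        np.testing.assert_array_equal(out.voxels, stack.voxels)

    def test_interior_square_conserves_inside_sums(self):
        rng = np.random.default_rng(43)
        stack = self._stack(rng)
        poly = RoiPolygon(np.array([[4, 4], [4, 9], [9, 9], [9, 4]],
                                   dtype=float))
        out = apply_front_mask(stack, poly)
        for c in range(4):
            inside = stack.voxels[c][:, 4:10, 4:10]
            assert out.voxels[c].sum() == pytest.approx(inside.sum())

    def test_polygon_fully_outside_rejected(self):
        rng = np.random.default_rng(47)
        stack = self._stack(rng)
        poly = RoiPolygon(np.array([[100, 100], [100, 110], [110, 110]],
                                   dtype=float))
        with pytest.raises(errors.PolygonOutsideImageError):
            apply_front_mask(stack, poly)

    def test_masking_removes_outside_spots_from_detection(self):
        """Spots planted outside the drawn outline disappear after masking."""
        rng = np.random.default_rng(53)
        shape = (10, 48, 64)
        vol = np.maximum(rng.normal(100, 4, shape), 0)
        inside_center = (5.0, 24.0, 20.0)
        outside_center = (5.0, 24.0, 50.0)
        sd._render_gaussian_spots(vol, [
            type("P", (), {"z": c[0], "y": c[1], "x": c[2]})()
            for c in (inside_center, outside_center)], amplitude=60.0)
        voxels = np.zeros((4,) + shape)
        voxels[2] = vol
        stack = ChannelStack(voxels)
        poly = RoiPolygon(np.array([[5, 5], [5, 42], [35, 42], [35, 5]],
                                   dtype=float))
        masked = apply_front_mask(stack, poly)
        from polarfish.cell_geometry import polygon_mask
        mask2d = polygon_mask(poly, shape[1:])
        mask3d = np.broadcast_to(mask2d, shape).copy()
        spots = detect_spots(masked, "rna1", mask3d)
        assert len(spots) == 1
        assert abs(spots[0].x - 20.0) <= 1.0
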