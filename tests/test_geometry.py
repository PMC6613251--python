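"""Projection, buffering, area, dissolve, clip, and containment contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely import affinity
from shapely.geometry import Polygon

from abode.geometry import (
    Frame,
    GeoPoint,
    ProjectionSpec,
    buffer_point,
    clip,
    contains,
    dissolve,
    polygon_area,
    polygon_from_rings,
    project,
    unproject,
)

from conftest import haversine_m, monte_carlo_area, ray_casting_contains

SPEC = ProjectionSpec(-80.0, 40.0)

UNIT_SQUARE = polygon_from_rings([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])


class TestProjection:
    def test_center_maps_to_origin(self):
        (p,) = project([GeoPoint(-80.0, 40.0)], SPEC)
        assert p.frame is Frame.PLANAR
        assert abs(p.x) < 1e-9 and abs(p.y) < 1e-9

    def test_small_latitude_offset_preserves_distance(self):
        # 0.01 deg of latitude near the centre is ~1111.9 m on the sphere
        pts = project([GeoPoint(-80.0, 40.0), GeoPoint(-80.0, 40.01)], SPEC)
        planar = math.hypot(pts[1].x - pts[0].x, pts[1].y - pts[0].y)
        oracle = haversine_m(-80.0, 40.0, -80.0, 40.01)
        assert planar == pytest.approx(oracle, rel=0.005)
        assert planar == pytest.approx(1111.9, rel=0.005)

    @pytest.mark.parametrize("dlon,dlat", [(0.5, 0.0), (0.0, 1.0), (1.5, -2.0)])
    def test_locally_length_true_within_300km(self, dlon, dlat):
        a, b = GeoPoint(-80.0, 40.0), GeoPoint(-80.0 + dlon, 40.0 + dlat)
        pa, pb = project([a, b], SPEC)
        planar = math.hypot(pb.x - pa.x, pb.y - pa.y)
        assert planar == pytest.approx(haversine_m(a.x, a.y, b.x, b.y), rel=0.005)

    def test_round_trip(self):
        pts = [GeoPoint(-80.3, 40.2), GeoPoint(-79.7, 39.9)]
        back = unproject(project(pts, SPEC), SPEC)
        for orig, rt in zip(pts, back):
            assert rt.x == pytest.approx(orig.x, abs=1e-9)
            assert rt.y == pytest.approx(orig.y, abs=1e-9)

    def test_invalid_latitude_rejected(self):
        with pytest.raises(ValueError):
            GeoPoint(0.0, 91.0)

    def test_non_finite_rejected_with_index(self):
        good = GeoPoint(0.0, 0.0)
        bad = object.__new__(GeoPoint)
        object.__setattr__(bad, "x", float("nan"))
        object.__setattr__(bad, "y", 0.0)
        object.__setattr__(bad, "frame", Frame.GEOGRAPHIC)
        with pytest.raises(ValueError, match="index 1"):
            project([good, bad], ProjectionSpec(0.0, 0.0))


class TestBuffer:
    def test_area_close_to_circle(self):
        poly = buffer_point((0.0, 0.0), 200.0, 64)
        assert polygon_area(poly) == pytest.approx(math.pi * 200.0**2, rel=0.005)

    def test_inscribed_area_ratio(self):
        # inscribed n-gon area deficit: ratio in [0.994, 1.0] at n=64
        ratio = polygon_area(buffer_point((5.0, -3.0), 100.0, 64)) / (math.pi * 100.0**2)
        assert 0.994 <= ratio <= 1.0

    def test_area_monotone_in_segments(self):
        areas = [polygon_area(buffer_point((0, 0), 50.0, n)) for n in (8, 16, 32, 64, 128)]
        assert all(a < b for a, b in zip(areas, areas[1:]))

    @pytest.mark.parametrize("radius", [0.0, -1.0])
    def test_nonpositive_radius_rejected(self, radius):
        with pytest.raises(ValueError):
            buffer_point((0, 0), radius)


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(UNIT_SQUARE) == pytest.approx(1.0)

    def test_square_with_centered_hole(self):
        poly = polygon_from_rings(
            [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)],
            [[(0.25, 0.25), (0.75, 0.25), (0.75, 0.75), (0.25, 0.75), (0.25, 0.25)]],
        )
        assert polygon_area(poly) == pytest.approx(0.75)

    def test_unclosed_ring_rejected(self):
        with pytest.raises(ValueError, match="not closed"):
            polygon_from_rings([(0, 0), (1, 0), (1, 1), (0, 1)])

    @given(
        dx=st.floats(-1e5, 1e5, allow_nan=False),
        dy=st.floats(-1e5, 1e5, allow_nan=False),
    )
    @settings(max_examples=30, derandomize=True)
    def test_translation_invariance(self, dx, dy):
        moved = affinity.translate(UNIT_SQUARE, dx, dy)
        assert polygon_area(moved) == pytest.approx(polygon_area(UNIT_SQUARE), rel=1e-9)


class TestDissolve:
    def test_disjoint_squares_keep_total_area(self):
        b = affinity.translate(UNIT_SQUARE, 5, 0)
        parts = dissolve([UNIT_SQUARE, b])
        assert len(parts) == 2
        assert sum(polygon_area(p) for p in parts) == pytest.approx(2.0)

    def test_idempotent_on_identical_inputs(self):
        parts = dissolve([UNIT_SQUARE, Polygon(UNIT_SQUARE.exterior.coords)])
        assert len(parts) == 1
        assert polygon_area(parts[0]) == pytest.approx(1.0)

    def test_union_area_never_exceeds_sum(self):
        rng = np.random.default_rng(7)
        polys = [
            buffer_point((rng.uniform(0, 500), rng.uniform(0, 500)), rng.uniform(50, 150))
            for _ in range(10)
        ]
        total = sum(polygon_area(p) for p in polys)
        merged = sum(polygon_area(p) for p in dissolve(polys))
        assert merged <= total + 1e-9

    def test_overlapping_circles_match_monte_carlo(self):
        a = buffer_point((0.0, 0.0), 200.0, 256)
        b = buffer_point((200.0, 0.0), 200.0, 256)
        merged = dissolve([a, b])
        mc = monte_carlo_area(merged[0] if len(merged) == 1 else merged[0], seed=1)
        assert sum(polygon_area(p) for p in merged) == pytest.approx(mc, rel=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dissolve([])


class TestClip:
    def test_self_clip_preserves_area(self):
        assert polygon_area(clip(UNIT_SQUARE, UNIT_SQUARE)) == pytest.approx(1.0)

    def test_disjoint_clip_is_empty(self):
        far = affinity.translate(UNIT_SQUARE, 10, 10)
        assert polygon_area(clip(UNIT_SQUARE, far)) == 0.0

    def test_half_overlap(self):
        shifted = affinity.translate(UNIT_SQUARE, 0.5, 0.0)
        assert polygon_area(clip(UNIT_SQUARE, shifted)) == pytest.approx(0.5)

    def test_area_bounded_and_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = buffer_point((rng.uniform(0, 100), rng.uniform(0, 100)), rng.uniform(20, 80))
            b = buffer_point((rng.uniform(0, 100), rng.uniform(0, 100)), rng.uniform(20, 80))
            ab = polygon_area(clip(a, b))
            assert ab <= min(polygon_area(a), polygon_area(b)) + 1e-9
            assert ab == pytest.approx(polygon_area(clip(b, a)), rel=1e-9, abs=1e-12)


class TestContains:
    def test_centroid_inside(self):
        assert contains(UNIT_SQUARE, (0.5, 0.5))

    def test_vertex_counts_as_inside(self):
        # closed-region convention: boundary points are inside
        assert contains(UNIT_SQUARE, (0.0, 0.0))
        assert contains(UNIT_SQUARE, (1.0, 0.5))

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError):
            contains(UNIT_SQUARE, GeoPoint(0.5, 0.5, Frame.GEOGRAPHIC))

    def test_agreement_with_ray_casting_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            # random convex polygon: hull of a disc point sample
            pts = rng.uniform(0, 100, (30, 2))
            from shapely.geometry import MultiPoint

            hull = MultiPoint([tuple(p) for p in pts]).convex_hull
            ring = list(hull.exterior.coords)
            xs = rng.uniform(-10, 110, 50)
            ys = rng.uniform(-10, 110, 50)
            for x, y in zip(xs, ys):
                assert contains(hull, (x, y)) == ray_casting_contains(ring, x, y)
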