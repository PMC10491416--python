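"""Oriented rectangles, corner ordering, sectors."""

import numpy as np
import pytest

from conftest import quad_corners, quad_mask, quad_rect
from vinebranch.geometry import (
    SectorSpec,
    angle_between,
    axis_points,
    in_sector,
    min_area_rect,
    order_corners,
    rect_from_corners,
    rect_iou,
    sector_for,
)
from vinebranch.segments import model_from_rect


class TestOrderCorners:
    def test_vertical_rect(self):
        r = rect_from_corners([(9, 29), (0, 0), (0, 29), (9, 0)])
        assert np.allclose(r.corners, [(0, 0), (9, 0), (9, 29), (0, 29)])
        assert r.short_len == 9.0 and r.long_len == 29.0

    def test_horizontal_rect_left_edge_is_top(self):
        # tie on y between the two short-edge midpoints is broken by x
        r = rect_from_corners([(30, 10), (0, 0), (30, 0), (0, 10)])
        assert np.allclose(r.corners, [(0, 10), (0, 0), (30, 0), (30, 10)])

    def test_clockwise_on_screen(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            c = quad_corners(*rng.uniform(30, 70, 2), rng.uniform(20, 60),
                             rng.uniform(5, 15), rng.uniform(-1.5, 1.5))
            r = order_corners(rng.permutation(c))
            # positive shoelace area = clockwise with y pointing down
            x, y = r.corners[:, 0], r.corners[:, 1]
            shoelace = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
            assert shoelace > 0
            # w1-w2 is a short edge and its midpoint is the top one
            assert np.linalg.norm(r.w2 - r.w1) <= np.linalg.norm(r.w3 - r.w2) + 1e-9
            tm, em = 0.5 * (r.w1 + r.w2), 0.5 * (r.w3 + r.w4)
            assert (tm[1], tm[0]) <= (em[1], em[0])

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            c = quad_corners(*rng.uniform(30, 70, 2), rng.uniform(20, 60),
                             rng.uniform(5, 15), rng.uniform(-1.5, 1.5))
            once = order_corners(rng.permutation(c))
            twice = order_corners(once.corners)
            assert np.allclose(once.corners, twice.corners)

    def test_degenerate_point(self):
        r = order_corners(np.tile([3.0, 4.0], (4, 1)))
        assert r.short_len == 0.0 and r.area == 0.0


class TestMinAreaRect:
    def test_axis_aligned_block(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 10:20] = True  # 30 rows x 10 cols of pixel centers
        r = min_area_rect(mask)
        assert r.short_len == pytest.approx(9.0)
        assert r.long_len == pytest.approx(29.0)
        assert np.allclose(r.center, [14.5, 19.5])

    def test_rotated_recovery(self):
        phi = np.radians(37.0)
        mask = quad_mask((200, 200), 100, 100, 90, 24, phi)
        r = min_area_rect(mask)
        ang = np.arctan2(r.long_axis_dir[0], r.long_axis_dir[1])
        assert abs(abs(ang) - phi) < np.radians(2.0)
        assert r.long_len == pytest.approx(90, abs=2.0)
        assert r.short_len == pytest.approx(24, abs=2.0)

    def test_single_pixel_and_line(self):
        m = np.zeros((10, 10), dtype=bool)
        m[4, 7] = True
        r = min_area_rect(m)
        assert np.allclose(r.corners, [[7, 4]] * 4)
        m[5:9, 7] = True
        r = min_area_rect(m)
        assert r.short_len == 0.0 and r.long_len == pytest.approx(4.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            min_area_rect(np.zeros((5, 5), dtype=bool))

    def test_contains_all_pixels(self, rng):
        for _ in range(20):
            mask = quad_mask((120, 120), *rng.uniform(40, 80, 2),
                             rng.uniform(20, 50), rng.uniform(6, 15),
                             rng.uniform(-1.5, 1.5))
            r = min_area_rect(mask)
            ys, xs = np.nonzero(mask)
            poly = r.polygon().buffer(1e-6)
            import shapely
            assert shapely.intersects_xy(poly, xs, ys).all()


def test_axis_points_vertical():
    r = rect_from_corners([(0, 0), (9, 0), (9, 29), (0, 29)])
    v1, v2, v3 = axis_points(r)
    assert np.allclose(v1, [4.5, 0])
    assert np.allclose(v2, [4.5, 14.5])
    assert np.allclose(v3, [4.5, 29])


class TestRectIoU:
    def test_analytic_overlap(self):
        a = rect_from_corners([(0, 0), (4, 0), (4, 2), (0, 2)])
        b = rect_from_corners([(2, 0), (6, 0), (6, 2), (2, 2)])
        assert rect_iou(a, b) == pytest.approx(1 / 3)

    def test_identity_and_disjoint(self):
        a = quad_rect(50, 50, 30, 10, 0.4)
        assert rect_iou(a, a) == pytest.approx(1.0)
        b = quad_rect(200, 200, 30, 10, 0.4)
        assert rect_iou(a, b) == 0.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a = quad_rect(*rng.uniform(20, 80, 2), rng.uniform(10, 40),
                          rng.uniform(4, 12), rng.uniform(-1.5, 1.5))
            b = quad_rect(*rng.uniform(20, 80, 2), rng.uniform(10, 40),
                          rng.uniform(4, 12), rng.uniform(-1.5, 1.5))
            assert rect_iou(a, b) == pytest.approx(rect_iou(b, a))
            assert 0.0 <= rect_iou(a, b) <= 1.0


class TestAngleBetween:
    def test_basics(self):
        assert angle_between([1, 0], [0, 1]) == pytest.approx(90.0)
        assert angle_between([1, 0], [2, 0]) == pytest.approx(0.0)
        assert angle_between([1, 0], [-3, 0]) == pytest.approx(180.0)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            angle_between([0, 0], [1, 0])


class TestSector:
    def test_full_angle_closed_form(self):
        r = rect_from_corners([(0, 0), (10, 0), (10, 30), (0, 30)])
        m = model_from_rect(0, r)
        s = sector_for(m, "top")
        assert s.full_angle == pytest.approx(2 * np.degrees(np.arctan(10 / 30)), abs=1e-9)

    def test_apex_ray_depth(self):
        r = rect_from_corners([(0, 0), (10, 0), (10, 30), (0, 30)])
        m = model_from_rect(0, r)
        top = sector_for(m, "top", 3.0)
        assert np.allclose(top.apex, [5, 15])         # v2
        assert np.allclose(top.center_ray, [0, -1])   # toward v1
        assert top.depth == pytest.approx(3.0 * 30)   # 3 x |v1 v3|
        end = sector_for(m, "end", 1.6)
        assert np.allclose(end.center_ray, [0, 1])
        assert end.depth == pytest.approx(1.6 * 30)

    def test_validation(self):
        with pytest.raises(ValueError):
            SectorSpec(apex=[0, 0], center_ray=[0, 0], full_angle=30, depth=10)
        with pytest.raises(ValueError):
            SectorSpec(apex=[0, 0], center_ray=[0, 1], full_angle=200, depth=10)
        with pytest.raises(ValueError):
            SectorSpec(apex=[0, 0], center_ray=[0, 1], full_angle=30, depth=0)

    def test_membership_examples(self):
        s = SectorSpec(apex=[0, 0], center_ray=[0, -1], full_angle=40, depth=50)
        assert in_sector(s, [0, 0])            # apex
        assert in_sector(s, [0, -40])          # on axis, in reach
        assert not in_sector(s, [0, -60])      # beyond depth
        assert in_sector(s, [10 * np.tan(np.radians(19)), -10])
        assert not in_sector(s, [10 * np.tan(np.radians(21)), -10])

    def test_membership_vs_grid_oracle(self, rng):
        # smaller sibling of acceptance criterion 1
        for _ in range(10):
            s = SectorSpec(
                apex=rng.uniform(-5, 5, 2),
                center_ray=rng.normal(size=2),
                full_angle=rng.uniform(10, 120),
                depth=rng.uniform(10, 60),
            )
            xs = np.linspace(-80, 80, 41)
            for x in xs:
                for y in xs:
                    p = np.array([x, y])
                    d = p - s.apex
                    dist = np.linalg.norm(d)
                    if dist == 0:
                        expect = True
                    else:
                        cosang = np.dot(d, s.center_ray) / dist
                        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                        expect = dist <= s.depth and ang <= s.full_angle / 2
                        # skip boundary band where float ties are legitimate
                        if (abs(dist - s.depth) < 1e-6
                                or abs(ang - s.full_angle / 2) < 1e-6):
                            continue
                    assert in_sector(s, p) == expect
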