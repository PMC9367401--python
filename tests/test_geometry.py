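"""Contour geometry: diamonds, octagons, resampling, rasterization, IoU."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snakeshot import geometry as G

from conftest import random_simple_polygon


def ray_cast_mask(vertices, height, width):
    """Independent per-pixel even-odd oracle (scalar ray casting)."""
    v = np.asarray(vertices, float)
    n = len(v)
    mask = np.zeros((height, width), dtype=bool)
    for i in range(height):
        for j in range(width):
            px, py = j + 0.5, i + 0.5
            inside = False
            for k in range(n):
                x1, y1 = v[k]
                x2, y2 = v[(k + 1) % n]
                if (y1 <= py) != (y2 <= py):
                    xi = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < xi:
                        inside = not inside
            mask[i, j] = inside
    return mask


class TestBoxToDiamond:
    def test_midpoints_clockwise(self):
        d = G.box_to_diamond(G.BoundingBox(0, 0, 4, 2))
        np.testing.assert_allclose(d, [[2, 0], [4, 1], [2, 2], [0, 1]])

    @given(st.floats(-50, 50), st.floats(-50, 50),
           st.floats(0.5, 80), st.floats(0.5, 80))
    @settings(deadline=None)
    def test_area_is_half_box_area(self, x0, y0, w, h):
        box = G.BoundingBox(x0, y0, x0 + w, y0 + h)
        d = G.box_to_diamond(box)
        assert abs(G.polygon_area(d)) == pytest.approx(box.area / 2, rel=1e-9)

    def test_degenerate_box_rejected(self):
        with pytest.raises(G.InvalidGeometryError):
            G.BoundingBox(10, 10, 10, 20)


class TestResampleContour:
    def test_square_to_eight_hits_corners_and_midpoints(self):
        sq = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], float)
        out = G.resample_contour(sq, 8)
        expected = [[0, 0], [2, 0], [4, 0], [4, 2], [4, 4], [2, 4], [0, 4], [0, 2]]
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_identity_on_uniform_contour(self):
        sq = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], float)
        np.testing.assert_allclose(G.resample_contour(sq, 4), sq, atol=1e-9)

    def test_against_dense_walk_oracle(self, rng):
        """Irregular pentagon: uniform arc spacing, agreeing with a dense-walk oracle."""
        pent = np.array([[0, 0], [7, 1], [9, 5], [4, 9], [-1, 4]], float)
        n = 128
        out = G.resample_contour(pent, n)
        # project output vertices onto the input's cumulative arc length: the
        # positions must be exactly uniform
        closed = np.vstack([pent, pent[:1]])
        seg = np.diff(closed, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        arc_pos = []
        for p in out:
            best = None
            for i in range(len(seg)):
                t = np.dot(p - closed[i], seg[i]) / seglen[i] ** 2
                if -1e-9 <= t <= 1 + 1e-9:
                    q = closed[i] + t * seg[i]
                    if np.linalg.norm(q - p) < 1e-6:
                        best = cum[i] + t * seglen[i]
                        break
            assert best is not None, "resampled vertex not on the boundary"
            arc_pos.append(best)
        gaps = np.diff(arc_pos)
        assert np.allclose(gaps, cum[-1] / n, rtol=1e-6)
        # dense-walk oracle: 128000 equal steps along the boundary, every 1000th
        steps = 1000 * n
        dense = G.resample_contour(pent, steps)
        np.testing.assert_allclose(out, dense[::1000], atol=1e-9)

    def test_perimeter_preserved_when_corners_sampled(self):
        """n a multiple of the vertex count of a regular polygon keeps corners."""
        theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        octg = np.stack([10 * np.cos(theta), 10 * np.sin(theta)], axis=1)
        per = lambda v: np.linalg.norm(np.diff(np.vstack([v, v[:1]]), axis=0), axis=1).sum()
        out = G.resample_contour(octg, 64)
        assert per(out) == pytest.approx(per(octg), rel=1e-6)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            G.resample_contour(np.array([[0, 0], [1, 0], [0, 1]], float), 2)


class TestBuildOctagon:
    def test_midpoint_extremes(self):
        box = G.BoundingBox(0, 0, 8, 4)
        ex = G.ExtremePointSet(top=(4, 0), leftmost=(0, 2), bottom=(4, 4), rightmost=(8, 2))
        octa = G.build_octagon(ex, box)
        expected = [[2, 0], [6, 0], [8, 1], [8, 3], [6, 4], [2, 4], [0, 3], [0, 1]]
        np.testing.assert_allclose(octa, expected)

    def test_corner_clipping(self):
        box = G.BoundingBox(0, 0, 8, 4)
        ex = G.ExtremePointSet(top=(7.5, 0), leftmost=(0, 2), bottom=(4, 4), rightmost=(8, 2))
        octa = G.build_octagon(ex, box)
        np.testing.assert_allclose(octa[0], [5.5, 0])   # left endpoint: 7.5 - 2
        np.testing.assert_allclose(octa[1], [8.0, 0])   # right endpoint clipped to corner

    def test_octagon_inside_box(self, rng):
        for _ in range(50):
            x0, y0 = rng.uniform(-10, 10, 2)
            w, h = rng.uniform(4, 40, 2)
            box = G.BoundingBox(x0, y0, x0 + w, y0 + h)
            ex = G.ExtremePointSet(
                top=(rng.uniform(x0, x0 + w), y0),
                leftmost=(x0, rng.uniform(y0, y0 + h)),
                bottom=(rng.uniform(x0, x0 + w), y0 + h),
                rightmost=(x0 + w, rng.uniform(y0, y0 + h)),
            )
            octa = G.build_octagon(ex, box)
            assert (octa[:, 0] >= x0 - 1e-9).all() and (octa[:, 0] <= x0 + w + 1e-9).all()
            assert (octa[:, 1] >= y0 - 1e-9).all() and (octa[:, 1] <= y0 + h + 1e-9).all()
            assert G.is_clockwise(octa)

    def test_180_degree_rotation_symmetry(self):
        """Midpoint-extreme octagons map onto themselves under box rotation."""
        box = G.BoundingBox(2, 3, 12, 9)
        cx, cy = 7.0, 6.0
        ex = G.ExtremePointSet(top=(cx, 3), leftmost=(2, cy), bottom=(cx, 9), rightmost=(12, cy))
        octa = G.build_octagon(ex, box)
        rotated = np.stack([2 * cx - octa[:, 0], 2 * cy - octa[:, 1]], axis=1)
        src = {tuple(np.round(p, 9)) for p in octa}
        dst = {tuple(np.round(p, 9)) for p in rotated}
        assert src == dst

    def test_far_outside_extreme_rejected(self):
        box = G.BoundingBox(0, 0, 8, 4)
        ex = G.ExtremePointSet(top=(4, -50), leftmost=(0, 2), bottom=(4, 4), rightmost=(8, 2))
        with pytest.raises(G.InvalidGeometryError):
            G.build_octagon(ex, box)


class TestContourToMask:
    def test_axis_aligned_square_exact_cover(self):
        sq = np.array([[2, 2], [7, 2], [7, 6], [2, 6]], float)
        mask = G.contour_to_mask(sq, 10, 10)
        assert mask.sum() == 5 * 4
        assert mask[2:6, 2:7].all()

    def test_outside_raster_is_empty(self):
        tri = np.array([[100, 100], [110, 100], [105, 110]], float)
        assert G.contour_to_mask(tri, 16, 16).sum() == 0

    def test_matches_ray_casting_oracle(self, rng):
        for _ in range(20):
            poly = random_simple_polygon(rng, int(rng.integers(5, 15)))
            mask = G.contour_to_mask(poly, 64, 64)
            np.testing.assert_array_equal(mask, ray_cast_mask(poly, 64, 64))

    def test_self_intersecting_even_odd(self):
        bowtie = np.array([[1, 1], [9, 9], [9, 1], [1, 9]], float)
        mask = G.contour_to_mask(bowtie, 10, 10)
        np.testing.assert_array_equal(mask, ray_cast_mask(bowtie, 10, 10))
        assert 0 < mask.sum() < 64  # two lobes, center line excluded

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValueError):
            G.contour_to_mask(np.array([[0, 0], [1, 0], [0, 1]], float), 0, 5)


class TestIoU:
    def test_mask_identities(self):
        a = G.contour_to_mask(np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float), 4, 4)
        b = G.contour_to_mask(np.array([[1, 0], [3, 0], [3, 2], [1, 2]], float), 4, 4)
        assert G.mask_iou(a, a) == 1.0
        assert G.mask_iou(a, ~a & False) == 0.0
        assert G.mask_iou(a, b) == pytest.approx(2 / 6)
        empty = np.zeros((4, 4), bool)
        assert G.mask_iou(empty, empty) == 0.0

    def test_mask_shape_mismatch(self):
        with pytest.raises(ValueError):
            G.mask_iou(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    def test_box_examples(self):
        assert G.box_iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
        assert G.box_iou((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(2 / 6)
        assert G.box_iou((0, 0, 2, 2), (2, 0, 4, 2)) == 0.0  # touching edges

    @given(st.tuples(*[st.floats(-20, 20) for _ in range(4)]),
           st.tuples(*[st.floats(-20, 20) for _ in range(4)]))
    @settings(deadline=None, max_examples=60)
    def test_box_iou_symmetric_bounded(self, a, b):
        ax0, ay0, aw, ah = a
        bx0, by0, bw, bh = b
        box_a = G.BoundingBox(ax0, ay0, ax0 + abs(aw) + 0.5, ay0 + abs(ah) + 0.5)
        box_b = G.BoundingBox(bx0, by0, bx0 + abs(bw) + 0.5, by0 + abs(bh) + 0.5)
        v = G.box_iou(box_a, box_b)
        assert v == G.box_iou(box_b, box_a)
        assert 0.0 <= v <= 1.0

    def test_mask_iou_agrees_with_pixel_count_oracle(self, rng):
        for _ in range(10):
            a = G.contour_to_mask(random_simple_polygon(rng, 8), 32, 32)
            b = G.contour_to_mask(random_simple_polygon(rng, 8), 32, 32)
            inter = int(np.sum(a & b))
            union = int(np.sum(a | b))
            expected = inter / union if union else 0.0
            assert G.mask_iou(a, b) == pytest.approx(expected, abs=1e-12)


class TestPipelineGeometry:
    def test_diamond_resampled_to_40_preserves_perimeter(self):
        box = G.BoundingBox(3, 5, 43, 29)
        d = G.box_to_diamond(box)
        d40 = G.resample_contour(d, 40)
        assert d40.shape == (40, 2)
        per = lambda v: np.linalg.norm(np.diff(np.vstack([v, v[:1]]), axis=0), axis=1).sum()
        assert per(d40) == pytest.approx(per(d), rel=1e-6)

    def test_coco_round_trip(self):
        poly = np.array([[1.5, 2.5], [4, 2], [3, 6]], float)
        np.testing.assert_allclose(G.coco_to_contour(G.contour_to_coco(poly)), poly)
        box = G.BoundingBox(1, 2, 5, 9)
        assert G.coco_to_box(G.box_to_coco(box)) == box
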