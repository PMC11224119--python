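"""Unit and property tests for the picking-point localization geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saffpick.errors import (
    ClassMissingError,
    EmptyMaskError,
    NoBranchLineError,
    RoiDegenerateError,
    RoiTooSmallError,
)
from saffpick.geometry import (
    ComponentMask,
    HoughParams,
    LineSegment,
    LocateConfig,
    Point2D,
    barycenter,
    binarize_edges,
    branch_roi,
    gradient_magnitude,
    hough_line_segments,
    largest_component,
    locate,
    picking_point,
    point_to_line_distance,
    project_point,
    select_picking_line,
)
from saffpick.synth import SceneSpec, generate_scene


def flood_fill_components(binary):
    """Brute-force 8-connected component enumeration (oracle)."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] and not seen[r0, c0]:
                stack, pixels = [(r0, c0)], set()
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    pixels.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] \
                                    and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(pixels)
    return comps


class TestLargestComponent:
    def test_picks_bigger_of_two_blobs(self):
        lm = np.zeros((10, 10), dtype=int)
        lm[1:2, 1:6] = 1  # 5 px
        lm[5:6, 1:4] = 1  # 3 px
        mask = largest_component(lm, 1)
        assert mask.pixel_count == 5
        assert mask.mask[1, 3] and not mask.mask[5, 2]

    def test_single_pixel(self):
        lm = np.zeros((4, 4), dtype=int)
        lm[2, 3] = 2
        mask = largest_component(lm, 2)
        assert mask.pixel_count == 1 and mask.mask[2, 3]

    def test_matches_flood_fill_oracle(self, rng):
        lm = (rng.random((30, 30)) < 0.3).astype(int)  # class-1 blobs
        comps = flood_fill_components(lm == 1)
        expected = max(comps, key=len)
        mask = largest_component(lm, 1)
        got = set(zip(*np.nonzero(mask.mask)))
        assert got == expected

    def test_missing_class_raises(self):
        with pytest.raises(ClassMissingError):
            largest_component(np.zeros((5, 5), dtype=int), 3)


class TestBarycenter:
    def test_single_pixel(self):
        m = np.zeros((10, 10), dtype=bool)
        m[7, 3] = True
        bc = barycenter(ComponentMask(m))
        assert (bc.x, bc.y) == (3.0, 7.0)

    def test_2x2_block(self):
        m = np.zeros((5, 5), dtype=bool)
        m[0:2, 0:2] = True
        bc = barycenter(ComponentMask(m))
        assert (bc.x, bc.y) == (0.5, 0.5)

    def test_random_blob_matches_pixel_mean(self, rng):
        m = rng.random((20, 20)) < 0.4
        m[0, 0] = True  # nonempty
        rows, cols = np.nonzero(m)
        bc = barycenter(m)
        assert bc.x == pytest.approx(cols.mean()) and bc.y == pytest.approx(rows.mean())

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            barycenter(np.zeros((3, 3), dtype=bool))


def _ball_mask(shape, rows, cols):
    m = np.zeros(shape, dtype=bool)
    m[rows[0] : rows[1] + 1, cols[0] : cols[1] + 1] = True
    return ComponentMask(m)


class TestBranchRoi:
    def test_extremal_pixel_scan(self):
        ball = _ball_mask((100, 100), (10, 20), (30, 50))
        roi = branch_roi(Point2D(40, 5), Point2D(40, 15), ball, (100, 100), margin=0.0)
        assert (roi.y_min, roi.y_max) == (20, 100)
        assert (roi.x_min, roi.x_max) == (30, 51)

    def test_margin_widens_and_clips(self):
        ball = _ball_mask((100, 100), (10, 20), (30, 50))
        roi = branch_roi(Point2D(40, 5), Point2D(40, 15), ball, (100, 100), margin=0.1)
        assert (roi.x_min, roi.x_max) == (28, 53)  # 10% of 20-px span = 2 px
        near_edge = _ball_mask((100, 100), (10, 20), (0, 20))
        roi2 = branch_roi(Point2D(10, 5), Point2D(10, 15), near_edge, (100, 100), margin=0.1)
        assert roi2.x_min == 0  # clipped at the image border

    def test_ball_touching_bottom_degenerate(self):
        ball = _ball_mask((100, 100), (90, 99), (30, 50))
        with pytest.raises(RoiDegenerateError):
            branch_roi(Point2D(40, 80), Point2D(40, 95), ball, (100, 100))


def eq3_gradient_oracle(f):
    """Direct per-pixel evaluation of the central-difference gradient."""
    h, w = f.shape
    out = np.zeros_like(f, dtype=float)
    for y in range(h):
        for x in range(w):
            xp, xm = min(x + 1, w - 1), max(x - 1, 0)
            yp, ym = min(y + 1, h - 1), max(y - 1, 0)
            fw = 0.5 * (f[y, xp] - f[y, xm])
            fh = 0.5 * (f[yp, x] - f[ym, x])
            out[y, x] = np.sqrt(fw**2 + fh**2)
    return out


class TestGradientAndEdges:
    def test_constant_image_zero_gradient(self):
        assert np.all(gradient_magnitude(np.full((5, 7), 3.0)) == 0.0)

    def test_linear_ramp_unit_gradient(self):
        x = np.tile(np.arange(8.0), (6, 1))
        g = gradient_magnitude(x)
        assert np.allclose(g[:, 1:-1], 1.0)

    def test_matches_per_pixel_oracle(self, rng):
        f = rng.random((8, 8))
        assert np.allclose(gradient_magnitude(f), eq3_gradient_oracle(f), atol=1e-12)

    def test_too_small_roi(self):
        with pytest.raises(RoiTooSmallError):
            gradient_magnitude(np.ones((2, 5)))

    def test_fixed_threshold(self):
        grad = np.array([[0.0, 1.0, 2.0, 3.0]])
        assert binarize_edges(grad, 2.0).tolist() == [[False, False, True, True]]

    def test_all_zero_otsu_is_all_false(self):
        assert not binarize_edges(np.zeros((4, 4)), "otsu").any()

    def test_otsu_matches_between_class_variance_search(self, rng):
        # bimodal gradient: low plateau + high edge band
        g = np.concatenate([rng.normal(1.0, 0.2, 600), rng.normal(8.0, 0.5, 120)])
        g = np.abs(g).reshape(24, 30)
        hist, edges = np.histogram(g, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2.0
        best_t, best_v = None, -1.0
        for i in range(1, 256):
            w0, w1 = hist[:i].sum(), hist[i:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (hist[:i] * centers[:i]).sum() / w0
            m1 = (hist[i:] * centers[i:]).sum() / w1
            v = w0 * w1 * (m0 - m1) ** 2
            if v > best_v:
                best_v, best_t = v, centers[i - 1]
        assert np.array_equal(binarize_edges(g, "otsu"), g > best_t)


class TestHough:
    def test_recovers_vertical_line(self):
        edge = np.zeros((60, 40), dtype=bool)
        edge[10:50, 20] = True
        segs = hough_line_segments(edge, HoughParams(threshold=10, min_length=20))
        assert segs
        ys = sorted([segs[0].q1.y, segs[0].q2.y])
        assert abs(segs[0].q1.x - 20) <= 1 and abs(segs[0].q2.x - 20) <= 1
        assert abs(ys[0] - 10) <= 1 and abs(ys[1] - 49) <= 1

    def test_blank_map_empty(self):
        assert hough_line_segments(np.zeros((20, 20), dtype=bool)) == []

    def test_two_crossing_lines_recovered_within_2_degrees(self):
        edge = np.zeros((80, 80), dtype=bool)
        for t in range(80):
            edge[t, t] = True  # 45 degrees
            edge[t, 70 - t // 2] = True  # atan(1/2) from vertical, crossing
        segs = hough_line_segments(edge, HoughParams(threshold=20, min_length=30))
        angles = set()
        for s in segs:
            ang = np.degrees(np.arctan2(s.q2.y - s.q1.y, s.q2.x - s.q1.x)) % 180.0
            angles.add(round(ang))
        def close(target):
            return any(min(abs(a - target), 180 - abs(a - target)) <= 2 for a in angles)
        assert close(45.0) and close(np.degrees(np.arctan2(2.0, -1.0)) % 180)


def eq5_slope_distance(p, seg):
    """Literal slope-intercept form of the point-line distance (oracle)."""
    x1, y1 = seg.q1.x, seg.q1.y
    x2, y2 = seg.q2.x, seg.q2.y
    m = (y1 - y2) / (x1 - x2)
    c = (x1 * y2 - y1 * x2) / (x1 - x2)
    return abs(m * p.x + c - p.y) / np.sqrt(1.0 + m * m)


class TestPointLineDistance:
    def test_horizontal_line(self):
        seg = LineSegment(Point2D(0, 0), Point2D(10, 0))
        assert point_to_line_distance(Point2D(5, 3), seg) == pytest.approx(3.0)

    def test_point_on_segment(self):
        seg = LineSegment(Point2D(1, 1), Point2D(9, 5))
        assert point_to_line_distance(Point2D(5, 3), seg) == pytest.approx(0.0)

    def test_agrees_with_slope_form_on_100_random_cases(self, rng):
        for _ in range(100):
            x1, y1, x2, y2, px, py = rng.uniform(-50, 50, 6)
            if abs(x1 - x2) < 1e-3:
                x2 = x1 + 1.0
            seg = LineSegment(Point2D(x1, y1), Point2D(x2, y2))
            p = Point2D(px, py)
            assert point_to_line_distance(p, seg) == pytest.approx(
                eq5_slope_distance(p, seg), abs=1e-9
            )

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=6),
           st.floats(0.1, 10.0))
    def test_symmetry_and_scaling_invariance(self, vals, scale):
        x1, y1, x2, y2, px, py = vals
        if abs(x1 - x2) + abs(y1 - y2) < 1e-6:
            x2, y2 = x1 + 1.0, y1 + 1.0
        seg = LineSegment(Point2D(x1, y1), Point2D(x2, y2))
        swapped = LineSegment(seg.q2, seg.q1)
        p = Point2D(px, py)
        d = point_to_line_distance(p, seg)
        assert point_to_line_distance(p, swapped) == pytest.approx(d, abs=1e-9)
        mx, my = (x1 + x2) / 2, (y1 + y2) / 2
        scaled = LineSegment(
            Point2D(mx + scale * (x1 - mx), my + scale * (y1 - my)),
            Point2D(mx + scale * (x2 - mx), my + scale * (y2 - my)),
        )
        assert point_to_line_distance(p, scaled) == pytest.approx(d, abs=1e-9)


class TestLineSelectionAndProjection:
    def test_single_candidate(self):
        seg = LineSegment(Point2D(0, 0), Point2D(0, 10))
        assert select_picking_line(Point2D(1, 1), Point2D(1, 2), [seg]) is seg

    def test_through_line_beats_distant_line(self):
        through = LineSegment(Point2D(5, 0), Point2D(5, 10))
        distant = LineSegment(Point2D(50, 0), Point2D(50, 10))
        chosen = select_picking_line(Point2D(5, 2), Point2D(5, 8), [distant, through])
        assert chosen is through

    def test_matches_bruteforce_over_10_random_candidates(self, rng):
        p1 = Point2D(*rng.uniform(0, 100, 2))
        p2 = Point2D(*rng.uniform(0, 100, 2))
        lines = [
            LineSegment(Point2D(*rng.uniform(0, 100, 2)), Point2D(*rng.uniform(0, 100, 2)))
            for _ in range(10)
        ]
        sums = [
            point_to_line_distance(p1, s) + point_to_line_distance(p2, s) for s in lines
        ]
        assert select_picking_line(p1, p2, lines) is lines[int(np.argmin(sums))]

    def test_empty_list_raises(self):
        with pytest.raises(NoBranchLineError):
            select_picking_line(Point2D(0, 0), Point2D(1, 1), [])

    def test_projection_onto_horizontal_line(self):
        seg = LineSegment(Point2D(0, 0), Point2D(10, 0))
        q = project_point(Point2D(5, 3), seg)
        assert (q.x, q.y) == pytest.approx((5.0, 0.0))

    def test_projection_of_point_on_line_is_identity(self):
        seg = LineSegment(Point2D(0, 0), Point2D(4, 2))
        q = project_point(Point2D(2, 1), seg)
        assert (q.x, q.y) == pytest.approx((2.0, 1.0))

    def test_projection_minimizes_distance_dense_sampling(self, rng):
        for _ in range(10):
            seg = LineSegment(Point2D(*rng.uniform(-20, 20, 2)),
                              Point2D(*rng.uniform(-20, 20, 2)))
            p = Point2D(*rng.uniform(-20, 20, 2))
            q = project_point(p, seg)
            a, b = seg.q1.as_array(), seg.q2.as_array()
            ts = np.linspace(-5, 5, 20001)
            pts = a[None] + ts[:, None] * (b - a)[None]
            dmin = np.hypot(*(pts - p.as_array()).T).min()
            assert np.hypot(q.x - p.x, q.y - p.y) <= dmin + 1e-6

    def test_picking_point_midpoint(self):
        pc = picking_point(Point2D(2, 2), Point2D(4, 6))
        assert (pc.x, pc.y) == (3.0, 4.0)
        same = picking_point(Point2D(1, 1), Point2D(1, 1))
        assert (same.x, same.y) == (1.0, 1.0)


class TestLocate:
    def test_vertical_scene_recovers_axis_midpoint(self, clean_scene):
        s = clean_scene
        res = locate(s.label_map, s.image)
        # picking point sits on the branch axis, midway between barycenter rows
        mid_y = 0.5 * (res.proj_filament.y + res.proj_ball.y)
        assert res.picking_point.y == pytest.approx(mid_y, abs=1e-9)
        assert abs(res.picking_point.x - s.gt_necking.x) <= 4.0
        expected_y = 0.5 * (s.gt_filament_bc.y + s.gt_ball_bc.y)
        assert abs(res.picking_point.y - expected_y) <= 2.0

    def test_result_invariants(self, clean_scene):
        res = locate(clean_scene.label_map, clean_scene.image)
        assert res.picking_point.x == pytest.approx(
            0.5 * (res.proj_filament.x + res.proj_ball.x), abs=1e-9)
        for p in (res.proj_filament, res.proj_ball, res.picking_point):
            assert point_to_line_distance(p, res.chosen_line) < 1e-6
        assert res.min_distance >= 0.0

    def test_missing_branch_class_raises(self, clean_scene):
        lm = clean_scene.label_map.copy()
        lm[lm == 3] = 0
        with pytest.raises(ClassMissingError):
            locate(lm, clean_scene.image)

    def test_translation_equivariance(self, clean_scene):
        s = clean_scene
        res = locate(s.label_map, s.image)
        dx, dy = 30, -20
        lm2 = np.roll(np.roll(s.label_map, dy, axis=0), dx, axis=1)
        img2 = np.roll(np.roll(s.image, dy, axis=0), dx, axis=1)
        res2 = locate(lm2, img2)
        assert res2.picking_point.x == pytest.approx(res.picking_point.x + dx, abs=1.0)
        assert res2.picking_point.y == pytest.approx(res.picking_point.y + dy, abs=1.0)

    def test_stage_name_in_error(self):
        lm = np.zeros((32, 32), dtype=int)
        lm[5:8, 5:8] = 1
        with pytest.raises(ClassMissingError, match="components"):
            locate(lm, np.zeros((32, 32, 3), dtype=np.uint8))
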