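"""Box geometry and IoU-loss-family unit and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germkit.boxgeom import Box, InvalidBoxError, iou, loss_breakdown, min_detectable_size

finite_coord = st.floats(-1e3, 1e3, allow_nan=False)
positive_side = st.floats(1e-3, 1e3, allow_nan=False)
boxes = st.builds(Box, cx=finite_coord, cy=finite_coord, w=positive_side, h=positive_side)

LOSSES = ("iou", "giou", "diou", "ciou", "eiou", "eciou")


def rasterized_iou(a: Box, b: Box, resolution: int = 4) -> float:
    """Brute-force IoU by counting sub-pixel cells on a fine grid."""
    ax1, ay1, ax2, ay2 = a.corners
    bx1, by1, bx2, by2 = b.corners
    x_lo, x_hi = min(ax1, bx1), max(ax2, bx2)
    y_lo, y_hi = min(ay1, by1), max(ay2, by2)
    nx = int(round((x_hi - x_lo) * resolution))
    ny = int(round((y_hi - y_lo) * resolution))
    xs = x_lo + (np.arange(nx) + 0.5) / resolution
    ys = y_lo + (np.arange(ny) + 0.5) / resolution
    gx, gy = np.meshgrid(xs, ys)
    in_a = (gx > ax1) & (gx < ax2) & (gy > ay1) & (gy < ay2)
    in_b = (gx > bx1) & (gx < bx2) & (gy > by1) & (gy < by2)
    inter = np.sum(in_a & in_b)
    union = np.sum(in_a | in_b)
    return inter / union


def random_box(rng: np.random.Generator, integer: bool = False) -> Box:
    if integer:
        x1, y1 = rng.integers(0, 20, size=2)
        w, h = rng.integers(1, 15, size=2)
        return Box.from_corners(float(x1), float(y1), float(x1 + w), float(y1 + h))
    cx, cy = rng.uniform(-10, 10, size=2)
    w, h = rng.uniform(0.5, 8, size=2)
    return Box(cx, cy, w, h)


class TestBox:
    def test_center_corner_round_trip(self):
        b = Box(3.5, -2.0, 4.0, 1.5)
        assert Box.from_corners(*b.corners) == b

    @pytest.mark.parametrize("w,h", [(0, 1), (1, 0), (-2, 3), (1, -1)])
    def test_degenerate_rejected(self, w, h):
        with pytest.raises(InvalidBoxError):
            Box(0, 0, w, h)

    def test_corner_form_ordering(self):
        x1, y1, x2, y2 = Box(0, 0, 2, 3).corners
        assert x1 < x2 and y1 < y2


class TestIoU:
    def test_identical_boxes(self):
        b = Box(1, 2, 3, 4)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        a = Box.from_corners(0, 0, 2, 2)
        b = Box.from_corners(10, 10, 12, 12)
        assert iou(a, b) == 0.0

    def test_partial_overlap_area_arithmetic(self):
        # intersection 1, union 4 + 4 - 1 = 7
        a = Box.from_corners(0, 0, 2, 2)
        b = Box.from_corners(1, 1, 3, 3)
        assert iou(a, b) == pytest.approx(1 / 7)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = random_box(rng), random_box(rng)
            assert iou(a, b) == pytest.approx(iou(b, a))

    def test_agrees_with_rasterization_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b = random_box(rng, integer=True), random_box(rng, integer=True)
            assert iou(a, b) == pytest.approx(rasterized_iou(a, b), abs=1e-3)


class TestLossBreakdown:
    def test_identity_all_zero(self):
        b = Box(5, 5, 3, 2)
        lb = loss_breakdown(b, b)
        assert lb.iou == 1.0
        assert lb.v == 0.0
        for name in LOSSES:
            assert lb.loss(name) == pytest.approx(0.0, abs=1e-12)

    def test_scale_only_mismatch(self):
        # same center, same aspect ratio, different scale: v = 0, rho2 = 0
        pred, truth = Box(0, 0, 2, 1), Box(0, 0, 4, 2)
        lb = loss_breakdown(pred, truth)
        assert lb.v == pytest.approx(0.0, abs=1e-12)
        assert lb.rho2_center == 0.0
        assert lb.loss_ciou == pytest.approx(1.0 - lb.iou)

    def test_hand_computed_disjoint_pair(self):
        # enclosing box (0,0,6,6): c2 = 72, cw = ch = 6; centers (1,1) and
        # (4,4): rho2 = 18; same aspect so v = 0; edge terms (2-4)^2/36 each
        pred = Box.from_corners(0, 0, 2, 2)
        truth = Box.from_corners(2, 2, 6, 6)
        lb = loss_breakdown(pred, truth)
        assert lb.iou == 0.0
        assert lb.c2 == pytest.approx(72.0)
        assert (lb.cw, lb.ch) == (6.0, 6.0)
        assert lb.rho2_center == pytest.approx(18.0)
        assert lb.loss_ciou == pytest.approx(1.25)
        assert lb.loss_eciou == pytest.approx(1.25 + 4 / 36 + 4 / 36)

    def test_aspect_term_formula(self):
        pred, truth = Box(0, 0, 2, 1), Box(0, 0, 1, 2)
        lb = loss_breakdown(pred, truth)
        expected_v = 4 / math.pi**2 * (math.atan(0.5) - math.atan(2.0)) ** 2
        assert lb.v == pytest.approx(expected_v)
        assert lb.alpha == pytest.approx(lb.v / ((1 - lb.iou) + lb.v), rel=1e-6)

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b = random_box(rng), random_box(rng)
            dx, dy = rng.uniform(-20, 20, size=2)
            lb1 = loss_breakdown(a, b)
            lb2 = loss_breakdown(a.translated(dx, dy), b.translated(dx, dy))
            for name in LOSSES:
                assert lb1.loss(name) == pytest.approx(lb2.loss(name), abs=1e-9)

    def test_scale_invariance_of_ratios(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a, b = random_box(rng), random_box(rng)
            k = rng.uniform(0.2, 5.0)
            lb1, lb2 = loss_breakdown(a, b), loss_breakdown(a.scaled(k), b.scaled(k))
            assert lb1.iou == pytest.approx(lb2.iou, abs=1e-9)
            assert lb1.v == pytest.approx(lb2.v, abs=1e-9)
            assert lb1.rho2_center / lb1.c2 == pytest.approx(
                lb2.rho2_center / lb2.c2, abs=1e-9
            )

    def test_strictly_positive_for_distinct_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            a, b = random_box(rng), random_box(rng)
            if a == b:
                continue
            lb = loss_breakdown(a, b)
            for name in LOSSES:
                assert lb.loss(name) > 0

    def test_eciou_dominates_ciou(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            a, b = random_box(rng), random_box(rng)
            lb = loss_breakdown(a, b)
            assert lb.loss_eciou >= lb.loss_ciou - 1e-12

    def test_geometric_invariants(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            lb = loss_breakdown(random_box(rng), random_box(rng))
            assert 0.0 <= lb.iou <= 1.0
            assert lb.v >= 0.0
            assert lb.rho2_center <= lb.c2
            assert 0.0 <= lb.loss_giou <= 2.0


class TestPropertyBased:
    @given(box=boxes)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_corner_center_round_trip(self, box):
        back = Box.from_corners(*box.corners)
        assert back.cx == pytest.approx(box.cx, abs=1e-6)
        assert back.w == pytest.approx(box.w, rel=1e-9)

    @given(a=boxes, b=boxes)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_loss_bounds_hold_everywhere(self, a, b):
        lb = loss_breakdown(a, b)
        assert 0.0 <= lb.iou <= 1.0
        assert lb.rho2_center <= lb.c2 + 1e-6
        assert lb.loss_eciou >= lb.loss_ciou - 1e-12
        assert 0.0 <= lb.loss_giou <= 2.0 + 1e-12


class TestDetectionHeads:
    @pytest.mark.parametrize(
        "stride,input_size,expected",
        [(4, 640, (160, 4)), (8, 640, (80, 8)), (16, 640, (40, 16)), (32, 640, (20, 32))],
    )
    def test_feature_map_and_min_target(self, stride, input_size, expected):
        assert min_detectable_size(stride, input_size) == expected

    def test_non_divisible_input_rejected(self):
        with pytest.raises(ValueError):
            min_detectable_size(32, 650)

    def test_unknown_stride_rejected(self):
        with pytest.raises(ValueError):
            min_detectable_size(5, 640)
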