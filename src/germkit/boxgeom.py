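"""Axis-aligned bounding boxes and the IoU loss family.

The box losses implemented here are the standard regression objectives of
single-stage detectors: plain IoU loss, GIoU, DIoU, CIoU, EIoU and their
combination ECIoU, which augments the CIoU aspect-ratio penalty with EIoU's
separate width and height penalties so that the two box edges can be adjusted
independently once the aspect ratio is roughly right.

Coordinates are continuous pixels with the origin at the top-left and y
increasing downward; boxes are closed real rectangles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Box",
    "LossBreakdown",
    "InvalidBoxError",
    "iou",
    "loss_breakdown",
    "min_detectable_size",
    "LOSS_NAMES",
]

_EPS = 1e-9

LOSS_NAMES = ("iou", "giou", "diou", "ciou", "eiou", "eciou")


class InvalidBoxError(ValueError):
    """Raised for a degenerate box (non-positive width or height)."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in center form: center (cx, cy), width w, height h.

    Width and height must be strictly positive.  Corner form is
    ``(x1, y1, x2, y2) = (cx - w/2, cy - h/2, cx + w/2, cy + h/2)``.
    """

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"box width/height must be > 0, got w={self.w}, h={self.h}")
        if not all(math.isfinite(v) for v in (self.cx, self.cy, self.w, self.h)):
            raise InvalidBoxError("box coordinates must be finite")

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "Box":
        if not (x2 > x1 and y2 > y1):
            raise InvalidBoxError(f"corners must satisfy x1<x2, y1<y2, got {(x1, y1, x2, y2)}")
        return cls((x1 + x2) / 2.0, (y1 + y2) / 2.0, x2 - x1, y2 - y1)

    @property
    def corners(self) -> tuple[float, float, float, float]:
        return (
            self.cx - self.w / 2.0,
            self.cy - self.h / 2.0,
            self.cx + self.w / 2.0,
            self.cy + self.h / 2.0,
        )

    @property
    def area(self) -> float:
        return self.w * self.h

    def translated(self, dx: float, dy: float) -> "Box":
        return Box(self.cx + dx, self.cy + dy, self.w, self.h)

    def scaled(self, k: float) -> "Box":
        """Scale the box about the coordinate origin by factor ``k`` > 0."""
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return Box(self.cx * k, self.cy * k, self.w * k, self.h * k)


@dataclass(frozen=True)
class LossBreakdown:
    """All geometric terms and loss values for one (prediction, truth) pair.

    ``iou``          -- overlap / union, in [0, 1]
    ``rho2_center``  -- squared Euclidean distance between box centers (px^2)
    ``c2``           -- squared diagonal of the smallest enclosing box (px^2)
    ``cw``, ``ch``   -- enclosing-box width and height (px)
    ``v``            -- aspect-ratio consistency term (4/pi^2) * dAtan^2
    ``alpha``        -- CIoU trade-off weight v / ((1 - IoU) + v)
    """

    iou: float
    rho2_center: float
    c2: float
    cw: float
    ch: float
    v: float
    alpha: float
    loss_iou: float
    loss_giou: float
    loss_diou: float
    loss_ciou: float
    loss_eiou: float
    loss_eciou: float

    def loss(self, name: str) -> float:
        """Return one of the six losses by short name ('iou' ... 'eciou')."""
        if name not in LOSS_NAMES:
            raise KeyError(f"unknown loss {name!r}; expected one of {LOSS_NAMES}")
        return getattr(self, f"loss_{name}")


def _intersection_area(a: Box, b: Box) -> float:
    ax1, ay1, ax2, ay2 = a.corners
    bx1, by1, bx2, by2 = b.corners
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    # corner-difference rounding can nudge iw/ih above the true side length
    # at large coordinates; the intersection never exceeds either area
    return min(iw * ih, a.area, b.area)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1]."""
    inter = _intersection_area(a, b)
    union = a.area + b.area - inter
    return inter / union


def loss_breakdown(pred: Box, truth: Box) -> LossBreakdown:
    """Compute every geometric term and all six regression losses.

    CIoU loss is ``1 - IoU + rho^2/c^2 + alpha * v`` with the aspect term
    ``v = (4/pi^2) (atan(w_gt/h_gt) - atan(w/h))^2``; ECIoU adds the EIoU
    edge terms ``(h - h_gt)^2 / c_h^2 + (w - w_gt)^2 / c_w^2``.
    """
    px1, py1, px2, py2 = pred.corners
    tx1, ty1, tx2, ty2 = truth.corners

    inter = _intersection_area(pred, truth)
    union = pred.area + truth.area - inter
    iou_val = inter / union

    # smallest enclosing box
    ex1, ey1 = min(px1, tx1), min(py1, ty1)
    ex2, ey2 = max(px2, tx2), max(py2, ty2)
    cw = ex2 - ex1
    ch = ey2 - ey1
    if cw <= 0 or ch <= 0:
        raise InvalidBoxError("degenerate enclosing box")
    c2 = cw * cw + ch * ch
    enclosing_area = cw * ch

    rho2 = (pred.cx - truth.cx) ** 2 + (pred.cy - truth.cy) ** 2

    datan = math.atan(truth.w / truth.h) - math.atan(pred.w / pred.h)
    v = (4.0 / math.pi**2) * datan * datan
    alpha = 0.0 if v == 0.0 else v / ((1.0 - iou_val) + v + _EPS)

    giou = iou_val - (enclosing_area - union) / enclosing_area

    loss_iou_val = 1.0 - iou_val
    loss_giou_val = 1.0 - giou
    loss_diou_val = 1.0 - iou_val + rho2 / c2
    loss_ciou_val = loss_diou_val + alpha * v
    loss_eiou_val = loss_diou_val + (pred.h - truth.h) ** 2 / (ch * ch) + (
        pred.w - truth.w
    ) ** 2 / (cw * cw)
    loss_eciou_val = loss_ciou_val + (pred.h - truth.h) ** 2 / (ch * ch) + (
        pred.w - truth.w
    ) ** 2 / (cw * cw)

    return LossBreakdown(
        iou=iou_val,
        rho2_center=rho2,
        c2=c2,
        cw=cw,
        ch=ch,
        v=v,
        alpha=alpha,
        loss_iou=loss_iou_val,
        loss_giou=loss_giou_val,
        loss_diou=loss_diou_val,
        loss_ciou=loss_ciou_val,
        loss_eiou=loss_eiou_val,
        loss_eciou=loss_eciou_val,
    )


def min_detectable_size(stride: int, input_size: int) -> tuple[int, int]:
    """Feature-map side and minimum detectable target side for a head stride.

    A detection head running at stride ``s`` on an ``input_size`` input sees a
    ``input_size/s`` square feature map and can resolve targets of roughly
    ``s x s`` pixels or larger (e.g. the P2/4 head on a 640 input gives a
    160x160 map for targets of 4x4 and up).
    """
    if stride not in (4, 8, 16, 32):
        raise ValueError(f"stride must be one of 4, 8, 16, 32, got {stride}")
    if input_size % stride != 0:
        raise ValueError(f"input size {input_size} not divisible by stride {stride}")
    return input_size // stride, stride
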