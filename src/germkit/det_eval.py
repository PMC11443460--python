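"""Detection evaluation: greedy matching, NMS, and precision/recall/AP/mAP.

Average precision uses all-point interpolation: the precision-recall curve
is replaced by its non-increasing envelope and integrated exactly over the
recall steps, the convention of modern VOC/YOLO evaluators.  mAP50 is the
mean of per-class APs at an IoU matching threshold of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boxgeom import Box, iou
from .vocab import CLASS_INDEX, CLASS_NAMES, check_label

__all__ = [
    "Detection",
    "GroundTruth",
    "ClassEval",
    "EvalResult",
    "nms",
    "match_and_score",
    "average_precision",
    "read_yolo_file",
    "write_yolo_file",
    "evaluate_dirs",
]

DEFAULT_MATCH_IOU = 0.5   # mAP50 matching threshold
DEFAULT_NMS_IOU = 0.7     # detector post-processing threshold


@dataclass(frozen=True)
class Detection:
    box: Box
    label: str
    confidence: float
    frame_id: str = ""

    def __post_init__(self) -> None:
        check_label(self.label)
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class GroundTruth:
    box: Box
    label: str
    frame_id: str = ""

    def __post_init__(self) -> None:
        check_label(self.label)


@dataclass
class ClassEval:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    ap: float
    # cumulative PR points in confidence order, one per retained detection
    pr_curve: list[tuple[float, float]] = field(default_factory=list, repr=False)


@dataclass
class EvalResult:
    per_class: dict[str, ClassEval]
    map50: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": name, "tp": ce.tp, "fp": ce.fp, "fn": ce.fn,
             "precision": ce.precision, "recall": ce.recall, "ap": ce.ap}
            for name, ce in self.per_class.items()
        ]
        return pd.DataFrame(rows)


def nms(dets: list[Detection], iou_threshold: float = DEFAULT_NMS_IOU) -> list[Detection]:
    """Greedy per-class, per-frame non-maximum suppression.

    Detections are visited in descending confidence (ties broken by input
    order) and kept unless their IoU with an already-kept detection of the
    same class and frame exceeds ``iou_threshold``.  The result preserves
    the original input order of the survivors.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    keep_flags = [False] * len(dets)
    groups: dict[tuple[str, str], list[int]] = {}
    for i, d in enumerate(dets):
        groups.setdefault((d.label, d.frame_id), []).append(i)
    for indices in groups.values():
        order = sorted(indices, key=lambda i: -dets[i].confidence)  # stable
        kept: list[int] = []
        for i in order:
            if all(iou(dets[i].box, dets[j].box) <= iou_threshold for j in kept):
                kept.append(i)
                keep_flags[i] = True
    return [d for d, keep in zip(dets, keep_flags) if keep]


def average_precision(tp_flags: list[bool], n_gt: int) -> tuple[float, list[tuple[float, float]]]:
    """All-point-interpolated AP from per-detection TP flags.

    ``tp_flags`` lists detections in descending-confidence order.  Returns
    the AP and the raw cumulative (recall, precision) points.
    """
    if n_gt == 0:
        return 0.0, []
    tp_cum = np.cumsum(np.asarray(tp_flags, dtype=float))
    n_det = np.arange(1, len(tp_flags) + 1)
    recall = tp_cum / n_gt
    precision = tp_cum / n_det
    curve = list(zip(recall.tolist(), precision.tolist()))

    # envelope integration over recall steps
    r = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    ap = 0.0
    for i in range(1, len(r) - 1):
        ap += (r[i] - r[i - 1]) * p[i]
    return float(ap), curve


def match_and_score(
    dets: list[Detection],
    truths: list[GroundTruth],
    iou_threshold: float = DEFAULT_MATCH_IOU,
) -> EvalResult:
    """Greedy confidence-ordered matching and per-class P/R/AP with mAP50.

    Per class, each detection (in descending-confidence order) is a true
    positive when its best-IoU unmatched same-frame truth reaches the
    threshold, consuming that truth; otherwise a false positive.  Unmatched
    truths are false negatives.  Matching never crosses frames or classes.
    mAP is averaged over classes that have ground truth.
    """
    per_class: dict[str, ClassEval] = {}
    aps: list[float] = []
    for cls in CLASS_NAMES:
        cls_dets = [d for d in dets if d.label == cls]
        cls_truths = [t for t in truths if t.label == cls]
        if not cls_dets and not cls_truths:
            continue
        order = sorted(range(len(cls_dets)), key=lambda i: -cls_dets[i].confidence)
        matched = [False] * len(cls_truths)
        tp_flags: list[bool] = []
        for i in order:
            det = cls_dets[i]
            best_j, best_iou = -1, 0.0
            for j, truth in enumerate(cls_truths):
                if matched[j] or truth.frame_id != det.frame_id:
                    continue
                val = iou(det.box, truth.box)
                if val > best_iou:
                    best_j, best_iou = j, val
            if best_j >= 0 and best_iou >= iou_threshold:
                matched[best_j] = True
                tp_flags.append(True)
            else:
                tp_flags.append(False)
        tp = sum(tp_flags)
        fp = len(tp_flags) - tp
        fn = len(cls_truths) - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        ap, curve = average_precision(tp_flags, len(cls_truths))
        per_class[cls] = ClassEval(tp, fp, fn, precision, recall, ap, curve)
        if cls_truths:
            aps.append(ap)
    map50 = float(np.mean(aps)) if aps else 0.0
    return EvalResult(per_class, map50)


# ---------------------------------------------------------------------------
# YOLO text I/O: one file per image, lines "class cx cy w h [confidence]"
# with coordinates normalised by image size.

def read_yolo_file(
    path: str | Path,
    image_width: int,
    image_height: int,
    frame_id: str | None = None,
) -> tuple[list[Detection], list[GroundTruth]]:
    """Read a YOLO-format txt file into detections (6 columns) or truths (5).

    Returns ``(detections, truths)``; lines with a confidence column land in
    the first list, lines without in the second.
    """
    path = Path(path)
    fid = frame_id if frame_id is not None else path.stem
    dets: list[Detection] = []
    truths: list[GroundTruth] = []
    for raw in path.read_text().splitlines():
        parts = raw.split()
        if not parts:
            continue
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}: malformed YOLO line {raw!r}")
        cls_idx = int(parts[0])
        if not 0 <= cls_idx < len(CLASS_NAMES):
            raise ValueError(f"{path}: class index {cls_idx} out of range")
        cx, cy, w, h = (float(v) for v in parts[1:5])
        box = Box(cx * image_width, cy * image_height, w * image_width, h * image_height)
        label = CLASS_NAMES[cls_idx]
        if len(parts) == 6:
            dets.append(Detection(box, label, float(parts[5]), fid))
        else:
            truths.append(GroundTruth(box, label, fid))
    return dets, truths


def write_yolo_file(
    path: str | Path,
    objects: list[Detection] | list[GroundTruth],
    image_width: int,
    image_height: int,
) -> None:
    lines = []
    for obj in objects:
        b = obj.box
        fields = [
            str(CLASS_INDEX[obj.label]),
            f"{b.cx / image_width:.6f}",
            f"{b.cy / image_height:.6f}",
            f"{b.w / image_width:.6f}",
            f"{b.h / image_height:.6f}",
        ]
        if isinstance(obj, Detection):
            fields.append(f"{obj.confidence:.6f}")
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def evaluate_dirs(
    pred_dir: str | Path,
    truth_dir: str | Path,
    image_width: int,
    image_height: int,
    iou_threshold: float = DEFAULT_MATCH_IOU,
) -> EvalResult:
    """Evaluate directories of per-image YOLO txt files against each other.

    Files are paired by stem; a truth file with no prediction counterpart
    contributes only false negatives.
    """
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    dets: list[Detection] = []
    truths: list[GroundTruth] = []
    for tf in sorted(truth_dir.glob("*.txt")):
        _, t = read_yolo_file(tf, image_width, image_height)
        truths.extend(t)
        pf = pred_dir / tf.name
        if pf.exists():
            d, _ = read_yolo_file(pf, image_width, image_height)
            dets.extend(d)
    return match_and_score(dets, truths, iou_threshold)
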