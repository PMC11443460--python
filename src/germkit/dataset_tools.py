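"""Dataset construction tooling: VOC XML <-> YOLO txt, bbox-aware
augmentation, seeded 7:2:1 splitting, and the acquisition scheduler.

Annotations follow the LabelImg on-disk conventions: corner-form pixel
coordinates in Pascal-VOC XML, and normalised center-size text lines for
YOLO training.  Augmentations transform images and boxes consistently and
are fully seeded where stochastic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from lxml import etree
from skimage.transform import rescale, rotate as _sk_rotate

from .boxgeom import Box
from .vocab import CLASS_INDEX, CLASS_NAMES, check_label

__all__ = [
    "AnnotationRecord",
    "ExperimentConfig",
    "AnnotationError",
    "voc_to_yolo",
    "yolo_to_voc",
    "read_voc_xml",
    "write_voc_xml",
    "hflip",
    "rotate",
    "scale",
    "add_noise",
    "flip_rotate",
    "AUGMENTATIONS",
    "split_dataset",
    "acquisition_schedule",
]

logger = logging.getLogger(__name__)

_CLIP_EPS = 1e-6


class AnnotationError(ValueError):
    """Raised for an annotation inconsistent with its image geometry."""


@dataclass(frozen=True)
class AnnotationRecord:
    """All labeled objects of one image, boxes in pixel corner coordinates."""

    image_id: str
    image_width: int
    image_height: int
    objects: tuple[tuple[str, Box], ...] = ()

    def __post_init__(self) -> None:
        for label, _ in self.objects:
            check_label(label)


@dataclass(frozen=True)
class ExperimentConfig:
    """Germination-trial layout: tray grid, treatments and acquisition plan.

    Defaults mirror a salt-stress trial with 9x9 seeds per tray, NaCl
    treatments from 0 (deionised-water control) to 150 mmol/L in three
    replicate trays each, imaged every 30 minutes for 48 hours at 26 C.
    """

    grid_rows: int = 9
    grid_cols: int = 9
    concentrations: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    replicates: int = 3
    interval_h: float = 0.5
    duration_h: float = 48.0
    temperature_c: float = 26.0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("tray grid must be at least 1x1")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        n = self.duration_h / self.interval_h
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"interval {self.interval_h} h must divide duration {self.duration_h} h"
            )

    @property
    def seeds_per_tray(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def n_trays(self) -> int:
        return len(self.concentrations) * self.replicates

    @property
    def total_seeds(self) -> int:
        return self.seeds_per_tray * self.n_trays

    @property
    def times(self) -> tuple[float, ...]:
        """Acquisition timestamps in hours: interval, 2*interval, ..., duration."""
        n = round(self.duration_h / self.interval_h)
        return tuple((i + 1) * self.interval_h for i in range(n))

    @property
    def tray_ids(self) -> tuple[str, ...]:
        return tuple(
            f"c{int(conc):03d}_r{rep}"
            for conc in self.concentrations
            for rep in range(1, self.replicates + 1)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "concentrations" in raw:
            raw["concentrations"] = tuple(float(c) for c in raw["concentrations"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        obj = {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "concentrations": list(self.concentrations),
            "replicates": self.replicates,
            "interval_h": self.interval_h,
            "duration_h": self.duration_h,
            "temperature_c": self.temperature_c,
        }
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


# ---------------------------------------------------------------------------
# VOC <-> YOLO conversion

def voc_to_yolo(record: AnnotationRecord) -> list[str]:
    """Convert a record to YOLO lines ``class_idx cx cy w h`` (normalised).

    Class indices are fixed: seed=0, S_root=1, L_root=2; coordinates are
    divided by the image size and printed with 6 decimals.
    """
    w_img, h_img = record.image_width, record.image_height
    lines = []
    for label, box in record.objects:
        x1, y1, x2, y2 = box.corners
        if x1 < -_CLIP_EPS or y1 < -_CLIP_EPS or x2 > w_img + _CLIP_EPS or y2 > h_img + _CLIP_EPS:
            raise AnnotationError(
                f"{record.image_id}: box {box.corners} outside {w_img}x{h_img} image"
            )
        lines.append(
            f"{CLASS_INDEX[label]} {box.cx / w_img:.6f} {box.cy / h_img:.6f} "
            f"{box.w / w_img:.6f} {box.h / h_img:.6f}"
        )
    return lines


def yolo_to_voc(
    lines: list[str], image_id: str, image_width: int, image_height: int
) -> AnnotationRecord:
    """Inverse of :func:`voc_to_yolo` (up to the 6-decimal rounding)."""
    objects = []
    for raw in lines:
        parts = raw.split()
        if len(parts) != 5:
            raise AnnotationError(f"malformed YOLO line {raw!r}")
        idx = int(parts[0])
        if not 0 <= idx < len(CLASS_NAMES):
            raise AnnotationError(f"class index {idx} out of range")
        cx, cy, w, h = (float(v) for v in parts[1:5])
        objects.append(
            (CLASS_NAMES[idx], Box(cx * image_width, cy * image_height, w * image_width, h * image_height))
        )
    return AnnotationRecord(image_id, image_width, image_height, tuple(objects))


def read_voc_xml(path: str | Path) -> AnnotationRecord:
    """Read a LabelImg-style Pascal-VOC XML annotation file."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    image_id = Path(root.findtext("filename", default=Path(path).stem)).stem
    size = root.find("size")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    objects = []
    for obj in root.iterfind("object"):
        label = check_label(obj.findtext("name"))
        bb = obj.find("bndbox")
        x1 = float(bb.findtext("xmin"))
        y1 = float(bb.findtext("ymin"))
        x2 = float(bb.findtext("xmax"))
        y2 = float(bb.findtext("ymax"))
        objects.append((label, Box.from_corners(x1, y1, x2, y2)))
    return AnnotationRecord(image_id, width, height, tuple(objects))


def write_voc_xml(record: AnnotationRecord, path: str | Path) -> None:
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = f"{record.image_id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(record.image_width)
    etree.SubElement(size, "height").text = str(record.image_height)
    etree.SubElement(size, "depth").text = "1"
    for label, box in record.objects:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = label
        bb = etree.SubElement(obj, "bndbox")
        x1, y1, x2, y2 = box.corners
        etree.SubElement(bb, "xmin").text = f"{x1:.2f}"
        etree.SubElement(bb, "ymin").text = f"{y1:.2f}"
        etree.SubElement(bb, "xmax").text = f"{x2:.2f}"
        etree.SubElement(bb, "ymax").text = f"{y2:.2f}"
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


# ---------------------------------------------------------------------------
# Augmentation: images are float arrays (H, W) or (H, W, C); boxes move with
# the content and are clipped to the canvas.  Objects pushed fully outside
# the canvas are dropped with a warning.

def _clip_box(box: Box, width: float, height: float) -> Box | None:
    x1, y1, x2, y2 = box.corners
    x1, x2 = max(x1, 0.0), min(x2, width)
    y1, y2 = max(y1, 0.0), min(y2, height)
    if x2 - x1 <= _CLIP_EPS or y2 - y1 <= _CLIP_EPS:
        return None
    return Box.from_corners(x1, y1, x2, y2)


def _transform_objects(record, transform) -> tuple[tuple[str, Box], ...]:
    out = []
    for label, box in record.objects:
        new = transform(box)
        if new is None:
            logger.warning("%s: dropped %s box outside canvas", record.image_id, label)
            continue
        out.append((label, new))
    return tuple(out)


def hflip(image: np.ndarray, record: AnnotationRecord) -> tuple[np.ndarray, AnnotationRecord]:
    """Mirror about the vertical axis: cx -> W - cx, widths unchanged."""
    w_img = record.image_width
    objs = _transform_objects(record, lambda b: Box(w_img - b.cx, b.cy, b.w, b.h))
    return image[:, ::-1].copy(), replace(record, image_id=record.image_id + "_hflip", objects=objs)


def rotate(
    image: np.ndarray, record: AnnotationRecord, angle: float
) -> tuple[np.ndarray, AnnotationRecord]:
    """Rotate image content by ``angle`` degrees (clockwise on screen) about
    the image center; each box's four corners are mapped and re-enclosed in
    an axis-aligned box, then clipped to the canvas.
    """
    w_img, h_img = record.image_width, record.image_height
    cx0, cy0 = w_img / 2.0, h_img / 2.0
    theta = math.radians(angle)
    cos_t, sin_t = math.cos(theta), math.sin(theta)

    def map_point(x: float, y: float) -> tuple[float, float]:
        dx, dy = x - cx0, y - cy0
        # screen-clockwise rotation in y-down pixel coordinates
        return cx0 + cos_t * dx - sin_t * dy, cy0 + sin_t * dx + cos_t * dy

    def map_box(b: Box) -> Box | None:
        x1, y1, x2, y2 = b.corners
        pts = [map_point(x1, y1), map_point(x2, y1), map_point(x1, y2), map_point(x2, y2)]
        xs, ys = zip(*pts)
        return _clip_box(Box.from_corners(min(xs), min(ys), max(xs), max(ys)), w_img, h_img)

    rotated = _sk_rotate(
        image.astype(float), -angle, resize=False, center=(cx0, cy0), order=1, mode="constant"
    )
    objs = _transform_objects(record, map_box)
    return rotated, replace(record, image_id=f"{record.image_id}_rot{angle:g}", objects=objs)


def scale(
    image: np.ndarray, record: AnnotationRecord, factor: float
) -> tuple[np.ndarray, AnnotationRecord]:
    """Resize content by ``factor`` about the origin on a fixed canvas.

    Box coordinates are multiplied by the factor and clipped; shrunk images
    are zero-padded at the bottom/right, grown images cropped.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    h_img, w_img = record.image_height, record.image_width
    resized = rescale(image.astype(float), factor, order=1, channel_axis=None if image.ndim == 2 else -1)
    canvas = np.zeros_like(image, dtype=float)
    h_copy, w_copy = min(h_img, resized.shape[0]), min(w_img, resized.shape[1])
    canvas[:h_copy, :w_copy] = resized[:h_copy, :w_copy]
    objs = _transform_objects(record, lambda b: _clip_box(b.scaled(factor), w_img, h_img))
    return canvas, replace(record, image_id=f"{record.image_id}_scale{factor:g}", objects=objs)


def add_noise(
    image: np.ndarray, record: AnnotationRecord, sigma: float, seed: int
) -> tuple[np.ndarray, AnnotationRecord]:
    """Add seeded Gaussian pixel noise; boxes are unchanged."""
    rng = np.random.default_rng(seed)
    noisy = image.astype(float) + rng.normal(0.0, sigma, size=image.shape)
    return noisy, replace(record, image_id=f"{record.image_id}_noise")


def flip_rotate(
    image: np.ndarray, record: AnnotationRecord, angle: float = 180.0
) -> tuple[np.ndarray, AnnotationRecord]:
    """Horizontal flip followed by rotation — the extra combined op."""
    img, rec = hflip(image, record)
    return rotate(img, rec, angle)


AUGMENTATIONS = ("hflip", "rotate", "scale", "noise", "flip_rotate")


# ---------------------------------------------------------------------------

def split_dataset(
    ids: list[str], ratios: tuple[float, float, float] = (7, 2, 1), seed: int = 0
) -> tuple[list[str], list[str], list[str]]:
    """Seeded shuffle split into train/val/test by the given ratios.

    Val and test sizes are floors of their shares; the remainder goes to
    train, so 1000 ids at 7:2:1 give 700/200/100.
    """
    if not ids:
        raise ValueError("ids must be nonempty")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    total = sum(ratios)
    n = len(ids)
    n_val = int(n * ratios[1] / total)
    n_test = int(n * ratios[2] / total)
    n_train = n - n_val - n_test
    order = list(ids)
    np.random.default_rng(seed).shuffle(order)
    return order[:n_train], order[n_train : n_train + n_val], order[n_train + n_val :]


def acquisition_schedule(config: ExperimentConfig) -> list[tuple[str, float]]:
    """All (tray_id, timestamp-in-hours) acquisitions of the trial.

    Each of the ``concentrations x replicates`` trays is imaged every
    ``interval_h`` hours on the half-open grid (0, duration], so a 48 h run
    at 30 min intervals yields 96 frames per tray.
    """
    return [(tray, t) for tray in config.tray_ids for t in config.times]
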