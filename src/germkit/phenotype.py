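"""Germination-vigor indices computed from per-frame detections.

A seed counts as germinated once its radicle reaches half the seed length,
i.e. once the detector reports an ``L_root`` object for it.  From the
per-frame L_root detections of one tray the module derives:

* germination rate  N_s / N x 100 (%), with N the seeds per tray;
* germination index sum_t G_t / D_t, with G_t the seeds newly germinated
  in the interval ending at t and D_t the elapsed time t in hours;
* root length, approximated by the diagonal of the detection box converted
  to millimetres, and its per-frame mean over germinated seeds.

Detector flicker (a cumulative count that decreases) is repaired by a
running maximum — germination is irreversible.  Root identity is not
tracked across frames; root-length statistics are per-frame cross sections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .boxgeom import Box
from .det_eval import Detection
from .dataset_tools import ExperimentConfig

__all__ = [
    "Calibration",
    "GerminationTimeline",
    "root_length_from_box",
    "germination_rate",
    "germination_index",
    "mean_root_length",
    "build_timeline",
    "vigor_table",
]


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale of the imaging rig."""

    mm_per_pixel: float

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")


@dataclass(frozen=True)
class GerminationTimeline:
    """Per-tray germination time series.

    ``germinated_counts[i]`` is the cumulative number of germinated seeds
    (L_root detections, capped at ``n_total``) at ``times[i]``;
    ``new_germinations[i]`` its first difference; ``root_boxes[i]`` the
    L_root boxes observed in that frame.
    """

    tray_id: str
    concentration: float
    times: tuple[float, ...]
    n_total: int
    germinated_counts: tuple[int, ...]
    new_germinations: tuple[int, ...]
    root_boxes: tuple[tuple[Box, ...], ...]

    def __post_init__(self) -> None:
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(t <= 0 for t in self.times):
            raise ValueError("times must be positive hours")
        counts = self.germinated_counts
        if len(counts) != len(self.times) or len(self.new_germinations) != len(self.times):
            raise ValueError("counts must align with times")
        if any(c2 < c1 for c1, c2 in zip(counts, counts[1:])):
            raise ValueError("germinated_counts must be non-decreasing")
        if counts and counts[-1] > self.n_total:
            raise ValueError("germinated count exceeds seed total")
        running = 0
        for g, c in zip(self.new_germinations, counts):
            running += g
            if running != c:
                raise ValueError("new_germinations must cumulate to germinated_counts")

    def _index(self, t: float) -> int:
        for i, ti in enumerate(self.times):
            if math.isclose(ti, t, rel_tol=1e-9, abs_tol=1e-9):
                return i
        raise KeyError(f"time {t} h not sampled; available: {self.times}")


def root_length_from_box(box: Box, cal: Calibration) -> float:
    """Root length in mm as the box diagonal scaled by the calibration."""
    return math.hypot(box.w, box.h) * cal.mm_per_pixel


def germination_rate(timeline: GerminationTimeline, t: float) -> float:
    """Percentage of seeds germinated by time ``t`` (must be sampled)."""
    i = timeline._index(t)
    return timeline.germinated_counts[i] / timeline.n_total * 100.0


def germination_index(timeline: GerminationTimeline, up_to: float | None = None) -> float:
    """Speed-weighted germination summary: sum over times of G_t / D_t.

    ``G_t`` is the number of seeds newly germinated in the interval ending
    at ``t`` and ``D_t`` the elapsed time ``t`` in hours, so earlier
    germination contributes more.  Unitless.
    """
    total = 0.0
    for t, g in zip(timeline.times, timeline.new_germinations):
        if up_to is not None and t > up_to + 1e-9:
            break
        total += g / t
    return total


def mean_root_length(timeline: GerminationTimeline, t: float, cal: Calibration) -> float:
    """Mean over germinated seeds of the box-diagonal root length at ``t``.

    Defined as 0 mm when no seed has germinated at ``t``.
    """
    boxes = timeline.root_boxes[timeline._index(t)]
    if not boxes:
        return 0.0
    return sum(root_length_from_box(b, cal) for b in boxes) / len(boxes)


def build_timeline(
    frames: dict[float, list[Detection]],
    config: ExperimentConfig,
    tray_id: str = "",
    concentration: float = 0.0,
) -> GerminationTimeline:
    """Assemble a tray timeline from per-timestamp detection lists.

    ``frames`` maps acquisition time (hours) to NMS-filtered detections of
    that frame.  The germinated count at each time is the number of L_root
    detections, capped at the seeds per tray and made monotone by a running
    maximum; new germinations are its first difference.
    """
    times = sorted(frames)
    if list(frames) != times:
        raise ValueError("frame timestamps must be provided in increasing order")
    n_total = config.seeds_per_tray
    counts: list[int] = []
    roots: list[tuple[Box, ...]] = []
    running_max = 0
    for t in times:
        l_roots = [d.box for d in frames[t] if d.label == "L_root"]
        raw = min(len(l_roots), n_total)
        running_max = max(running_max, raw)
        counts.append(running_max)
        roots.append(tuple(l_roots))
    news = [counts[0]] + [c2 - c1 for c1, c2 in zip(counts, counts[1:])] if counts else []
    return GerminationTimeline(
        tray_id=tray_id,
        concentration=concentration,
        times=tuple(times),
        n_total=n_total,
        germinated_counts=tuple(counts),
        new_germinations=tuple(news),
        root_boxes=tuple(roots),
    )


def vigor_table(
    timelines: list[GerminationTimeline], cal: Calibration, out_csv: str | Path | None = None
) -> pd.DataFrame:
    """Tidy per-(tray, time) table of the three vigor indices.

    Columns: tray, concentration, time_h, germination_rate_pct,
    germination_index_cum (index accumulated up to the row's time) and
    mean_root_length_mm.  Optionally written as CSV.
    """
    rows = []
    for tl in timelines:
        for t in tl.times:
            rows.append(
                {
                    "tray": tl.tray_id,
                    "concentration": tl.concentration,
                    "time_h": t,
                    "germination_rate_pct": germination_rate(tl, t),
                    "germination_index_cum": germination_index(tl, up_to=t),
                    "mean_root_length_mm": mean_root_length(tl, t, cal),
                }
            )
    frame = pd.DataFrame(rows)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return frame
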