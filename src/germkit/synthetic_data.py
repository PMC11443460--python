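"""Synthetic salt-stress germination time-lapse data with ground truth.

The generator emulates the statistical structure of a cucumber-seed
germination trial in NaCl solution: 81 seeds in a 9x9 tray, radicle
emergence around 24-28 h of incubation, root elongation slowed by salt,
mild promotion of both germination and elongation at 30 mmol/L, monotone
inhibition at higher doses, and no germination at all from 160 mmol/L up.
Each tray is rendered as a grayscale frame sequence (bright seed ellipses,
dimmer curved radicles on a dark background) with exact per-object
bounding-box annotations, and a classical threshold/connected-component
reference detector closes the loop so the whole phenotyping pipeline runs
with no trained network.

All stochastic operations take explicit RNG seeds; nothing uses global
random state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import dilation, disk, opening

from .boxgeom import Box
from .dataset_tools import AnnotationRecord, ExperimentConfig
from .det_eval import Detection
from .phenotype import Calibration, GerminationTimeline

__all__ = [
    "GrowthModel",
    "SceneSpec",
    "SeedTrajectory",
    "TraySimulation",
    "Frame",
    "simulate_tray",
    "render_frames",
    "reference_detect",
    "detect_tray_timeline",
]

logger = logging.getLogger(__name__)

# default germination probability by NaCl concentration (mmol/L); shaped to
# the observed dose response: mild promotion at 30, monotone inhibition
# above, nothing from 160 up.  The trial reports no per-concentration
# probabilities, so these are generator defaults, not measured values.
DEFAULT_P_GERM_PROFILE: tuple[tuple[float, float], ...] = (
    (0.0, 0.85),
    (30.0, 0.92),
    (60.0, 0.75),
    (90.0, 0.55),
    (120.0, 0.30),
    (150.0, 0.10),
)


@dataclass(frozen=True)
class GrowthModel:
    """Stochastic radicle growth model under salt stress.

    ``p_germ(c)`` interpolates the profile and is exactly 0 at or above
    ``zero_conc_threshold``.  Emergence time is Normal(mean, sd) truncated
    to positive values.  Root length grows linearly after emergence at
    ``growth_rate(c)``, the control rate scaled by a dose factor that is
    slightly above 1 at 30 mmol/L and declines with concentration.
    A seed counts as germinated once its root reaches half the seed length.
    """

    p_germ_profile: tuple[tuple[float, float], ...] = DEFAULT_P_GERM_PROFILE
    t_emerge_mean: float = 26.0
    t_emerge_sd: float = 4.0
    growth_rate_ck: float = 0.5          # mm/h in deionised water
    seed_length_mm: float = 8.0
    zero_conc_threshold: float = 160.0

    def p_germ(self, conc: float) -> float:
        if conc >= self.zero_conc_threshold:
            return 0.0
        xs = [c for c, _ in self.p_germ_profile] + [self.zero_conc_threshold]
        ys = [p for _, p in self.p_germ_profile] + [0.0]
        return float(np.interp(conc, xs, ys))

    def growth_rate(self, conc: float) -> float:
        factor = float(np.interp(conc, [0.0, 30.0, self.zero_conc_threshold], [1.0, 1.08, 0.45]))
        return self.growth_rate_ck * factor

    @property
    def germination_length_mm(self) -> float:
        return self.seed_length_mm / 2.0


@dataclass(frozen=True)
class SceneSpec:
    """Rendering geometry and imaging model of the synthetic tray.

    One seed per grid cell of ``cell_px`` pixels; the image side is
    ``grid * cell_px``.  Seeds are bright ellipses (length
    ``seed_length_mm`` at ``mm_per_pixel`` scale), radicles are curved
    polylines of the model's true length drawn ``root_thickness_px`` wide.
    Radicles shorter than ``min_render_length_mm`` stay hidden under the
    seed coat and are not rendered or annotated.
    """

    cell_px: int = 80
    mm_per_pixel: float = 0.5
    seed_length_mm: float = 8.0
    seed_aspect: float = 0.55            # minor/major axis ratio
    root_thickness_px: int = 3
    background: float = 0.08
    seed_intensity: float = 0.9
    root_intensity: float = 0.55
    noise_sigma: float = 0.02
    min_render_length_mm: float = 2.0

    @property
    def seed_length_px(self) -> float:
        return self.seed_length_mm / self.mm_per_pixel

    def image_size(self, config: ExperimentConfig) -> tuple[int, int]:
        return config.grid_rows * self.cell_px, config.grid_cols * self.cell_px

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.mm_per_pixel)


@dataclass(frozen=True)
class SeedTrajectory:
    """Fate of one seed: position, germination, emergence and geometry."""

    row: int
    col: int
    germinates: bool
    t_emerge: float          # hours; meaningful only if germinates
    growth_rate: float       # mm/h
    orientation: float       # seed major-axis angle, radians
    curvature: float         # radicle curvature, rad per pixel of arc

    def root_length_mm(self, t: float) -> float:
        if not self.germinates or t <= self.t_emerge:
            return 0.0
        return (t - self.t_emerge) * self.growth_rate


@dataclass
class TraySimulation:
    tray_id: str
    concentration: float
    config: ExperimentConfig
    model: GrowthModel
    trajectories: list[SeedTrajectory] = field(repr=False)

    def germinated_count(self, t: float) -> int:
        half = self.model.germination_length_mm
        return sum(1 for s in self.trajectories if s.root_length_mm(t) >= half)

    def truth_timeline(self, times: tuple[float, ...] | None = None) -> GerminationTimeline:
        """Ground-truth timeline from the true (unrendered) trajectories.

        Root boxes are synthetic squares whose diagonal equals the true root
        length in millimetres, so ``mean_root_length`` with a unit
        calibration (1 mm/px) recovers the true cross-sectional mean.
        """
        if times is None:
            times = self.config.times
        half = self.model.germination_length_mm
        counts, news, boxes = [], [], []
        prev = 0
        for t in times:
            lengths = [
                s.root_length_mm(t)
                for s in self.trajectories
                if s.root_length_mm(t) >= half
            ]
            count = len(lengths)
            counts.append(count)
            news.append(count - prev)
            prev = count
            side = [length / math.sqrt(2.0) for length in lengths]
            boxes.append(tuple(Box(0.0, 0.0, s, s) for s in side))
        return GerminationTimeline(
            tray_id=self.tray_id,
            concentration=self.concentration,
            times=tuple(times),
            n_total=self.config.seeds_per_tray,
            germinated_counts=tuple(counts),
            new_germinations=tuple(news),
            root_boxes=tuple(boxes),
        )


def simulate_tray(
    config: ExperimentConfig,
    model: GrowthModel,
    conc: float,
    seed: int,
    tray_id: str | None = None,
) -> TraySimulation:
    """Simulate the fate of every seed in one tray at one NaCl dose.

    Each of the ``grid_rows x grid_cols`` seeds independently germinates
    with probability ``p_germ(conc)``; emergence times are truncated-normal;
    roots elongate linearly at the dose-scaled rate.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    p = model.p_germ(conc)
    rate = model.growth_rate(conc)
    trajectories = []
    for row in range(config.grid_rows):
        for col in range(config.grid_cols):
            germinates = bool(rng.random() < p)
            t_emerge = float(rng.normal(model.t_emerge_mean, model.t_emerge_sd))
            while t_emerge <= 0:
                t_emerge = float(rng.normal(model.t_emerge_mean, model.t_emerge_sd))
            orientation = float(rng.uniform(0, 2 * math.pi))
            curvature = float(rng.uniform(-1, 1)) * 0.02
            trajectories.append(
                SeedTrajectory(row, col, germinates, t_emerge, rate, orientation, curvature)
            )
    if tray_id is None:
        tray_id = f"c{int(conc):03d}"
    return TraySimulation(tray_id, conc, config, model, trajectories)


# ---------------------------------------------------------------------------
# Rendering

Frame = tuple[float, np.ndarray, AnnotationRecord]


def _bbox_of_mask(mask: np.ndarray) -> Box:
    rows, cols = np.nonzero(mask)
    return Box.from_corners(cols.min(), rows.min(), cols.max() + 1.0, rows.max() + 1.0)


def _root_pixels(
    start: tuple[float, float],
    heading: float,
    curvature: float,
    length_px: float,
    thickness_px: int,
    shape: tuple[int, int],
) -> np.ndarray:
    """Rasterise a constant-curvature radicle of the given arc length."""
    mask = np.zeros(shape, dtype=bool)
    n_steps = max(1, int(round(length_px)))
    x, y = start
    theta = heading
    radius = thickness_px // 2
    points = [(x, y)]
    for _ in range(n_steps):
        x += math.cos(theta)
        y += math.sin(theta)
        theta += curvature
        points.append((x, y))
    h_img, w_img = shape
    for px, py in points:
        r0, c0 = int(round(py)), int(round(px))
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                if dr * dr + dc * dc <= radius * radius:
                    r, c = r0 + dr, c0 + dc
                    if 0 <= r < h_img and 0 <= c < w_img:
                        mask[r, c] = True
    return mask


def render_frames(
    sim: TraySimulation,
    scene: SceneSpec,
    times: tuple[float, ...] | None = None,
    noise_seed: int = 0,
) -> list[Frame]:
    """Render one tray's frame sequence with exact box annotations.

    Returns ``(time_h, image, record)`` triples.  Seed ellipses are static;
    radicles grow from the ellipse tip along a gently curved arc.  A radicle
    that would leave its grid cell is clipped at the cell budget with a
    warning.  Object classes follow the germination standard: ``S_root``
    while the true root length is below half the seed length, ``L_root``
    from there on.
    """
    config = sim.config
    if times is None:
        times = config.times
    h_img, w_img = scene.image_size(config)
    semi_major = scene.seed_length_px / 2.0
    semi_minor = semi_major * scene.seed_aspect
    half_mm = sim.model.germination_length_mm
    max_len_px = scene.cell_px / 2.0 - semi_major - 2.0

    # static per-seed geometry
    seeds_geom = []
    for traj in sim.trajectories:
        cx = (traj.col + 0.5) * scene.cell_px
        cy = (traj.row + 0.5) * scene.cell_px
        # skimage's rotation is sign-flipped w.r.t. y-down angles
        rr, cc = draw_ellipse(
            cy, cx, semi_minor, semi_major, shape=(h_img, w_img), rotation=-traj.orientation
        )
        ellipse_mask = np.zeros((h_img, w_img), dtype=bool)
        ellipse_mask[rr, cc] = True
        tip = (
            cx + semi_major * math.cos(traj.orientation),
            cy + semi_major * math.sin(traj.orientation),
        )
        seeds_geom.append((traj, ellipse_mask, _bbox_of_mask(ellipse_mask), tip))

    rng = np.random.default_rng(noise_seed)
    frames: list[Frame] = []
    for t in times:
        image = np.full((h_img, w_img), scene.background)
        objects: list[tuple[str, Box]] = []
        for traj, ellipse_mask, seed_box, tip in seeds_geom:
            image[ellipse_mask] = scene.seed_intensity
            objects.append(("seed", seed_box))
            length_mm = traj.root_length_mm(t)
            if length_mm < scene.min_render_length_mm:
                continue
            length_px = length_mm / scene.mm_per_pixel
            if length_px > max_len_px:
                logger.warning(
                    "%s seed (%d,%d): root clipped to cell budget at t=%.1f h",
                    sim.tray_id, traj.row, traj.col, t,
                )
                length_px = max_len_px
            root_mask = _root_pixels(
                tip, traj.orientation, traj.curvature, length_px,
                scene.root_thickness_px, (h_img, w_img),
            )
            root_mask &= ~ellipse_mask
            if not root_mask.any():
                continue
            image[root_mask] = scene.root_intensity
            label = "L_root" if length_mm >= half_mm else "S_root"
            objects.append((label, _bbox_of_mask(root_mask)))
        if scene.noise_sigma > 0:
            image = image + rng.normal(0.0, scene.noise_sigma, size=image.shape)
        image = np.clip(image, 0.0, 1.0)
        record = AnnotationRecord(
            image_id=f"{sim.tray_id}_t{t:05.1f}h".replace(".", "p"),
            image_width=w_img,
            image_height=h_img,
            objects=tuple(objects),
        )
        frames.append((t, image, record))
    return frames


# ---------------------------------------------------------------------------
# Classical reference detector

def reference_detect(
    image: np.ndarray,
    scene: SceneSpec,
    frame_id: str = "",
    threshold: float = 0.3,
    min_component_area: int = 6,
) -> list[Detection]:
    """Threshold / connected-component detector for the synthetic imaging model.

    Each foreground component is split into seed bodies (a morphological
    opening removes the thin radicle; opened regions of at least a third of
    the nominal seed area count as seeds) and the protruding root
    remainder.  The root's length is estimated from its box diagonal,
    corrected for the stroke width, and classified against half the seed
    length; confidence is the region's mean intensity (deterministic).
    """
    binary = image > threshold
    labels = cc_label(binary)
    selem = disk(scene.root_thickness_px // 2 + 1)
    half_mm = scene.seed_length_mm / 2.0
    min_root_area = 2 * scene.root_thickness_px
    semi_major = scene.seed_length_px / 2.0
    min_seed_area = math.pi * semi_major * (semi_major * scene.seed_aspect) / 3.0
    pad = scene.root_thickness_px + 2
    h_img, w_img = image.shape
    detections: list[Detection] = []
    for region in regionprops(labels):
        if region.area < min_component_area:
            continue
        # work in a padded window around the component, not the full image
        r0w = max(0, region.bbox[0] - pad)
        c0w = max(0, region.bbox[1] - pad)
        r1w = min(h_img, region.bbox[2] + pad)
        c1w = min(w_img, region.bbox[3] + pad)
        window = (slice(r0w, r1w), slice(c0w, c1w))
        comp = labels[window] == region.label
        img_win = image[window]
        body = opening(comp, selem)
        seed_bodies = np.zeros_like(comp)
        if body.any():
            body_labels = cc_label(body)
            for br in regionprops(body_labels, intensity_image=img_win):
                if br.area < min_seed_area:
                    continue  # root chunk that survived the opening
                seed_bodies |= body_labels == br.label
                r0, c0, r1, c1 = br.bbox
                conf = float(np.clip(br.intensity_mean, 0.05, 0.99))
                detections.append(
                    Detection(
                        Box.from_corners(c0w + c0, r0w + r0, c0w + c1, r0w + r1),
                        "seed", conf, frame_id,
                    )
                )
        # a 1-px dilation clears the boundary ring the opening leaves behind
        root_mask = comp & ~dilation(seed_bodies, disk(1))
        root_labels = cc_label(root_mask)
        for rp in regionprops(root_labels, intensity_image=img_win):
            if rp.area < min_root_area:
                continue
            r0, c0, r1, c1 = rp.bbox
            box = Box.from_corners(c0w + c0, r0w + r0, c0w + c1, r0w + r1)
            diag_px = math.hypot(box.w, box.h)
            # the stroke width and chord/arc gap inflate the diagonal by
            # roughly (thickness - 0.5) px for the default rendering
            est_len_mm = max(0.0, diag_px - (scene.root_thickness_px - 0.5)) * scene.mm_per_pixel
            label = "L_root" if est_len_mm >= half_mm else "S_root"
            # confidence combines contrast with the S/L classification
            # margin, so near-threshold calls rank low
            margin = min(1.0, abs(est_len_mm - half_mm) / 1.0)
            root_conf = float(np.clip(rp.intensity_mean * (0.5 + 0.5 * margin), 0.05, 0.99))
            detections.append(Detection(box, label, root_conf, frame_id))
    return detections


def detect_tray_timeline(
    sim: TraySimulation,
    scene: SceneSpec,
    times: tuple[float, ...] | None = None,
    noise_seed: int = 0,
) -> GerminationTimeline:
    """simulate -> render -> detect -> timeline closure for one tray."""
    from .det_eval import nms
    from .phenotype import build_timeline

    frames = render_frames(sim, scene, times, noise_seed)
    per_time = {
        t: nms(reference_detect(image, scene, frame_id=record.image_id))
        for t, image, record in frames
    }
    return build_timeline(per_time, sim.config, sim.tray_id, sim.concentration)
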