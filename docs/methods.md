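# Methods

This note records the models, conventions and numerical choices behind
`germkit`, and what the synthetic experiments do and do not establish.

## Box geometry and the loss family

Boxes are closed real rectangles in continuous pixel coordinates, origin
top-left, y down; no half-open pixel semantics enter at the geometry level.
Width and height must be strictly positive — degenerate boxes raise rather
than propagate infinities, including the (unreachable for valid inputs)
zero-size enclosing box.

The six losses share one breakdown computation. CIoU's trade-off weight is
α = v / ((1 − IoU) + v), guarded by ε = 1e-9 and defined as 0 when v = 0,
following the original CIoU formulation. ECIoU is implemented as the single
sum of the CIoU terms and the EIoU edge terms, not as a two-phase schedule
that first optimises CIoU and then switches to EIoU: the staged description
is read as a qualitative account of optimisation dynamics, and a branch
point between "phases" would be arbitrary. GIoU and DIoU follow their
original definitions (GIoU = IoU − |C∖(A∪B)|/|C|; DIoU loss
= 1 − IoU + ρ²/c²); GIoU loss lives in [0, 2], all others in [0, ·).

## The regression harness

`fit_box` parameterises the moving box as (cx, cy, log w, log h) so the
sides stay positive, and descends the chosen loss with central-difference
gradients (h = 1e-4 in parameter space). Plain fixed-step gradient descent
is a poor optimiser for these surfaces: they are piecewise smooth with
ridges and kinks (edge-alignment events), and a fixed step either zigzags
or oscillates without reaching a 1e-3 tolerance. The harness therefore
uses per-parameter sign-adaptive steps (resilient-propagation style:
initial step 0.05, grow ×1.2 while the gradient sign holds, halve on a
flip, capped at 2.0) with a monotone guard — an update is only accepted if
it strictly decreases the loss, with up to 40 halvings of the proposed
step. When no scaling of the gradient ray decreases the loss (GIoU has a
containment plateau whose descent cone is a correlated center-and-size
direction that no single coordinate spans), a pattern search over the 24
coordinate-pair rays ±e_i ± e_j is tried before declaring a stall. The
recorded loss trace is non-increasing by construction and the whole
procedure is deterministic.

Divergence (non-finite loss) is recorded as `converged=False`, never
raised. Random fitting scenarios are unit-scale (target sides in [1, 4],
centers jittered by under half the target size so the pair overlaps),
drawn from an explicit `numpy` generator.

Under these defaults the non-IoU losses reach loss < 1e-3 on ≥95 of 100
random overlapping scenarios within 2000 iterations; GIoU is consistently
the slowest and is the only one that occasionally exhausts the budget,
matching its known slow-convergence behaviour when boxes must be inflated
and then re-shrunk. Plain IoU loss is flat (zero gradient) for disjoint
boxes and correctly reports non-convergence there.

## Coordinate Attention

The block is inference-only math: mean-pool the (C, H, W) input along
width and along height, concatenate the two profiles, apply a shared
C → C/r 1×1 transform with a ReLU (chosen over hard-swish for
determinism and simplicity), split, expand back to C channels per
direction, and squash with a logistic into attention maps a_h (C×H) and
a_w (C×W) that gate the input multiplicatively. Batch normalisation is
omitted (identity at inference; weights are injected, never trained
here). Default reduction ratio r = 32, overridable; weights load from
NPZ or JSON containers for fixtures.

## Detection evaluation

Matching is greedy in descending confidence (stable sort, ties by input
order), never across frames or class labels; a detection is a true
positive when its best-IoU unmatched truth reaches the threshold (default
0.5, the mAP50 convention). AP integrates the non-increasing envelope of
the cumulative precision-recall sequence over every recall step
(all-point interpolation, the modern VOC/YOLO convention); the test-suite
oracle recomputes the same definition by brute-force enumeration.
mAP averages the APs of classes that have ground truth. NMS defaults to
an IoU threshold of 0.7, applied per class and frame. Precision and
recall are defined as 0 when their denominators vanish.

## Vigor indices

Germination is equated with L_root class membership (radicle at least
half the seed length); S_root detections contribute to neither the count
nor root-length statistics. Root length is the detection-box diagonal
scaled by the mm-per-pixel calibration — a deliberate approximation that
under-reads strongly curved roots (the synthetic default curvature keeps
the chord within ~1% of the arc). Root identity is not tracked across
frames: mean root length is a per-frame cross-section over germinated
seeds, 0 mm when none has germinated.

The detected cumulative count per frame is capped at the tray's seed
total (duplicate detections cannot exceed the physical count) and made
monotone by a running maximum, since germination is irreversible and any
decrease is detector flicker. The germination index uses newly germinated
counts G_t (the standard convention for Σ G_t/D_t) with D_t in hours, and
is reported unitless.

## Dataset tooling

VOC corners are treated as 0-based with x2/y2 exclusive-by-value; the
fixed class order is seed=0, S_root=1, L_root=2; YOLO lines print six
decimals. Rotation maps the four box corners and re-encloses them
axis-aligned (detection-style, inflating area at non-axis angles); the
angle convention is screen-clockwise in y-down coordinates, and the image
transform is matched to it (verified by content-centroid tests). Scaling
multiplies coordinates about the origin on a fixed canvas; noise is
seeded Gaussian and leaves boxes untouched. Objects transformed fully
outside the canvas are dropped with a logged warning. The split assigns
floor shares to val and test and the remainder to train (1000 → 700/200/100)
via a seeded shuffle. The acquisition schedule uses the half-open
convention (0, duration]: 96 frames per tray at 30-minute intervals over
48 h, 1728 frames for 6 treatments × 3 replicates.

## Synthetic data: what it emulates

`GrowthModel` encodes the trial's qualitative dose response: germination
probability 0.85 in water, mildly promoted to 0.92 at 30 mmol/L NaCl,
declining monotonically to 0.10 at 150 mmol/L and exactly 0 at ≥160
mmol/L (linear interpolation between anchors). No per-dose probabilities
are published for the real trial; these anchors are generator defaults
chosen to reproduce the reported ordering, not measured values. Radicle
emergence is Normal(26 h, 4 h) truncated positive — "around 24 hours"
with the visible-emergence lag — independent of dose; elongation is
linear at 0.5 mm/h in water, scaled by a dose factor that peaks at 1.08
(30 mmol/L) and falls to 0.45 toward the zero-germination threshold.
Seeds are 8 mm, so the germination standard is a 4 mm radicle.

Rendering places one seed per 80 px cell (0.5 mm/px; 720×720 for a 9×9
tray): a bright ellipse (intensity 0.9, aspect 0.55) with a
constant-curvature radicle stroke (width 3 px, intensity 0.55) on a dark
background (0.08) with optional Gaussian noise (default σ = 0.02).
Radicles shorter than 2 mm stay hidden under the seed coat — unrendered
and unannotated — mirroring the real visibility lag of a just-pierced
testa. A radicle that would leave its cell is clipped at the cell budget
with a warning (it is already L_root by then, so counts are unaffected;
mean root length saturates slightly at late CK time points). Annotation
boxes are exact bounding boxes of the rendered pixel masks.

The reference detector thresholds at 0.3, splits each connected component
into seed bodies (morphological opening with a radius-2 disk removes the
stroke; opened regions under a third of the nominal ellipse area are
treated as root fragments, not seeds) and a root remainder (after a 1 px
dilation of the bodies clears the boundary ring). Root length is
estimated from the remainder's box diagonal minus the empirically
calibrated stroke inflation (thickness − 0.5 px), and classed against
4 mm; confidence is mean intensity scaled by the classification margin,
so near-threshold calls rank low. On rendered frames it achieves mAP50
≈ 0.93–0.97, with S↔L flips of near-threshold radicles the dominant
error.

What passing the synthetic closure shows: the detection, evaluation and
vigor arithmetic are mutually consistent and recover known parameters
through the full image pipeline within binomial sampling error (3 trays ×
81 seeds per dose). What it does not show: performance on real imagery —
the renderer has no specular filter-paper texture, touching seeds,
non-elliptical seed coats, secondary roots, lighting drift, or detector
domain shift; real deployments need a trained detector in place of the
classical reference.

## Problem sizes and runtime choices

The test suite and the acceptance script run the pipeline at a 6-hour
frame interval (8 frames per tray; final-frame rates are unaffected, the
germination index is computed on the same grid for estimate and truth)
and the full 18-tray layout — chosen as the smallest sampling that still
exercises every dose with three replicates. The full 30-minute grid is
available through `ExperimentConfig()` defaults. The oracle suites use
200 random integer box pairs (IoU rasterization at 4 sub-pixels per
pixel) and 100 random ≤6-box detection instances, at tolerances 1e-3 and
1e-9 respectively.

## Known limitations

* The box-diagonal root length is a chord-length proxy; strongly curved
  or S-shaped roots are under-measured by design.
* The germination index depends on the sampling grid; comparisons are
  only meaningful on a common grid.
* GIoU fitting can exhaust the iteration budget on extreme disjoint
  aspect-mismatch scenarios (an optimiser-independent property of its
  plateau structure).
* The L_root count cap at the tray total is a repair for duplicate
  detections, not a deduplication: a frame with one missed and one
  duplicated root can still count correctly for the wrong reason.
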