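"""Dataset construction walk-through: conversion, augmentation, split,
acquisition schedule.

Reproduces the counts of a full salt-stress trial layout: 1458 seeds in
18 trays, 1728 frames at 30-minute intervals, and a 1000-image dataset
split 7:2:1 into 700/200/100.
"""

import numpy as np

from germkit.boxgeom import Box
from germkit.dataset_tools import (
    AnnotationRecord,
    ExperimentConfig,
    acquisition_schedule,
    hflip,
    split_dataset,
    voc_to_yolo,
)

# VOC-corner annotation -> normalised YOLO line
record = AnnotationRecord("img0", 640, 640, (("seed", Box.from_corners(0, 0, 320, 320)),))
print("YOLO line for a quarter-image seed box:", voc_to_yolo(record)[0])

# bbox-aware horizontal flip
image = np.zeros((640, 640))
_, flipped = hflip(image, record)
print("after hflip the box center moves to cx =", flipped.objects[0][1].cx)

# seeded 7:2:1 split of a 1000-image dataset
ids = [f"img{i:04d}" for i in range(1000)]
train, val, test = split_dataset(ids, (7, 2, 1), seed=0)
print(f"split sizes: train={len(train)}, val={len(val)}, test={len(test)}")

# the standard trial layout
config = ExperimentConfig()
schedule = acquisition_schedule(config)
print(f"trial: {config.total_seeds} seeds in {config.n_trays} trays, "
      f"{len(schedule)} frames ({len(config.times)} per tray every "
      f"{config.interval_h} h for {config.duration_h} h)")
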