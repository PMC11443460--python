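"""Score a toy detector run: NMS, matching, precision/recall/AP/mAP50.

One frame, two seeds and one long root in the ground truth; the detector
finds both seeds (one with a duplicate that NMS removes), misses nothing,
and adds one spurious low-confidence root.
"""

from germkit import Box, Detection, GroundTruth, match_and_score, nms

truths = [
    GroundTruth(Box(20, 20, 16, 9), "seed", "f0"),
    GroundTruth(Box(60, 20, 16, 9), "seed", "f0"),
    GroundTruth(Box(32, 40, 20, 6), "L_root", "f0"),
]
raw_detections = [
    Detection(Box(20, 20, 16, 9), "seed", 0.95, "f0"),
    Detection(Box(21, 20, 16, 9), "seed", 0.60, "f0"),   # duplicate
    Detection(Box(60, 21, 16, 9), "seed", 0.90, "f0"),
    Detection(Box(32, 40, 20, 6), "L_root", 0.85, "f0"),
    Detection(Box(90, 90, 10, 4), "L_root", 0.30, "f0"),  # spurious
]

kept = nms(raw_detections, iou_threshold=0.7)
print(f"NMS kept {len(kept)} of {len(raw_detections)} detections")

result = match_and_score(kept, truths, iou_threshold=0.5)
for cls, ce in result.per_class.items():
    print(f"{cls:<7} TP={ce.tp} FP={ce.fp} FN={ce.fn} "
          f"P={ce.precision:.2f} R={ce.recall:.2f} AP={ce.ap:.3f}")
print(f"mAP50 = {result.map50:.3f}")
print()
print("the spurious root ranks below every true positive, so L_root AP")
print("stays 1.0 even though L_root precision is 0.5.")
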