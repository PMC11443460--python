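"""Compare the IoU-family losses on a hand-sized box pair.

Builds a prediction box and a ground-truth box that touch at one corner,
prints every geometric term and all six regression losses.  The ECIoU value
exceeds the CIoU value by the two separate width/height penalties.
"""

from germkit import Box, loss_breakdown

pred = Box.from_corners(0, 0, 2, 2)
truth = Box.from_corners(2, 2, 6, 6)
lb = loss_breakdown(pred, truth)

print(f"prediction {pred.corners}, truth {truth.corners}")
print(f"IoU                = {lb.iou:.4f}   (boxes touch at a corner: no overlap)")
print(f"center distance^2  = {lb.rho2_center:.1f} px^2")
print(f"enclosing diag^2   = {lb.c2:.1f} px^2, c_w = {lb.cw}, c_h = {lb.ch}")
print(f"aspect term v      = {lb.v:.4f}   (same 1:1 aspect ratio -> 0)")
for name in ("iou", "giou", "diou", "ciou", "eiou", "eciou"):
    print(f"loss_{name:<6} = {lb.loss(name):.4f}")
print()
print("eciou - ciou =", f"{lb.loss_eciou - lb.loss_ciou:.4f}",
      "= (h-h_gt)^2/c_h^2 + (w-w_gt)^2/c_w^2 = 4/36 + 4/36")
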