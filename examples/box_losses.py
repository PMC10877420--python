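"""Compare IoU, CIoU and MPDIoU on one predicted/true box pair.

The predicted box (0,0,2,2) and the true box (1,1,3,3) overlap by 1 px^2
out of a 7 px^2 union.  MPDIoU subtracts the squared top-left and
bottom-right corner distances, normalized by the squared image diagonal,
so the same geometric error is penalized more in a small image than a
large one.
"""

from micropest import Box, ImageDims, ciou_loss, iou, mpdiou, mpdiou_loss

pred = Box(0, 0, 2, 2)
truth = Box(1, 1, 3, 3)

print(f"IoU                       : {iou(pred, truth):.6f}")

loss, bd = ciou_loss(pred, truth)
print(f"CIoU loss                 : {loss:.6f}  "
      f"(center term {bd.rho2:.0f}/{bd.c2:.0f}, aspect penalty v={bd.v:.3f})")

for side in (10, 100):
    score, bd = mpdiou(pred, truth, ImageDims(side, side))
    print(f"MPDIoU in a {side:>3}px image   : {score:.6f}  "
          f"(corner penalties {bd.d1_sq:.0f}+{bd.d2_sq:.0f} over {side}^2+{side}^2)")

print(f"MPDIoU loss (10px image)  : {mpdiou_loss(pred, truth, ImageDims(10, 10)):.6f}")
# The corner penalties shrink with image size: the score approaches plain
# IoU (0.142857) as the same 1-px misalignment matters less at 100 px.
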