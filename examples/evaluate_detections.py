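"""Score a toy detector output against ground truth.

Three detections against two ground-truth boxes of class A: a confident
hit, a duplicate (counted as a false positive once the truth is consumed)
and a late hit.  The PR envelope integrates to the class AP.
"""

from micropest import Box, Detection, GroundTruthBox, evaluate

gts = [[GroundTruthBox(Box(10, 10, 30, 30), "A"),
        GroundTruthBox(Box(50, 50, 70, 70), "A")]]
dets = [[Detection(Box(11, 11, 31, 31), "A", 0.95),   # TP
         Detection(Box(12, 9, 32, 29), "A", 0.80),    # duplicate -> FP
         Detection(Box(49, 52, 69, 71), "A", 0.60)]]  # TP

res = evaluate(dets, gts, iou_threshold=0.5)
print(f"TP={res.tp['A']} FP={res.fp['A']} FN={res.fn['A']}")
print(f"precision={res.precision['A']:.3f} recall={res.recall['A']:.3f} "
      f"F1={res.f1['A']:.3f}")
print("PR curve points (recall, precision):",
      [(round(r, 3), round(p, 3)) for r, p in res.pr_curve['A']])
print(f"AP={res.ap_per_class['A']:.4f}  mAP={res.map_value:.4f}")
# AP here is 0.5*1.0 + 0.5*(2/3) = 0.8333: full precision up to recall 0.5,
# then the envelope drops to 2/3 when the second truth is only found after
# a false positive.
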