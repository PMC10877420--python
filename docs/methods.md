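# Methods

This note documents the models implemented in `micropest`, the choices
made where a published formulation leaves details open, what the
synthetic data does and does not emulate, and the numerical conventions
the tests rely on.

## Bounding-box losses

Boxes are axis-aligned rectangles in continuous, 0-based corner
coordinates (x1, y1, x2, y2); all annotation readers normalize to this
form (VOC's 1-based integer corners map to `(xmin−1, ymin−1, xmax, ymax)`).

* **IoU** — intersection over union, with explicit zero-area
  conventions: a zero-area union gives IoU 0, except two identical
  degenerate points, which count as a perfect match.  This avoids 0/0
  without special-casing callers.
* **CIoU loss** — `1 − IoU + ρ²/c² + αv`, where ρ is the center
  distance, c the diagonal of the smallest box enclosing both, `v =
  (4/π²)(arctan(w_gt/h_gt) − arctan(w/h))²` the aspect-ratio penalty and
  `α = v/(1 − IoU + v)` its balance factor.  In the differentiable
  (batched) path α is treated as a constant during backpropagation, the
  standard convention: α exists to weight v, not to be optimized itself.
* **MPDIoU** — `IoU − d₁²/(w²+h²) − d₂²/(w²+h²)` with d₁/d₂ the
  top-left / bottom-right corner distances.  The normalizer (w, h) is
  the **input image** width/height.  The construction leaves this open;
  normalizing by the image diagonal makes each penalty term a
  scale-free quantity in [0, 1] and gives the documented limit behaviour
  (penalties vanish as the image grows around fixed boxes).  The score
  lies in (−2, 1]; its loss `1 − MPDIoU` is zero exactly when the boxes
  coincide and stays informative for disjoint boxes, where plain IoU is
  flat.

Scalar and batched implementations are deliberately separate: the
scalar path is plain float arithmetic used by matching/metrics; the
batched path runs on the autodiff engine and feeds the detector loss.
Tests pin the two against each other and against independently coded
formulas (tolerance 1e-12 scalar, 1e-7 batched) and check analytic
gradients against central differences at 1e-4.

## The autodiff engine

No deep-learning framework is used anywhere; `micropest.nn` is a small
reverse-mode autodiff over numpy float64 arrays: broadcasting
arithmetic, matmul, reductions, shape ops, gather, and grouped 2-D
convolution via im2col.  Elementwise max/min route the gradient to the
winning argument (ties to the first), which makes IoU-style losses
differentiable almost everywhere — the measure-zero tie set is
irrelevant for optimization.  Everything the detector trains through is
finite-difference-checked in the test suite.

## SCConv

The block is `1×1 compress (C→C/2) → SRU → CRU → 1×1 restore → +x`.
Output shape always equals input shape, and zeroing the restore
convolution reduces the block to the identity (pure skip), which is the
ablation oracle in the tests.

**SRU.**  Group normalization (default 4 groups, ε=1e-5) provides
per-channel scales γ.  Channel weight `W_c = |γ_c| / Σ|γ|`; a channel is
*informative* when `W_c ≥ threshold/C`, i.e. its weight reaches
`threshold` times the mean level.  The published construction gives the
separation idea but no explicit cut; the mean-level rule is
parameter-free across widths and the threshold (default 1.0) is
configurable.  The gate uses |γ| so that a large negative scale — which
also carries signal — is not discarded.  The two weighted streams
`W1⊗X` and `W2⊗X` (applied to the normalized features) are each split
into channel halves and cross-added (`X11+X22`, `X21+X12`), then
concatenated.  This requires an even channel count, which the compress
convolution guarantees.  Because W1+W2 = W, reconstruction conserves the
weighted mass exactly — a property test.

**CRU.**  Channels split `split_ratio : 1−split_ratio` (default ½) into
an upper and lower group, each squeezed by a 1×1 convolution (ratio 2).
The rich path is a 3×3 group-wise convolution plus a 1×1 point-wise
convolution, summed; the cheap path concatenates a 1×1 transform with
the untouched squeezed features, the channel plan chosen so both
candidates span all C channels (a mismatch is a configuration error).
Global average pooling gives per-channel scores s₁, s₂; the fusion
weights are the pairwise softmax `β₁ = e^{s₁}/(e^{s₁}+e^{s₂})`,
`β₂ = 1 − β₁`, applied per channel.  β₁+β₂ = 1 holds to machine
precision by construction and is asserted, not assumed.

## Bi-level routing attention

Feature maps are partitioned into S×S non-overlapping regions (H, W must
divide by S).  Queries/keys/values come from bias-free linear maps of
the tokens.  Coarse level: region descriptors are token means; the
affinity `Aʳ = Qʳ(Kʳ)ᵀ` is reduced row-wise to the top-k indices, ties
broken toward the lower region index (stable argsort) so routing is
deterministic.  Fine level: each query region's tokens attend to the
gathered keys/values of its k routed regions with scaled-dot-product
softmax attention — the published sketch omits the softmax and the
1/√d scale, but without them the operator is unbounded, so the standard
form is used.  Local context enhancement is a depth-wise convolution
(kernel 5, configurable) over the value map, added to the attention
output.

Routing indices are computed outside the gradient tape (top-k is
non-differentiable); gradients flow through the gathered keys/values via
a one-hot matmul gather.  Multi-head attention routes per head by
default (a shared-routing variant is available).  Since no grid
placement or (S, k) values are published for the detector, the tiny
model uses S=2, k=4 (all regions) at its 8×8 head resolution — an
implementation default, not a reproduction.

Correctness anchor: with k = S² and LCE zeroed, the layer must equal an
independently coded dense attention to 1e-5 (it agrees to ~1e-16); this
holds across S ∈ {1, 2, 4}.

## Evaluation metrics

Matching is class-aware, greedy in descending confidence, consuming at
most one ground truth per detection at IoU ≥ 0.5 (the threshold is a
parameter; no published matching rule exists to follow).  Conventions
for empty denominators: precision, recall and F1 are 0 when undefined.
AP integrates the precision envelope over recall exactly (all-points
interpolation); the 11-point variant is selectable.  A class with no
ground truth has no AP and is excluded from mAP.  The AP implementation
is pinned against an exhaustive envelope-integral oracle for every
TP/FP pattern up to length 6.

## Data pipeline

The augmentation operators and their default ranges: crop keeping
70–95% of each side; rotation ±30° plus occasional axis rotations
(90/180/270°); local enlargement 1.2–2.0× (zoom into a random window,
resized back); exposure gain 0.5–1.5; Gaussian noise σ 5–20 on the
8-bit scale.  Only the operator *list* is published; these ranges are
chosen as typical moderate photometric/geometric jitter and are fully
configurable.  Geometric operators transform boxes exactly (rotation
takes the axis-aligned hull of the rotated corners, pixels are rotated
with the exact inverse map so boxes and pixels agree); photometric ones
leave boxes untouched.  Boxes are clipped to bounds and dropped below
2 px a side.

Expansion by factor f keeps each original and adds f−1 variants with a
seeded random operator each; 417 originals × 11 = 4,587, matching the
study bookkeeping.  The quality filter flags images whose total box
area is under 20% of the image (the blur criterion was a manual step and
is out of scope).  Splitting apportions each class 6:2:2 by largest
remainder with ties to the earlier partition — the only deterministic
rule consistent with the published per-class sizes (1008 → 605/202/201,
1033 → 620/207/206); membership within the deterministic sizes is
shuffled by seed.

## Synthetic scenes

Scenes emulate the *structure* of the acquisition setting: four pest
classes A–D rendered as ellipse-plus-head blobs with class-specific hue
and eccentricity plus per-instance jitter (similar classes, varied
instances), on leaf-green textured or sticky-board yellow backgrounds,
small relative target size (default 2–8% of the side), global
illumination gain 0.6–1.4, and optional occlusion that hides 20–50% of
a blob's pixels while the annotation keeps the full extent (a partially
hidden insect is still labelled whole).  Everything is deterministic
given the seed; scene i of a dataset uses child seed (seed, i).

What the generator does **not** emulate: insect morphology and texture,
out-of-focus blur, leaf venation, specular highlights, scale variation
from camera distance, or annotation noise.  Passing tests therefore
demonstrate that the algorithms and training loop are correct and can
fit a separable small-object task — not that the tiny detector would
reach any particular accuracy on real macro photographs.

The `easy_config` setting used for smoke training makes the task
separable on purpose: well-spread hues, no occlusion, 16–24 px targets
on a 64 px canvas, mild illumination variation.

## Tiny detector

Stride-8 single-scale anchor head over a three-stage stem
(3→16→32→32 channels, stride-2 3×3 convolutions with GroupNorm+SiLU),
an SCConv block after the middle stage and a BRA layer before the 1×1
head; ~20k parameters.  Two anchors (14×14, 24×24 px) match the easy
scene size range.  Decoding is YOLO-style: sigmoid center offsets within
the cell, width/height = anchor·(2σ(t))² bounded in (0, 4·anchor).
Targets take the cell containing the box center and the best
width/height-IoU anchor, first target winning a contested slot.

Loss: `total = λ_box·mean(ℒ_box) + λ_obj·BCE(objectness) +
λ_cls·BCE(class)` with λ = (0.05, 1.0, 0.5), the conventional weighting
for this family.  Objectness BCE weights positive cells 8× — with ~2
targets per 128 anchor slots an unweighted mean drowns the positive
signal; this balanced form is standard practice.  The objectness bias is
initialized to −3 so the untrained model predicts background.  The
decomposition identity `total = Σ λ_i·component_i` is asserted to 1e-9
at every step.

Training uses Adam (lr 5e-3, batch 4), fully seeded: initialization,
shuffling and the data are reproducible, and identical seeds give
identical loss histories.  Divergence (non-finite loss) aborts with a
diagnostic.  Prediction decodes all anchors, filters by
objectness×class confidence and applies class-wise greedy NMS
(defaults: confidence 0.25 for deployment-style output, 0.1 for mAP
evaluation where recall matters; NMS IoU 0.45).

Problem sizes for the end-to-end checks were chosen as the smallest
that exercise the full pipeline meaningfully: 200 training scenes of
64×64 px, 20 epochs, 50 held-out scenes.  At these sizes the detector
reaches mAP@0.5 ≈ 0.67–0.75 (seed-dependent) with all three loss
components decreasing; the acceptance bar is 0.5.

The loss-variant harness trains MPDIoU and CIoU models from identical
seeds and reports paired box-loss curves and epochs-to-threshold.  The
comparison is qualitative by design: at this scale run-to-run noise is
comparable to the variant effect, so no ordering is asserted.

## Known limitations

* The autodiff engine is eager and unfused; it is sized for 64-px
  inputs and ~10⁴–10⁵ parameters, not for production training.
* Single-scale head only; the full multi-scale detector of the original
  design is out of scope.
* The SRU gate rule and the BRA placement/(S, k) are reasoned defaults
  where the source leaves them unspecified; both are configurable and
  clearly separated from published content above.
* mAP is reported at IoU 0.5 only (no COCO-style 0.5:0.95 averaging).
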