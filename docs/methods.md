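# Methods

## Problem setting

Cucumber seeds germinating in substrate soil are monitored by overhead RGB
imaging of 25 cm dishes holding a 7x7 grid of 49 seeds.  The detection
targets are emerging radicles, annotated in two classes by comparing root
length to the seed body: a root shorter than the seed is `SROOT`, longer is
`LROOT` (ties break toward `SROOT`; the rule is defined only for strict
comparisons).  Soil makes the task hard in ways hydroponic imagery is not:
radicles may burrow and re-emerge (risking repeated identification of one
seed), and the background contains stones with seed-like color and fibers
with radicle-like shape.

The package implements the full pipeline around a lightweight, NMS-free
detection transformer, plus the germination-vigor statistics computed from
its detections.

## Detector

The detector is a set-prediction network in the real-time-DETR mold:

* **Backbone.**  The baseline variant (`baseline_r18`) is a
  ResNet-18-derived feature extractor (7x7 stem, four stages of two
  residual blocks) emitting P3/P4/P5 maps at 1/8, 1/16, 1/32 resolution.
  The lightweight variants replace it with a 2-conv stem followed by three
  stages of ADown downsampling + GELAN aggregation blocks.
* **ADown** halves the spatial extent by a 2x2 average pool, a channel
  split, a stride-2 3x3 conv branch and a 3x3 max-pool + 1x1 conv branch,
  concatenated.  In the `adown` ablation variant the stage-entry strided
  3x3 convs of the ResNet backbone are replaced by ADown operators (with a
  1x1 fuse conv in the deeper stages and the original 1x1 stride-2
  projection kept as the shortcut).
* **GELAN (`RepNCSPELAN4`)** combines a CSP channel split with ELAN-style
  stacking: two chained computation blocks (RepNCSP + 3x3 conv) whose
  intermediate outputs all concatenate into a 1x1 transition.
* **OREPA.**  In the re-parameterizable variants the two trailing 3x3
  convs of every GELAN block are multi-branch linear blocks: a full 3x3
  "origin" conv, a 1x1 conv, a sequential 1x1-to-3x3 pair with `mid`
  internal channels, and a 1x1 conv + 3x3 average pool, each behind a
  per-output-channel scaling vector, summed, batch-normalized, SiLU.
  Because every branch is linear, `squeeze()` collapses the whole block
  into one conv (sequential branches contract over the internal channel,
  parallel branches sum after center-padding kernels to 3x3, scaling and
  normalization fold multiplicatively).  The collapse is performed in
  float64; the measured train-vs-deploy drift is ~1e-6 per block, well
  inside the 1e-4 block / 1e-3 model tolerances asserted in tests.
* **Hybrid encoder.**  One transformer encoder layer (8 heads in 2 groups,
  FFN 928) runs on the flattened P5 tokens with 2-D sine positions; a
  top-down + bottom-up convolutional path (1x1 laterals, stride-2 3x3
  downsamplers, four RepNCSP fusion blocks) fuses P3-P5 at a 256-channel
  common width.
* **Decoder.**  Per-token class logits and anchor-relative boxes are
  predicted over all encoder tokens; the top 300 tokens by best class
  score become queries.  Three pre-norm decoder layers follow, each with
  grouped self-attention, grouped cross-attention over the multi-scale
  memory, and an FFN (1817 wide); a shared head refines boxes in logit
  space layer by layer.  Attention "grouping" evaluates the 8 heads in 2
  independent groups and concatenates — numerically identical to standard
  multi-head attention; it expresses how the computation is distributed.
  Memory keys/values are layer-normalized and projected once, shared by
  all decoder layers (one projection instead of one per layer).  No NMS is
  applied anywhere; post-processing is per-query argmax + threshold.

### Initialization

Convolutions use He-normal initialization (variance 2/fan-in), dense
layers Xavier-uniform, attention output projections zero (each attention
block starts as an identity residual), box-regression output layers zero
(initial boxes coincide with their anchors), and classification biases -4
(a low-probability prior).  These choices matter disproportionately at
desk scale: with them, the query stream stays informative from the first
step instead of collapsing toward a constant.

### Parameter and FLOP accounting

`count_params` sums all trainable arrays of the train-form model (OREPA
branches un-squeezed) and reports millions at one decimal.  `count_flops`
traces one forward pass at the given input size and charges each conv
`2*H*W*(Cin*K^2 + 1)*Cout` at its output resolution (the `+1` bias term is
charged by convention whether or not the conv carries a bias) and each
matmul (attention, linear) 2x its multiply-accumulates; pooling,
normalization and activations are free.  Totals are reported in G at one
decimal.

The published description of the architecture fixes the block topology but
not every internal width (encoder/decoder FFN widths, fusion-block hidden
channels, GELAN stage widths, OREPA branch widths, ADown channel splits).
Those widths are calibrated here so that the variant tags reproduce the
published accounting ladder exactly — 19.8 / 19.2 / 9.1 / 14.1 M
parameters and 56.9 / 34.9 G FLOPs at 640x640 — and they are frozen as the
package defaults.  The ladder is therefore the definition of the variants,
not an empirical result.  One printed inconsistency is inherited
knowingly: the source table lists a different FLOP value for the
OREPA-augmented ablation row than for the final model although the only
difference (the NWD loss term) cannot change inference cost; the final
model's 34.9 G is the value targeted here.

## Objective

Predictions are matched one-to-one to ground truth per decoder stage by
Hungarian assignment under

    cost = 2 (1 - p_class) + 5 L1(box) + 0.5 [ r (1 - NWD) + (1 - r)(1 - GIoU) ]

with `r = 0.5` by default; the same blended box term (plus L1) forms the
box loss of matched pairs, and the 0.5 box gain mirrors the canonical
training configuration.  NWD embeds a box as the Gaussian
N((cx, cy), diag(w^2/4, h^2/4)); for axis-aligned Gaussians the squared
2-Wasserstein distance is the squared Euclidean distance between
(cx, cy, w/2, h/2) vectors, and the similarity is `exp(-sqrt(W2^2)/C)`
with `C = 12.8` by default.  The square-root form is the default because
it is the unit-consistent distance and because the package's own reference
values (`exp(-5)`, `exp(-sqrt 2)`) require it; the literal squared form is
available via `squared_exponent=True`.  NWD participates in the matching
cost as well as the loss (switchable, `nwd_in_matching`).  Classification
uses a varifocal-style IoU-aware binary cross-entropy: matched queries
carry their (clipped) IoU as a soft target with weight equal to the
target; negatives are weighted `0.75 p^2`.

## Evaluation

Greedy confidence-ordered matching at IoU >= threshold, class-aware, each
ground truth consumed at most once.  Precision uses the convention P = 1
when nothing was predicted; recall is 0 when there are no positives.  AP
is the 101-point interpolated area under the precision-recall envelope
(COCO convention; the IoU grid for mAP@[0.5:0.95] is 0.50:0.05:0.95), and
the implementation is tested to 1e-9 against a brute-force envelope
enumeration on a thousand random detection sets.  The error taxonomy
separates a detection re-hitting a consumed ground truth ("repeated") from
an unlocalized detection ("false alarm"); both still count as FP in
precision/recall/AP, and missed = FN, so the taxonomy components always
sum to the matcher's FP + FN.  The confusion matrix assigns same-class
matches first, then allows remaining detections to claim remaining ground
truths across classes (off-diagonal cells); row/column sums remain
consistent with the class-aware TP/FP/FN by construction.

## Germination statistics

Germination rate is `100 N_t / N` percent; the germination index is
`sum_t G_t / D_t` with `G_t` the seeds newly germinated on day `D_t` — the
formula form is used throughout (the prose "total germinated over total
days" paraphrase conflicts with it and loses the early-germination
weighting that makes the index a vigor measure).  Detections become
per-seed events by snapping each box center to the nearest dish-grid cell
center (ties to the lower row-major index); a seed is germinated from the
first above-threshold root-class detection in its cell and stays so —
`N_t` counts distinct seeds, never raw detections, which is exactly the
dedup the repeated-identification problem demands.  A class upgrade
(SROOT to LROOT) never changes germination status.

## Synthetic scenes

The generator emulates the acquisition setting: dark brown soil built from
a base color plus band-limited Gaussian noise (sigma 6 px) and fine pixel
noise; bright mottled stone ellipses (colors near seed color) and thin
pale fiber curves (colors near radicle color) as distractors; elliptical
seeds (default 26-40 px long at 640x640, aspect 0.45) on a jittered 7x7
grid; quadratic-Bezier radicles of 0.3-2.2 seed lengths for the germinated
fraction (default 0.6); buried segments alpha-blended into the soil with
probability 0.2.  Annotation boxes cover the seed body plus the visible
radicle extent (configurable to root-only; the box-extent convention is
not fixed by the annotation rule, which defines classes, not boxes), and
the class always follows the true root length — matching what a human
annotator watching the dish would know, and enabling the buried-root
invariants to be asserted from stored truth.  Scenes are bit-reproducible
from their parameter set, and `generate_dataset` records per-image child
seeds in a manifest so any image can be regenerated exactly.  The 7:2:1
train/test/val split is image-level (largest-remainder apportionment, so
1000 images give exactly 700/200/100); the middle share is the test set,
following the order in which the splits are named.

What the generator does **not** model: real soil texture statistics,
lighting variation, hypocotyl/cotyledon stages, seed burrowing dynamics,
camera noise.  Tests passing on synthetic scenes therefore demonstrate
the correctness of the pipeline's logic (labeling, geometry, bookkeeping,
optimization) — not field performance on real dishes.

## Augmentation

Four mild photometric transforms fire independently per call: box blur
(kernel <= 5), median blur, CLAHE (clip limit 4 on the 8-bit scale), and
grayscale (luminance replicated to 3 channels so the network input stays
3-channel).  Only the blur probability (1%) is canonical; the other three
default to the same rate.  All four preserve geometry, so boxes pass
through untouched; geometric and destructive augmentations (mosaic,
pixelation) are deliberately absent because partially buried radicles do
not survive them.  Augmentation applies to the training split only.

## Training and the smoke setting

Full-scale training follows the canonical configuration (100 epochs,
batch 4, 640x640, box gain 0.5, workers 4, cache off, no pretrained
weights) with AdamW (lr 1e-4, weight decay 1e-4, global gradient-norm
clip 0.1); it is supported but GPU-scale.  The desk-scale smoke setting —
the configuration the test suite exercises — is deliberately easy: 50
training scenes at 160x160 with a 3x3 grid of large (26-34 px), fully
germinated, unburied, short-root seeds (so one class is present and box
sizes are uniform), model at 60 queries, batch 1, lr 7e-4, 3 epochs.
Under it, CPU training shows a monotone drop in total loss and reaches
mAP@0.5 of roughly 0.4 on a held-out synthetic split in a few minutes.
That demonstrates the loop (augment -> forward -> match -> loss ->
backward -> update -> evaluate) optimizes end to end; it says nothing
about converged accuracy.  Training is deterministic given the seed;
checkpoints restore bit-identical weights.

## Numerical conventions and degenerate inputs

* OREPA squeeze and conv+norm fusion compose kernels in float64, cast to
  float32; equivalence tolerances: 1e-4 per block, 1e-3 full model.
* `label_root_class` rejects non-positive lengths; equal lengths are SROOT.
* AP with no ground truth returns NaN with a warning; mAP with no classes
  raises.
* An empty target list leaves all queries background; an empty batch gives
  zero loss with a warning.
* Detections centered outside the unit square are logged and dropped
  before seed assignment.
* Double re-parameterization and double squeezing are warning no-ops.
* All randomness flows from explicit integer seeds (numpy Generators); the
  parameter-initialization stream is seeded per model build.

## Known limitations

* The NN core is a compact numpy autodiff engine; it is single-device,
  eager, and unoptimized compared to mainstream frameworks — adequate for
  desk-scale training and inference, not for 100-epoch full-resolution
  runs.
* Accounting calibration pins widths to the published ladder; other width
  assignments reproduce the same totals, so the variants should be read as
  one consistent realization, not a unique reconstruction.
* The smoke mAP criterion is stochastic; it is pinned to a fixed seed.
* `workers` is accepted for configuration compatibility; data loading is
  in-process regardless.
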