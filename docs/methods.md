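# Methods

## Scope and model

The package reimplements the YOLO-IFSC broiler-face identification
architecture and its study pipeline in numpy. The detector is a one-stage,
anchor-free network: an n-scale YOLOv11 baseline (depth multiple 0.50,
width multiple 0.25, widths capped at 256) whose graph is declared as a
24-layer table in `yolo_ifsc.network.BASE_LAYERS`; named variants replace
blocks at fixed 0-based layer indices. Identity recognition is cast as
24-class detection: each bird is one class, and mAP@0.5 over those classes
is the headline metric.

### Placement of the substituted blocks

Published descriptions of the layer indices are not mutually consistent
under a single numbering, so the registry fixes one concrete mapping and
documents it:

- Inception-F, Position 1: the three stride-2 backbone downsampling
  convolutions (layers 3, 5, 7). The block is built in a stride-2 form
  there (all five paths downsample); its default form is stride 1 and
  preserves spatial size, which is what the block-level tests exercise.
  This is the only placement at which the published Position-1 parameter
  total (≈2.11 M, a ≈0.5 M drop from baseline) is reachable: the backbone
  C3k2 feature blocks together hold only ≈0.12 M parameters, so replacing
  those could never shed that much.
- Inception-F, Position 2: the two neck C3k2 blocks that directly follow a
  concatenation and are not claimed by C2f-Faster (layers 16 and 22).
- C2f-Faster, Position 2 (the configuration used in the combined models):
  neck C3k2 blocks at layers 13 and 19. Position 1 (backbone layers 2 and
  4) is registered for completeness.
- SPPELANF replaces SPPF at layer 9; CBAM replaces C2PSA at layer 10.

### Block hyperparameters

Several interior widths of the bespoke blocks are free design parameters.
They were fixed once, by calibrating against the published per-variant
complexity budget of the original design (parameter totals to ±0.05 M,
FLOPs to ±0.2 G), and are frozen as package defaults:

- **Inception-F**: every path runs at the input width and ends in a grouped
  1×1 projection to the output width. Backbone placements use strongly
  grouped projections (`pw_groups = r3_groups = 32`, clamped to divide the
  channel counts) — there the block is nearly parameter-free, which is what
  makes Position 1 a ≈0.46 M saving. The neck placements sit after channel
  concatenations and keep denser mixing (groups 2, and 4 for the grouped
  path at layer 22). R1 is a 3×3 depthwise conv with dilation 2 (padding
  2·stride-matched); R2 a 5×5 depthwise conv, also dilation 2 (padding 4) —
  the dilation is applied to both paths; R4/R5 use 3×3 max/average pooling
  (stride follows the block). Fusion logits are zero-initialised so the
  block starts as an unbiased average; softmax runs over the active paths
  only (3 for variant A, 4 for B, 5 for F).
- **C2f-Faster**: hidden ratio e inherits the replaced stage's value
  (0.5 in the neck); the bottleneck is PConv(P = 1/4) → 1×1 reduce (0.5×)
  → 1×1 project, plus the residual. The reducing (rather than expanding)
  pointwise pair keeps the block inside the published parameter/FLOP budget
  of the Position-2 model.
- **SPPELANF**: intermediate width c\* = C_in/16. The cross-layer 1×1
  fusion convs and the final projection are what distinguish it from SPPF;
  a narrow c\* is the only regime in which the block family stays at or
  below SPPF's cost, as the published totals require (see "Known
  conflicts"). Interior CBS units use LeakyReLU (slope 0.1); all other CBS
  units use SiLU.
- **CBAM**: reduction ratio 16 (the conventional default), shared two-layer
  MLP with ReLU between layers, 7×7 spatial conv.

## Complexity accounting

Parameters are counted by exact enumeration of learnable arrays
(convolution kernels, biases, BN scale/shift, fusion logits); analytic
per-layer formulas are cross-checked against this enumeration in the test
suite. Conv+BN stacks carry no conv bias, so a CBS unit holds
k²·C_in/g·C_out + 2·C_out learnable scalars.

FLOPs are counted at a stated input size with one global convention: 2
FLOPs per multiply–accumulate for convolutions and attention matrix
products, 2 FLOPs per element for normalisation, 1 per element for
activations, k² comparison ops per output element for pooling; residual
additions and fusion weighting are ignored. PConv is booked at the
fraction P of the equivalent full convolution
(K_h·K_w·C_in·C_out·H·W·P) — the standard complexity claim for partial
convolution, and the convention under which its cost ratio to a full conv
is exactly P. The MAC→FLOP factor of 2 is a single constant, never tuned
per variant.

### Known conflicts in the published totals

The published per-variant tables are not mutually additive (the
single-module deltas for the pooling and attention substitutions disagree
with the ablation-ladder deltas by up to 0.05 M), and the pooling row is
structurally impossible at face value: SPPELANF with c\* = C_in/2 is a
strict superset of SPPF's convolutions, yet the published row shows a
0.20 M *decrease* against a baseline whose entire SPPF holds 0.165 M. The
package resolves this by the narrow-c\* design above, which reproduces
every published total within ±0.05 M / ±0.2 G simultaneously. The
baseline's FLOP total is similarly pinned: the C2f-Faster band forces the
baseline into 6.4–6.45 G under any single global convention, so the
package reports 6.4 G against the published 6.6 G (inside the ±0.2 G
band at its edge).

## Detection head, loss and training

The head is decoupled and anchor-free with a 16-bin discretised distance
distribution per box side; decoding takes the softmax expectation of the
bins at each cell, offsets from the cell centre, scales by the stride, and
applies class-wise greedy NMS (IoU 0.45, confidence 0.25 by default;
deterministic tie-break by confidence, then box area, then input order).

The loss is the standard three-term composite: complete-IoU box regression,
per-class binary cross-entropy over all anchors, and a two-bin interpolated
distribution-focal term, with gains 7.5/0.5/1.5 and normalisation by the
number of positive anchors. Assignment uses a centre prior — each ground
truth claims the cell containing its centre at every scale where the cell
centre falls inside the box. This is simpler than task-aligned assignment
(which weights candidates by a classification–IoU alignment score); on the
small synthetic corpora used here the centre prior is more stable because
an untrained classifier provides no useful alignment signal. The
classifier's final bias is initialised to −4 so the initial objectness
prior is low.

Training is momentum-SGD (0.937) with weight decay 5e-4 and a linear
learning-rate decay from lr0 = 0.01 to lr0·lrf = 1e-4 over the epoch
budget. Every random draw (weight init, shuffling, scene generation) flows
from explicit seeds, so a configuration reproduces its loss curve exactly.

Problem sizes: the packaged smoke experiment trains the IFSC variant for 30
epochs on a 120-image synthetic corpus (72/24/24 train/val/test) at
160×160 input, batch 16 — a scale chosen so the full loop (including
per-epoch validation mAP) completes in minutes on one CPU core while still
showing clear learning (losses fall monotonically; validation mAP@0.5
rises from zero). These runs demonstrate the machinery, not the published
real-data accuracy; see Limitations.

## Metrics

Matching is greedy per class: detections in descending confidence order,
each matched to the unmatched ground truth with the highest IoU ≥ 0.5
(ties: smaller ground-truth index); unmatched detections are false
positives, unmatched ground truths false negatives. AP is the exact area
under the monotone (right-to-left cummax) precision envelope over the
recall sweep — the continuous integral, not 11- or 101-point
interpolation — and mAP is the arithmetic mean over classes with at least
one ground truth (empty classes are excluded with a warning). F1 is the
harmonic mean of P and R with 0/0 ≡ 0; published F1 columns for this
architecture are not always the harmonic mean of the printed P and R
(they appear to come from a different operating point), so agreement there
is treated as a consistency check, not an identity.

## Synthetic data

Real recordings of the tagged flock are not redistributable, so the
generator emulates their annotated structure: 640×640 scenes on a textured
litter background, 2–6 birds per image (uniform), each a white ellipse
cluster with a face disc, comb, eyes in the upper third, beak, and a 2×2
coloured tag glyph (8-colour palette, 64 codes for 24 identities) standing
in for the coloured neck tags; tight face boxes include comb and glyph.
Pairwise box overlap is capped (default IoU ≤ 0.15, with bounded retries),
and roughly half the scenes get darkened vertical cage-bar stripes.
Identity coverage is constructive: all 24 identities cycle through every
split.

What the generator does **not** emulate: real feather texture, pose and
viewpoint variation, motion blur, lighting gradients, or inter-individual
facial similarity. Passing tests on this material demonstrates that the
pipeline (annotation flow, training dynamics, metric computation,
occlusion bookkeeping) is correct — not that the detector would reach any
particular accuracy on real poultry imagery.

### Progressive occlusion

One uniform dark-grey (40, 40, 40) rectangle per selected face box,
emulating cage bars/feeders: level 1 confined to the periocular zone
(upper third of the box), covering ≤ 10 % of the box with zero overflow;
level 2 spanning the eye/cheek band (upper ~45 %), covering 20 ± 3 %, with
horizontal overflow past the box allowed and capped at half the box width
(the original protocol leaves the overflow magnitude unbounded); level 3
centred, covering 50 ± 5 % with at most 5 % of the occluder outside the
box. Rectangle dimensions are corrected by an integer trim/grow loop so
the *pixel-counted* coverage — not the real-valued target — lands inside
the band; boxes smaller than 4 px cannot satisfy the bands and are
rejected.

## Dataset pipeline

- SSIM filtering is streaming: frame i is kept iff its grayscale windowed
  SSIM against the last *kept* frame is below the threshold (0.65); the
  first frame is always kept. This makes the filter idempotent.
- Stratified splitting draws the test set first, then validation from the
  remainder, with largest-remainder proportional allocation per stratum
  (which provably never over-draws a stratum; a defensive shrink-with-
  warning path remains for exotic allocators).
- Augmentation draws one of three strategies per derivative: rotation in
  ±45° (boxes replaced by the clipped axis-aligned hull of their rotated
  corners; hulls below 20 % of the original box area are dropped, and a
  derivative that loses all its boxes is redrawn), salt-and-pepper noise
  at 0.5–3 % density (exactly ⌈d·H·W⌋ pixels, sampled without
  replacement, set to 0 or 255), and gamma γ ∈ [0.5, 1.5] with HSV value
  scaling ±20 %. Noise and photometric derivatives reuse the source
  annotations verbatim.
- Note that rotating a box to its axis-aligned hull and back is *not* an
  involution — hulls inflate — so round-trip tests assert centre recovery
  and containment rather than exact box recovery.

## Numerical choices

Float32 throughout; sigmoid/SiLU inputs clipped at ±60 before
exponentiation; log-softmax computed via a detached max shift; BCE with
logits in the standard stable form. Max-pool backward routes the gradient
to the argmax element (first index on ties) — chained 5×5 pools therefore
disagree with finite differences at tie plateaus, which is the standard
subgradient choice, and gradient tests avoid those configurations.
Convolutions run as im2col + batched GEMM with fast paths for 1×1
(pure matmul) and depthwise kernels.

## Limitations

- The published real-data results (91.5 % mAP@0.5, P/R/F1 columns, FPS and
  embedded-platform figures) are out of reach by construction: the real
  dataset is not public and the published training budget is 500 GPU
  epochs. Nothing in this package claims those numbers.
- The numpy engine is single-threaded BLAS-bound; it is meant for
  correctness and desk-scale experiments, not production training.
- Inception-F's stride-2 backbone form and the narrow SPPELANF width are
  calibrated design choices (see above); other choices satisfying the same
  published budgets may exist.
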