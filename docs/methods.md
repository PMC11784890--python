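# Methods

This note records the models, conventions and design decisions behind
`cropdet`, in the order a reader meets them: the box-loss family, the
re-parameterizable blocks, the feature operators, the detector assembly,
evaluation, the synthetic-data model, and the numerical/engineering
choices. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Box losses

All losses take corner-format boxes `(x1, y1, x2, y2)` and are
differentiable through the package's autodiff tensors, so the same code is
used for scalar evaluation, the convergence harness and detector training.

**IoU / GIoU.** IoU is intersection over union with the denominator
guarded by `max(union, eps)` so that `iou(a, a) == 1` exactly and a pair of
zero-area boxes scores 0 by convention. GIoU subtracts the normalized dead
area of the smallest enclosing box; a degenerate enclosing box makes the
penalty 0, so GIoU falls back to IoU.

**EIoU.** `1 − IoU` plus three penalties — squared centre distance over the
enclosing diagonal, and squared width/height differences over the squared
enclosing width/height — each in [0, 1].

**SIoU.** The angle term is read as
`Λ = 1 − 2 sin²(arcsin(c_h/σ) − π/4)` with `c_h` the centre *y*-offset and
`σ` the centre distance; the distance term
`Δ = Σ_t (1 − e^{−γρ_t})`, `γ = 2 − Λ`, uses `ρ_x = (Δc_x / C_w)²` with
`C_w, C_h` the *enclosing-box* width/height (the reading consistent with
the loss's published worked values; the centre-offset reading would make
`ρ` identically 1). The shape term uses exponent 4. At coincident centres
(`σ < eps`) both `Λ` and `ρ` are defined as 0, removing the 0/0.

**Inner-IoU.** IoU of both boxes rescaled about their own centres by a
ratio (> 0); ratio 1 reduces exactly to IoU. Default ratio 1.0; sensible
range 0.5–1.5.

**SIMIoU.** Coordinates are first normalized by the image extent, after
which the image has unit height and width. The canonical form is
`1 − inner^θ + (d1/2 + d2/2)^θ + ½αγ` with `d1`/`d2` the squared distances
between upper-left/lower-right corners. A variant normalizing the corner
term by `(h² + w²)` and `(hw)` — which degenerate to 2 and 1 after
normalization — is exposed via `corner_norm="shape"`; the half/half form is
canonical because it is the stated total loss. `α` is defined as 0 when
`γ = 0` and IoU = 1 (perfect match), removing that 0/0. `θ` defaults to 1
and is configurable; no published value exists for it or for the inner
ratio.

Degenerate-input policy throughout: `eps = 1e-9` guards every denominator;
identity pairs score exactly 0 on every loss (this is asserted exactly, not
to a tolerance).

## Re-parameterization (CFB)

`DBBConv` trains four parallel branches — main 3×3, 1×1, 1×1→3×3, and a
3×3 stride-1 average pool — each ending in its own batch norm, summed
before the SiLU activation. Fusion folds each branch to an equivalent 3×3
kernel + bias (BN→conv folding; 1×1 embedded at the kernel centre; the
average pool as a channel-diagonal uniform kernel; the 1×1→3×3 pair by
channel composition) and sums them. Two details make fusion *exact* rather
than approximate:

* the sequential branch pads its intermediate map with the 1×1 stage's own
  BN bias (a `PadWithBias` layer), which is what makes the two-conv
  composition hold at borders;
* equivalence holds in eval mode (running BN statistics); fusion arithmetic
  is carried out in float64 regardless of the model dtype.

Stride-2 placements drop the average-pool branch (pooling with stride 2
has no 3×3-kernel equivalent); the blocks used inside C2f bottlenecks are
always stride 1. `CFB` is the C2f block with both bottleneck convolutions
replaced by `DBBConv`s (a `diverse="first"` flag restricts it to the first
conv; both is the default). Fusion is idempotent, and the deploy-mode
parameter count equals a plain 3×3 conv with bias.

Parameter-count comparisons between fused and plain models are made with
both sides in deploy form (`count_parameters(model, "deploy")` folds every
conv+BN pair). In train form a plain block carries BN affine pairs where
the fused block carries conv biases — a few hundred parameters that would
spoil the "exactly equal" claim without reflecting any real difference at
deployment.

## Feature operators

**CARAFE** (defaults: 64 compressed channels, 3×3 encoder, 5×5 reassembly
kernel, scale 2 — the operator's canonical settings; the architecture only
names the operator): a 1×1 compressor and a small encoder predict
`scale²·k_up²` logits per location, pixel-shuffled to output resolution and
softmax-normalized, so every output cell is a convex combination of its
source neighborhood. Neighborhoods are edge-replicated at borders, which
preserves the convexity bound (output extremes never exceed source
extremes) and makes constant inputs exactly invariant.

**FEM/FSM** (the lateral-branch enhancer): the map is average-pooled along
height and along width; the two directional channel descriptors are
concatenated (2C) and squeezed through a shared bottleneck (reduction 4,
ReLU) into a per-channel sigmoid gate in (0, 1); the gated values are added
residually (`x + g⊙x`) and a channel-preserving 1×1 conv+BN screens the
result. Average pooling and the logistic gate are package choices — the
operator's description names neither — and the final projection preserves
the channel count.

**Positional code**: fixed 2-D sine/cosine embedding, channels split into
x-sin/x-cos/y-sin/y-cos quarters, temperature 10 000 (transformer
convention).

## Detector assembly

The backbone follows the YOLOv8 layout — stride-2 conv stem, alternating
stride-2 convs and C2f stages with depths (3, 6, 6, 3) and channels
(64, 128, 256, 512, 512) at L scale, SPPF on top — and emits strides
8/16/32. "Stage 2" and "stage 6" (the ten-layer indexing of that layout)
are the C2f blocks replaced by CFB. The head projects all three maps to a
256-d hidden space, applies one transformer encoder layer (AIFI, 8 heads,
FFN 1024) to the stride-32 map with the 2-D positional code, fuses
top-down and bottom-up through RepC3-style fusion blocks (depth 3 at L
scale), and decodes with six decoder layers over 300 queries. Each decoder
layer does self-attention (queries + a position embedding derived from the
current reference boxes by a small MLP), cross-attention over the
concatenated multi-scale tokens, and an FFN; per-layer heads emit class
logits and sigmoid-space box refinements, with references detached between
layers (the initial learned anchor grid stays trainable through layer 1).
Deep supervision applies the loss at all six layers. Inference takes the
top-k scoring (query, class) pairs — no NMS.

Decoder cross-attention is standard dense multi-head attention rather than
multi-scale deformable attention. The source architecture says nothing
about decoder internals beyond the layer count; dense attention is exact,
simple to differentiate, and cheap at the scales this package actually
runs (the full-scale model is built for parameter accounting, not
forward passes). Denoising queries and encoder-side query selection are
deliberately not implemented — nothing indicates the original used them —
which is one reason exact parameter-count matching cannot be guaranteed.

**Parameter accounting.** The published sizes are 37.67 M for the plain
hybrid (RTYO) and 38.14 M with the LFPN. The exact channel widths of the
hybrid are unpublished; this reconstruction pins them by the two
conventions it combines (YOLOv8-L backbone widths; 256-d RT-DETR-L-style
head) and achieves 37.69 M and 38.19 M (deploy form, 5 classes) — within
0.2 % — with the CFB variant fusing back to the baseline count exactly,
and the LFPN adding 0.49 M (two CARAFE upsamplers at 74 k each and three
FEM gates at 116 k each) against the published delta of 0.47 M.
`scripts/acceptance.py` recomputes all four counts.

**Matching and training.** Queries are assigned to ground truth per
decoder layer by the Hungarian algorithm (scipy's
`linear_sum_assignment`) on the DETR-family cost
`2·focal-style class cost + 5·L1(cxcywh) + 2·(1 − GIoU)`. The training
loss is sigmoid focal classification (α 0.25, γ 2) over all queries plus
L1 and the configured box loss (SIMIoU by default) on matched pairs,
normalized by match count and averaged over the batch, summed over layers.
Default optimizer settings follow the reference training recipe: AdamW,
lr 1e-4, weight decay 1e-4, 2000 warm-up steps, batch 4, 640×640 input,
seed 0. A single integer seed drives initialization, batch order and data
generation.

## Evaluation

Greedy score-ordered matching (highest-IoU tie-break, each ground truth
consumed once), precision `TP/(TP+FP)` and recall `TP/(TP+FN)` with 0/0
defined as 0, 101-point interpolated AP (precision envelope sampled on the
recall grid 0:0.01:1; a continuous trapezoid variant is switchable), mAP
as the mean of per-class APs over IoU 0.5:0.05:0.95. Classes with zero
ground-truth instances are excluded from the means — relevant because the
emulated survey's rarest class has tens of instances against hundreds of
thousands. The confusion matrix matches class-agnostically at IoU 0.5 with
a 0.25 score threshold (both configurable), sending unmatched ground truth
to a background column and unmatched detections to a background row. The
test suite checks the evaluator against an independently coded oracle
(shapely geometry, explicit P-R sweep) to 1e-4.

## Synthetic scenes

The generator emulates the structure of an oil-palm UAV survey rather than
its appearance: a planting grid (default pitch 64 px with 8 px jitter) of
procedural canopy blobs in five classes sampled from the survey's
training-split shares (healthy 0.766, small 0.216, yellow 0.0118, grass
0.0036, dead 0.0023; a validation-share variant is available). Canopy
radii are Gaussian (mean 13 px, sd 3) with a separate small-class mode
(mean 7 px, sd 1.5), so well over 30 % of boxes fall under 32×32 px — the
small-object regime of interest. Class-conditioned hue, an irregular rim
for the grass class, a random-orientation illumination ramp (amplitude
0.25) and Gaussian sensor noise (sd 4 of 255) provide nuisance variation.
Annotations are emitted by the renderer from its own pixel mask, so boxes
are tight by construction. The whole dataset is a pure function of
(spec, seed), byte-identical on rerun.

What this does *not* emulate: real canopy texture, inter-crown occlusion
geometry, perspective and altitude variation, or within-class appearance
continua. Passing tests therefore demonstrate that the pipeline learns and
evaluates correctly on data with the survey's *statistical* structure, not
that it reaches any particular accuracy on real UAV imagery.

One inconsistency in the reference survey's instance table is resolved in
the generator's favour: the printed class counts sum to 262 851, not the
printed 262 811 total, so shares are normalized by the component sum
(which still reproduces the quoted 0.766 / 0.00228 shares).

## Convergence harness

`loss_convergence_sim` regresses seeded random boxes (centres in
[0.2, 0.8], sides in [0.1, 0.4] of the unit square) onto random targets by
gradient descent in `(cx, cy, log w, log h)` — the log-size
parameterization keeps sides positive and tames the 1/w gradient of small
boxes — with a constant step of 0.05, reporting median steps to IoU ≥ 0.99,
mean final loss, and failure rate at a 2000-step cap. Under a constant
step, a loss whose gradient magnitude does not shrink as the optimum is
approached (GIoU's overlap term) makes the iterate orbit rather than
settle, while SIMIoU's corner term vanishes smoothly at the optimum and
lets the iterate come to rest: this is the stationarity difference the
harness is designed to expose, and the failure-rate column reports it
directly. An `invsqrt` schedule (step/√t), under which every loss in the
family converges, is provided for completeness.

## Numerical and engineering choices

* The package runs on its own reverse-mode autodiff engine (`cropdet.nn`):
  NumPy arrays with a recorded tape, im2col convolutions, pooling,
  attention and layer/batch norm. Gradients of every operator are checked
  against central finite differences in the test suite.
* Float64 is the default and is used for all exactness-sensitive work
  (fusion, losses, oracles). Training casts the model to float32
  (`set_default_dtype` + `Module.astype`), roughly quartering step time on
  CPU; BN statistics follow the model dtype.
* BN: eps 1e-5, momentum 0.1; eval mode uses running statistics (fusion
  equivalence is an eval-mode statement).
* Elementwise `max`/`min` use an even subgradient split at ties.
* Initialization: He for convs, uniform fan-in for linear layers, class
  heads biased to a 1 % positive prior (focal convention), final box-head
  layers zero-initialized so refinement starts from the anchors.
* The trainability check ("overfit smoke") uses a tiny-width preset
  (channels 8–48, hidden 32, 30 queries) on 8 two-class 160×160 scenes,
  300 AdamW steps at lr 1e-3 with 50 warm-up steps, batch 4 — sizes chosen
  so the whole check is a few CPU-minutes. It reaches train-set AP50 ≥ 0.5
  from a fixed seed; this validates the training loop end to end, nothing
  more.
* Checkpoints are NumPy `.npz` archives of the state dict plus a JSON
  metadata entry (model size, variant flags, deployed flag); `cropdet
  fuse` reads a train-form checkpoint and writes the fused deploy form.

## Known limitations

* No GPU path, no mixed precision, no data augmentation; the engine is
  CPU-bound and intended for desk-scale verification, not production
  training.
* Dense decoder attention scales quadratically with token count; at
  640×640 the full-scale model is for parameter accounting and small-crop
  inference, not high-throughput detection.
* Accuracy figures on real UAV surveys are out of reach by construction
  (no real data ships with the package); the synthetic results bound
  correctness, not field performance.
* FLOPs are not reported: no consistent counting convention exists for
  the mixed conv/attention stack, and none was published to match.
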