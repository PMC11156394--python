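# Methods

This note records the models and procedures implemented in `pestdet`, the
parameters that matter, the numerical choices, and what the synthetic data
does and does not establish.

## Problem setting

Field photographs of crop pests combine three difficulties: many species
with long-tailed label counts, targets whose body size spans roughly an
order of magnitude within one image, and dense clusters of individuals.
The package implements a two-stage detector shaped by those difficulties —
a hierarchical windowed-attention backbone for multi-scale features, a
neighborhood self-attention neck that sharpens per-level features before
pyramid fusion, cascade refinement heads, and score-decaying suppression —
plus the data-side response to imbalance: offline copy-paste expansion.

## Numerical stack

No deep-learning framework is used: the package carries its own
reverse-mode autodiff over float32 numpy arrays (`pestdet._tensor`), with
layers, SGD-with-momentum and weight decay in `pestdet.nn`. Layers operate
on single channels-last images; batching is gradient accumulation, which
preserves effective-batch semantics exactly (the per-step update is the
mean of per-image gradients). Convolutions are gather + matmul; their
backward pass scatter-adds through the gather indices. Gradient checks
against central differences cover every primitive.

## Synthetic scenes

`SceneSpec` fixes image size, instance count, class-probability vector,
instance size range (the long side of the ground-truth box, in pixels),
an overlap policy and a seed. Backgrounds are smoothed low-frequency noise
around a muted green-brown; instances are drawn large (ellipse body, head,
dorsal stripe, leg strokes), rotated uniformly, then resized so the tight
box's long side equals an integer drawn uniformly from the size range —
hence the configured range is realised exactly, endpoints included.
Class identity is carried by hue (golden-ratio spacing), body aspect
(5 values) and leg-pair count (4 values), so classes are genuinely
separable by appearance, which is what makes a memorisation benchmark
meaningful. Placement retries up to 100 positions per instance
(pairwise box IoU ≤ 0.2 unless `density_mode`), then reports the spec
infeasible.

Default conditions: 256×256 scenes, 3 instances, 40–120 px targets. These
defaults are what the small-scale training benchmark uses; they put
targets across three pyramid levels while keeping a scene drawable in
~40 ms. What the generator does **not** emulate: real insect morphology,
lighting physics, occlusion by foliage, background clutter correlated
with targets, camera noise statistics. Tests passing on these scenes
establish that the architecture, losses and optimisation are wired
correctly and can fit multi-scale multi-class data — not field accuracy.

`make_imbalanced_counts` interpolates a head count down to a tail count
linearly (rounded), giving long-tailed profiles like 242…3 over a class
axis; `build_imbalanced_dataset` realises any count vector exactly.

## Copy-paste balancing and online augmentation

Instances are cut at their rounded boxes and pasted as hard rectangles
(no blending) — deliberately, so a cut/paste round trip is pixel-exact
and testable. New pasted images are appended until every deficient class
reaches the target count exactly; saturated classes and all original
images are untouched. Pasted boxes keep pairwise IoU ≤ 0.2 (also against
pre-existing boxes): dense but resolvable layouts. Patches are optionally
scale-jittered ±20 % and flipped (defaults on) to vary posture. The
per-class target is a single deterministic parameter; no per-class jitter
of the target is applied.

Online augmentation is photometric (brightness/contrast/saturation as
affine pixel maps, hue as a rotation about the gray axis in RGB space,
Gaussian noise) plus horizontal flip with exact box reflection, and
rectangular erasing filled with the image mean that is rejected if it
would cover more than half of any ground-truth box (20 placement tries,
then skipped). A fully zeroed policy is a bit-exact identity.

## Backbone

Patch partition flattens 4×4×3 blocks (row-major, channels fastest;
lossless), a linear embedding maps 48 → C with a LayerNorm, and four
stages of pre-norm blocks follow, stages 2–4 preceded by patch merging
(2×2 concat → linear 4C→2C; no pre-norm here, so an averaging projection
preserves constants). Blocks alternate plain and shifted window
attention (window M, shift M/2) with relative position bias; the shifted
variant's mask uses −inf logits, so attention between tokens from
non-adjacent pre-shift zones is exactly zero after softmax (asserted in
tests). When a stage's grid equals one window the shift would be a pure
bijection, so it is skipped. Divisibility contract: input side divisible
by 4·M·8.

Defaults: embed C=128 (making stages 2–4 produce 256/512/1024 channels),
depths (2,2,6,2), heads (4,8,16,32), M=8 — M is chosen so 160/80/40-wide
grids tile evenly, avoiding padding ambiguity. The `tiny` profile
(C=32, depths (2,2,2,2), heads (2,4,8,8), M=4, MLP ratio 2) keeps the
full topology at CPU cost; M=4 lets 128–256 px test images satisfy the
divisibility contract. Weights are truncated-normal (std 0.02), seeded;
no pretraining.

## SCF-FPN neck

Per level: 1×1 reduction to the neck width C (256 full / 64 tiny) gives
X; the U×V neighborhood of every position is unfolded (zero padding, same
spatial size — padding keeps A and X aligned for the residual) into R;
D = R ⊙ X′ flattens to C′ = U·V·C channels with fixed row-major (u, v)
order, channels fastest; G = [X; D] passes two 1×1 convolutions back to
C and is added residually. Both projections are **zero-initialised**, so
a fresh SCF module is exactly the identity on X — the attention branch
cannot perturb training at initialisation, and the residual guarantee is
asserted to 0 ulp. A 3×3 convolution follows per level, then the
standard top-down pyramid (nearest-neighbour 2× upsampling, lateral sum,
one 3×3 smoothing per P level) and P6 as a 2×2 stride-2 max pool of P5.
Windows default to (7,7)/(5,5)/(3,3) for strides 8/16/32 and are
overridable (`SCFConfig.uniform(3|5|7)`) to reproduce the uniform-window
ablation axes. The channel "downsampling" before SCF is purely a channel
reduction — resolution is unchanged, which the pyramid shapes require.

## Cascade detector

Anchors: one scale (4× stride) and ratios (0.5, 1, 2) per location on
P3–P6. The RPN is a shared 3×3 tower with objectness and delta heads;
training assigns positives at IoU ≥ 0.6 (plus each GT's best anchor),
negatives below 0.3, sampling 128 anchors at 1:1. Proposals decode with
clamped log-scale deltas (|dw|, |dh| ≤ 4), clip to the image, and pass
per-level hard NMS (0.7).

Each of the three refinement stages assigns positives at its threshold
(0.5/0.6/0.7 — strictly increasing, so positive sets shrink
monotonically), samples 32 RoIs at 1:1, pools 7×7 features from the
scale-assigned pyramid level (bilinear, one sample per bin), and applies
a two-fc head with a (K+1)-way classifier and class-agnostic regressor.
Ground-truth boxes are appended to each stage's candidate set during
training so positives exist from the first iteration. Stage losses are
cross-entropy + smooth-L1 with weights (1, 0.5, 0.25) and stage-tightened
delta normalisation; box refinement between stages is detached.

Inference: final boxes are the stage-3 regressions (B3); final per-class
scores average the three stage classifiers evaluated along the box
trajectory (stage s scored on its own input boxes). The alternative
reading — all three classifiers re-scored on the final boxes — is
available as `score_mode="final_boxes"`. Linear Soft-NMS runs per class:
greedy selection of the max-score box, overlapping scores multiplied by
(1 − IoU) when IoU ≥ N_t = 0.5, floor 0.05. N_t and the floor are
conventional values exposed in `CascadeConfig`. With floor 0, the
survivor set of hard NMS is a subset of Soft-NMS's (property-tested).

## Optimisation schedule

`TrainConfig` defaults to the reference recipe: SGD momentum 0.9, base
lr 0.01, weight decay 0.05 (coupled L2), 100 epochs, ×0.1 at epochs 80
and 90, input 1280 px, effective batch 64 via accumulation of one-image
micro-batches. Gradient clipping at global norm 10 guards the early
iterations. `(config, seed)` determines data order, initialisation,
augmentation and RoI sampling, hence the full loss trajectory.

The CPU memorisation benchmark (`overfit_benchmark`) uses its own
small-scale settings: tiny profile, 20 scenes at 256², 3 classes, 200
optimizer steps at effective batch 2, lr 0.01, weight decay 0 (decay is
counterproductive when the goal is to memorise 20 images). It reaches
train-set mAP@0.5 ≈ 0.95–1.0 in ~4 minutes on one core. Problem sizes
throughout the test suite (6-class toy sets, an 8-class 242…3 imbalance
profile balanced to 165, 1280 px forward passes with shallow depths)
were chosen so the full suite and the acceptance script each run in
minutes on a single CPU.

## Evaluation

mAP@0.5 is the class-mean 101-point interpolated AP; matching is greedy
in score order, best free GT by IoU, one match per GT. Precision and
recall are reported at the detector's score floor over all retained
detections. Ties in score are broken lexicographically by box
coordinates, making evaluation invariant to detection ordering within
equal scores. The implementation is self-contained and is verified in
tests against hand-computed PR curves.

## Known limitations

- Attention windows do not pad: input sides must be divisible by 4·M·8.
- RoI pooling samples one point per bin; coarser than 4-sample alignment.
- The numpy stack is single-image and single-threaded beyond BLAS; the
  full 1280 px profile is practical for forward passes (~1 min) but not
  for full-schedule training.
- Scene realism is deliberately limited (see above); absolute metric
  values on synthetic scenes say nothing about field imagery.
- `balance_classes` requires at least one source instance per class; it
  cannot invent an unseen class.
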