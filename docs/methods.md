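# Methods

## The segmentation model

`ddanet` implements a U-shaped encoder–decoder for binary segmentation of
intracerebral haemorrhage (ICH) on 2-D grayscale CT slices. The design
targets the two features that make this task hard: lesions are often tiny
and low-contrast, and lesion pixels are a vanishing fraction of each slice
(severe class imbalance).

**Encoder.** A ResNet-style backbone sliced into five stages. The
basic-block depth-34 recipe is the default (stage widths 64, 64, 128, 256,
512); a bottleneck depth-50 recipe (64, 256, 512, 1024, 2048) is available
through `ModelConfig(encoder_depth=50)`. Stage 1 is the 7×7/2 stem, stage 2
is the 3×3/2 max-pool plus the first residual layer, and stages 3–5 halve
the resolution once more each, so stage ℓ emits features at 1/2ℓ of the
input resolution. Input height and width must be multiples of 32.

**Dilated-convolution pooling (DCP).** At every encoder level except the
first, a side branch consumes the previous level's (enriched) feature map:
parallel 3×3 convolutions at dilation rates 1, 2 and 4 (effective extents
3, 5, 9 pixels; each followed by batch-norm and ReLU) are concatenated,
compressed by a 1×1 convolution (+BN+ReLU), and 2×2/2 max-pooled. The
branch output matches the next stage's channels and resolution and is
summed element-wise into that stage's output; the sum is both the decoder
skip and the next stage's input. Each dilated branch is padded by its
dilation rate so all branches share the input's spatial size before
concatenation.

**Self-attention bridge.** The deepest enriched feature passes through a
non-local block: 1×1 convolutions produce query/key (channels reduced by 8)
and value (full channels) tensors; the attention matrix is the softmax over
key positions of q·k (no 1/√d temperature — none appears in the defining
form); the output is the input plus a 1×1 re-projection of the
attention-weighted values. Rows of the attention matrix are probability
distributions over all spatial positions, which is what lets high-level
semantics inform every location.

**Decoder.** Five steps of: ×2 bilinear upsampling → concatenation with the
matching encoder skip (levels 4, 3, 2, 1; the fifth step, at full
resolution, has no skip) → residual block (two 3×3 conv+BN stages with an
identity or 1×1-projected shortcut) → channel-then-spatial attention.
Channel attention is squeeze-excitation (global average pool → 1×1
bottleneck with reduction 16 → ReLU → 1×1 → logistic gate); spatial
attention stacks the channel-wise mean and max maps and gates through a 7×7
convolution and logistic. Decoder widths default to 256, 128, 64, 64, 32.
The head is a 1×1 convolution to one channel with a logistic squashing,
giving a per-pixel lesion probability at input resolution.

**Objective.** `L = α·L_BCE + β·L_Dice` with α = β = 1. BCE gives stable
per-pixel calibration; the soft-Dice term directly optimises overlap so
small lesions are not drowned by the background majority. The Dice
smoothing constant is 1.0 (resolves empty-vs-empty as a perfect match);
probabilities are clamped to [1e-7, 1−1e-7] before logarithms.

**Metrics.** Per slice, from pixel confusion counts of the thresholded map
(threshold 0.5, `≥` convention): Dice, Jaccard, sensitivity, specificity
and accuracy = (TP+TN)/total, aggregated as mean ± population standard
deviation. Degenerate slices use benchmark conventions: empty truth and
empty prediction score 1.0 on the overlap metrics; empty truth with false
positives scores sensitivity 0.0 (symmetrically for specificity).

## Training protocol

Adam at a constant learning rate 1e-4, batch size 4, up to 150 epochs by
default. After every epoch the model is scored on the selection set and the
checkpoint is overwritten whenever the mean test Dice strictly improves, so
the saved weights are always the argmax epoch. Scoring selection on the
test fold is the reference protocol but is optimistic (the fold steers
which weights survive); `TrainConfig.val_fraction > 0` instead carves a
validation subset out of the training pairs and leaves the test fold
untouched until final evaluation. Augmentation (random rotation ±30°,
flips, scaling 0.9–1.1, contrast gain 0.8–1.2, additive noise σ = 0.02) is
applied on the fly to training pairs only; geometric transforms hit image
and mask identically (mask via nearest-neighbour so it stays binary).
Cross-validation shuffles slice ids with a seeded generator and deals them
round-robin into folds (sizes differ by at most one; 318 slices over five
folds gives 64/64/64/63/63); slice-level splitting is the default, matching
the reference protocol.

## Numerical and initialisation choices

* All layers run on the package's own reverse-mode autodiff engine over
  NumPy (`ddanet.autodiff`); convolution uses im2col + BLAS matmul, and
  every primitive's gradient is validated against central finite
  differences in the test suite. Model compute is single precision; the
  loss/metric code paths accept double-precision arrays and are exercised
  at 1e-10 tolerance against scalar-loop oracles.
* Convolutions are He-normal initialised, biases zero, with two deliberate
  exceptions. (1) The head bias starts at the logit of `head_prior`
  (default 0.03), so the initial probability map matches the heavy
  background/lesion imbalance instead of predicting 50 % lesion everywhere
  — standard practice for rare-foreground detection heads, and it removes
  hundreds of wasted optimiser steps of background suppression. (2) The
  squeeze-excitation bottleneck starts near-neutral (weights ×0.01, bias
  +0.1): with very narrow bottlenecks the global-average input is nearly
  constant across images, and an unlucky He draw would leave the gate
  rectifier-dead — permanently, because its input barely varies. The
  near-neutral start makes the gate begin as a mild identity and guarantees
  gradient flow to every parameter.
* Batch normalisation uses eps 1e-5 and momentum 0.1; evaluation mode uses
  running statistics, making inference bit-deterministic.
  `reset_to_identity()` puts a layer in an exact pass-through state, which
  the analytic unit tests use to decouple block algebra from batch
  statistics.
* Max-pool and channel-wise max break ties by first index; no behaviour
  depends on it.
* Bilinear upsampling uses half-pixel centres; the backward pass is the
  exact adjoint of the forward interpolation matrix.

## The phantom generator

Real ICH datasets are small, private and expensive to label, so the package
ships a seeded generator of synthetic axial head phantoms with exact
ground truth. Each slice (normalised [0, 1] intensities) contains a dark
background, a bright elliptical skull ring (0.95) of configurable
thickness, mid-intensity parenchyma (0.45) with smooth low-frequency
texture (±0.03, Gaussian-filtered noise), and 1–3 lesions: ellipses
deformed by low-order radial harmonics (amplitude ≤ 0.15), radius 2–7 px,
placed strictly inside the brain, at 0.08–0.25 intensity above the
parenchyma, plus additive Gaussian noise (σ = 0.02). The mask is the exact
union of lesion supports. Under the defaults, lesion pixels are well below
5 % of the image, reproducing the class-imbalance regime; the low contrast
floor keeps lesions detectable in principle (mean lesion-minus-parenchyma
gap ≥ half the minimum contrast before noise).

What the phantoms do *not* model: Hounsfield-unit radiometry, beam
hardening and streak artifacts, ventricles/sulci anatomy, the five clinical
ICH subtypes, or 3-D slice correlation. Passing tests therefore demonstrate
that the architecture, objective, and protocol machinery are correct and
trainable end-to-end — not clinical-grade performance on real CT.

## Problem sizes used by the test suite and acceptance script

The verification suite runs the full pipeline at deliberately small scale:
a narrow model (`ModelConfig.small()`: stage widths 8/8/16/32/64, decoder
32/32/16/16/8, gate reduction 4) and 64×64 phantoms. The memorisation
("overfit") run trains on 8 slices for 400 epochs (800 optimiser steps at
batch 4) with augmentation off — a capacity/trainability check, not the
generalisation protocol — and is expected to reach train mean Dice ≥ 0.95
from a chance-level start. The acceptance script additionally generates a
318-slice phantom corpus for prevalence and fold-size accounting and builds
the full-width default model once for parameter accounting (≈31 M
parameters; ablating the DCP branches or the attention bridge strictly
reduces the count).

## Known limitations

* CPU-only and NumPy-bound: fine at smoke scale, not at 512×512 clinical
  scale with the full-width model.
* Binary lesion-vs-background only; no subtype classification, no 3-D
  context, no test-time augmentation.
* The ImageNet-pretrained encoder option requires a user-supplied local
  weights file in the package's own npz layout (shape-matched loading with
  grayscale stem adaptation); no weights are bundled or downloaded.
* Model selection on the test fold reproduces the reference protocol and
  inherits its optimism; use `val_fraction` for unbiased selection.
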