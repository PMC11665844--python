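# ddanet

Dilated-attention encoder–decoder for **intracerebral haemorrhage (ICH)
segmentation** on brain CT slices, with a seeded synthetic head-phantom
benchmark.

ICH is a medical emergency: outcomes hinge on quickly finding and
delineating the bleed on non-contrast CT, yet the haemorrhages that matter
most are often tiny and barely brighter than the surrounding parenchyma,
and lesion pixels are a sub-percent minority of every slice. This package
is for researchers who want a transparent, fully-testable reference
implementation of a modern attention-augmented U-Net for this regime — the
network, its training protocol, and a phantom data generator that
reproduces the statistical shape of the problem (bright skull ring,
textured parenchyma, few-pixel low-contrast lesions) with exact ground
truth.

## The model

A five-stage ResNet-style encoder feeds a U-shaped decoder, with three
additions aimed at small, low-contrast lesions:

* **Dilated-convolution pooling (DCP)** side branches at encoder levels
  2–5: parallel 3×3 convolutions at dilation rates 1/2/4 widen the
  receptive field without losing detail; the fused, pooled branch is summed
  into the next stage.
* A **non-local self-attention bridge** on the deepest feature: attention
  weights `softmax(q·k)` over all position pairs let global semantics guide
  local decisions, `y = x + Conv(v·wᵀ)`.
* A decoder of bilinear upsampling, skip concatenation, **residual blocks**
  and **channel+spatial attention** gates, ending in a 1×1 head with
  logistic output.

Training minimises the hybrid objective

```
L = α·L_BCE + β·L_Dice,      α = β = 1
L_BCE  = −(1/N) Σ [yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)]
L_Dice = 1 − (2 Σ yᵢpᵢ + s) / (Σ yᵢ + Σ pᵢ + s)
```

with Adam (lr 1e-4, batch 4), checkpointing on best test-fold Dice, and
five-fold cross-validation. Evaluation reports Dice, Jaccard, sensitivity,
specificity and accuracy per slice, aggregated as mean ± std.

Everything runs on the package's own compact reverse-mode autodiff engine
over NumPy (`ddanet.autodiff`) — no deep-learning framework required — and
every gradient primitive is verified against finite differences in the test
suite.

## Worked example

```python
import tempfile
from ddanet.engine import TrainConfig, evaluate, train_fold
from ddanet.network import ModelConfig
from ddanet.objective import LossConfig
from ddanet.phantom import PhantomConfig, generate_dataset

pairs = generate_dataset(PhantomConfig(size=64, seed=7), 8)
cfg = TrainConfig(max_epochs=400, seed=3, augment_train=False,
                  checkpoint_dir=tempfile.mkdtemp())
ckpt, log = train_fold(ModelConfig.small(), LossConfig(), cfg, pairs, pairs)
print(evaluate(ckpt, pairs))
```

On one CPU this memorisation run takes a few minutes and prints

```
MetricsReport(n=8, dice=0.994±0.005, jaccard=0.989±0.010, sensitivity=0.999±0.003,
specificity=1.000±0.000, accuracy=1.000±0.000)
```

— the narrow CPU-scale model drives train Dice from 0 (it starts at the
background prior) to ≈0.99 on eight 64×64 phantoms, confirming that the
architecture, loss and training loop fit the task end to end. Specificity
and accuracy sit near 1.0 because background dominates every slice; Dice
and Jaccard are the informative numbers in this regime.

The `examples/` directory holds short narrative scripts, one per
capability: phantom generation, the building blocks, losses and metrics,
training + prediction, and cross-validation. A thin CLI wraps the same
pipelines:

```bash
ddanet generate --out data --n 16 --seed 7
ddanet split --data data --folds 5 --seed 0 --out folds.json
ddanet train --data data --out run --small --epochs 50 --seed 0
ddanet predict --checkpoint run/best.npz --out pred data/phantom-7-0000.png
ddanet summarize            # architecture table and parameter count
```

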