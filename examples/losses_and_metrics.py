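"""The hybrid BCE+Dice objective and the five evaluation metrics on a toy
prediction.

The loss drives training; the metrics (computed from pixel confusion
counts after thresholding) are how segmentation quality is reported.
"""

import numpy as np

from ddanet.network import binarize
from ddanet.objective import (LossConfig, bce_loss, dice_loss, evaluate_masks,
                              total_loss)

rng = np.random.default_rng(3)
truth = np.zeros((32, 32))
truth[10:16, 12:20] = 1                      # a 6x8 lesion
prob = np.clip(truth * 0.8 + rng.normal(0.08, 0.05, truth.shape), 0.001, 0.999)

y, p = truth.reshape(-1), prob.reshape(-1)
print(f"BCE loss:   {bce_loss(y, p):.4f}")
print(f"Dice loss:  {dice_loss(y, p):.4f}")
print(f"total loss: {total_loss(y, p, LossConfig(alpha=1.0, beta=1.0)):.4f}  (alpha=beta=1)")

metrics = evaluate_masks(binarize(prob, 0.5), truth)
for name, value in metrics.as_dict().items():
    print(f"{name:>12s}: {value:.4f}")
print()
print("Dice/Jaccard score region overlap; sensitivity is lesion recall;")
print("specificity and accuracy are dominated by the background majority.")
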