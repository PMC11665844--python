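"""Walk through the four building blocks on a random feature map.

Shows the shape contract of each block and the simplex property of the
self-attention weights (every query's weights over key positions sum to 1).
"""

import numpy as np

from ddanet.autodiff import Tensor
from ddanet.blocks import (BlockConfig, CSABlock, DCPBlock, ResidualBlock,
                           SelfAttention)

rng = np.random.default_rng(0)
x = Tensor(rng.random((1, 16, 32, 32)))

dcp = DCPBlock(BlockConfig(16, 32), rng=rng)
print(f"DCP block:        {x.shape} -> {dcp(x).shape}  (context + x2 downsampling)")

res = ResidualBlock(16, 32, rng=rng)
print(f"residual block:   {x.shape} -> {res(x).shape}  (projected shortcut)")

csa = CSABlock(16, reduction=4, rng=rng)
print(f"channel+spatial:  {x.shape} -> {csa(x).shape}  (multiplicative gating)")

sam = SelfAttention(BlockConfig(16, 16, attention_key_reduction=8), rng=rng)
small = rng.random((16, 4, 4))
att = sam.attention_tensors(small)
print(f"self-attention:   weights {att.weights.shape}, "
      f"row sums in [{att.weights.sum(1).min():.6f}, {att.weights.sum(1).max():.6f}]")
print()
print("Every attention row is a probability distribution over all 16 spatial")
print("positions, which is how the block mixes global context into each pixel.")
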