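"""Building blocks of the dilated-attention segmentation network.

Four composable units:

* :class:`DCPBlock` — dilated-convolution pooling: parallel 3×3 convolutions
  at increasing dilation rates capture multiscale context, a 1×1 convolution
  compresses the concatenated branches, and a 2×2 max-pool halves the
  spatial resolution.
* :class:`SelfAttention` — a non-local block: 1×1 convolutions produce
  query/key/value tensors, attention weights are the softmax over key
  positions of q·k, and the re-projected weighted values are added back to
  the input (``y = x + Conv(v @ wᵀ)``).
* :class:`ResidualBlock` — two 3×3 conv+BN stages with an identity (or
  1×1-projected) shortcut, rectified after the sum.
* :class:`ChannelAttention` / :class:`SpatialAttention` / :class:`CSABlock`
  — squeeze-excitation channel gating followed by a mean/max-map spatial
  gate, applied sequentially in the decoder.

All blocks operate on NCHW tensors and preserve spatial size except
:class:`DCPBlock`, which exactly halves it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate, conv2d, max_pool2d
from .errors import ConfigurationError, DimensionError
from .nn import BatchNorm2d, Conv2d, Module

__all__ = [
    "BlockConfig", "AttentionTensors", "DCPBlock", "SelfAttention",
    "ResidualBlock", "ChannelAttention", "SpatialAttention", "CSABlock",
]


@dataclass
class BlockConfig:
    """Hyperparameters shared by the building blocks.

    dilation_rates
        Dilations of the parallel 3×3 branches in the DCP block; strictly
        increasing.  The default [1, 2, 4] grows the effective kernel
        extents geometrically (3, 5, 9 pixels).
    channel_reduction
        Squeeze-excitation bottleneck ratio of the channel gate.
    attention_key_reduction
        Channel divisor for the query/key projections of the self-attention
        block (value keeps full channels).
    spatial_kernel
        Odd kernel size of the spatial-gate convolution.
    """

    in_channels: int
    out_channels: int
    dilation_rates: tuple[int, ...] = (1, 2, 4)
    channel_reduction: int = 16
    attention_key_reduction: int = 8
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("in_channels and out_channels must be positive")
        rates = tuple(self.dilation_rates)
        if not rates:
            raise ConfigurationError("dilation_rates must be non-empty")
        if any(r < 1 for r in rates) or any(b <= a for a, b in zip(rates, rates[1:])):
            raise ConfigurationError(
                f"dilation_rates must be strictly increasing positives, got {rates}")
        self.dilation_rates = rates
        if self.channel_reduction < 1:
            raise ConfigurationError("channel_reduction must be positive")
        if self.attention_key_reduction < 1:
            raise ConfigurationError("attention_key_reduction must be positive")
        if self.spatial_kernel < 1 or self.spatial_kernel % 2 == 0:
            raise ConfigurationError(
                f"spatial_kernel must be odd and positive, got {self.spatial_kernel}")


@dataclass
class AttentionTensors:
    """Intermediate tensors of one self-attention evaluation.

    ``q``: (positions × reduced channels), ``k``: (reduced channels ×
    positions), ``v``: (channels × positions), ``weights``: (query positions
    × key positions), each row softmax-normalised to sum to 1.
    """

    q: np.ndarray
    k: np.ndarray
    v: np.ndarray
    weights: np.ndarray


class DCPBlock(Module):
    """Dilated-convolution pooling: multiscale context then ×2 downsampling."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.branch_convs = _mlist(
            Conv2d(cfg.in_channels, cfg.out_channels, 3, padding=d, dilation=d, rng=rng)
            for d in cfg.dilation_rates)
        self.branch_norms = _mlist(
            BatchNorm2d(cfg.out_channels) for _ in cfg.dilation_rates)
        merged = cfg.out_channels * len(cfg.dilation_rates)
        self.fuse_conv = Conv2d(merged, cfg.out_channels, 1, rng=rng)
        self.fuse_norm = BatchNorm2d(cfg.out_channels)

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        for axis, n in (("height", h), ("width", w)):
            if n < 2 or n % 2:
                raise DimensionError(
                    f"DCP block requires an even {axis} >= 2, got {n}")
        branches = [norm(conv(x)).relu()
                    for conv, norm in zip(self.branch_convs, self.branch_norms)]
        merged = concatenate(branches, axis=1)
        fused = self.fuse_norm(self.fuse_conv(merged)).relu()
        return max_pool2d(fused, kernel=2, stride=2)


class SelfAttention(Module):
    """Non-local self-attention over all spatial positions, with residual add."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        c, r = cfg.in_channels, cfg.attention_key_reduction
        if c % r:
            raise ConfigurationError(
                f"in_channels ({c}) must be divisible by attention_key_reduction ({r})")
        self.cfg = cfg
        self.reduced = c // r
        self.q_conv = Conv2d(c, self.reduced, 1, rng=rng)
        self.k_conv = Conv2d(c, self.reduced, 1, rng=rng)
        self.v_conv = Conv2d(c, c, 1, rng=rng)
        self.out_conv = Conv2d(c, c, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        p = h * w
        q = self.q_conv(x).reshape(n, self.reduced, p).transpose(0, 2, 1)  # N×P×C'
        k = self.k_conv(x).reshape(n, self.reduced, p)                     # N×C'×P
        v = self.v_conv(x).reshape(n, c, p)                                # N×C×P
        weights = (q @ k).softmax(axis=-1)       # rows: one query's key weights
        attended = v @ weights.transpose(0, 2, 1)  # out[:, i] = sum_j w_ij v_j
        y = self.out_conv(attended.reshape(n, c, h, w))
        return x + y

    def attention_tensors(self, x: Tensor) -> AttentionTensors:
        """The q/k/v/weights arrays for one (unbatched or batch-1) input."""
        data = x.data if isinstance(x, Tensor) else np.asarray(x)
        if data.ndim == 3:
            data = data[None]
        t = Tensor(data)
        n, c, h, w = t.shape
        p = h * w
        q = self.q_conv(t).data.reshape(n, self.reduced, p).transpose(0, 2, 1)
        k = self.k_conv(t).data.reshape(n, self.reduced, p)
        v = self.v_conv(t).data.reshape(n, c, p)
        logits = q @ k
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        weights = e / e.sum(axis=-1, keepdims=True)
        return AttentionTensors(q=q[0], k=k[0], v=v[0], weights=weights[0])


class ResidualBlock(Module):
    """3×3 conv → BN → ReLU → 3×3 conv → BN, summed with a shortcut, rectified.

    The shortcut is the identity when shapes already match, otherwise a
    1×1 convolution + BN (also used for strided encoder stages).
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride=stride, padding=1, rng=rng)
        self.norm1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, padding=1, rng=rng)
        self.norm2 = BatchNorm2d(out_channels)
        if in_channels != out_channels or stride != 1:
            self.shortcut_conv = Conv2d(in_channels, out_channels, 1, stride=stride, rng=rng)
            self.shortcut_norm = BatchNorm2d(out_channels)
        else:
            self.shortcut_conv = None
            self.shortcut_norm = None

    @property
    def has_projection(self) -> bool:
        return self.shortcut_conv is not None

    def forward(self, x: Tensor) -> Tensor:
        main = self.norm2(self.conv2(self.norm1(self.conv1(x)).relu()))
        short = x if self.shortcut_conv is None else self.shortcut_norm(self.shortcut_conv(x))
        return (main + short).relu()


class BottleneckBlock(Module):
    """1×1 reduce → 3×3 → 1×1 expand residual unit (deep encoder recipe)."""

    expansion = 4

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        width = out_channels // self.expansion
        self.conv1 = Conv2d(in_channels, width, 1, rng=rng)
        self.norm1 = BatchNorm2d(width)
        self.conv2 = Conv2d(width, width, 3, stride=stride, padding=1, rng=rng)
        self.norm2 = BatchNorm2d(width)
        self.conv3 = Conv2d(width, out_channels, 1, rng=rng)
        self.norm3 = BatchNorm2d(out_channels)
        if in_channels != out_channels or stride != 1:
            self.shortcut_conv = Conv2d(in_channels, out_channels, 1, stride=stride, rng=rng)
            self.shortcut_norm = BatchNorm2d(out_channels)
        else:
            self.shortcut_conv = None
            self.shortcut_norm = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h)).relu()
        h = self.norm3(self.conv3(h))
        short = x if self.shortcut_conv is None else self.shortcut_norm(self.shortcut_conv(x))
        return (h + short).relu()


class ChannelAttention(Module):
    """Squeeze-excitation channel gate: GAP → 1×1 → ReLU → 1×1 → logistic."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if channels % reduction:
            raise ConfigurationError(
                f"channel_reduction ({reduction}) must divide channels ({channels})")
        hidden = channels // reduction
        self.squeeze = Conv2d(channels, hidden, 1, rng=rng)
        # near-neutral gate init: small weights + positive bias keep the
        # (possibly very narrow) bottleneck rectifier alive for any input,
        # so the gate starts as a mild identity and always carries gradient
        self.squeeze.weight.data *= 0.01
        self.squeeze.bias.data[:] = 0.1
        self.excite = Conv2d(hidden, channels, 1, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3), keepdims=True)
        return self.excite(self.squeeze(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class SpatialAttention(Module):
    """Per-position gate from stacked channel-mean and channel-max maps."""

    def __init__(self, kernel_size: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ConfigurationError(
                f"spatial_kernel must be odd and positive, got {kernel_size}")
        self.conv = Conv2d(2, 1, kernel_size, padding=kernel_size // 2, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        mean_map = x.mean(axis=1, keepdims=True)
        max_map = x.max(axis=1, keepdims=True)
        stacked = concatenate([mean_map, max_map], axis=1)
        return self.conv(stacked).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class CSABlock(Module):
    """Channel-then-spatial attention, applied sequentially."""

    def __init__(self, channels: int, reduction: int = 16, spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.channel(x))


def _mlist(modules):
    from .nn import ModuleList
    return ModuleList(modules)
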