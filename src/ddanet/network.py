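"""The dilated-attention encoder-decoder segmentation network.

A U-shaped binary segmentation model for grayscale CT slices:

* **Encoder** — a ResNet-style backbone (basic-block depth-34 recipe or
  bottleneck depth-50 recipe) sliced into five stages; stage ℓ emits
  ``stage_channels[ℓ-1]`` channels at 1/2ℓ of the input resolution.
* **DCP side branches** — at each configured level ℓ ∈ {2..5} a
  dilated-convolution-pooling block consumes the level-(ℓ−1) feature and is
  summed element-wise into the level-ℓ stage output; the enriched sum feeds
  both the decoder skip and the next stage.
* **Bridge** — optional non-local self-attention on the deepest feature.
* **Decoder** — five steps of ×2 bilinear upsampling, skip concatenation
  (levels 4→1; the final step has no same-resolution skip), a residual
  block and channel-spatial attention.
* **Head** — 1×1 convolution to one channel plus a logistic squashing,
  yielding a per-pixel lesion probability map at input resolution.

Input height and width must be divisible by 32 (five halvings).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concatenate, upsample_bilinear_x2
from .blocks import (BlockConfig, BottleneckBlock, CSABlock, DCPBlock,
                     ResidualBlock, SelfAttention)
from .errors import ConfigurationError, DimensionError
from . import nn
from .nn import BatchNorm2d, Conv2d, MaxPool2d, Module, ModuleList, Sequential

__all__ = ["ModelConfig", "DDANet", "binarize", "count_parameters",
           "save_checkpoint", "load_checkpoint"]

_STAGE_BLOCKS = {34: (3, 4, 6, 3), 50: (3, 4, 6, 3)}
_DEFAULT_STAGE_CHANNELS = {34: (64, 64, 128, 256, 512),
                           50: (64, 256, 512, 1024, 2048)}


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``stage_channels`` may be left ``None`` to use the reference recipe for
    the chosen ``encoder_depth``.  ``dcp_levels`` selects which encoder
    levels (2–5) receive a dilated-convolution side branch; an empty tuple
    reduces the encoder to the plain backbone.
    """

    in_channels: int = 1
    encoder_depth: int = 34
    stage_channels: tuple[int, ...] | None = None
    use_pretrained_encoder: bool = False
    pretrained_weights: str | None = None
    dcp_levels: tuple[int, ...] = (2, 3, 4, 5)
    sam_at_bridge: bool = True
    decoder_channels: tuple[int, ...] = (256, 128, 64, 64, 32)
    output_threshold: float = 0.5
    dcp_dilation_rates: tuple[int, ...] = (1, 2, 4)
    channel_reduction: int = 16
    attention_key_reduction: int = 8
    spatial_kernel: int = 7
    #: expected foreground prior; the head bias starts at its logit so the
    #: initial probability map matches the heavy background/lesion imbalance
    head_prior: float = 0.03

    def __post_init__(self):
        if self.encoder_depth not in _STAGE_BLOCKS:
            raise ConfigurationError(
                f"encoder_depth must be one of {sorted(_STAGE_BLOCKS)}, "
                f"got {self.encoder_depth}")
        if self.stage_channels is None:
            self.stage_channels = _DEFAULT_STAGE_CHANNELS[self.encoder_depth]
        self.stage_channels = tuple(int(c) for c in self.stage_channels)
        if len(self.stage_channels) != 5:
            raise ConfigurationError(
                f"stage_channels must have 5 entries, got {len(self.stage_channels)}")
        self.dcp_levels = tuple(int(l) for l in self.dcp_levels)
        if any(l not in (2, 3, 4, 5) for l in self.dcp_levels):
            raise ConfigurationError(
                f"dcp_levels must be a subset of {{2,3,4,5}}, got {self.dcp_levels}")
        self.decoder_channels = tuple(int(c) for c in self.decoder_channels)
        if len(self.decoder_channels) != 5:
            raise ConfigurationError(
                f"decoder_channels must have 5 entries, got {len(self.decoder_channels)}")
        if not 0.0 < self.output_threshold < 1.0:
            raise ConfigurationError(
                f"output_threshold must lie in (0, 1), got {self.output_threshold}")
        if not 0.0 < self.head_prior < 1.0:
            raise ConfigurationError(
                f"head_prior must lie in (0, 1), got {self.head_prior}")
        self.dcp_dilation_rates = tuple(int(d) for d in self.dcp_dilation_rates)
        if self.in_channels < 1:
            raise ConfigurationError("in_channels must be positive")
        if self.sam_at_bridge and self.stage_channels[4] % self.attention_key_reduction:
            raise ConfigurationError(
                f"bridge channels ({self.stage_channels[4]}) must be divisible by "
                f"attention_key_reduction ({self.attention_key_reduction})")

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """A narrow configuration for CPU-scale smoke runs and tests."""
        defaults = dict(stage_channels=(8, 8, 16, 32, 64),
                        decoder_channels=(32, 32, 16, 16, 8),
                        channel_reduction=4,
                        attention_key_reduction=8)
        defaults.update(overrides)
        return cls(**defaults)


def _make_stage(block_cls, in_channels, out_channels, n_blocks, stride, rng):
    blocks = [block_cls(in_channels, out_channels, stride=stride, rng=rng)]
    blocks += [block_cls(out_channels, out_channels, rng=rng) for _ in range(n_blocks - 1)]
    return Sequential(*blocks)


class Encoder(Module):
    """Five-stage ResNet-style backbone.

    Stage 1 is the 7×7/2 stem (1/2 resolution); stage 2 is the 3×3/2
    max-pool plus the first residual layer (1/4); stages 3–5 halve once
    more each, reaching 1/32.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        ch = cfg.stage_channels
        counts = _STAGE_BLOCKS[cfg.encoder_depth]
        block_cls = ResidualBlock if cfg.encoder_depth == 34 else BottleneckBlock
        self.stem_conv = Conv2d(cfg.in_channels, ch[0], 7, stride=2, padding=3, rng=rng)
        self.stem_norm = BatchNorm2d(ch[0])
        self.pool = MaxPool2d(3, stride=2, padding=1)
        self.layer1 = _make_stage(block_cls, ch[0], ch[1], counts[0], 1, rng)
        self.layer2 = _make_stage(block_cls, ch[1], ch[2], counts[1], 2, rng)
        self.layer3 = _make_stage(block_cls, ch[2], ch[3], counts[2], 2, rng)
        self.layer4 = _make_stage(block_cls, ch[3], ch[4], counts[3], 2, rng)

    def stage(self, level: int, x: Tensor) -> Tensor:
        """Apply encoder stage `level` (1-based) to the previous level's output."""
        if level == 1:
            return self.stem_norm(self.stem_conv(x)).relu()
        if level == 2:
            return self.layer1(self.pool(x))
        return getattr(self, f"layer{level - 1}")(x)

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = []
        for level in range(1, 6):
            x = self.stage(level, x)
            feats.append(x)
        return feats


class DDANet(Module):
    """Encoder-decoder lesion segmentation network with a probability head."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or ModelConfig()
        rng = np.random.default_rng(seed)
        ch = cfg.stage_channels
        self.encoder = Encoder(cfg, rng)
        if cfg.use_pretrained_encoder:
            _load_pretrained(self.encoder, cfg)
        self.dcp_blocks = ModuleList()
        self._dcp_index: dict[int, int] = {}
        for level in sorted(set(cfg.dcp_levels)):
            bc = BlockConfig(in_channels=ch[level - 2], out_channels=ch[level - 1],
                             dilation_rates=cfg.dcp_dilation_rates)
            self._dcp_index[level] = len(self.dcp_blocks)
            self.dcp_blocks.append(DCPBlock(bc, rng=rng))
        if cfg.sam_at_bridge:
            sam_cfg = BlockConfig(in_channels=ch[4], out_channels=ch[4],
                                  attention_key_reduction=cfg.attention_key_reduction)
            self.sam = SelfAttention(sam_cfg, rng=rng)
        else:
            self.sam = None
        # decoder: step i upsamples, concatenates skip level 4-i (steps 0-3),
        # then residual + channel-spatial attention
        skip_ch = [ch[3], ch[2], ch[1], ch[0], 0]
        prev = ch[4]
        self.decoder_res = ModuleList()
        self.decoder_csa = ModuleList()
        for out_ch, sk in zip(cfg.decoder_channels, skip_ch):
            self.decoder_res.append(ResidualBlock(prev + sk, out_ch, rng=rng))
            self.decoder_csa.append(CSABlock(out_ch, cfg.channel_reduction,
                                             cfg.spatial_kernel, rng=rng))
            prev = out_ch
        self.head = Conv2d(prev, 1, 1, rng=rng)
        self.head.bias.data[:] = np.log(cfg.head_prior / (1.0 - cfg.head_prior))

    # -- encoder with DCP enrichment -----------------------------------------

    def encode(self, x: Tensor) -> list[Tensor]:
        """Enriched per-level features: stage output (+ DCP side branch)."""
        feats = []
        cur = x
        for level in range(1, 6):
            out = self.encoder.stage(level, cur)
            idx = self._dcp_index.get(level)
            if idx is not None:
                out = out + self.dcp_blocks[idx](cur)
            feats.append(out)
            cur = out
        return feats

    def forward(self, x: Tensor) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.dtype != nn.DTYPE and not x.requires_grad:
            x = Tensor(x.data.astype(nn.DTYPE))
        if x.ndim != 4:
            raise DimensionError(f"expected NCHW input, got {x.ndim} dimensions")
        _, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise ConfigurationError(
                f"model expects {self.cfg.in_channels} input channel(s), got {c}")
        for axis, n in (("height", h), ("width", w)):
            if n % 32:
                raise DimensionError(
                    f"input {axis} must be a multiple of 32, got {n}")
        feats = self.encode(x)
        d = feats[4]
        if self.sam is not None:
            d = self.sam(d)
        skips = [feats[3], feats[2], feats[1], feats[0], None]
        for res, csa, skip in zip(self.decoder_res, self.decoder_csa, skips):
            d = upsample_bilinear_x2(d)
            if skip is not None:
                d = concatenate([d, skip], axis=1)
            d = csa(res(d))
        logits = self.head(d)
        prob = logits.sigmoid()
        n = prob.shape[0]
        return prob.reshape(n, h, w)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one (H, W) or (C, H, W) image, in eval mode."""
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        was_training = self.training
        self.eval()
        try:
            out = self.forward(Tensor(arr[None])).data[0]
        finally:
            self.train(was_training)
        return out


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map to a {0,1} mask (``>=`` convention)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return (np.asarray(prob) >= threshold).astype(np.uint8)


def count_parameters(model: Module) -> int:
    """Total number of learnable scalar parameters."""
    return sum(p.data.size for p in model.parameters())


# -- pretrained-weight adaptation ---------------------------------------------


def _load_pretrained(encoder: Encoder, cfg: ModelConfig) -> None:
    if not cfg.pretrained_weights:
        raise ConfigurationError(
            "use_pretrained_encoder requires a local weights file "
            "(ModelConfig.pretrained_weights); none was given and no weights are "
            "bundled — set use_pretrained_encoder=False to train from random "
            "initialization")
    path = Path(cfg.pretrained_weights)
    if not path.exists():
        raise ConfigurationError(
            f"pretrained encoder weights not found at {path}; set "
            "use_pretrained_encoder=False to train from random initialization")
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    own = encoder.state_dict()
    loaded = 0
    for key, value in state.items():
        if key not in own:
            continue
        target = own[key]
        if key == "stem_conv.weight" and value.shape[1] != target.shape[1]:
            # adapt an RGB stem to grayscale by averaging the colour kernels
            value = np.repeat(value.mean(axis=1, keepdims=True),
                              target.shape[1], axis=1)
        if value.shape == target.shape:
            own[key] = np.asarray(value, dtype=np.float64)
            loaded += 1
    if loaded == 0:
        raise ConfigurationError(
            f"no parameter in {path} matched the encoder recipe")
    encoder.load_state_dict(own)


# -- checkpointing ------------------------------------------------------------


def save_checkpoint(model: DDANet, path: str | Path) -> Path:
    """Write weights (npz) plus a sidecar JSON of the full ModelConfig."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.cfg), indent=2) + "\n")
    return path


def load_checkpoint(path: str | Path) -> DDANet:
    """Rebuild a model from a weights container and its sidecar config."""
    path = Path(path)
    if path.suffix != ".npz" and not path.exists():
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ConfigurationError(f"missing checkpoint sidecar config {sidecar}")
    raw = json.loads(sidecar.read_text())
    raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    model = DDANet(ModelConfig(**raw))
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    model.load_state_dict(state)
    return model
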