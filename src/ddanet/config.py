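"""Run configuration: YAML loading, validation and round-tripping.

A run configuration composes the model, loss, training and phantom
configurations with the data/output paths.  Absent keys take the protocol
defaults (Adam at 1e-4, batch 4, 150 epochs, α = β = 1); unknown keys are
rejected with the offending key named, so typos cannot silently fall back
to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .engine import TrainConfig
from .errors import ConfigurationError
from .network import ModelConfig
from .objective import LossConfig
from .phantom import PhantomConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Composition of all sub-configurations plus paths."""

    data_dir: str = "data"
    output_dir: str = "runs"
    threshold: float = 0.5
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError(
                f"threshold must lie in (0, 1), got {self.threshold}")

    def resolved(self) -> "RunConfig":
        self.data_dir = str(Path(self.data_dir))
        self.output_dir = str(Path(self.output_dir))
        return self


_SECTIONS = {"model": ModelConfig, "loss": LossConfig,
             "train": TrainConfig, "phantom": PhantomConfig}


def _build(cls, raw: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key {sorted(unknown)[0]!r} in section {section!r}")
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    try:
        return cls(**coerced)
    except ConfigurationError as exc:
        raise ConfigurationError(f"in section {section!r}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Parse and fully validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} must contain a mapping at top level")
    top_allowed = {"data_dir", "output_dir", "threshold"} | set(_SECTIONS)
    unknown = set(raw) - top_allowed
    if unknown:
        raise ConfigurationError(f"unknown top-level key {sorted(unknown)[0]!r}")
    kwargs = {k: raw[k] for k in ("data_dir", "output_dir", "threshold") if k in raw}
    for section, cls in _SECTIONS.items():
        sub = raw.get(section, {}) or {}
        if not isinstance(sub, dict):
            raise ConfigurationError(f"section {section!r} must be a mapping")
        kwargs[section] = _build(cls, sub, section)
    return RunConfig(**kwargs).resolved()


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Serialize a RunConfig back to YAML (inverse of :func:`load_config`)."""
    path = Path(path)
    doc = {"data_dir": cfg.data_dir, "output_dir": cfg.output_dir,
           "threshold": cfg.threshold}
    for section in _SECTIONS:
        sub = asdict(getattr(cfg, section))
        doc[section] = {k: list(v) if isinstance(v, tuple) else v
                        for k, v in sub.items()}
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
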