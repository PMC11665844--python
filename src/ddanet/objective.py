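"""Hybrid training objective and segmentation evaluation metrics.

The training loss is a weighted sum of binary cross-entropy and soft Dice,

    L_total = α·L_BCE + β·L_Dice,
    L_BCE   = −(1/N) Σᵢ [yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)],
    L_Dice  = 1 − (2 Σᵢ yᵢpᵢ + s) / (Σᵢ yᵢ + Σᵢ pᵢ + s),

with α = β = 1 by default.  BCE drives per-pixel calibration and is stable
under the heavy background/lesion imbalance of CT slices; the Dice term
directly optimises region overlap, so tiny lesions are not drowned out by
the background.  The smoothing constant ``s`` resolves the empty-vs-empty
0/0 case, and probabilities are clamped away from {0, 1} before the logs.

Evaluation uses pixel confusion counts per slice:

    Dice = 2TP/(2TP+FP+FN)   Jaccard = TP/(TP+FP+FN)
    Sen  = TP/(TP+FN)        Spe     = TN/(FP+TN)
    Acc  = (TP+TN)/(TP+TN+FP+FN)

aggregated across slices as mean ± population standard deviation.  Both
loss functions accept plain NumPy arrays or autodiff tensors, so the same
code path is exercised by training and by closed-form oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .errors import ConfigurationError, DimensionError

__all__ = [
    "LossConfig", "ConfusionCounts", "SliceMetrics", "MetricsReport",
    "bce_loss", "dice_loss", "total_loss",
    "confusion", "metrics_from_counts", "evaluate_masks", "aggregate",
]

METRIC_NAMES = ("dice", "jaccard", "sensitivity", "specificity", "accuracy")


@dataclass
class LossConfig:
    """Weights and numerical guards of the hybrid objective.

    ``alpha``/``beta`` weight the BCE and Dice terms (the adopted setting is
    1.0/1.0); ``smooth`` is the Dice smoothing constant; ``clamp_eps``
    floors the log arguments of the BCE term.
    """

    alpha: float = 1.0
    beta: float = 1.0
    smooth: float = 1.0
    clamp_eps: float = 1e-7

    def __post_init__(self):
        if self.alpha < 0:
            raise ConfigurationError(f"alpha must be nonnegative, got {self.alpha}")
        if self.beta < 0:
            raise ConfigurationError(f"beta must be nonnegative, got {self.beta}")
        if self.alpha + self.beta <= 0:
            raise ConfigurationError("alpha + beta must be positive")
        if self.smooth <= 0:
            raise ConfigurationError(f"smooth must be positive, got {self.smooth}")
        if not 0.0 < self.clamp_eps < 0.5:
            raise ConfigurationError(
                f"clamp_eps must lie in (0, 0.5), got {self.clamp_eps}")


def _check_lengths(y, p) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    n = p.size if isinstance(p, Tensor) else np.asarray(p).size
    if y.size != n:
        raise ValueError(f"label vector has {y.size} entries but predictions have {n}")
    return y


def _flat(p):
    return p.reshape(-1) if isinstance(p, Tensor) else np.asarray(p, dtype=np.float64).reshape(-1)


def _log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def _clip(x, lo, hi):
    return x.clip(lo, hi) if isinstance(x, Tensor) else np.clip(x, lo, hi)


def _sum(x):
    return x.sum()


def bce_loss(y, p, clamp_eps: float = 1e-7):
    """Mean binary cross-entropy of probabilities `p` against labels `y`.

    Probabilities are clamped to [clamp_eps, 1−clamp_eps] before the logs.
    Returns a float for array input, a scalar tensor for tensor input.
    """
    y = _check_lengths(y, p)
    p = _flat(p)
    if isinstance(p, Tensor):
        y = y.astype(p.dtype)  # keep the graph in the model's compute dtype
    pc = _clip(p, clamp_eps, 1.0 - clamp_eps)
    n = y.size
    loss = -(_sum(y * _log(pc)) + _sum((1.0 - y) * _log(1.0 - pc))) * (1.0 / n)
    return loss if isinstance(loss, Tensor) else float(loss)


def dice_loss(y, p, smooth: float = 1.0):
    """Soft Dice loss 1 − (2Σyp + s)/(Σy + Σp + s)."""
    y = _check_lengths(y, p)
    p = _flat(p)
    if isinstance(p, Tensor):
        y = y.astype(p.dtype)
    inter = _sum(y * p)
    denom = _sum(y * 1.0) + _sum(p) + smooth
    loss = 1.0 - (2.0 * inter + smooth) / denom
    return loss if isinstance(loss, Tensor) else float(loss)


def total_loss(y, p, cfg: LossConfig | None = None):
    """α·BCE + β·Dice; zero-weighted terms are skipped entirely."""
    cfg = cfg or LossConfig()
    terms = []
    if cfg.alpha > 0:
        terms.append(cfg.alpha * bce_loss(y, p, cfg.clamp_eps))
    if cfg.beta > 0:
        terms.append(cfg.beta * dice_loss(y, p, cfg.smooth))
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out


# -- confusion counts and metrics ---------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of one predicted mask against its ground truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SliceMetrics:
    """The five overlap/classification metrics of a single slice."""

    dice: float
    jaccard: float
    sensitivity: float
    specificity: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(pred_mask, truth_mask) -> ConfusionCounts:
    """Exact TP/FP/TN/FN pixel tallies for co-registered binary masks."""
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise DimensionError(
            f"mask shapes differ: prediction {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, empty_ok: bool) -> float:
    if den == 0:
        return 1.0 if empty_ok else 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> SliceMetrics:
    """The five metrics of one slice, with degenerate-count conventions.

    An empty truth with an empty prediction scores 1.0 on every overlap
    metric (the "both agree there is nothing" convention); an empty truth
    with false positives scores 0.0 on sensitivity, and symmetrically for
    specificity with an all-lesion truth.
    """
    dice = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, empty_ok=True)
    jac = _ratio(c.tp, c.tp + c.fp + c.fn, empty_ok=True)
    sen = _ratio(c.tp, c.tp + c.fn, empty_ok=c.fp == 0)
    spe = _ratio(c.tn, c.fp + c.tn, empty_ok=c.fn == 0)
    acc = _ratio(c.tp + c.tn, c.total, empty_ok=True)
    return SliceMetrics(dice=dice, jaccard=jac, sensitivity=sen,
                        specificity=spe, accuracy=acc)


def evaluate_masks(pred_mask, truth_mask) -> SliceMetrics:
    """Convenience: confusion counts then metrics in one call."""
    return metrics_from_counts(confusion(pred_mask, truth_mask))


@dataclass
class MetricsReport:
    """Per-slice metric table plus mean ± population-std aggregates."""

    per_slice: pd.DataFrame          # columns: slice_id + the five metrics
    mean: pd.Series
    std: pd.Series

    @property
    def n_slices(self) -> int:
        return len(self.per_slice)

    def to_csv(self, path) -> None:
        """One row per slice, plus mean and std footer rows."""
        table = self.per_slice.copy()
        footer = pd.DataFrame([
            {"slice_id": "mean", **self.mean.to_dict()},
            {"slice_id": "std", **self.std.to_dict()},
        ])
        pd.concat([table, footer], ignore_index=True).to_csv(path, index=False)

    def __str__(self) -> str:
        parts = [f"{m}={self.mean[m]:.3f}±{self.std[m]:.3f}" for m in METRIC_NAMES]
        return f"MetricsReport(n={self.n_slices}, " + ", ".join(parts) + ")"


def aggregate(reports: list[SliceMetrics],
              slice_ids: list[str] | None = None) -> MetricsReport:
    """Mean and population standard deviation of per-slice metrics."""
    if not reports:
        raise ValueError("cannot aggregate an empty list of slice metrics")
    if slice_ids is None:
        slice_ids = [str(i) for i in range(len(reports))]
    if len(slice_ids) != len(reports):
        raise ValueError("slice_ids and reports have different lengths")
    rows = [{"slice_id": sid, **r.as_dict()} for sid, r in zip(slice_ids, reports)]
    table = pd.DataFrame(rows)
    values = table[list(METRIC_NAMES)]
    return MetricsReport(per_slice=table,
                         mean=values.mean(),
                         std=values.std(ddof=0))
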