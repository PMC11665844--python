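"""Training, checkpointing, cross-validation and evaluation pipelines.

The protocol mirrors common practice for small clinical segmentation sets:
five-fold cross-validation over slices (seeded shuffle + round-robin
assignment, so fold sizes differ by at most one), Adam at a constant
learning rate, on-the-fly augmentation of training pairs only, and
checkpoint-on-best: after every epoch the model is scored on the held-out
fold and the weights are saved whenever the mean test Dice strictly
improves.

Scoring the selection metric on the test fold itself is optimistic — the
fold steers which weights are kept — so :class:`TrainConfig.val_fraction`
optionally carves a validation subset out of the training pairs and selects
on that instead, leaving the test fold untouched until the final
evaluation.
"""

from __future__ import annotations

import json
import tempfile
from dataclasses import dataclass, field, replace as _replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .errors import ConfigurationError
from .network import DDANet, ModelConfig, binarize, load_checkpoint, save_checkpoint
from .nn import Adam
from .objective import (LossConfig, MetricsReport, SliceMetrics, aggregate,
                        confusion, metrics_from_counts, total_loss)
from .phantom import SlicePair, augment

__all__ = ["FoldManifest", "TrainConfig", "TrainLog", "five_fold_split",
           "train_fold", "evaluate", "cross_validate", "CrossValResult"]


@dataclass
class FoldManifest:
    """Deterministic assignment of every sample id to exactly one test fold."""

    n_samples: int
    n_folds: int
    assignment: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.assignment.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.assignment.items() if f != fold]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.n_folds
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"n_samples": self.n_samples, "n_folds": self.n_folds,
             "seed": self.seed, "assignment": self.assignment}, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "FoldManifest":
        raw = json.loads(Path(path).read_text())
        return cls(n_samples=raw["n_samples"], n_folds=raw["n_folds"],
                   assignment=dict(raw["assignment"]), seed=raw["seed"])


def five_fold_split(sample_ids: Sequence[str], n_folds: int = 5,
                    seed: int = 0) -> FoldManifest:
    """Seeded shuffle then round-robin fold assignment.

    Every id lands in exactly one fold and fold sizes differ by at most 1
    (e.g. 318 ids over 5 folds gives sizes 64, 64, 64, 63, 63).
    """
    ids = [str(s) for s in sample_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} samples, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: i % n_folds for i, j in enumerate(order)}
    return FoldManifest(n_samples=len(ids), n_folds=n_folds,
                        assignment=assignment, seed=seed)


@dataclass
class TrainConfig:
    """Optimisation settings (defaults follow the reference protocol:
    Adam, learning rate 1e-4, batch size 4, up to 150 epochs)."""

    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 150
    optimizer: str = "adam"
    seed: int = 0
    device: str = "cpu"
    checkpoint_dir: str | None = None
    augment_train: bool = True
    augment_ops: tuple[str, ...] = ("rotate", "flip", "scale", "contrast", "noise")
    val_fraction: float = 0.0      # >0 selects checkpoints on a train-side split
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.max_epochs < 1:
            raise ConfigurationError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.optimizer.lower() != "adam":
            raise ConfigurationError(
                f"only the adaptive-moment ('adam') optimizer is supported, "
                f"got {self.optimizer!r}")
        if self.device != "cpu":
            raise ConfigurationError(f"only device='cpu' is supported, got {self.device!r}")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ConfigurationError("val_fraction must lie in [0, 1)")


@dataclass
class TrainLog:
    """Per-epoch record of one training run."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = 0
    best_dice: float = -np.inf
    trained_ids: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _batched(pairs: list[SlicePair], batch_size: int):
    for i in range(0, len(pairs), batch_size):
        yield pairs[i:i + batch_size]


def _stack_batch(batch: list[SlicePair]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([p.image for p in batch])[:, None, :, :]
    masks = np.stack([p.mask for p in batch]).astype(np.float64)
    return images, masks


def _mean_test_metrics(model: DDANet, pairs: list[SlicePair], loss_cfg: LossConfig,
                       threshold: float, batch_size: int) -> tuple[float, float, MetricsReport]:
    """(mean test loss, mean test Dice, full report) in evaluation mode."""
    model.eval()
    losses, reports, ids = [], [], []
    try:
        for batch in _batched(pairs, batch_size):
            images, masks = _stack_batch(batch)
            prob = model(Tensor(images)).data
            losses.append(float(total_loss(masks.reshape(-1), prob, loss_cfg)))
            for p, pr in zip(batch, prob):
                reports.append(metrics_from_counts(confusion(binarize(pr, threshold), p.mask)))
                ids.append(p.slice_id)
    finally:
        model.train()
    report = aggregate(reports, ids)
    return float(np.mean(losses)), float(report.mean["dice"]), report


def train_fold(model_cfg: ModelConfig, loss_cfg: LossConfig, train_cfg: TrainConfig,
               train_pairs: list[SlicePair], test_pairs: list[SlicePair],
               evaluate_fn: Callable[[DDANet, list[SlicePair]], float] | None = None,
               ) -> tuple[Path, TrainLog]:
    """Train one fold and return (best checkpoint path, full TrainLog).

    ``evaluate_fn``, when given, replaces the built-in test-Dice scorer for
    checkpoint selection (model, selection_pairs) -> score; the built-in
    scorer reports mean test Dice at ``train_cfg.threshold``.
    """
    if not train_pairs or not test_pairs:
        raise ValueError("train and test sets must both be non-empty")
    rng = np.random.default_rng(train_cfg.seed)
    model = DDANet(model_cfg, seed=int(rng.integers(2 ** 31)))
    optim = Adam(model.parameters(), lr=train_cfg.learning_rate)

    selection_pairs = test_pairs
    fit_pairs = list(train_pairs)
    if train_cfg.val_fraction > 0:
        n_val = max(1, int(round(train_cfg.val_fraction * len(fit_pairs))))
        if n_val >= len(fit_pairs):
            raise ConfigurationError("val_fraction leaves no training pairs")
        order = rng.permutation(len(fit_pairs))
        selection_pairs = [fit_pairs[i] for i in order[:n_val]]
        fit_pairs = [fit_pairs[i] for i in order[n_val:]]

    ckpt_dir = Path(train_cfg.checkpoint_dir) if train_cfg.checkpoint_dir \
        else Path(tempfile.mkdtemp(prefix="ddanet-ckpt-"))
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    ckpt_path = ckpt_dir / "best.npz"

    log = TrainLog()
    for epoch in range(1, train_cfg.max_epochs + 1):
        order = rng.permutation(len(fit_pairs))
        epoch_losses = []
        model.train()
        for b, batch_idx in enumerate(_batched(list(order), train_cfg.batch_size)):
            batch = [fit_pairs[i] for i in batch_idx]
            if train_cfg.augment_train:
                batch = [augment(p, rng, train_cfg.augment_ops) for p in batch]
            images, masks = _stack_batch(batch)
            prob = model(Tensor(images, requires_grad=False))
            loss = total_loss(masks.reshape(-1), prob.reshape(-1), loss_cfg)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {b + 1}")
            model.zero_grad()
            loss.backward()
            optim.step()
            epoch_losses.append(loss.item())
            log.trained_ids.update(p.slice_id for p in batch)

        if evaluate_fn is not None:
            score = float(evaluate_fn(model, selection_pairs))
            test_loss, test_report = np.nan, None
        else:
            test_loss, score, test_report = _mean_test_metrics(
                model, selection_pairs, loss_cfg, train_cfg.threshold,
                train_cfg.batch_size)
        row = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
               "test_loss": test_loss, "test_dice": score}
        if test_report is not None:
            for m in ("jaccard", "sensitivity", "specificity", "accuracy"):
                row[f"test_{m}"] = float(test_report.mean[m])
        log.epochs.append(row)
        if score > log.best_dice:
            log.best_dice = score
            log.best_epoch = epoch
            save_checkpoint(model, ckpt_path)
    return ckpt_path, log


def evaluate(model_or_checkpoint, pairs: list[SlicePair], threshold: float = 0.5,
             batch_size: int = 4) -> MetricsReport:
    """Forward → binarize → confusion → per-slice metrics → aggregate.

    Runs in evaluation mode; no parameters are updated.
    """
    if isinstance(model_or_checkpoint, (str, Path)):
        model = load_checkpoint(model_or_checkpoint)
    else:
        model = model_or_checkpoint
    if not pairs:
        raise ValueError("cannot evaluate on an empty set of pairs")
    shapes = {p.image.shape for p in pairs}
    if len(shapes) > 1:
        raise ConfigurationError(f"pairs have inconsistent shapes: {sorted(shapes)}")
    was_training = model.training
    model.eval()
    reports, ids = [], []
    try:
        for batch in _batched(pairs, batch_size):
            images, _ = _stack_batch(batch)
            prob = model(Tensor(images)).data
            for p, pr in zip(batch, prob):
                pred = binarize(pr, threshold)
                reports.append(metrics_from_counts(confusion(pred, p.mask)))
                ids.append(p.slice_id)
    finally:
        model.train(was_training)
    return aggregate(reports, ids)


@dataclass
class CrossValResult:
    """Per-fold reports plus the pooled per-slice aggregate."""

    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    logs: list[TrainLog]
    checkpoints: list[Path]


def cross_validate(all_pairs: list[SlicePair], manifest: FoldManifest,
                   model_cfg: ModelConfig, loss_cfg: LossConfig,
                   train_cfg: TrainConfig) -> CrossValResult:
    """Train on each fold's complement, evaluate on the fold, pool slices."""
    by_id = {p.slice_id: p for p in all_pairs}
    missing = set(manifest.assignment) - set(by_id)
    extra = set(by_id) - set(manifest.assignment)
    if missing or extra:
        raise ConfigurationError(
            f"manifest does not cover the pairs (missing={sorted(missing)[:3]}, "
            f"unassigned={sorted(extra)[:3]})")
    fold_reports, logs, ckpts, slice_metrics, slice_ids = [], [], [], [], []
    for fold in range(manifest.n_folds):
        test_pairs = [by_id[s] for s in manifest.fold_ids(fold)]
        train_pairs = [by_id[s] for s in manifest.train_ids(fold)]
        fold_dir = (Path(train_cfg.checkpoint_dir) / f"fold{fold}"
                    if train_cfg.checkpoint_dir else None)
        fold_cfg = _replace(train_cfg, seed=train_cfg.seed + fold,
                            checkpoint_dir=str(fold_dir) if fold_dir else None)
        ckpt, log = train_fold(model_cfg, loss_cfg, fold_cfg, train_pairs, test_pairs)
        report = evaluate(ckpt, test_pairs, threshold=train_cfg.threshold,
                          batch_size=train_cfg.batch_size)
        fold_reports.append(report)
        logs.append(log)
        ckpts.append(ckpt)
        for _, row in report.per_slice.iterrows():
            slice_ids.append(row["slice_id"])
            slice_metrics.append(SliceMetrics(
                dice=row["dice"], jaccard=row["jaccard"],
                sensitivity=row["sensitivity"], specificity=row["specificity"],
                accuracy=row["accuracy"]))
    pooled = aggregate(slice_metrics, slice_ids)
    return CrossValResult(fold_reports=fold_reports, pooled=pooled,
                          logs=logs, checkpoints=ckpts)
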