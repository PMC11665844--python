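"""Shared fixtures: tiny phantoms, small model configs, and the session-wide
overfit training run reused by the engine and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from ddanet.engine import TrainConfig, train_fold
from ddanet.network import ModelConfig
from ddanet.objective import LossConfig
from ddanet.phantom import PhantomConfig, generate_dataset


def upcast_params(module) -> None:
    """Promote a module's parameters to float64 for finite-difference checks."""
    for p in module.parameters():
        p.data = p.data.astype(np.float64)
    for m in module.modules():
        for name, buf in list(m._buffers.items()):
            m._buffers[name] = buf.astype(np.float64)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar-valued `f` at `x`."""
    x = x.astype(np.float64)
    grad = np.zeros_like(x)
    flat = x.reshape(-1)
    gflat = grad.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f(x)
        flat[i] = orig - eps
        lo = f(x)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return grad


@pytest.fixture(scope="session")
def phantom_pairs_64():
    """Eight 64×64 phantom slices — the overfit-smoke training set."""
    return generate_dataset(PhantomConfig(size=64, seed=7), 8)


@pytest.fixture(scope="session")
def overfit_run(phantom_pairs_64, tmp_path_factory):
    """One seeded memorisation run on 8 phantoms with the protocol settings
    (Adam, lr 1e-4, batch 4, α=β=1); shared across tests because it is the
    single most expensive computation in the suite."""
    ckpt_dir = tmp_path_factory.mktemp("overfit-ckpt")
    tcfg = TrainConfig(max_epochs=OVERFIT_EPOCHS, seed=3, augment_train=False,
                       checkpoint_dir=str(ckpt_dir))
    ckpt, log = train_fold(ModelConfig.small(), LossConfig(), tcfg,
                           phantom_pairs_64, phantom_pairs_64)
    return ckpt, log, phantom_pairs_64


OVERFIT_EPOCHS = 400  # smoke-scale step budget (2 optimiser steps per epoch)
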