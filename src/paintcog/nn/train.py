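"""Shared minibatch training loop with a piecewise learning-rate schedule.

Deterministic given the seed: epoch shuffles come from one seeded
Generator, and all arithmetic is single-threaded NumPy.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .layers import BatchNorm2d
from .losses import softmax_cross_entropy, mse_loss
from .optim import Adam, piecewise_lr

__all__ = ["TrainConfig", "fit_network", "calibrate_batchnorm"]


def calibrate_batchnorm(model, X: np.ndarray, rng: np.random.Generator,
                        max_samples: int = 512) -> None:
    """Refresh batch-norm running statistics with one momentum-1 pass.

    Short training schedules leave the exponentially averaged running
    moments far from the activation statistics the trained weights produce;
    a single full-batch pass (on up to ``max_samples`` training images)
    replaces them with the realized moments, so eval-mode inference matches
    training behavior.
    """
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    idx = rng.permutation(X.shape[0])[:max_samples]
    saved = [b.momentum for b in bns]
    for b in bns:
        b.momentum = 1.0
    model.forward(X[idx], train=True)
    for b, m in zip(bns, saved):
        b.momentum = m


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam with a step-decay schedule).

    Defaults follow the published training recipe for the score-prediction
    network: 30 epochs, initial rate 0.01 halved every 10 epochs, minibatch
    128 (clipped to the training-set size), L2 coefficient 0.005.
    """

    optimizer: str = "adam"
    max_epochs: int = 30
    initial_lr: float = 0.01
    batch_size: int = 128
    schedule: str = "piecewise"
    drop_period: int = 10
    drop_factor: float = 0.5
    l2: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1 or self.initial_lr <= 0 or self.batch_size < 1:
            raise ValueError("epochs, learning rate and batch size must be positive")
        if not (0 < self.drop_factor <= 1):
            raise ValueError("drop factor must lie in (0, 1]")

    def lr_at(self, epoch: int) -> float:
        if self.schedule == "piecewise":
            return piecewise_lr(self.initial_lr, epoch, self.drop_period, self.drop_factor)
        return self.initial_lr

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


def fit_network(model, X: np.ndarray, y: np.ndarray, config: TrainConfig,
                task: str = "classification") -> list[float]:
    """Train ``model`` in place; returns the per-epoch mean loss curve.

    ``X`` is NCHW float32 in [0, 1]; ``y`` integer labels (classification)
    or float targets (regression, MSE loss).
    """
    if task == "classification" and np.unique(y).size < 2:
        raise ValueError("training set must contain at least two classes")
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.initial_lr, weight_decay=config.l2)
    batch = min(config.batch_size, n)
    loss_fn = softmax_cross_entropy if task == "classification" else mse_loss
    curve: list[float] = []
    for epoch in range(1, config.max_epochs + 1):
        opt.lr = config.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            opt.zero_grad()
            out = model.forward(X[idx], train=True)
            loss, grad = loss_fn(out, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss}); "
                    "reduce the learning rate")
            model.backward(grad)
            opt.step()
            losses.append(loss)
        curve.append(float(np.mean(losses)))
    calibrate_batchnorm(model, X, rng)
    return curve
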