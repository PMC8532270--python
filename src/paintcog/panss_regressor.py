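"""Convolutional regression of PANSS scores from paintings.

A compact 10-layer network maps a 224x224x3 painting to one scalar score:

====  =======================  ============
 #    layer                    output size
====  =======================  ============
 1    image input              224x224x3
 2    batch norm               224x224x3
 3    conv 8x8, stride 4       55x55x8
 4    batch norm               55x55x8
 5    conv 3x3, stride 2       27x27x16
 6    batch norm               27x27x16
 7    conv 3x3, stride 2       13x13x32
 8    average pool 3x3/2 p1    7x7x32
 9    fully connected          1
 10   MSE regression output    1
====  =======================  ============

Kernel geometries are the minimal conventional choices realizing these
output sizes; a rectifier follows each convolution (disable with
``relu=False`` for a purely linear stack).  One independent network is
trained per target (P, N, G, total) with Adam under the step-decay recipe
(30 epochs, lr 0.01 halved every 10, minibatch 128, L2 0.005).  Targets are
z-scored internally using training-set statistics and predictions mapped
back, which keeps the published learning rate usable on raw score scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import images_to_tensor
from .nn import (
    AvgPool2d, BatchNorm2d, Conv2d, Flatten, Linear, ReLU, Sequential,
    TrainConfig, fit_network,
)
from .stats_compare import rmse

__all__ = [
    "TABLE_SHAPES",
    "PanssNetSpec",
    "build_panss_net",
    "default_train_config",
    "split_valid_subjects",
    "PanssRegression",
    "RegressionResults",
    "train_and_evaluate",
]

TARGET_COLUMNS = {"p": "panss_p", "n": "panss_n", "g": "panss_g", "total": "panss_total"}

#: printed layer output sizes (C, H, W), verified at build time
TABLE_SHAPES = (
    ("input", (3, 224, 224)),
    ("conv1", (8, 55, 55)),
    ("conv2", (16, 27, 27)),
    ("conv3", (32, 13, 13)),
    ("avgpool", (32, 7, 7)),
    ("fc", (1,)),
)


@dataclass(frozen=True)
class PanssNetSpec:
    layers: tuple  # (name, expected shape)

    def expected(self, name: str):
        return dict(self.layers)[name]


class _ShapeError(AssertionError):
    pass


def build_panss_net(seed: int = 0, relu: bool = True):
    """Build the regression network; returns ``(PanssNetSpec, model)``.

    The realized forward-pass shapes are verified against the printed sizes
    at build time (hard assertion).
    """
    rng = np.random.default_rng(seed)
    layers = [BatchNorm2d(3), Conv2d(3, 8, 8, stride=4, padding=0, rng=rng)]
    if relu:
        layers.append(ReLU())
    layers += [BatchNorm2d(8), Conv2d(8, 16, 3, stride=2, padding=0, rng=rng)]
    if relu:
        layers.append(ReLU())
    layers += [BatchNorm2d(16), Conv2d(16, 32, 3, stride=2, padding=0, rng=rng)]
    if relu:
        layers.append(ReLU())
    layers += [AvgPool2d(3, 2, 1), Flatten(), Linear(7 * 7 * 32, 1, rng=rng)]
    model = Sequential(*layers)
    spec = PanssNetSpec(layers=TABLE_SHAPES)
    realized = forward_shapes(model, (3, 224, 224))
    for name, expect in TABLE_SHAPES[1:]:
        if realized[name] != expect:
            raise _ShapeError(f"{name}: realized {realized[name]} != printed {expect}")
    return spec, model


def forward_shapes(model: Sequential, input_shape) -> dict:
    """Probe realized output shapes of the named stages with a zero input."""
    x = np.zeros((1,) + tuple(input_shape), dtype=np.float32)
    shapes: dict = {}
    conv_i = 0
    for layer in model.layers:
        x = layer.forward(x, train=False)
        if isinstance(layer, Conv2d):
            conv_i += 1
            shapes[f"conv{conv_i}"] = x.shape[1:]
        elif isinstance(layer, AvgPool2d):
            shapes["avgpool"] = x.shape[1:]
        elif isinstance(layer, Linear):
            shapes["fc"] = x.shape[1:]
    return shapes


def default_train_config(seed: int = 0) -> TrainConfig:
    """The published training recipe for the score-prediction network."""
    return TrainConfig(optimizer="adam", max_epochs=30, initial_lr=0.01,
                       batch_size=128, schedule="piecewise", drop_period=10,
                       drop_factor=0.5, l2=0.005, seed=seed)


def split_valid_subjects(cohort, train_frac: float = 0.75, seed: int = 0,
                         group: str | None = "SCZ"):
    """Exclude subjects with missing PANSS; split the rest train/test.

    The training share is ``floor(train_frac * n_valid)``.  By default only
    patients enter (scores are collected clinically from the patient group);
    pass ``group=None`` to use every scored subject.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    valid = [s.id for s in cohort.subjects
             if not s.panss_missing and (group is None or s.group == group)]
    if not valid:
        raise ValueError("no subjects with valid PANSS scores")
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(valid))
    n_train = int(np.floor(train_frac * len(order)))
    return list(order[:n_train]), list(order[n_train:])


@dataclass
class RegressionResults:
    """Test-set RMSE and actual-vs-predicted pairs for one target."""

    target: str
    rmse: float
    baseline_rmse: float  # mean-predictor on the same test set
    pairs: pd.DataFrame   # columns: id, actual, predicted
    loss_curve: list
    n_train: int
    n_test: int
    seed: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "target": self.target, "rmse": self.rmse,
            "baseline_rmse": self.baseline_rmse,
            "n_train": self.n_train, "n_test": self.n_test,
        }])

    def to_json_dict(self) -> dict:
        return {
            "target": self.target, "rmse": self.rmse,
            "baseline_rmse": self.baseline_rmse,
            "n_train": self.n_train, "n_test": self.n_test, "seed": self.seed,
            "pairs": self.pairs.to_dict(orient="records"),
        }


class PanssRegression:
    """Fit one score-prediction network per PANSS target on a cohort.

    Parameters
    ----------
    cohort : Cohort
    target : "p", "n", "g" or "total"
    config : TrainConfig (defaults to the published recipe)
    input_size : image size fed to the network; (224, 224) realizes the
        printed layer shapes
    """

    def __init__(self, cohort, target: str = "total",
                 config: TrainConfig | None = None, train_frac: float = 0.75,
                 input_size=(224, 224), group: str | None = "SCZ"):
        if target not in TARGET_COLUMNS:
            raise ValueError(f"target must be one of {sorted(TARGET_COLUMNS)}")
        self.cohort = cohort
        self.target = target
        self.config = config or default_train_config()
        self.train_frac = train_frac
        self.input_size = tuple(input_size)
        self.group = group

    def fit(self, seed: int | None = None) -> RegressionResults:
        seed = self.config.seed if seed is None else seed
        train_ids, test_ids = split_valid_subjects(
            self.cohort, self.train_frac, seed=seed, group=self.group)
        if not test_ids:
            raise ValueError("test split is empty; reduce train_frac")
        col = TARGET_COLUMNS[self.target]
        score_of = {s.id: getattr(s, col) for s in self.cohort.subjects}
        y_train = np.array([score_of[i] for i in train_ids], dtype=np.float64)
        y_test = np.array([score_of[i] for i in test_ids], dtype=np.float64)
        X_train = images_to_tensor(self.cohort.images, train_ids, self.input_size)
        X_test = images_to_tensor(self.cohort.images, test_ids, self.input_size)

        if self.input_size == (224, 224):
            _, model = build_panss_net(seed=seed)
        else:  # scaled-down variant for quick tests; same topology, adapted fc
            _, model = _build_free_size_net(self.input_size, seed=seed)

        # z-score targets on the training set; predictions mapped back
        mu, sd = y_train.mean(), y_train.std()
        sd = sd if sd > 0 else 1.0
        cfg = TrainConfig(**{**self.config.to_dict(), "seed": seed})
        curve = fit_network(model, X_train, (y_train - mu) / sd, cfg, task="regression")

        preds = []
        for start in range(0, X_test.shape[0], 64):
            out = model.forward(X_test[start:start + 64], train=False)
            preds.append(out.reshape(-1))
        predicted = np.concatenate(preds) * sd + mu
        pairs = pd.DataFrame({"id": test_ids, "actual": y_test, "predicted": predicted})
        return RegressionResults(
            target=self.target,
            rmse=rmse(predicted, y_test),
            baseline_rmse=rmse(np.full_like(y_test, y_train.mean()), y_test),
            pairs=pairs, loss_curve=curve,
            n_train=len(train_ids), n_test=len(test_ids), seed=seed)


def _build_free_size_net(input_size, seed: int = 0):
    """Same conv stack on a non-standard canvas; fc width inferred."""
    rng = np.random.default_rng(seed)
    model = Sequential(
        BatchNorm2d(3),
        Conv2d(3, 8, 8, stride=4, padding=0, rng=rng), ReLU(),
        BatchNorm2d(8),
        Conv2d(8, 16, 3, stride=2, padding=0, rng=rng), ReLU(),
        BatchNorm2d(16),
        Conv2d(16, 32, 3, stride=2, padding=0, rng=rng), ReLU(),
        AvgPool2d(3, 2, 1),
        Flatten(),
    )
    probe = model.forward(np.zeros((1, 3) + tuple(input_size), dtype=np.float32))
    model.layers.append(Linear(probe.shape[1], 1, rng=rng))
    return None, model


def train_and_evaluate(cohort, target: str, config: TrainConfig | None = None,
                       **kwargs) -> RegressionResults:
    """Functional wrapper: fit :class:`PanssRegression` in one call."""
    return PanssRegression(cohort, target=target, config=config, **kwargs).fit()
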