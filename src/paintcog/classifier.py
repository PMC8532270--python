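"""Patient-vs-control painting classification with a residual CNN.

Protocol: a per-class hold-out split (defaults: 20 train / 15 test healthy,
266 train / 15 test patients), 13x duplication-oversampling of the healthy
training minority (never of the test set), cross-entropy training of a
residual network with a 2-neuron head, confusion-matrix evaluation, and the
whole cycle repeated over independently re-drawn splits with the per-run
accuracies summarized as mean +/- SD.

Two network variants: ``resnet18`` (the standard 18-weighted-layer residual
topology, 4 stages of 2 basic blocks at widths 64/128/256/512, input
224x224x3) and ``small`` (a 2-stage residual net for desk-scale runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .nn import (
    BatchNorm2d, Conv2d, GlobalAvgPool, Linear, MaxPool2d, ReLU,
    ResidualBlock, Sequential, TrainConfig, fit_network, softmax,
)

__all__ = [
    "NetworkSpec",
    "SplitPlan",
    "ConfusionMatrix2x2",
    "RunSummary",
    "build_residual_net",
    "make_split",
    "oversample_minority",
    "train_classifier",
    "evaluate_classifier",
    "images_to_tensor",
    "PaintingClassifier",
    "ClassificationResults",
    "repeated_runs",
]

#: label coding: control is 0, patient is 1 (patient = positive class)
HC_LABEL, SCZ_LABEL = 0, 1


@dataclass(frozen=True)
class NetworkSpec:
    """Declared layer list with expected output shapes (C, H, W) / (F,)."""

    layers: tuple  # of (name, kind, expected_shape)
    head_width: int


@dataclass(frozen=True)
class SplitPlan:
    train: dict  # group -> tuple of ids
    test: dict
    seed: int

    def __post_init__(self):
        for g in self.train:
            overlap = set(self.train[g]) & set(self.test[g])
            if overlap:
                raise ValueError(f"train/test overlap in group {g}: {overlap}")

    def all_train(self) -> list:
        return [i for g in sorted(self.train) for i in self.train[g]]

    def all_test(self) -> list:
        return [i for g in sorted(self.test) for i in self.test[g]]


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Patient = positive: TP patients called patients, TN controls called controls."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        """Percent correct over the test set."""
        return 100.0 * (self.tp + self.tn) / self.n

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass(frozen=True)
class RunSummary:
    """Per-run accuracies (percent) with their mean and SD."""

    accuracies: tuple

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        if len(self.accuracies) < 2:
            return 0.0
        return float(np.std(self.accuracies, ddof=1))


def _stem(width: int, in_ch: int, rng, small: bool):
    if small:
        return [Conv2d(in_ch, width, 3, stride=1, padding=1, rng=rng)]
    return [Conv2d(in_ch, width, 7, stride=2, padding=3, rng=rng),
            BatchNorm2d(width), ReLU(), MaxPool2d(3, 2, 1)]


def build_residual_net(variant: str = "small", input_shape=(3, 224, 224),
                       n_outputs: int = 2, seed: int = 0):
    """Construct a residual classifier; returns ``(NetworkSpec, model)``.

    Residual blocks are pre-activation (y = x + F(x)); ``resnet18`` uses the
    standard 4-stage/2-block topology with a replaced ``n_outputs``-neuron
    head, ``small`` a 2-block net suitable for quick CPU training.
    """
    c, h, w = input_shape
    rng = np.random.default_rng(seed)
    specs = []
    if variant == "resnet18":
        if (h, w) != (224, 224):
            raise ValueError("resnet18 variant expects 224x224 input")
        layers = _stem(64, c, rng, small=False)
        specs.append(("stem", "conv7x7/2+maxpool", (64, 56, 56)))
        cur = 64
        hw = 56
        for stage, width in enumerate((64, 128, 256, 512)):
            stride = 1 if stage == 0 else 2
            layers.append(ResidualBlock(cur, width, stride=stride, rng=rng))
            layers.append(ResidualBlock(width, width, stride=1, rng=rng))
            hw = hw // stride
            specs.append((f"stage{stage + 1}", "2x basic block", (width, hw, hw)))
            cur = width
    elif variant == "small":
        layers = _stem(8, c, rng, small=True)
        specs.append(("stem", "conv3x3", (8, h, w)))
        layers.append(ResidualBlock(8, 8, stride=1, rng=rng))
        specs.append(("stage1", "basic block", (8, h, w)))
        layers.append(ResidualBlock(8, 16, stride=2, rng=rng))
        specs.append(("stage2", "basic block /2", (16, h // 2, w // 2)))
        cur, hw = 16, h // 2
    else:
        raise ValueError(f"unknown variant {variant!r}")
    layers += [BatchNorm2d(cur), ReLU(), GlobalAvgPool()]
    specs.append(("pool", "global average pool", (cur,)))
    layers.append(Linear(cur, n_outputs, rng=rng))
    specs.append(("head", "fully connected", (n_outputs,)))
    model = Sequential(*layers)
    return NetworkSpec(layers=tuple(specs), head_width=n_outputs), model


DEFAULT_PLAN_COUNTS = {"HC": (20, 15), "SCZ": (266, 15)}


def make_split(cohort, plan_counts: dict | None = None, seed: int = 0) -> SplitPlan:
    """Draw disjoint per-class train/test id sets, uniformly without replacement."""
    plan_counts = plan_counts or DEFAULT_PLAN_COUNTS
    rng = np.random.default_rng(seed)
    by_group = cohort.ids_by_group()
    train, test = {}, {}
    for group, (n_train, n_test) in plan_counts.items():
        ids = np.array(sorted(by_group[group]))
        if len(ids) < n_train + n_test:
            raise ValueError(
                f"group {group} has {len(ids)} subjects, needs {n_train + n_test}")
        picked = rng.choice(ids, size=n_train + n_test, replace=False)
        train[group] = tuple(picked[:n_train])
        test[group] = tuple(picked[n_train:])
    return SplitPlan(train=train, test=test, seed=seed)


def oversample_minority(train_ids, factor: int) -> list:
    """Duplicate every minority-class training id exactly ``factor`` times."""
    if int(factor) != factor or factor < 1:
        raise ValueError("oversampling factor must be an integer >= 1")
    return [i for i in train_ids for _ in range(int(factor))]


def images_to_tensor(images: dict, ids, size: tuple) -> np.ndarray:
    """Stack images as NCHW float32 in [0, 1], bilinear-resizing if needed."""
    h, w = size
    out = np.empty((len(ids), 3, h, w), dtype=np.float32)
    for k, sid in enumerate(ids):
        arr = images[sid]
        if arr.shape[:2] != (h, w):
            arr = np.asarray(Image.fromarray(arr).resize((w, h), Image.BILINEAR))
        out[k] = arr.transpose(2, 0, 1).astype(np.float32) / 255.0
    return out


def train_classifier(model, train_images: np.ndarray, labels: np.ndarray,
                     train_config: TrainConfig) -> list[float]:
    """Cross-entropy training; returns the per-epoch loss curve."""
    return fit_network(model, train_images, np.asarray(labels, dtype=np.int64),
                       train_config, task="classification")


def predict_labels(model, images: np.ndarray, batch: int = 64) -> np.ndarray:
    """Argmax class per image; logit ties resolve toward the control class."""
    preds = []
    for start in range(0, images.shape[0], batch):
        logits = model.forward(images[start:start + batch], train=False)
        preds.append(np.argmax(logits, axis=1))  # first (HC) wins ties
    return np.concatenate(preds)


def evaluate_classifier(model, test_images: np.ndarray, labels: np.ndarray):
    """Confusion matrix (patient positive) and accuracy percent on a test set."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("test set is empty")
    pred = predict_labels(model, test_images)
    cm = ConfusionMatrix2x2(
        tp=int(np.sum((pred == SCZ_LABEL) & (labels == SCZ_LABEL))),
        fn=int(np.sum((pred == HC_LABEL) & (labels == SCZ_LABEL))),
        fp=int(np.sum((pred == SCZ_LABEL) & (labels == HC_LABEL))),
        tn=int(np.sum((pred == HC_LABEL) & (labels == HC_LABEL))),
    )
    return cm, cm.accuracy


@dataclass
class ClassificationResults:
    """Aggregated repeated-run hold-out results."""

    summary_runs: RunSummary
    confusion_matrices: list
    loss_curves: list
    plans: list
    variant: str
    oversample_factor: int
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return self.summary_runs.mean

    @property
    def sd_accuracy(self) -> float:
        return self.summary_runs.sd

    def summary(self) -> pd.DataFrame:
        rows = [{"run": i + 1, "accuracy": acc, **cm.as_dict()}
                for i, (acc, cm) in enumerate(
                    zip(self.summary_runs.accuracies, self.confusion_matrices))]
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "variant": self.variant,
            "oversample_factor": self.oversample_factor,
            "seed": self.seed,
            "n_runs": len(self.summary_runs.accuracies),
            "accuracies": list(self.summary_runs.accuracies),
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "confusion_matrices": [c.as_dict() for c in self.confusion_matrices],
        }


class PaintingClassifier:
    """Repeated hold-out residual-CNN classification of a painting cohort.

    Parameters
    ----------
    cohort : Cohort
    variant : "small" or "resnet18"
    input_size : (H, W) fed to the network (224x224 for resnet18)
    plan_counts : per-group (train, test) counts; defaults to the
        20/15 healthy, 266/15 patient hold-out
    oversample_factor : duplication factor for the healthy training minority
    train_config : optimization hyperparameters
    """

    def __init__(self, cohort, variant: str = "small", input_size=(64, 64),
                 plan_counts: dict | None = None, oversample_factor: int = 13,
                 train_config: TrainConfig | None = None):
        self.cohort = cohort
        self.variant = variant
        self.input_size = (224, 224) if variant == "resnet18" else tuple(input_size)
        self.plan_counts = plan_counts or DEFAULT_PLAN_COUNTS
        self.oversample_factor = oversample_factor
        self.train_config = train_config or TrainConfig(max_epochs=10, batch_size=64)

    def _run_once(self, run_seed: int):
        plan = make_split(self.cohort, self.plan_counts, seed=run_seed)
        train_ids = oversample_minority(plan.train["HC"], self.oversample_factor) \
            + list(plan.train["SCZ"])
        test_ids = plan.all_test()
        # test-set purity: the oversampled training multiset never leaks test ids
        assert not set(train_ids) & set(test_ids)
        group_of = {s.id: s.group for s in self.cohort.subjects}
        y_train = np.array([SCZ_LABEL if group_of[i] == "SCZ" else HC_LABEL
                            for i in train_ids])
        y_test = np.array([SCZ_LABEL if group_of[i] == "SCZ" else HC_LABEL
                           for i in test_ids])
        X_train = images_to_tensor(self.cohort.images, train_ids, self.input_size)
        X_test = images_to_tensor(self.cohort.images, test_ids, self.input_size)
        _, model = build_residual_net(self.variant, (3,) + self.input_size,
                                      n_outputs=2, seed=run_seed)
        cfg = TrainConfig(**{**self.train_config.to_dict(), "seed": run_seed})
        curve = train_classifier(model, X_train, y_train, cfg)
        cm, acc = evaluate_classifier(model, X_test, y_test)
        return plan, curve, cm, acc

    def fit(self, n_runs: int = 10, seed: int = 0) -> ClassificationResults:
        """Run the split/oversample/train/evaluate cycle ``n_runs`` times."""
        if n_runs < 1:
            raise ValueError("need at least one run")
        accs, cms, curves, plans = [], [], [], []
        for r in range(n_runs):
            run_seed = (seed * 10007 + r) % (2**31 - 1)
            plan, curve, cm, acc = self._run_once(run_seed)
            plans.append(plan)
            curves.append(curve)
            cms.append(cm)
            accs.append(acc)
        return ClassificationResults(
            summary_runs=RunSummary(accuracies=tuple(accs)),
            confusion_matrices=cms, loss_curves=curves, plans=plans,
            variant=self.variant, oversample_factor=self.oversample_factor,
            seed=seed)


def repeated_runs(cohort, n_runs: int = 10, base_config: dict | None = None,
                  seed: int = 0) -> ClassificationResults:
    """Functional wrapper around :class:`PaintingClassifier`."""
    base_config = base_config or {}
    clf = PaintingClassifier(cohort, **base_config)
    return clf.fit(n_runs=n_runs, seed=seed)
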