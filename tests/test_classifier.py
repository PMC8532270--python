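"""Residual classifier: topology, split protocol, oversampling, evaluation."""

import numpy as np
import pytest

from paintcog.classifier import (
    ConfusionMatrix2x2,
    PaintingClassifier,
    RunSummary,
    build_residual_net,
    evaluate_classifier,
    images_to_tensor,
    make_split,
    oversample_minority,
)
from paintcog.nn import ResidualBlock, TrainConfig, fit_network


class TestBuildNet:
    def test_head_width_is_two(self):
        spec, model = build_residual_net("resnet18", (3, 224, 224), n_outputs=2)
        assert spec.head_width == 2
        out = model.forward(np.zeros((1, 3, 224, 224), dtype=np.float32))
        assert out.shape == (1, 2)

    def test_small_variant_declared_shapes_match_forward(self):
        """Shape propagation oracle: declared stage shapes equal realized ones."""
        spec, model = build_residual_net("small", (3, 64, 64), n_outputs=2)
        x = np.zeros((2, 3, 64, 64), dtype=np.float32)
        realized = []
        for layer in model.layers:
            x = layer.forward(x)
            realized.append(x.shape[1:])
        declared = dict((name, shape) for name, _, shape in spec.layers)
        assert declared["stem"] == (8, 64, 64)
        assert declared["stage2"] == (16, 32, 32)
        assert realized[-1] == (2,)
        assert declared["stage2"] in realized

    def test_every_block_satisfies_residual_identity(self):
        _, model = build_residual_net("small", (3, 32, 32))
        blocks = [m for m in model.modules() if isinstance(m, ResidualBlock)]
        assert blocks
        for b in blocks:
            if b.shortcut is None:
                b.zero_residual_branch()
                x = np.random.default_rng(0).normal(
                    size=(2, 8, 16, 16)).astype(np.float32)
                assert np.array_equal(b.forward(x), x)

    def test_bad_variant_and_shape_rejected(self):
        with pytest.raises(ValueError):
            build_residual_net("vgg", (3, 64, 64))
        with pytest.raises(ValueError):
            build_residual_net("resnet18", (3, 64, 64))


class TestSplit:
    def _cohort(self, n_hc=35, n_scz=281):
        # metadata-only stand-in: split logic never touches images
        class C:
            def __init__(self):
                self._groups = {"HC": [f"HC{i:04d}" for i in range(n_hc)],
                                "SCZ": [f"SCZ{i:04d}" for i in range(n_scz)]}

            def ids_by_group(self):
                return self._groups

        return C()

    def test_study_design_totals(self):
        plan = make_split(self._cohort(), seed=0)
        assert len(plan.all_train()) == 286
        assert len(plan.all_test()) == 30
        assert len(plan.train["HC"]) == 20 and len(plan.test["HC"]) == 15
        assert len(plan.train["SCZ"]) == 266 and len(plan.test["SCZ"]) == 15

    def test_same_seed_reproduces_plan(self):
        a = make_split(self._cohort(), seed=5)
        b = make_split(self._cohort(), seed=5)
        assert a == b

    def test_disjointness_over_many_seeds(self):
        cohort = self._cohort(40, 60)
        counts = {"HC": (25, 10), "SCZ": (40, 15)}
        for seed in range(100):
            plan = make_split(cohort, counts, seed=seed)
            for g in ("HC", "SCZ"):
                assert len(set(plan.train[g]) & set(plan.test[g])) == 0
                assert len(plan.train[g]) == counts[g][0]
                assert len(plan.test[g]) == counts[g][1]

    def test_insufficient_class_size_rejected(self):
        with pytest.raises(ValueError):
            make_split(self._cohort(10, 300), seed=0)


class TestOversample:
    def test_study_arithmetic(self):
        ids = [f"HC{i}" for i in range(20)]
        assert len(oversample_minority(ids, 13)) == 260

    def test_identity_factor(self):
        ids = ["a", "b", "c"]
        assert oversample_minority(ids, 1) == ids

    def test_exact_multiplicity(self):
        out = oversample_minority(["x", "y", "z"], 2)
        assert len(out) == 6
        assert all(out.count(i) == 2 for i in ("x", "y", "z"))

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            oversample_minority(["a"], 0)


class _FixedPredictor:
    """Stand-in model emitting predetermined logits."""

    def __init__(self, labels):
        self.labels = np.asarray(labels)

    def forward(self, x, train=False):
        n = x.shape[0]
        logits = np.zeros((n, 2), dtype=np.float32)
        logits[np.arange(n), self.labels[:n]] = 1.0
        self.labels = self.labels[n:] if len(self.labels) > n else self.labels
        return logits


class TestEvaluate:
    def test_perfect_predictor(self):
        y = np.array([0] * 15 + [1] * 15)
        cm, acc = evaluate_classifier(_FixedPredictor(y), np.zeros((30, 3, 8, 8)), y)
        assert acc == 100.0
        assert cm.fn == cm.fp == 0 and cm.tp == 15 and cm.tn == 15

    def test_inverting_predictor(self):
        y = np.array([0] * 5 + [1] * 5)
        cm, acc = evaluate_classifier(_FixedPredictor(1 - y), np.zeros((10, 3, 8, 8)), y)
        assert acc == 0.0 and cm.tp == 0 and cm.tn == 0

    def test_27_of_30_gives_90(self):
        y = np.array([0] * 15 + [1] * 15)
        pred = y.copy()
        pred[:3] = 1 - pred[:3]
        cm, acc = evaluate_classifier(_FixedPredictor(pred), np.zeros((30, 3, 8, 8)), y)
        assert acc == pytest.approx(90.0)
        assert cm.n == 30


class TestRunSummary:
    def test_published_run_aggregation(self):
        """The ten printed per-run accuracies average to 90.33."""
        runs = (96.67, 96.67, 93.33, 90.00, 90.00, 90.00, 90.00, 86.67, 86.67, 83.33)
        rs = RunSummary(accuracies=runs)
        assert round(rs.mean, 2) == 90.33
        assert rs.sd > 0

    def test_single_run_sd_zero(self):
        rs = RunSummary(accuracies=(90.0,))
        assert rs.mean == 90.0 and rs.sd == 0.0

    def test_identical_runs_sd_zero(self):
        rs = RunSummary(accuracies=(88.0, 88.0, 88.0))
        assert rs.sd == 0.0


class TestTraining:
    def test_separable_color_pair_reaches_full_training_accuracy(self):
        """Blue-fill vs red-fill images are learned in a few epochs."""
        rng = np.random.default_rng(0)
        X = np.zeros((16, 3, 16, 16), dtype=np.float32)
        X[:8, 2] = 1.0   # blue class
        X[8:, 0] = 1.0   # red class
        X += rng.normal(0, 0.02, X.shape).astype(np.float32)
        y = np.array([0] * 8 + [1] * 8)
        _, model = build_residual_net("small", (3, 16, 16), seed=1)
        curve = fit_network(model, X, y, TrainConfig(max_epochs=5, batch_size=8,
                                                     seed=1), "classification")
        assert all(np.isfinite(curve))
        _, acc = evaluate_classifier(model, X, y)
        assert acc == 100.0

    def test_repeat_with_same_seed_is_identical(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3, 16, 16)).astype(np.float32)
        y = np.array([0, 1] * 6)
        curves = []
        for _ in range(2):
            _, model = build_residual_net("small", (3, 16, 16), seed=3)
            curves.append(fit_network(model, X, y,
                                      TrainConfig(max_epochs=2, batch_size=6, seed=3),
                                      "classification"))
        assert curves[0] == curves[1]

    def test_fit_on_cohort_respects_test_purity(self, tiny_cohort):
        clf = PaintingClassifier(
            tiny_cohort, variant="small", input_size=(32, 32),
            plan_counts={"HC": (12, 6), "SCZ": (20, 6)}, oversample_factor=2,
            train_config=TrainConfig(max_epochs=2, batch_size=16))
        res = clf.fit(n_runs=2, seed=4)
        assert len(res.summary_runs.accuracies) == 2
        for plan, cm in zip(res.plans, res.confusion_matrices):
            assert cm.n == 12
            for g in ("HC", "SCZ"):
                assert not set(plan.train[g]) & set(plan.test[g])
        df = res.summary()
        assert list(df.columns[:2]) == ["run", "accuracy"]
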