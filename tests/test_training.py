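"""Split arithmetic, cross-entropy, training reproducibility and regimes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import log_loss

import wearstate as ws
from wearstate.io import FeatureDataset
from wearstate.training import (
    OptimizerConfig,
    categorical_cross_entropy,
    split_type1,
    split_type2,
)

#: Published pool size and per-fold test-set sizes of the 15-subject cohort.
POOL = 880_590
FOLD_TEST_SIZES = [59_500, 62_860, 62_760, 60_720, 68_940, 50_910, 53_140,
                   50_410, 53_430, 50_810, 67_420, 57_640, 62_450, 63_110, 56_490]


class TestTypeISplit:
    def test_published_70_20_10_sizes(self):
        plan = split_type1(POOL, seed=0)
        assert (len(plan.train), len(plan.val), len(plan.test)) == (616_413, 176_118, 88_059)

    def test_tiny_pool(self):
        plan = split_type1(10, seed=0)
        assert (len(plan.train), len(plan.val), len(plan.test)) == (7, 2, 1)

    def test_deterministic_and_disjoint(self):
        a, b = split_type1(1000, seed=5), split_type1(1000, seed=5)
        for x, y in zip((a.train, a.val, a.test), (b.train, b.val, b.test)):
            np.testing.assert_array_equal(x, y)
        a.validate(1000)

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_type1(9)


def _fake_cohort_dataset(test_sizes: list[int]) -> FeatureDataset:
    """Index-only dataset with the published per-subject sample counts."""
    subject_ids = np.repeat([f"S{i + 1}" for i in range(len(test_sizes))], test_sizes)
    n = len(subject_ids)
    return FeatureDataset(np.zeros((n, 28)), np.zeros(n, dtype=np.int64), subject_ids)


@pytest.fixture(scope="module")
def cohort_ds():
    return _fake_cohort_dataset(FOLD_TEST_SIZES)


class TestTypeIISplit:
    def test_published_fold_sizes(self, cohort_ds):
        """All 15 leave-one-subject-out folds reproduce the published
        train/validation/test sample counts exactly."""
        expected_train = [656_872, 654_184, 654_264, 655_896, 649_320, 663_744,
                         661_960, 664_144, 661_728, 663_824, 650_536, 658_360,
                         654_512, 653_984, 659_280]
        for i, test_size in enumerate(FOLD_TEST_SIZES):
            plan = split_type2(cohort_ds, f"S{i + 1}", seed=0)
            assert len(plan.test) == test_size
            assert len(plan.train) == expected_train[i]
            assert len(plan.val) == POOL - test_size - expected_train[i]

    def test_no_subject_leakage(self, features):
        for subject in ("S1", "S2", "S3"):
            plan = split_type2(features, subject, seed=3)
            held = set(np.flatnonzero(features.subject_ids == subject))
            assert held == set(plan.test.tolist())
            assert not held & set(plan.train.tolist())
            assert not held & set(plan.val.tolist())

    def test_unknown_subject(self, features):
        with pytest.raises(ValueError, match="unknown subject"):
            split_type2(features, "S99")

    def test_single_subject_cohort_rejected(self):
        ds = _fake_cohort_dataset([100])
        with pytest.raises(ValueError, match="one subject"):
            split_type2(ds, "S1")


class TestCrossEntropy:
    def test_perfect_predictions(self):
        y = np.eye(5)
        assert categorical_cross_entropy(y, y) == 0.0

    def test_uniform_predictions(self):
        y = np.eye(5)[[0, 2, 4]]
        p = np.full((3, 5), 0.2)
        assert categorical_cross_entropy(y, p) == pytest.approx(np.log(5), abs=1e-12)

    def test_hand_computed_two_samples(self):
        y = np.zeros((2, 5))
        y[0, 0] = y[1, 3] = 1.0
        p = np.array([
            [0.5, 0.125, 0.125, 0.125, 0.125],       # true class 0 at p=0.5
            [0.1875, 0.1875, 0.1875, 0.25, 0.1875],  # true class 3 at p=0.25
        ])
        got = categorical_cross_entropy(y, p)
        assert got == pytest.approx((-np.log(0.5) - np.log(0.25)) / 2, abs=1e-9)

    def test_zero_probability_clipped_not_raised(self):
        y = np.eye(5)[[1]]
        p = np.zeros((1, 5))
        p[0, 0] = 1.0
        loss = categorical_cross_entropy(y, p)
        assert loss == pytest.approx(-np.log(1e-12))

    def test_matches_sklearn_log_loss(self):
        rng = np.random.default_rng(8)
        raw = rng.random((500, 5))
        p = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 5, 500)
        y = np.eye(5)[labels]
        ours = categorical_cross_entropy(y, p)
        ref = log_loss(labels, p, labels=list(range(5)))
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_invalid_rows_rejected(self):
        y = np.eye(5)[[0]]
        with pytest.raises(ValueError, match="sum to 1"):
            categorical_cross_entropy(y, np.full((1, 5), 0.3))


class TestTrainModel:
    def test_zero_learning_rate_freezes_history(self, features):
        spec = ws.build_model()
        plan = split_type1(features.n_samples, seed=0)
        opt = OptimizerConfig(name="sgd", learning_rate=0.0, epochs=3)
        model = ws.train_model(spec, features, plan, opt, seed=0)
        assert model.history["train_loss"].nunique() == 1
        assert model.history["val_loss"].nunique() == 1

    def test_reproducible_histories(self, features):
        spec = ws.build_model()
        plan = split_type1(features.n_samples, seed=0)
        opt = OptimizerConfig(epochs=2)
        h1 = ws.train_model(spec, features, plan, opt, seed=4).history
        h2 = ws.train_model(spec, features, plan, opt, seed=4).history
        pd.testing.assert_frame_equal(h1, h2)  # bit-identical

    def test_loss_decreases_and_recall_high(self, trained_type1, features):
        model, plan = trained_type1
        h = model.history
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0] or \
            h["train_loss"].iloc[0] == 0.0
        report = model.evaluate(features, plan.val)
        assert report.macro_recall >= 0.9

    def test_empty_split_member_rejected(self, features):
        spec = ws.build_model()
        plan = split_type1(features.n_samples, seed=0)
        plan.val = np.empty(0, dtype=np.int64)
        with pytest.raises(ValueError, match="empty split"):
            ws.train_model(spec, features, plan, OptimizerConfig(epochs=1))


class TestCompareOptimizers:
    def test_two_optimizers_full_metric_blocks(self, features):
        spec = ws.build_model()
        plan = split_type1(features.n_samples, seed=0)
        configs = [OptimizerConfig(name="adam", epochs=2),
                   OptimizerConfig(name="sgd", learning_rate=0.05, epochs=2)]
        table = ws.compare_optimizers(spec, features, plan, configs, seed=0)
        assert list(table["optimizer"]) == ["adam", "sgd"]
        # accuracy + 5 classes x (recall, precision, f1) = 16 metrics per row
        assert table.shape == (2, 17)
        assert table.notna().all().all()

    def test_single_config(self, features):
        spec = ws.build_model()
        plan = split_type1(features.n_samples, seed=0)
        table = ws.compare_optimizers(spec, features, plan,
                                      [OptimizerConfig(epochs=1)], seed=0)
        assert len(table) == 1

    def test_no_configs_rejected(self, features):
        plan = split_type1(features.n_samples, seed=0)
        with pytest.raises(ValueError):
            ws.compare_optimizers(ws.build_model(), features, plan, [])
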