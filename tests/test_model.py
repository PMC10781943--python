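"""Class balancing, tuning/elimination, and evaluation metrics."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from runfatigue.model import (
    SplitSpec,
    TuneSpec,
    balance_classes,
    metrics_from_confusion,
    train_evaluate,
    tune_and_select,
)
from runfatigue.simulate import FEATURE_NAMES
from runfatigue.vt2 import LabeledDataset

from conftest import dataset_from_truth


def _make_dataset(n_pre: int, n_post: int, informative: float = 0.0,
                  seed: int = 0, features=FEATURE_NAMES) -> LabeledDataset:
    """A LabeledDataset with Gaussian features; ``informative`` shifts the
    first feature's post-class mean (in SD units)."""
    rng = np.random.default_rng(seed)
    n = n_pre + n_post
    data = pd.DataFrame({f: rng.normal(0, 1, n) for f in features})
    label = np.array(["pre"] * n_pre + ["post"] * n_post)
    data[features[0]] += (label == "post") * informative
    data["t"] = np.arange(n, dtype=float)
    data["step_time"] = 0.35
    data["stage"] = (data["t"] // 180).astype(int)
    data["velocity"] = 3.0
    data["label"] = label
    data["excluded"] = False
    return LabeledDataset(data=data)


FAST_TUNE = TuneSpec(n_trees_grid=(50,), max_features_grid=(3,), do_rfe=False)


class TestBalanceClasses:
    def test_small_disparity_unchanged(self):
        ds = _make_dataset(1000, 980)
        out = balance_classes(ds, seed=1)
        assert out.class_counts() == {"pre": 1000, "post": 980}
        pd.testing.assert_frame_equal(out.data, ds.data)

    def test_large_disparity_undersampled_to_minority(self):
        out = balance_classes(_make_dataset(2000, 800), seed=1)
        assert out.class_counts() == {"pre": 800, "post": 800}

    def test_deterministic_under_seed(self):
        ds = _make_dataset(2000, 800)
        a = balance_classes(ds, seed=9)
        b = balance_classes(ds, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_empty_class_rejected(self):
        ds = _make_dataset(50, 50)
        ds.data["label"] = "pre"
        with pytest.raises(ValueError):
            balance_classes(ds, seed=0)


class TestMetrics:
    def test_hand_computed_confusion_fixture(self):
        """TP=40 FN=10 FP=5 TN=45: direct arithmetic oracle (p_o=.85, p_e=.5)."""
        m = metrics_from_confusion(tp=40, fn=10, fp=5, tn=45)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["sensitivity"] == pytest.approx(0.80)
        assert m["specificity"] == pytest.approx(0.90)
        assert m["f1"] == pytest.approx(80 / 95, abs=5e-4)  # ~0.842
        assert m["kappa"] == pytest.approx(0.70)

    def test_perfect_predictions(self):
        m = metrics_from_confusion(tp=50, fn=0, fp=0, tn=50)
        assert m["accuracy"] == 1.0
        assert m["kappa"] == 1.0


class TestTuneAndSelect:
    def test_perfectly_separating_feature_retained(self):
        ds = _make_dataset(150, 150, informative=8.0, seed=2)
        params, selected, diag = tune_and_select(
            ds.X, ds.y, tune=TuneSpec(n_trees_grid=(50,), max_features_grid=(3,),
                                      rfe_n_trees=50),
            cv_folds=10, seed=0,
        )
        assert FEATURE_NAMES[0] in selected
        assert diag["cv_accuracy"] > 0.97

    def test_pure_noise_features_give_chance_cv_accuracy(self):
        """Best CV accuracy stays ~0.5 on balanced noise (10 seeds)."""
        accs = []
        for seed in range(10):
            ds = _make_dataset(400, 400, informative=0.0, seed=seed,
                               features=FEATURE_NAMES[:4])
            _, _, diag = tune_and_select(
                ds.data[list(FEATURE_NAMES[:4])], ds.data["label"],
                tune=TuneSpec(n_trees_grid=(50,), max_features_grid=(2,),
                              rfe_n_trees=50, rfe_max_samples=256),
                cv_folds=10, seed=seed,
            )
            accs.append(diag["cv_accuracy"])
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_grid_of_size_one_returned(self):
        ds = _make_dataset(100, 100, seed=3)
        params, selected, _ = tune_and_select(ds.X, ds.y, tune=FAST_TUNE, seed=0)
        assert params == {"n_trees": 50, "max_features": 3}
        assert selected == list(FEATURE_NAMES)

    def test_elimination_stops_at_two_features(self):
        ds = _make_dataset(80, 80, informative=3.0, seed=4)
        _, selected, diag = tune_and_select(
            ds.X[list(FEATURE_NAMES[:3])], ds.y,
            tune=TuneSpec(n_trees_grid=(50,), max_features_grid=(2,), rfe_n_trees=50),
            cv_folds=5, seed=0,
        )
        assert len(diag["elimination_path"][-1][0]) == 2
        assert len(selected) >= 2


class TestTrainEvaluate:
    def test_report_consistent_with_confusion_matrix(self):
        ds = _make_dataset(400, 300, informative=2.0, seed=5)
        report = train_evaluate(ds, tune=FAST_TUNE, seed=1)
        cm = report.confusion
        m = metrics_from_confusion(**cm)
        assert report.accuracy == pytest.approx(m["accuracy"])
        assert report.kappa == pytest.approx(m["kappa"])
        assert report.sensitivity == pytest.approx(m["sensitivity"])
        assert report.specificity == pytest.approx(m["specificity"])
        assert report.f1 == pytest.approx(m["f1"])
        assert report.ci_low <= report.accuracy <= report.ci_high

    def test_no_train_test_leakage(self):
        ds = _make_dataset(300, 300, seed=6)
        report = train_evaluate(ds, tune=FAST_TUNE, seed=2)
        assert set(report.train_index).isdisjoint(report.test_index)
        assert len(report.train_index) + len(report.test_index) == 600

    def test_strong_effect_learned(self):
        ds = _make_dataset(400, 400, informative=3.0, seed=7)
        report = train_evaluate(ds, tune=FAST_TUNE, seed=0)
        assert report.accuracy > 0.9
        assert report.ci_high == pytest.approx(1.0, abs=0.05) or report.ci_high < 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        """Null control: shuffling labels destroys all signal (20 seeds)."""
        accs = []
        for seed in range(20):
            ds = _make_dataset(200, 200, informative=2.0, seed=seed)
            rng = np.random.default_rng(seed)
            ds.data["label"] = rng.permutation(ds.data["label"].to_numpy())
            report = train_evaluate(ds, tune=FAST_TUNE, seed=seed)
            accs.append(report.accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.07

    def test_class_absent_from_data_rejected(self):
        ds = _make_dataset(100, 100, seed=8)
        ds.data["label"] = "pre"
        with pytest.raises(ValueError):
            train_evaluate(ds, tune=FAST_TUNE, seed=0)

    def test_balance_applied_to_training_side(self):
        ds = _make_dataset(900, 300, seed=9)
        report = train_evaluate(ds, tune=FAST_TUNE, seed=0)
        before = report.class_balance_before
        after = report.class_balance_after
        assert before["pre"] > before["post"]
        assert after["pre"] == after["post"] == before["post"]


class TestMonotoneLearnability:
    def test_accuracy_nondecreasing_in_effect_size(self):
        """Planted effect levels 0.5 / 1.5 / 3.0 SD; one inversion allowed
        across 10 seeds (stationary generator, model on truth features)."""
        from runfatigue import EffectSpec, ProtocolSpec, generate_subject

        inversions = 0
        for seed in range(10):
            accs = []
            for level in (0.5, 1.5, 3.0):
                rec = generate_subject(
                    ProtocolSpec(n_stages=2),
                    EffectSpec.null(shifts={"RT_APu": level}),
                    seed=300 + seed,
                )
                ds = dataset_from_truth(rec)
                report = train_evaluate(ds, tune=FAST_TUNE, seed=seed)
                accs.append(report.accuracy)
            inversions += sum(accs[i + 1] < accs[i] - 1e-9 for i in range(2))
        assert inversions <= 1
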