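"""Subject-specific random-forest classification of pre/post-VT2 state.

One model per runner: stratified 80/20 split, random under-sampling of
the majority class when the disparity is large, out-of-bag grid search
over forest size and features-per-split, recursive feature elimination
by ten-fold cross-validated accuracy, and evaluation on the untouched
20% with the full metric suite (accuracy with exact binomial 95% CI,
Cohen's kappa, sensitivity, specificity, F1). The positive class is
post-VT2 throughout.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.stats.proportion import proportion_confint

from .simulate import FEATURE_NAMES
from .vt2 import LABEL_POST, LABEL_PRE, LabeledDataset

__all__ = [
    "SplitSpec",
    "TuneSpec",
    "ModelReport",
    "balance_classes",
    "tune_and_select",
    "train_evaluate",
    "metrics_from_confusion",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split and cross-validation layout."""

    train_fraction: float = 0.8
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class TuneSpec:
    """Hyperparameter grid and feature-elimination settings.

    The out-of-bag grid spans forest size and candidate features per
    split; defaults are 100-1000 trees and 1-5 features (≈√10 = 3 is the
    conventional choice for ten features). ``rfe_n_trees`` sets the
    forest size used while ranking candidate subsets during recursive
    elimination (None = the tuned size; a smaller value trades a little
    ranking stability for a large speed-up). ``do_rfe=False`` skips
    elimination and keeps all features.
    """

    n_trees_grid: Sequence[int] = (100, 250, 500, 1000)
    max_features_grid: Sequence[int] = (1, 2, 3, 5)
    do_rfe: bool = True
    rfe_n_trees: int | None = None
    rfe_max_samples: int | float | None = None
    min_features: int = 2

    def __post_init__(self) -> None:
        if len(self.n_trees_grid) == 0 or len(self.max_features_grid) == 0:
            raise ValueError("grid must be non-empty")
        if any(nt < 50 for nt in self.n_trees_grid):
            raise ValueError("grid tree counts must be >= 50")
        if self.min_features < 2:
            raise ValueError("min_features must be >= 2")


@dataclass
class ModelReport:
    """Fitted-model summary for one runner (one row of the results table)."""

    accuracy: float
    ci_low: float
    ci_high: float
    kappa: float
    sensitivity: float
    specificity: float
    f1: float
    confusion: dict  # keys tp, fn, fp, tn (positive class = post-VT2)
    selected_features: list
    hyperparameters: dict
    class_balance_before: dict
    class_balance_after: dict
    n_train: int
    n_test: int
    seed: int
    cv_accuracy: float | None = None
    oob_error: float | None = None
    train_index: list = field(default_factory=list)
    test_index: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """All report metrics from a 2×2 confusion matrix (positive = post).

    accuracy = (TP+TN)/N; sensitivity = TP/(TP+FN); specificity =
    TN/(TN+FP); F1 = 2TP/(2TP+FP+FN); kappa = (p_o − p_e)/(1 − p_e) with
    p_e the chance agreement implied by the marginals.
    """
    n = tp + fn + fp + tn
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = (tp + tn) / n
    p_pos_true = (tp + fn) / n
    p_pos_pred = (tp + fp) / n
    p_e = p_pos_true * p_pos_pred + (1 - p_pos_true) * (1 - p_pos_pred)
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1.0 else 1.0
    return {
        "accuracy": p_o,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
        "kappa": kappa,
    }


def balance_classes(dataset: LabeledDataset, max_disparity: float = 1.5,
                    seed: int = 0) -> LabeledDataset:
    """Random under-sampling of the majority class when disparity is large.

    If the majority/minority count ratio exceeds ``max_disparity``, the
    majority class is subsampled uniformly without replacement down to
    the minority count; otherwise the dataset is returned unchanged.
    Deterministic under ``seed``; temporal row order is preserved.
    """
    counts = dataset.class_counts()
    n_pre, n_post = counts[LABEL_PRE], counts[LABEL_POST]
    if n_pre == 0 or n_post == 0:
        raise ValueError(f"both classes must be non-empty, got {counts}")
    major, minor = (LABEL_PRE, n_post) if n_pre >= n_post else (LABEL_POST, n_pre)
    if max(n_pre, n_post) / min(n_pre, n_post) <= max_disparity:
        return dataset
    rng = np.random.default_rng(seed)
    labeled = dataset.labeled
    major_idx = labeled.index[labeled["label"] == major].to_numpy()
    keep = rng.choice(major_idx, size=minor, replace=False)
    drop = np.setdiff1d(major_idx, keep)
    data = dataset.data.drop(index=drop).reset_index(drop=True)
    return LabeledDataset(data=data, vt2=dataset.vt2,
                          replacement_log=list(dataset.replacement_log))


def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds, n_trees: int,
                 max_features: int, seed: int,
                 max_samples: int | float | None = None) -> float:
    correct = 0
    for k, (tr, te) in enumerate(folds):
        ms = max_samples
        if isinstance(ms, int):
            ms = min(ms, tr.size)
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=min(max_features, X.shape[1]),
            random_state=seed + k,
            n_jobs=1,
            max_samples=ms,
        )
        rf.fit(X[tr], y[tr])
        correct += int((rf.predict(X[te]) == y[te]).sum())
    return correct / X.shape[0]


def tune_and_select(X_train: pd.DataFrame, y_train: pd.Series | np.ndarray,
                    tune: TuneSpec = TuneSpec(), cv_folds: int = 10,
                    seed: int = 0) -> tuple[dict, list[str], dict]:
    """Hyperparameter tuning by OOB error, then recursive feature elimination.

    Stage 1 fits one forest per grid point on the full training set and
    picks the (n_trees, max_features) pair minimising out-of-bag error
    (ties: fewer trees, then fewer features per split). Stage 2 starts
    from all features and repeatedly drops the feature whose removal
    yields the highest cross-validated accuracy, using the same fold
    partition for every subset comparison; the subset with the best CV
    accuracy overall is kept, with ties resolved toward the larger
    subset. Returns (hyperparameters, selected features, diagnostics).
    """
    X = X_train.to_numpy(dtype=float)
    y = np.asarray(y_train)
    features = list(X_train.columns)

    best_oob = None
    for nt in tune.n_trees_grid:
        for mf in tune.max_features_grid:
            rf = RandomForestClassifier(
                n_estimators=nt,
                max_features=min(mf, len(features)),
                oob_score=True,
                bootstrap=True,
                random_state=seed,
                n_jobs=1,
            )
            rf.fit(X, y)
            err = 1.0 - rf.oob_score_
            if best_oob is None or err < best_oob[0] - 1e-12:
                best_oob = (err, nt, mf)
    oob_err, n_trees, max_features = best_oob
    params = {"n_trees": int(n_trees), "max_features": int(max_features)}
    diagnostics: dict = {"oob_error": float(oob_err), "elimination_path": []}

    if not tune.do_rfe:
        return params, features, diagnostics

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    rfe_trees = tune.rfe_n_trees or n_trees
    col = {f: i for i, f in enumerate(features)}

    def acc(subset: list[str]) -> float:
        cols = [col[f] for f in subset]
        return _cv_accuracy(X[:, cols], y, folds, rfe_trees, max_features, seed,
                            max_samples=tune.rfe_max_samples)

    current = list(features)
    best_subset = list(current)
    best_acc = acc(current)
    diagnostics["elimination_path"].append((list(current), best_acc))
    while len(current) > tune.min_features:
        candidates = [(acc([f for f in current if f != drop]), drop) for drop in current]
        cand_acc, dropped = max(candidates, key=lambda c: (c[0], -current.index(c[1])))
        current = [f for f in current if f != dropped]
        diagnostics["elimination_path"].append((list(current), cand_acc))
        # ties favour the larger subset, so only strictly better wins
        if cand_acc > best_acc:
            best_acc, best_subset = cand_acc, list(current)
    diagnostics["cv_accuracy"] = float(best_acc)
    return params, best_subset, diagnostics


def train_evaluate(dataset: LabeledDataset,
                   split: SplitSpec = SplitSpec(),
                   tune: TuneSpec = TuneSpec(),
                   max_disparity: float = 1.5,
                   seed: int = 0,
                   return_model: bool = False):
    """Full subject-specific modelling pass on a labeled dataset.

    Stratified 80/20 split, under-sampling and tuning on the training
    side only, final forest fitted on the full (balanced) training set,
    metrics from the untouched test set. Returns a :class:`ModelReport`
    (and the fitted forest plus test frame when ``return_model``).
    """
    labeled = dataset.labeled.reset_index(drop=True)
    y_all = labeled["label"].to_numpy()
    classes = set(np.unique(y_all))
    if classes != {LABEL_PRE, LABEL_POST}:
        raise ValueError(f"need both pre and post classes, got {sorted(classes)}")

    idx = np.arange(len(labeled))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=1.0 - split.train_fraction,
        stratify=y_all,
        random_state=seed,
    )
    test = labeled.iloc[test_idx]
    if len(set(test["label"])) < 2:
        raise ValueError("a class is absent from the test partition")

    train_ds = LabeledDataset(data=labeled.iloc[train_idx].reset_index(drop=True),
                              vt2=dataset.vt2)
    balance_before = train_ds.class_counts()
    train_ds = balance_classes(train_ds, max_disparity=max_disparity, seed=seed)
    balance_after = train_ds.class_counts()

    params, selected, diagnostics = tune_and_select(
        train_ds.X, train_ds.y, tune=tune, cv_folds=split.cv_folds, seed=seed
    )

    forest = RandomForestClassifier(
        n_estimators=params["n_trees"],
        max_features=min(params["max_features"], len(selected)),
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(train_ds.X[selected], train_ds.y.to_numpy())

    y_true = test["label"].to_numpy()
    y_pred = forest.predict(test[selected])
    tp = int(((y_pred == LABEL_POST) & (y_true == LABEL_POST)).sum())
    fn = int(((y_pred == LABEL_PRE) & (y_true == LABEL_POST)).sum())
    fp = int(((y_pred == LABEL_POST) & (y_true == LABEL_PRE)).sum())
    tn = int(((y_pred == LABEL_PRE) & (y_true == LABEL_PRE)).sum())
    m = metrics_from_confusion(tp, fn, fp, tn)
    ci_low, ci_high = proportion_confint(tp + tn, len(y_true), alpha=0.05, method="beta")

    report = ModelReport(
        accuracy=m["accuracy"],
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        kappa=m["kappa"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        f1=m["f1"],
        confusion={"tp": tp, "fn": fn, "fp": fp, "tn": tn},
        selected_features=list(selected),
        hyperparameters=params,
        class_balance_before=balance_before,
        class_balance_after=balance_after,
        n_train=len(train_ds.labeled),
        n_test=len(test),
        seed=int(seed),
        cv_accuracy=diagnostics.get("cv_accuracy"),
        oob_error=diagnostics.get("oob_error"),
        train_index=[int(i) for i in train_idx],
        test_index=[int(i) for i in test_idx],
    )
    if return_model:
        return report, forest, test
    return report
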