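"""TreeSHAP correctness against exhaustive Shapley enumeration, importance
ranking, and dependence/dispersion diagnostics."""
from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from runfatigue._treeshap import forest_shap
from runfatigue.explain import (
    compute_shap,
    dependence_table,
    importance_proportions,
)
from runfatigue.model import train_evaluate, TuneSpec
from runfatigue.simulate import FEATURE_NAMES

from conftest import dataset_from_truth


# ---------------------------------------------------------------------------
# independent oracle: exhaustive Shapley enumeration with tree-path-dependent
# conditional expectations
# ---------------------------------------------------------------------------

def _cond_exp(tree, x, S):
    t = tree.tree_

    def rec(node):
        if t.children_left[node] < 0:
            v = t.value[node, 0, :]
            return v[1] / v.sum()
        f = t.feature[node]
        if f in S:
            nxt = t.children_left[node] if x[f] <= t.threshold[node] else t.children_right[node]
            return rec(nxt)
        wl = t.weighted_n_node_samples[t.children_left[node]]
        wr = t.weighted_n_node_samples[t.children_right[node]]
        return (wl * rec(t.children_left[node]) + wr * rec(t.children_right[node])) / (wl + wr)

    return rec(0)


def _brute_shapley(forest, x, m):
    phi = np.zeros(m)
    for est in forest.estimators_:
        for i in range(m):
            others = [j for j in range(m) if j != i]
            for k in range(m):
                for S in combinations(others, k):
                    w = factorial(len(S)) * factorial(m - len(S) - 1) / factorial(m)
                    phi[i] += w * (_cond_exp(est, x, set(S) | {i}) - _cond_exp(est, x, set(S)))
    return phi / len(forest.estimators_)


def _fit_forest(m, n_trees, max_depth, seed=0, n=240):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, m))
    y = (X.sum(axis=1) + 0.3 * rng.normal(size=n) > 0).astype(int)
    rf = RandomForestClassifier(n_estimators=n_trees, max_depth=max_depth,
                                random_state=seed).fit(X, y)
    return rf, rng.normal(size=(6, m))


class TestTreeShapOracle:
    @pytest.mark.parametrize(
        "m,max_depth,n_trees",
        [(1, 1, 1), (2, 2, 3), (3, 3, 5), (3, None, 8)],
        ids=["stump", "depth2-pair", "depth3-triple", "deep-triple"],
    )
    def test_matches_exhaustive_enumeration(self, m, max_depth, n_trees):
        rf, Xt = _fit_forest(m, n_trees, max_depth)
        phi, base = forest_shap(rf, Xt)
        for r in range(len(Xt)):
            expected = _brute_shapley(rf, Xt[r], m)
            assert np.allclose(phi[r], expected, atol=1e-10)

    def test_local_accuracy_reconstructs_probability(self):
        rf, Xt = _fit_forest(4, 20, None)
        phi, base = forest_shap(rf, Xt)
        proba = rf.predict_proba(Xt)[:, 1]
        assert np.abs(base + phi.sum(axis=1) - proba).max() < 1e-9

    def test_single_split_stump_closed_form(self):
        """Balanced stump: SHAP of the split feature is ±(p_R − p_L)/2."""
        X = np.repeat([[-1.0], [1.0]], 50, axis=0)
        y = np.array([0] * 50 + [1] * 50)
        rf = RandomForestClassifier(n_estimators=1, max_depth=1,
                                    bootstrap=False, random_state=0).fit(X, y)
        phi, base = forest_shap(rf, np.array([[2.0], [-2.0]]))
        assert phi[0, 0] == pytest.approx(0.5)   # (1 - 0)/2
        assert phi[1, 0] == pytest.approx(-0.5)
        assert base == pytest.approx(0.5)

    def test_constant_model_all_zero(self):
        """Single-leaf trees attribute nothing to any feature."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        y = np.array([0, 1] * 50)
        rf = RandomForestClassifier(n_estimators=5, min_samples_split=1000,
                                    random_state=0).fit(X, y)
        phi, base = forest_shap(rf, X[:10])
        assert np.all(phi == 0.0)


class TestComputeShap:
    def _fitted(self, informative=2.5, seed=0, n=300):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({f: rng.normal(0, 1, n) for f in FEATURE_NAMES[:4]})
        y = np.where(rng.random(n) < 0.5, "post", "pre")
        X.iloc[:, 0] += (y == "post") * informative
        rf = RandomForestClassifier(n_estimators=30, random_state=seed).fit(X, y)
        return rf, X.iloc[:40]

    def test_feature_mismatch_rejected(self):
        rf, X = self._fitted()
        with pytest.raises(ValueError):
            compute_shap(rf, X.rename(columns={X.columns[0]: "bogus"}))

    def test_sign_convention_toward_post(self):
        """High values of the post-shifted feature push predictions up."""
        rf, X = self._fitted()
        res = compute_shap(rf, X)
        top = X.columns[0]
        j = res.feature_names.index(top)
        v = X[top].to_numpy()
        hi = res.values[v >= np.quantile(v, 0.75), j]
        lo = res.values[v <= np.quantile(v, 0.25), j]
        assert hi.mean() > 0 > lo.mean()

    def test_importance_proportions_sum_to_one_and_rank(self):
        rf, X = self._fitted()
        res = compute_shap(rf, X)
        table = importance_proportions(res)
        assert table["proportion"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table["feature"].iloc[0] == X.columns[0]
        assert (table["proportion"] >= 0).all()

    def test_importance_invariant_to_observation_order(self):
        rf, X = self._fitted()
        a = importance_proportions(compute_shap(rf, X))
        b = importance_proportions(compute_shap(rf, X.iloc[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_all_zero_shap_uniform_with_warning(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({f: rng.normal(size=80) for f in FEATURE_NAMES[:3]})
        y = np.array(["pre", "post"] * 40)
        rf = RandomForestClassifier(n_estimators=3, min_samples_split=1000,
                                    random_state=0).fit(X, y)
        res = compute_shap(rf, X.iloc[:10])
        with pytest.warns(UserWarning):
            table = importance_proportions(res)
        assert np.allclose(table["proportion"], 1.0 / 3)

    def test_duplicated_features_share_importance(self):
        """With feature bagging off, identical columns earn equal credit."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=500)
        y = np.where(a + 0.4 * rng.normal(size=500) > 0, "post", "pre")
        X = pd.DataFrame({"a1": a, "a2": a.copy(), "b": rng.normal(size=500)})
        rf = RandomForestClassifier(n_estimators=800, max_features=None,
                                    random_state=0).fit(X, y)
        res = compute_shap(rf, X.iloc[:200])
        imp = res.mean_abs
        assert imp["a1"] == pytest.approx(imp["a2"], rel=0.05)


class TestDominantFeatureRecovery:
    def test_planted_dominant_feature_ranked_first(self):
        """One informative feature, rest at zero effect: ranked 1 in >=90%
        of 20 seeds (stationary generator, truth features)."""
        from runfatigue import EffectSpec, ProtocolSpec, generate_subject

        hits = 0
        for seed in range(20):
            rec = generate_subject(
                ProtocolSpec(n_stages=2),
                EffectSpec.null(shifts={"RT_APu": 1.5}),
                seed=500 + seed,
            )
            ds = dataset_from_truth(rec)
            report, forest, test = train_evaluate(
                ds, tune=TuneSpec(n_trees_grid=(50,), max_features_grid=(3,),
                                  do_rfe=False),
                seed=seed, return_model=True,
            )
            res = compute_shap(forest, test[report.selected_features].head(120))
            if importance_proportions(res)["feature"].iloc[0] == "RT_APu":
                hits += 1
        assert hits >= 18


class TestDependence:
    def test_single_feature_model_is_step_function(self):
        """A model seeing only one feature has zero within-bin dispersion."""
        rng = np.random.default_rng(3)
        # four distinct feature levels so quantile bins never straddle a split
        a = rng.choice([-2.0, -1.0, 1.0, 2.0], size=400)
        y = np.where(a > 0, "post", "pre")
        X = pd.DataFrame({"a": a})
        rf = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        res = compute_shap(rf, X.iloc[:100])
        dep = dependence_table(res, "a", n_bins=4)
        assert dep.dispersion["shap_sd"].max() < 1e-12

    def test_unknown_feature_rejected(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=100)})
        y = np.where(X["a"] > 0, "post", "pre")
        rf = RandomForestClassifier(n_estimators=5, random_state=0).fit(X, y)
        res = compute_shap(rf, X.iloc[:20])
        with pytest.raises(KeyError):
            dependence_table(res, "nope")

    def test_empty_observations_give_empty_table(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=100)})
        y = np.where(X["a"] > 0, "post", "pre")
        rf = RandomForestClassifier(n_estimators=5, random_state=0).fit(X, y)
        res = compute_shap(rf, X.iloc[:0])
        dep = dependence_table(res, "a")
        assert dep.points.empty

    def test_planted_interaction_raises_within_bin_dispersion(self):
        """A stage-gated effect makes a feature's SHAP context-dependent:
        paired comparison over 10 seeds."""
        from runfatigue import EffectSpec, ProtocolSpec, generate_subject

        def rel_dispersion(gated: bool, seed: int) -> float:
            eff = EffectSpec(
                shifts={"RT_APu": 1.5},
                vt2_fraction=0.45,
                gate_stage={"RT_APu": 2} if gated else {},
            )
            rec = generate_subject(ProtocolSpec(n_stages=3), eff, seed=seed)
            ds = dataset_from_truth(rec)
            report, forest, test = train_evaluate(
                ds, tune=TuneSpec(n_trees_grid=(50,), max_features_grid=(3,),
                                  do_rfe=False),
                seed=seed, return_model=True,
            )
            res = compute_shap(forest, test[report.selected_features].head(150),
                               annotations=test[["stage", "velocity"]].head(150))
            dep = dependence_table(res, "RT_APu", n_bins=8)
            w = dep.dispersion
            within = float(np.average(w["shap_sd"], weights=w["n"]))
            # normalise by the feature's overall SHAP spread so the metric
            # compares *shape* (context dependence), not attribution size
            return within / float(np.std(dep.points["shap"]))

        gaps = [rel_dispersion(True, 700 + s) - rel_dispersion(False, 700 + s)
                for s in range(10)]
        assert np.mean(gaps) > 0
        assert sum(g > 0 for g in gaps) >= 7
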