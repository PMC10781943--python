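"""Model interpretation: SHAP attributions, importance, dependence tables.

Wraps the package's path-dependent TreeSHAP engine into the result
objects the analysis reports: per-observation additive attributions on
the probability-of-post-VT2 scale (values above zero push the prediction
toward the post-VT2 class), normalised mean-|SHAP| importance
proportions, and dependence tables with a per-stage vertical-dispersion
summary that quantifies feature-interaction effects.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._treeshap import forest_shap

__all__ = [
    "ShapResult",
    "DependenceResult",
    "compute_shap",
    "importance_proportions",
    "dependence_table",
    "shap_to_csv",
    "plot_importance",
    "plot_dependence",
]

LOCAL_ACCURACY_TOL = 1e-6


@dataclass
class ShapResult:
    """SHAP attributions for one fitted subject model.

    ``values[i, j]`` is the contribution of feature ``j`` to observation
    ``i``'s predicted probability of the post-VT2 class, relative to
    ``base_value`` (the cover-weighted expectation of the model output).
    ``data`` holds the observations' feature values; ``annotations``
    optionally carries per-observation stage index and belt velocity.
    """

    values: np.ndarray
    base_value: float
    feature_names: list
    data: pd.DataFrame
    annotations: pd.DataFrame | None = None

    @property
    def mean_abs(self) -> pd.Series:
        return pd.Series(np.abs(self.values).mean(axis=0), index=self.feature_names)


def compute_shap(model, observations: pd.DataFrame,
                 annotations: pd.DataFrame | None = None) -> ShapResult:
    """Per-observation SHAP attributions toward the post-VT2 class.

    ``model`` is a forest fitted on the selected feature subset;
    ``observations`` must carry exactly those columns (order included).
    Local accuracy — base value plus the attribution row reproducing the
    model's predicted probability — is asserted for every observation to
    1e-6, not sampled.
    """
    expected = list(getattr(model, "feature_names_in_", observations.columns))
    if list(observations.columns) != expected:
        raise ValueError(
            f"observation columns {list(observations.columns)} do not match "
            f"the model's features {expected}"
        )
    X = observations.to_numpy(dtype=float)
    pos = int(np.flatnonzero(model.classes_ == "post")[0]) if "post" in model.classes_ else 1
    phi, base = forest_shap(model, X, positive_class=pos)
    if len(X):
        proba = model.predict_proba(observations)[:, pos]
        gap = np.abs(base + phi.sum(axis=1) - proba)
        if gap.max() > LOCAL_ACCURACY_TOL:
            raise AssertionError(
                f"local accuracy violated: max |base + sum(phi) - p| = {gap.max():.3g}"
            )
    ann = annotations.reset_index(drop=True) if annotations is not None else None
    return ShapResult(values=phi, base_value=base,
                      feature_names=list(observations.columns),
                      data=observations.reset_index(drop=True), annotations=ann)


def importance_proportions(shap: ShapResult) -> pd.DataFrame:
    """Features ranked by mean |SHAP|, with proportions summing to 1.

    The proportion of feature j is mean|SHAP|_j divided by the sum over
    all features; an all-zero SHAP matrix (constant model) yields uniform
    proportions with a warning.
    """
    if shap.values.size == 0:
        raise ValueError("empty SHAP matrix")
    mean_abs = shap.mean_abs
    total = mean_abs.sum()
    if total == 0.0:
        warnings.warn("all SHAP values are zero; returning uniform proportions",
                      stacklevel=2)
        props = pd.Series(1.0 / len(mean_abs), index=mean_abs.index)
    else:
        props = mean_abs / total
    out = pd.DataFrame({
        "feature": mean_abs.index,
        "mean_abs_shap": mean_abs.to_numpy(),
        "proportion": props.to_numpy(),
    })
    out = out.sort_values(["mean_abs_shap", "feature"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class DependenceResult:
    """A dependence-plot table plus its vertical-dispersion summary.

    ``points`` has one row per observation (feature value, SHAP value,
    stage, velocity); ``dispersion`` gives the SD of the SHAP values
    within narrow feature-value bins, per velocity stage — large values
    flag observations whose attribution depends on the *other* features,
    i.e. interaction effects.
    """

    feature: str
    points: pd.DataFrame
    dispersion: pd.DataFrame


def dependence_table(shap: ShapResult, feature: str, n_bins: int = 10) -> DependenceResult:
    """Dependence table for one feature with interaction diagnostics."""
    if feature not in shap.feature_names:
        raise KeyError(f"{feature!r} is not among the explained features "
                       f"{shap.feature_names}")
    j = shap.feature_names.index(feature)
    points = pd.DataFrame({
        "observation": np.arange(shap.values.shape[0]),
        "value": shap.data[feature].to_numpy(),
        "shap": shap.values[:, j],
    })
    if shap.annotations is not None:
        for col in ("stage", "velocity"):
            if col in shap.annotations:
                points[col] = shap.annotations[col].to_numpy()
    if "stage" not in points:
        points["stage"] = 0
    if points.empty:
        return DependenceResult(feature=feature, points=points,
                                dispersion=pd.DataFrame(columns=["stage", "bin", "n", "shap_sd"]))
    edges = np.unique(np.quantile(points["value"], np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:
        points["bin"] = 0
    else:
        points["bin"] = np.clip(np.searchsorted(edges, points["value"], side="right") - 1,
                                0, edges.size - 2)
    disp = (points.groupby(["stage", "bin"])["shap"]
            .agg(n="size", shap_sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
            .reset_index())
    return DependenceResult(feature=feature, points=points.drop(columns="bin"),
                            dispersion=disp)


def shap_to_csv(shap: ShapResult, path: str | Path) -> None:
    """Long-format export: one row per (observation, feature)."""
    n, m = shap.values.shape
    rows = {
        "observation": np.repeat(np.arange(n), m),
        "feature": np.tile(shap.feature_names, n),
        "value": shap.data.to_numpy(dtype=float).ravel(),
        "shap": shap.values.ravel(),
    }
    df = pd.DataFrame(rows)
    if shap.annotations is not None:
        for col in ("stage", "velocity"):
            if col in shap.annotations:
                df[col] = np.repeat(shap.annotations[col].to_numpy(), m)
    df.to_csv(path, index=False)


def summary_to_json(shap: ShapResult, path: str | Path) -> None:
    ranking = importance_proportions(shap)
    payload = {
        "base_value": shap.base_value,
        "n_observations": int(shap.values.shape[0]),
        "ranking": ranking.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def plot_importance(shap: ShapResult, path: str | Path) -> None:
    """Horizontal bar chart of importance proportions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranking = importance_proportions(shap).iloc[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.4 * len(ranking) + 1))
    ax.barh(ranking["feature"], ranking["proportion"], color="#4878b0")
    ax.set_xlabel("proportion of mean |SHAP|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dependence(shap: ShapResult, feature: str, path: str | Path) -> None:
    """Dependence scatter (feature value vs SHAP), coloured by velocity."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dep = dependence_table(shap, feature)
    fig, ax = plt.subplots(figsize=(6, 4))
    c = dep.points["velocity"] if "velocity" in dep.points else None
    sc = ax.scatter(dep.points["value"], dep.points["shap"], c=c, s=8, cmap="viridis")
    if c is not None:
        fig.colorbar(sc, ax=ax, label="belt velocity (m/s)")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel(feature)
    ax.set_ylabel("SHAP value (toward post-VT2)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
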