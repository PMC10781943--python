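"""Second-ventilatory-threshold detection, labeling and outlier handling.

The second ventilatory threshold (VT2) is the intensity at which minute
ventilation starts rising over-proportionally to V̇O2. Here it is located
automatically with a continuous two-segment piecewise-linear (hinge) fit
of V̇E against V̇O2 — the V-slope family of methods — replacing the human
raters of laboratory practice. The step-feature matrix is then split into
pre/post-VT2 classes with a 20 s exclusion window around the threshold,
and per-stage ±3 SD outliers are replaced by their nearest in-bounds
neighbour's value.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import FEATURE_NAMES

__all__ = [
    "NoThresholdError",
    "VT2Estimate",
    "LabeledDataset",
    "detect_vt2",
    "label_and_mask",
    "replace_outliers",
]

log = logging.getLogger(__name__)

LABEL_PRE = "pre"
LABEL_POST = "post"


class NoThresholdError(RuntimeError):
    """No breakpoint with an over-proportional V̇E increase was found."""


@dataclass(frozen=True)
class VT2Estimate:
    """A detected VT2 with breakpoint-fit diagnostics."""

    vt2_time: float
    breakpoint_index: int
    slope_pre: float
    slope_post: float
    sse: float
    method: str = "vslope-hinge"

    @property
    def slope_ratio(self) -> float:
        return self.slope_post / self.slope_pre


@dataclass
class LabeledDataset:
    """Per-step feature matrix with pre/post-VT2 labels.

    ``data`` has the ten feature columns plus ``t``, ``step_time``,
    ``stage``, ``velocity``, ``label`` (pre/post, empty for excluded
    rows) and ``excluded``. Labeling is a partition: every row is exactly
    one of pre, post or excluded. ``replacement_log`` records outlier
    replacements as (row index, feature, original, replacement).
    """

    data: pd.DataFrame
    vt2: VT2Estimate | None = None
    replacement_log: list[tuple[int, str, float, float]] = field(default_factory=list)

    @property
    def labeled(self) -> pd.DataFrame:
        return self.data.loc[~self.data["excluded"]]

    @property
    def X(self) -> pd.DataFrame:
        return self.labeled[list(FEATURE_NAMES)]

    @property
    def y(self) -> pd.Series:
        return self.labeled["label"]

    def class_counts(self) -> dict[str, int]:
        vc = self.labeled["label"].value_counts()
        return {LABEL_PRE: int(vc.get(LABEL_PRE, 0)), LABEL_POST: int(vc.get(LABEL_POST, 0))}

    @property
    def replaced_fraction(self) -> float:
        n_values = len(self.data) * len(FEATURE_NAMES)
        return len(self.replacement_log) / n_values if n_values else 0.0


def detect_vt2(breaths: pd.DataFrame, min_slope_ratio: float = 1.1,
               edge_fraction: float = 0.10, min_breaths: int = 40) -> VT2Estimate:
    """Locate VT2 on smoothed breath data by a two-segment V-slope fit.

    For every candidate breakpoint on a grid over the interior breaths
    (the first and last ``edge_fraction`` are excluded), a continuous
    two-segment linear model of V̇E as a function of V̇O2 is fitted by
    least squares; the candidate minimising the total SSE wins, with ties
    going to the earliest breath (conservative: more post-VT2 data). The
    VT2 time is the time of the selected breath. If the winning fit does
    not show an over-proportional increase (post/pre slope ratio below
    ``min_slope_ratio``), :class:`NoThresholdError` is raised — e.g. for
    single-slope data.
    """
    n = len(breaths)
    if n < min_breaths:
        raise ValueError(f"need at least {min_breaths} breaths, got {n}")
    x = breaths["vo2"].to_numpy(dtype=float)
    y = breaths["ve"].to_numpy(dtype=float)
    lo = int(np.ceil(edge_fraction * n))
    hi = int(np.floor((1.0 - edge_fraction) * n))
    if hi - lo < 3:
        raise ValueError("too few interior breaths for breakpoint search")

    best = None  # (sse, index, slope_pre, slope_post)
    ones = np.ones_like(x)
    for i in range(lo, hi):
        hinge = np.clip(x - x[i], 0.0, None)
        A = np.column_stack([ones, x, hinge])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, i, float(coef[1]), float(coef[1] + coef[2]))
    sse, i, s_pre, s_post = best
    if s_pre <= 0 or s_post / s_pre < min_slope_ratio:
        raise NoThresholdError(
            f"no over-proportional V̇E increase: slope ratio "
            f"{s_post / s_pre if s_pre > 0 else float('nan'):.3f} < {min_slope_ratio}"
        )
    return VT2Estimate(
        vt2_time=float(breaths["time"].iloc[i]),
        breakpoint_index=i,
        slope_pre=s_pre,
        slope_post=s_post,
        sse=sse,
    )


def ventilatory_equivalents(breaths: pd.DataFrame) -> pd.DataFrame:
    """Diagnostic V̇E/V̇O2 and V̇E/V̇CO2 curves (dimensionless, V̇E in mL/min)."""
    out = breaths[["time"]].copy()
    out["ve_vo2"] = breaths["ve"] * 1000.0 / breaths["vo2"]
    out["ve_vco2"] = breaths["ve"] * 1000.0 / breaths["vco2"]
    return out


def label_and_mask(steps: pd.DataFrame, vt2: VT2Estimate | float,
                   window: float = 20.0) -> LabeledDataset:
    """Split steps into pre/post-VT2 classes with an exclusion window.

    Steps whose contact time is more than ``window`` seconds before VT2
    are labeled pre; more than ``window`` seconds after, post; all steps
    inside the ±window band are excluded from the dataset (but kept in
    the table with ``excluded=True``). Raises if either class would be
    empty.
    """
    if not steps["t"].is_monotonic_increasing:
        raise ValueError("steps must be time-ordered")
    vt2_time = vt2.vt2_time if isinstance(vt2, VT2Estimate) else float(vt2)
    data = steps.copy().reset_index(drop=True)
    t = data["t"].to_numpy(dtype=float)
    pre = t < vt2_time - window
    post = t > vt2_time + window
    label = np.where(pre, LABEL_PRE, np.where(post, LABEL_POST, ""))
    data["label"] = label
    data["excluded"] = ~(pre | post)
    if not pre.any() or not post.any():
        raise NoThresholdError(
            f"VT2 at {vt2_time:.1f} s leaves an empty class "
            f"(pre={int(pre.sum())}, post={int(post.sum())})"
        )
    return LabeledDataset(data=data, vt2=vt2 if isinstance(vt2, VT2Estimate) else None)


def replace_outliers(dataset: LabeledDataset, n_sd: float = 3.0) -> LabeledDataset:
    """Replace per-stage ±3 SD outliers by the nearest in-bounds value.

    For each feature and each 3-min stage, the stage-local mean and
    sample SD are computed once (including candidate points — a single
    pass). Any value outside mean ± ``n_sd``·SD is replaced by the value
    of the temporally nearest same-stage point that is itself within
    bounds (ties go to the earlier point). Labels, row count and
    in-bounds values are never touched. If a stage has no in-bounds
    point for some feature, it is left unchanged with a warning.
    """
    data = dataset.data.copy()
    log_entries: list[tuple[int, str, float, float]] = []
    for stage, idx in data.groupby("stage").groups.items():
        idx = np.asarray(idx)
        tvals = data.loc[idx, "t"].to_numpy(dtype=float)
        for feat in FEATURE_NAMES:
            v = data.loc[idx, feat].to_numpy(dtype=float)
            if v.size < 2:
                continue
            mu = v.mean()
            sd = v.std(ddof=1)
            if sd == 0.0:
                continue
            in_bounds = np.abs(v - mu) <= n_sd * sd
            if in_bounds.all():
                continue
            if not in_bounds.any():
                warnings.warn(
                    f"stage {stage}: every {feat} value flagged; left unchanged",
                    stacklevel=2,
                )
                continue
            good_pos = np.flatnonzero(in_bounds)
            for pos in np.flatnonzero(~in_bounds):
                dt = np.abs(tvals[good_pos] - tvals[pos])
                # earliest neighbour wins on an exact distance tie
                nearest = good_pos[np.lexsort((tvals[good_pos], dt))[0]]
                original = v[pos]
                replacement = v[nearest]
                data.loc[idx[pos], feat] = replacement
                log_entries.append((int(idx[pos]), feat, float(original), float(replacement)))
    if log_entries:
        log.info("replaced %d outlying values (%.3f%% of matrix)",
                 len(log_entries),
                 100.0 * len(log_entries) / (len(data) * len(FEATURE_NAMES)))
    return LabeledDataset(data=data, vt2=dataset.vt2,
                          replacement_log=dataset.replacement_log + log_entries)
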