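"""Shared fixtures: small synthetic recordings reused across test modules."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from runfatigue import EffectSpec, ProtocolSpec, generate_subject
from runfatigue.simulate import DEFAULT_FEATURE_NOISE
from runfatigue.vt2 import LabeledDataset, label_and_mask

ZERO_NOISE = {k: 0.0 for k in DEFAULT_FEATURE_NOISE}

#: reference planted post-VT2 shifts (units: step-to-step SD at fixed velocity)
REF_SHIFTS = {"RT_APu": 1.0, "RFD_maxD": 0.75, "RT_LTu": 0.5}


def noise_free_effects(**overrides) -> EffectSpec:
    base = dict(
        feature_noise=ZERO_NOISE,
        gyro_noise_sd=0.0,
        grf_noise_sd=0.0,
        timing_jitter=0.0,
        breath_noise=0.0,
    )
    base.update(overrides)
    return EffectSpec(**base)


@pytest.fixture(scope="session")
def noisefree_recording():
    """Three-stage noise-free subject: the oracle-equivalence workhorse."""
    return generate_subject(ProtocolSpec(n_stages=3), noise_free_effects(), seed=7)


@pytest.fixture(scope="session")
def small_recording():
    """Two-stage subject with default noise and the reference shifts."""
    return generate_subject(
        ProtocolSpec(n_stages=2), EffectSpec(shifts=REF_SHIFTS, vt2_fraction=0.6), seed=11
    )


def dataset_from_truth(rec, window: float = 20.0) -> LabeledDataset:
    """LabeledDataset built from generator-truth features and the planted VT2."""
    steps = rec.true_steps.rename(columns={"period": "step_time"})
    return label_and_mask(steps, rec.ground_truth["vt2_time"], window=window)
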