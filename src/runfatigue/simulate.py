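"""Synthetic incremental treadmill-run generator with known ground truth.

The study data this package analyses (13 recreational runners on an
instrumented treadmill, incremental 3-min stages to exhaustion) are not
publicly deposited, so this module generates recordings that carry the
statistical structure the downstream analysis assumes, together with the
ground truth needed to test every stage:

* a vertical GRF channel at 516 Hz built from two raised-cosine lobes per
  stance (impact peak ~1.6 BW at ~25 ms, active peak ~2.2-2.8 BW at
  mid-stance), zero force in flight, cadence 2.6-3.0 steps/s rising
  mildly with belt velocity, duty factor ~0.35 falling slightly with
  velocity;
* six trunk angular-velocity channels (C7 and L5, three anatomical axes
  each) at 218 Hz: stride-periodic sinusoid per axis whose per-step
  amplitude sets the extracted angular range exactly, plus a constant
  per-axis bias (the drift source) and white noise;
* breath-by-breath V̇O2/V̇CO2/V̇E with V̇O2 following belt velocity through
  first-order kinetics and V̇E piecewise-linear in V̇O2 with a slope
  increase at the planted second ventilatory threshold (VT2).

Post-VT2 "fatigue" effects are planted by modulating waveform parameters
(never by editing extracted features), so the full extraction chain is
exercised. Effect sizes are expressed in units of the feature's
step-to-step standard deviation at fixed velocity, which equals the
pre-VT2 standard deviation exactly when velocity coupling is disabled
(:meth:`EffectSpec.null` — the configuration used for null controls).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import sosfiltfilt

from .signal import FilterSpec, GRF_CUTOFF_HZ

__all__ = [
    "FEATURE_NAMES",
    "TRUNK_AXES",
    "ProtocolSpec",
    "EffectSpec",
    "RawSubjectRecording",
    "generate_subject",
    "generate_breaths",
    "generate_cohort",
    "derive_subject_seeds",
    "write_recording",
    "read_recording",
]

#: The ten per-step features, in canonical column order. RT_<axis><level>
#: are angular-displacement ranges: LT = vertical (axial) rotation,
#: MD = flexion/extension, AP = lateral flexion; u = upper trunk (C7),
#: lo = lower trunk (L5).
FEATURE_NAMES: tuple[str, ...] = (
    "GRF_peak",
    "I_total",
    "RFD_maxD",
    "RFD_avgD",
    "RT_LTu",
    "RT_MDu",
    "RT_APu",
    "RT_LTlo",
    "RT_MDlo",
    "RT_APlo",
)

#: gyroscope channel names, one per trunk level and anatomical axis
TRUNK_AXES: tuple[str, ...] = ("c7_lt", "c7_md", "c7_ap", "l5_lt", "l5_md", "l5_ap")

_RT_TO_AXIS = {
    "RT_LTu": "c7_lt",
    "RT_MDu": "c7_md",
    "RT_APu": "c7_ap",
    "RT_LTlo": "l5_lt",
    "RT_MDlo": "l5_md",
    "RT_APlo": "l5_ap",
}

_G = 9.81  # m/s^2

# velocity range (m/s) over which cadence / amplitude couplings are mapped
_V_LO, _V_HI = 2.5, 5.0

# trunk angular amplitudes (deg, half-range) at the reference velocity;
# literature-typical trunk/pelvis oscillation magnitudes during running
_TRUNK_AMP0 = {
    "c7_lt": 4.0,
    "c7_md": 2.5,
    "c7_ap": 3.0,
    "l5_lt": 5.0,
    "l5_md": 4.0,
    "l5_ap": 4.5,
}

#: default step-to-step relative noise SD of the waveform parameter behind
#: each feature (== the feature's relative SD at fixed velocity, since every
#: feature is proportional to its parameter)
DEFAULT_FEATURE_NOISE: dict[str, float] = {
    "GRF_peak": 0.04,
    "I_total": 0.04,
    "RFD_maxD": 0.05,
    "RFD_avgD": 0.05,
    "RT_LTu": 0.06,
    "RT_MDu": 0.06,
    "RT_APu": 0.06,
    "RT_LTlo": 0.06,
    "RT_MDlo": 0.06,
    "RT_APlo": 0.06,
}


@dataclass(frozen=True)
class ProtocolSpec:
    """Incremental treadmill protocol and acquisition metadata.

    Defaults follow the study design: 3-min stages, +0.28 m/s per stage,
    start velocity ~85% of 10-k tempo (2.5-3.61 m/s across runners), GRF
    sampled at 516 Hz and trunk IMUs at 218 Hz. The default 7 stages
    (21 min) put per-subject step counts in the 2347-3577 range the
    original datasets spanned.
    """

    start_velocity: float = 3.0
    stage_duration: float = 180.0
    velocity_increment: float = 0.28
    n_stages: int = 7
    body_mass: float = 78.9
    grf_rate: float = 516.0
    imu_rate: float = 218.0

    def __post_init__(self) -> None:
        for name in (
            "start_velocity",
            "stage_duration",
            "velocity_increment",
            "n_stages",
            "body_mass",
            "grf_rate",
            "imu_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def duration(self) -> float:
        """Total test duration in seconds."""
        return self.stage_duration * self.n_stages

    def stage_at(self, t: np.ndarray | float) -> np.ndarray | int:
        """0-based stage index at time ``t`` (clipped to the last stage)."""
        s = np.floor(np.asarray(t) / self.stage_duration).astype(int)
        s = np.clip(s, 0, self.n_stages - 1)
        return int(s) if np.isscalar(t) else s

    def velocity_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Belt velocity (m/s) at time ``t``."""
        v = self.start_velocity + self.velocity_increment * np.asarray(
            self.stage_at(t), dtype=float
        )
        return float(v) if np.isscalar(t) else v


@dataclass(frozen=True)
class EffectSpec:
    """Planted post-VT2 effects and noise configuration.

    ``shifts`` maps feature names to post-VT2 mean shifts in units of that
    feature's step-to-step SD at fixed velocity. ``onset`` is either a
    step change at VT2 or a linear ramp from VT2 to test end (emulating a
    dispersed transition phase). ``velocity_coupling`` scales how strongly
    waveform parameters follow belt velocity: 1.0 reproduces the
    physiological couplings (active peak 2.2->2.8 BW, trunk amplitudes
    +8%/(m/s)); 0.0 makes every feature stationary so that, with zero
    shifts, pre- and post-VT2 step distributions are identical.
    ``gate_stage`` optionally restricts a feature's planted shift to
    stages at or above the given index, which induces a feature
    interaction visible as vertical dispersion in dependence plots.
    """

    shifts: Mapping[str, float] = field(default_factory=dict)
    onset: str = "step"
    vt2_fraction: float = 0.65
    feature_noise: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FEATURE_NOISE))
    velocity_coupling: float = 1.0
    gate_stage: Mapping[str, int] = field(default_factory=dict)
    breath_noise: float = 0.015
    vo2_slow: float = 1.2  # V̇O2 slow-component drift, mL·kg⁻¹·min⁻¹ per min
    gyro_noise_sd: float = 1.0  # deg/s white noise
    gyro_bias: float = 0.5  # deg/s constant per-axis bias (drift source)
    grf_noise_sd: float = 1.5  # N, clipped so force never goes negative
    timing_jitter: float = 0.01  # relative SD of the step period

    def __post_init__(self) -> None:
        if not 0.0 < self.vt2_fraction < 1.0:
            raise ValueError(f"vt2_fraction must lie in (0, 1), got {self.vt2_fraction}")
        if self.onset not in ("step", "ramp"):
            raise ValueError(f"onset must be 'step' or 'ramp', got {self.onset!r}")
        unknown = set(self.shifts) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature(s) in shifts: {sorted(unknown)}")
        for k, v in self.feature_noise.items():
            if v < 0:
                raise ValueError(f"noise SD for {k} must be >= 0")
        for name in ("breath_noise", "vo2_slow", "gyro_noise_sd", "gyro_bias", "grf_noise_sd", "timing_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def null(cls, **overrides) -> "EffectSpec":
        """A stationary, effect-free configuration for null controls.

        Zero planted shifts and zero velocity coupling: the ten features
        are exchangeable across the whole trial, so any classifier should
        perform at chance.
        """
        base = dict(shifts={}, velocity_coupling=0.0)
        base.update(overrides)
        return cls(**base)

    def noise_sd(self, feature: str) -> float:
        return float(self.feature_noise.get(feature, DEFAULT_FEATURE_NOISE[feature]))

    def multiplier(self, feature: str, t: np.ndarray, stage: np.ndarray, vt2_time: float,
                   duration: float) -> np.ndarray:
        """Waveform-parameter multiplier implementing the planted shift."""
        t = np.asarray(t, dtype=float)
        d = float(self.shifts.get(feature, 0.0))
        if d == 0.0:
            return np.ones_like(t)
        if self.onset == "step":
            ramp = (t > vt2_time).astype(float)
        else:
            ramp = np.clip((t - vt2_time) / max(duration - vt2_time, 1e-9), 0.0, 1.0)
        gate = self.gate_stage.get(feature)
        if gate is not None:
            ramp = ramp * (np.asarray(stage) >= gate)
        # the SD unit stays meaningful in noise-free configurations
        scale = self.noise_sd(feature) or DEFAULT_FEATURE_NOISE[feature]
        return 1.0 + d * scale * ramp


@dataclass
class RawSubjectRecording:
    """Synchronised raw streams for one subject plus generator ground truth.

    All streams share a common clock origin (t = 0 at test start).
    ``ground_truth`` carries the planted VT2 time, the effect spec used,
    the per-step stance schedule and the per-step true feature values
    (computed from each step's realised waveform parameters after passing
    the isolated stance through the same low-pass filter spec the
    pipeline applies, so the truth reflects what ideal extraction of this
    stance would yield).
    """

    grf_time: np.ndarray
    grf: np.ndarray
    gyro_time: np.ndarray
    gyro: pd.DataFrame  # columns TRUNK_AXES, deg/s
    breaths: pd.DataFrame  # columns time, vo2, vco2, ve
    body_mass: float
    protocol: ProtocolSpec
    effects: EffectSpec
    ground_truth: dict

    @property
    def true_steps(self) -> pd.DataFrame:
        """Per-step ground truth: schedule, stage, velocity, true features."""
        return self.ground_truth["steps"]


def _effective_velocity(v: np.ndarray | float, v_start: float, coupling: float):
    """Velocity at which every coupled waveform parameter is evaluated.

    Full coupling (1.0) uses the true belt velocity; zero coupling
    freezes every parameter at its start-velocity value, making the
    generated features stationary across the whole trial.
    """
    return v_start + coupling * (np.asarray(v, dtype=float) - v_start)


def _cadence(v: np.ndarray | float) -> np.ndarray | float:
    """Step frequency (steps/s), 2.6 at 2.5 m/s rising to 3.0 at 5.0 m/s."""
    return 2.6 + 0.4 * np.clip((np.asarray(v, dtype=float) - _V_LO) / (_V_HI - _V_LO), 0.0, 1.0)


def _duty_factor(v: np.ndarray | float) -> np.ndarray | float:
    """Stance fraction of the step period, ~0.35 decreasing with velocity."""
    return 0.35 - 0.016 * np.clip(np.asarray(v, dtype=float) - _V_LO, 0.0, _V_HI - _V_LO)


def _active_peak_bw(v: np.ndarray | float) -> np.ndarray | float:
    """Active-peak amplitude in body weights, 2.2 -> 2.8 BW over 2.5-5 m/s."""
    frac = np.clip((np.asarray(v, dtype=float) - _V_LO) / (_V_HI - _V_LO), 0.0, 1.0)
    return 2.2 + 0.6 * frac


def _trunk_amp(axis: str, v: np.ndarray | float) -> np.ndarray | float:
    """Trunk oscillation half-amplitude (deg), +8% per m/s above 2.5."""
    base = _TRUNK_AMP0[axis]
    return base * (1.0 + 0.08 * np.clip(np.asarray(v, dtype=float) - _V_LO, 0.0, None))


_IMPACT_PEAK_T = 0.025  # s, time of impact peak within stance
_IMPACT_HALF_W = 0.025  # s, raised-cosine half-width of the impact lobe
_IMPACT_PEAK_BW = 1.6


def _stance_waveform(s: np.ndarray, a_imp: float, a_act: float, stance: float,
                     peak_frac: float, body_weight: float) -> np.ndarray:
    """Two-lobe stance force (N) at times ``s`` relative to contact start.

    Impact lobe: raised cosine peaking at 25 ms. Active lobe: asymmetric
    raised cosine, zero (with zero slope) at both contact boundaries and
    peaking at ``peak_frac`` of stance.
    """
    f = np.zeros_like(s)
    m = np.abs(s - _IMPACT_PEAK_T) < _IMPACT_HALF_W
    f[m] += a_imp * body_weight * 0.5 * (1.0 + np.cos(np.pi * (s[m] - _IMPACT_PEAK_T) / _IMPACT_HALF_W))
    tp = peak_frac * stance
    rise = (s >= 0) & (s <= tp)
    fall = (s > tp) & (s <= stance)
    f[rise] += a_act * body_weight * 0.5 * (1.0 - np.cos(np.pi * s[rise] / tp))
    f[fall] += a_act * body_weight * 0.5 * (1.0 + np.cos(np.pi * (s[fall] - tp) / ((1.0 - peak_frac) * stance)))
    return f


def _stance_truth(a_imp: float, a_act: float, stance: float, peak_frac: float,
                  mass: float, rate: float, sos: np.ndarray,
                  phase: float = 0.0) -> tuple[float, float, float, float]:
    """True GRF features of one stance after ideal low-pass processing.

    The isolated stance is rendered at the force-plate rate (with the
    sampling-grid ``phase`` offset of the contact within the trial, so
    discretisation affects truth and extraction identically) with
    generous zero padding, filtered with the pipeline's filter spec, and
    the feature definitions applied directly (threshold crossing +
    gradient walk for the boundaries, trapezoidal impulse,
    central-difference RFD to the force peak).
    """
    n_pad = int(round(0.15 * rate))
    s = np.arange(-n_pad, int(np.ceil(stance * rate)) + n_pad) / rate + phase
    f = _stance_waveform(s, a_imp, a_act, stance, peak_frac, mass * _G)
    f = sosfiltfilt(sos, f)
    above = np.flatnonzero(f > 40.0)
    i, j = above[0], above[-1]
    while i > 0 and f[i - 1] < f[i]:
        i -= 1
    while j + 1 < f.size and f[j + 1] < f[j]:
        j += 1
    seg = f[i : j + 1]
    ipk = int(np.argmax(seg))
    grf_peak = seg[ipk] / mass
    i_total = float(np.trapezoid(seg, dx=1.0 / rate))
    sub = seg[: ipk + 1]
    d = (sub[2:] - sub[:-2]) * rate / 2.0
    rfd_max = float(d.max()) / 1000.0
    rfd_avg = (seg[ipk] - seg[0]) / (ipk / rate) / 1000.0
    return float(grf_peak), i_total, rfd_max, rfd_avg


def _step_schedule(protocol: ProtocolSpec, effects: EffectSpec, rng: np.random.Generator
                   ) -> pd.DataFrame:
    """Sequential footfall schedule: contact times, periods, stance durations."""
    rows = []
    t = 0.3  # brief settling interval before the first contact
    while True:
        v = protocol.velocity_at(t)
        ve = _effective_velocity(v, protocol.start_velocity, effects.velocity_coupling)
        period = (1.0 + effects.timing_jitter * rng.standard_normal()) / _cadence(ve)
        period = max(period, 0.2)
        if t + period > protocol.duration:
            break
        stance = _duty_factor(ve) * period
        rows.append((t, period, stance, protocol.stage_at(t), v))
        t += period
    return pd.DataFrame(rows, columns=["t", "period", "stance", "stage", "velocity"])


def generate_breaths(protocol: ProtocolSpec, effects: EffectSpec, seed: int | np.random.Generator
                     ) -> tuple[pd.DataFrame, float]:
    """Breath-by-breath gas exchange with a planted V-slope breakpoint.

    V̇O2 follows the stage velocity profile through first-order kinetics
    (time constant 30 s) plus the slow-component drift seen at heavy
    intensity, which keeps V̇O2 strictly increasing within stages (and the
    breakpoint's time identifiable); V̇E is piecewise-linear in V̇O2 with
    ventilatory equivalent ~25 below the planted VT2 and a steeper slope
    above it; V̇CO2 tracks a respiratory exchange ratio rising
    0.85 -> 1.15 over the test. Returns the breath table and the planted
    VT2 time (s).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dur = protocol.duration
    vt2_time = effects.vt2_fraction * dur
    # clean VO2 trajectory on a 1 s grid
    tgrid = np.arange(0.0, dur + 1.0)
    target = protocol.body_mass * (10.0 + 12.0 * protocol.velocity_at(tgrid))  # mL/min
    tau = 30.0
    vo2 = np.empty_like(target)
    vo2[0] = 0.85 * target[0]
    for i in range(1, vo2.size):
        vo2[i] = vo2[i - 1] + (target[i] - vo2[i - 1]) / tau
    vo2 = vo2 + protocol.body_mass * effects.vo2_slow * tgrid / 60.0
    vo2_break = float(np.interp(vt2_time, tgrid, vo2))

    # breath times: breathing frequency ramps 0.35 -> 0.85 Hz over the test
    times = []
    t = 1.0
    while t < dur:
        times.append(t)
        fb = 0.35 + 0.5 * t / dur
        t += 1.0 / fb
    bt = np.asarray(times)

    vo2_b = np.interp(bt, tgrid, vo2)
    s_pre, s_post = 0.025, 0.045  # L/min ventilation per mL/min VO2
    ve_b = np.where(
        vo2_b <= vo2_break,
        s_pre * vo2_b,
        s_pre * vo2_break + s_post * (vo2_b - vo2_break),
    )
    rer = 0.85 + 0.30 * bt / dur
    vco2_b = rer * vo2_b

    noise = effects.breath_noise
    vo2_obs = vo2_b * np.clip(1.0 + noise * rng.standard_normal(bt.size), 0.05, None)
    ve_obs = ve_b * np.clip(1.0 + noise * rng.standard_normal(bt.size), 0.05, None)
    vco2_obs = vco2_b * np.clip(1.0 + noise * rng.standard_normal(bt.size), 0.05, None)
    breaths = pd.DataFrame({"time": bt, "vo2": vo2_obs, "vco2": vco2_obs, "ve": ve_obs})
    return breaths, vt2_time


def generate_subject(protocol: ProtocolSpec, effects: EffectSpec, seed: int
                     ) -> RawSubjectRecording:
    """Generate one synchronised subject recording with ground truth.

    Identical (protocol, effects, seed) triples yield identical
    recordings. Raises if the planted VT2 fraction places the breakpoint
    outside the recording's breath window.
    """
    if not 0.0 < effects.vt2_fraction < 1.0:
        raise ValueError("vt2_fraction places VT2 outside the recording")
    rng = np.random.default_rng(seed)
    mass = protocol.body_mass
    bw = mass * _G
    dur = protocol.duration
    vt2_time = effects.vt2_fraction * dur
    coupling = effects.velocity_coupling

    steps = _step_schedule(protocol, effects, rng)
    ns = len(steps)
    t0 = steps["t"].to_numpy()
    stage = steps["stage"].to_numpy()
    vel = steps["velocity"].to_numpy()

    def _mult(feat: str) -> np.ndarray:
        return effects.multiplier(feat, t0, stage, vt2_time, dur)

    def _noise(feat: str) -> np.ndarray:
        return 1.0 + effects.noise_sd(feat) * rng.standard_normal(ns)

    v_eff = _effective_velocity(vel, protocol.start_velocity, coupling)
    m_itot = _mult("I_total")
    a_act = _active_peak_bw(v_eff) * _noise("GRF_peak") * _mult("GRF_peak") * m_itot
    a_imp = _IMPACT_PEAK_BW * _noise("RFD_maxD") * _mult("RFD_maxD") * m_itot
    peak_frac = np.clip(0.5 / (_noise("RFD_avgD") * _mult("RFD_avgD")), 0.3, 0.7)
    trunk_amp = {
        feat: _trunk_amp(axis, v_eff) * _noise(feat) * _mult(feat)
        for feat, axis in _RT_TO_AXIS.items()
    }

    # ---- vertical GRF at grf_rate ----
    n_grf = int(round(dur * protocol.grf_rate))
    grf_time = np.arange(n_grf) / protocol.grf_rate
    force = np.zeros(n_grf)
    rate = protocol.grf_rate
    for i in range(ns):
        i0 = int(np.ceil(t0[i] * rate))
        i1 = min(int(np.floor((t0[i] + steps["stance"].iat[i]) * rate)) + 1, n_grf)
        s = grf_time[i0:i1] - t0[i]
        force[i0:i1] += _stance_waveform(
            s, a_imp[i], a_act[i], steps["stance"].iat[i], peak_frac[i], bw
        )
    if effects.grf_noise_sd > 0:
        force = force + effects.grf_noise_sd * rng.standard_normal(n_grf)
    force = np.clip(force, 0.0, None)

    # ---- trunk angular velocity at imu_rate ----
    n_imu = int(round(dur * protocol.imu_rate))
    gyro_time = np.arange(n_imu) / protocol.imu_rate
    step_idx = np.searchsorted(t0, gyro_time, side="right") - 1
    in_step = (step_idx >= 0) & (step_idx < ns)
    sidx = np.clip(step_idx, 0, ns - 1)
    u = np.where(
        in_step,
        (gyro_time - t0[sidx]) / steps["period"].to_numpy()[sidx],
        0.0,
    )
    in_step &= u < 1.0
    gyro = {}
    phases = {axis: rng.uniform(-0.5, 0.5) for axis in TRUNK_AXES}
    bias_signs = {axis: rng.choice([-1.0, 1.0]) for axis in TRUNK_AXES}
    for feat, axis in _RT_TO_AXIS.items():
        amp = trunk_amp[feat]
        omega = np.where(
            in_step,
            amp[sidx] * (2.0 * np.pi / steps["period"].to_numpy()[sidx])
            * np.cos(2.0 * np.pi * u + phases[axis]),
            0.0,
        )
        omega = omega + bias_signs[axis] * effects.gyro_bias
        if effects.gyro_noise_sd > 0:
            omega = omega + effects.gyro_noise_sd * rng.standard_normal(n_imu)
        gyro[axis] = omega
    gyro_df = pd.DataFrame(gyro, columns=list(TRUNK_AXES))

    # ---- breaths ----
    breaths, _ = generate_breaths(protocol, effects, rng)

    # ---- per-step ground truth ----
    sos = FilterSpec(order=2, cutoff=GRF_CUTOFF_HZ, rate=protocol.grf_rate).sos
    truth = {name: np.empty(ns) for name in FEATURE_NAMES}
    for i in range(ns):
        phase = np.ceil(t0[i] * rate) / rate - t0[i]
        gp, it, rmax, ravg = _stance_truth(
            a_imp[i], a_act[i], steps["stance"].iat[i], peak_frac[i], mass, rate, sos,
            phase=phase,
        )
        truth["GRF_peak"][i] = gp
        truth["I_total"][i] = it
        truth["RFD_maxD"][i] = rmax
        truth["RFD_avgD"][i] = ravg
    for feat in _RT_TO_AXIS:
        truth[feat] = 2.0 * trunk_amp[feat]
    true_steps = pd.concat([steps.reset_index(drop=True), pd.DataFrame(truth)], axis=1)

    ground_truth = {
        "vt2_time": float(vt2_time),
        "seed": int(seed),
        "effects": _effects_to_dict(effects),
        "steps": true_steps,
    }
    return RawSubjectRecording(
        grf_time=grf_time,
        grf=force,
        gyro_time=gyro_time,
        gyro=gyro_df,
        breaths=breaths,
        body_mass=mass,
        protocol=protocol,
        effects=effects,
        ground_truth=ground_truth,
    )


def derive_subject_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-subject seeds from a master seed (counter-based)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


#: cohort draw ranges mirroring the 13-runner study design
DEFAULT_COHORT_RANGES: dict = {
    "start_velocity": (2.5, 3.61),
    "n_stages": (5, 6, 7),
    "body_mass": (78.85, 6.89),  # mean, SD
    "vt2_fraction": (0.55, 0.75),  # the transition-phase window of the test
}


def generate_cohort(n_subjects: int, master_seed: int,
                    protocol_ranges: Mapping | None = None,
                    effects: EffectSpec | None = None,
                    protocol: ProtocolSpec | None = None,
                    ) -> list[RawSubjectRecording]:
    """Generate a cohort of independent subjects from stated ranges.

    Per-subject start velocity, stage count, body mass and VT2 fraction
    are drawn from ``protocol_ranges`` (defaults mirror the study: start
    velocity 2.5-3.61 m/s, 5-7 completed stages, body mass ~N(78.85,
    6.89) kg, VT2 at 55-75% of test duration); per-subject recording
    seeds are derived deterministically from the master seed, so two
    calls with the same master seed are identical.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    ranges = dict(DEFAULT_COHORT_RANGES)
    if protocol_ranges:
        ranges.update(protocol_ranges)
    base_protocol = protocol or ProtocolSpec()
    base_effects = effects or EffectSpec()
    # separate stream for cohort-level draws so per-subject seeds stay stable
    draw_rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), 791]))
    seeds = derive_subject_seeds(master_seed, n_subjects)
    cohort = []
    for i in range(n_subjects):
        v0 = draw_rng.uniform(*ranges["start_velocity"])
        nst = int(draw_rng.choice(ranges["n_stages"]))
        mass = float(np.clip(draw_rng.normal(*ranges["body_mass"]), 55.0, 105.0))
        vt2f = draw_rng.uniform(*ranges["vt2_fraction"])
        proto = replace(base_protocol, start_velocity=v0, n_stages=nst, body_mass=mass)
        eff = replace(base_effects, vt2_fraction=vt2f)
        cohort.append(generate_subject(proto, eff, seeds[i]))
    return cohort


# ---------------------------------------------------------------------------
# plain-text round trip: grf.csv, imu.csv, breaths.csv + ground-truth sidecar
# ---------------------------------------------------------------------------

_IMU_CSV_COLS = ["c7_x", "c7_y", "c7_z", "l5_x", "l5_y", "l5_z"]
# CSV x/y/z map to anatomical axes in the order LT (vertical rotation),
# MD (flexion/extension), AP (lateral flexion)
_CSV_TO_AXIS = dict(zip(_IMU_CSV_COLS, TRUNK_AXES))


def _effects_to_dict(effects: EffectSpec) -> dict:
    d = asdict(effects)
    d["shifts"] = dict(effects.shifts)
    d["feature_noise"] = dict(effects.feature_noise)
    d["gate_stage"] = dict(effects.gate_stage)
    return d


def write_recording(rec: RawSubjectRecording, outdir: str | Path) -> None:
    """Write a recording as three CSV files plus a JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time": rec.grf_time, "fz": rec.grf}).to_csv(outdir / "grf.csv", index=False)
    imu = pd.DataFrame({"time": rec.gyro_time})
    for csv_col, axis in _CSV_TO_AXIS.items():
        imu[csv_col] = rec.gyro[axis].to_numpy()
    imu.to_csv(outdir / "imu.csv", index=False)
    rec.breaths.to_csv(outdir / "breaths.csv", index=False)
    gt = dict(rec.ground_truth)
    gt["steps"] = gt["steps"].to_dict(orient="list")
    gt["protocol"] = asdict(rec.protocol)
    gt["body_mass"] = rec.body_mass
    (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=1))


def read_recording(indir: str | Path) -> RawSubjectRecording:
    """Read a recording previously written by :func:`write_recording`."""
    indir = Path(indir)
    grf = pd.read_csv(indir / "grf.csv")
    imu = pd.read_csv(indir / "imu.csv")
    breaths = pd.read_csv(indir / "breaths.csv")
    gt = json.loads((indir / "ground_truth.json").read_text())
    protocol = ProtocolSpec(**gt.pop("protocol"))
    body_mass = gt.pop("body_mass")
    eff_d = gt["effects"]
    effects = EffectSpec(**eff_d)
    gt["steps"] = pd.DataFrame(gt["steps"])
    gyro = pd.DataFrame({axis: imu[c].to_numpy() for c, axis in _CSV_TO_AXIS.items()})
    return RawSubjectRecording(
        grf_time=grf["time"].to_numpy(),
        grf=grf["fz"].to_numpy(),
        gyro_time=imu["time"].to_numpy(),
        gyro=gyro,
        breaths=breaths,
        body_mass=body_mass,
        protocol=protocol,
        effects=effects,
        ground_truth=gt,
    )
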