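"""Footfall detection and per-step feature extraction.

Footfalls are found on the (filtered) vertical GRF with a 40 N threshold
followed by a gradient walk that refines each boundary to the nearest
local minimum / zero-gradient sample. Ten features are computed per step:
four from the force channel (GRF_peak, I_total, RFD_maxD, RFD_avgD) and
six trunk angular-displacement ranges (three anatomical axes at C7 and
L5). The step window for angular ranges runs from one contact start to
the next, since trunk motion is not confined to stance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal import (
    AngleSeries,
    FilterSpec,
    GRF_CUTOFF_HZ,
    IMU_CUTOFF_HZ,
    butterworth_lowpass,
    integrate_gyro,
    remove_drift,
)
from .simulate import FEATURE_NAMES, TRUNK_AXES, RawSubjectRecording

__all__ = [
    "Footfall",
    "StepRejected",
    "detect_footfalls",
    "grf_features",
    "angular_ranges",
    "extract_all",
    "FEATURE_NAMES",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_N = 40.0
MIN_STANCE_S = 0.08   # contacts shorter than this are threshold chatter
MIN_FLIGHT_S = 0.03   # gaps shorter than this are merged into one contact


class StepRejected(ValueError):
    """A step whose waveform violates a feature precondition (e.g. the
    force peak falls on the first contact sample, leaving RFD undefined)."""


@dataclass(frozen=True)
class Footfall:
    """One detected ground contact on the force timeline."""

    start_index: int
    end_index: int  # inclusive
    start_time: float
    end_time: float

    @property
    def stance_duration(self) -> float:
        return self.end_time - self.start_time


def detect_footfalls(vgrf: np.ndarray, rate: float,
                     threshold: float = DEFAULT_THRESHOLD_N,
                     min_stance: float = MIN_STANCE_S,
                     min_flight: float = MIN_FLIGHT_S) -> list[Footfall]:
    """Detect ground contacts on a vertical GRF series.

    For each maximal run of samples above ``threshold``, the contact
    boundaries are refined by walking backward from the upward crossing
    and forward from the downward crossing to the nearest sample where
    the discrete gradient changes sign (a local minimum of the curve).
    Runs separated by less than ``min_flight`` are merged; refined
    contacts shorter than ``min_stance`` are discarded. An empty or
    always-subthreshold signal yields an empty list.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    f = np.asarray(vgrf, dtype=float)
    if f.size == 0:
        return []
    above = f > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(f.size - 1)

    # merge runs separated by implausibly short flight phases
    merged: list[list[int]] = []
    min_gap = int(round(min_flight * rate))
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    out: list[Footfall] = []
    prev_end = -1
    for s, e in merged:
        i = s
        while i - 1 > prev_end and f[i - 1] < f[i]:
            i -= 1
        j = e
        while j + 1 < f.size and f[j + 1] < f[j]:
            j += 1
        if (j - i) / rate < min_stance:
            continue
        out.append(Footfall(start_index=i, end_index=j,
                            start_time=i / rate, end_time=j / rate))
        prev_end = j
    return out


def grf_features(segment: np.ndarray, rate: float, body_mass: float
                 ) -> tuple[float, float, float, float]:
    """GRF features for one contact segment.

    Returns ``(GRF_peak, I_total, RFD_maxD, RFD_avgD)``:

    * GRF_peak — max force normalised by body mass (N·kg⁻¹);
    * I_total — trapezoidal impulse over the contact (N·s, unnormalised);
    * RFD_maxD — maximum of the central-finite-difference rate of force
      development between contact start and the force peak (kN·s⁻¹);
    * RFD_avgD — mean slope over the same interval, i.e.
      (F_peak − F_start) / (t_peak − t_start) (kN·s⁻¹).

    Raises :class:`StepRejected` if the peak falls on the first sample
    (no loading phase, RFD undefined).
    """
    f = np.asarray(segment, dtype=float)
    ipk = int(np.argmax(f))
    if ipk < 2:
        raise StepRejected("force peak at contact onset: RFD undefined")
    grf_peak = float(f[ipk]) / body_mass
    i_total = float(np.trapezoid(f, dx=1.0 / rate))
    sub = f[: ipk + 1]
    d = (sub[2:] - sub[:-2]) * rate / 2.0
    rfd_max = float(d.max()) / 1000.0
    rfd_avg = float(f[ipk] - f[0]) / (ipk / rate) / 1000.0
    return grf_peak, i_total, rfd_max, rfd_avg


def angular_ranges(angles: dict[str, np.ndarray], start: int, stop: int) -> dict[str, float]:
    """Max-min angular range per axis over one step window [start, stop).

    ``angles`` maps axis names to angle series already resampled onto the
    force clock.
    """
    if stop <= start:
        raise ValueError("empty step window")
    return {axis: float(np.ptp(a[start:stop])) for axis, a in angles.items()}


def trunk_angles_on_force_clock(rec: RawSubjectRecording,
                                imu_filter: FilterSpec | None = None) -> dict[str, np.ndarray]:
    """Filter, integrate and drift-correct each gyro axis, then resample.

    Angular velocity is low-pass filtered (15 Hz default) before
    integration; the integrated angle is drift-corrected with a single
    least-squares line per trial and linearly interpolated onto the force
    timeline, which both systems share by synchronisation.
    """
    spec = imu_filter or FilterSpec(order=2, cutoff=IMU_CUTOFF_HZ, rate=rec.protocol.imu_rate)
    out = {}
    for axis in TRUNK_AXES:
        omega = butterworth_lowpass(rec.gyro[axis].to_numpy(), spec)
        angle = remove_drift(integrate_gyro(omega, rec.protocol.imu_rate))
        out[axis] = np.interp(rec.grf_time, angle.time, angle.angle)
    return out


_AXIS_TO_RT = {
    "c7_lt": "RT_LTu", "c7_md": "RT_MDu", "c7_ap": "RT_APu",
    "l5_lt": "RT_LTlo", "l5_md": "RT_MDlo", "l5_ap": "RT_APlo",
}


def extract_all(rec: RawSubjectRecording,
                grf_filter: FilterSpec | None = None,
                imu_filter: FilterSpec | None = None,
                threshold: float = DEFAULT_THRESHOLD_N,
                prefiltered: bool = False) -> pd.DataFrame:
    """Extract the full per-step feature matrix from one recording.

    Returns one row per retained step with the ten features plus the
    contact time ``t``, ``step_time`` (contact start to next contact
    start), ``stage`` index and belt ``velocity`` from the protocol
    clock. The final footfall has no following contact and is dropped;
    steps rejected at the feature level are logged and skipped. With
    ``prefiltered=True`` the force channel is used as-is (e.g. for
    noise-free oracle comparisons).
    """
    rate = rec.protocol.grf_rate
    if prefiltered:
        force = np.asarray(rec.grf, dtype=float)
    else:
        spec = grf_filter or FilterSpec(order=2, cutoff=GRF_CUTOFF_HZ, rate=rate)
        force = butterworth_lowpass(rec.grf, spec)
    footfalls = detect_footfalls(force, rate, threshold=threshold)
    if len(footfalls) < 2:
        return pd.DataFrame(columns=["t", "step_time", "stage", "velocity", *FEATURE_NAMES])

    angles = trunk_angles_on_force_clock(rec, imu_filter=imu_filter)
    rows = []
    n_rejected = 0
    for ff, nxt in zip(footfalls[:-1], footfalls[1:]):
        try:
            gp, it, rmax, ravg = grf_features(
                force[ff.start_index : ff.end_index + 1], rate, rec.body_mass
            )
        except StepRejected as exc:
            n_rejected += 1
            log.warning("step at t=%.3f s rejected: %s", ff.start_time, exc)
            continue
        ranges = angular_ranges(angles, ff.start_index, nxt.start_index)
        row = {
            "t": ff.start_time,
            "step_time": nxt.start_time - ff.start_time,
            "stage": rec.protocol.stage_at(ff.start_time),
            "velocity": rec.protocol.velocity_at(ff.start_time),
            "GRF_peak": gp,
            "I_total": it,
            "RFD_maxD": rmax,
            "RFD_avgD": ravg,
        }
        row.update({_AXIS_TO_RT[axis]: ranges[axis] for axis in TRUNK_AXES})
        rows.append(row)
    if n_rejected:
        log.info("rejected %d of %d steps", n_rejected, len(footfalls) - 1)
    return pd.DataFrame(rows, columns=["t", "step_time", "stage", "velocity", *FEATURE_NAMES])
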