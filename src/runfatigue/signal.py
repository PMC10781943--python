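"""Low-level signal conditioning for treadmill running trials.

Covers the three conditioning steps the analysis relies on: zero-phase
Butterworth low-pass filtering of the force and angular-velocity channels,
breath-by-breath smoothing with a centred moving average, and gyroscope
integration with least-squares drift removal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "FilterSpec",
    "AngleSeries",
    "butterworth_lowpass",
    "moving_average_breaths",
    "integrate_gyro",
    "remove_drift",
]

#: default cutoffs: 30 Hz for the force channel, 15 Hz for angular velocity
GRF_CUTOFF_HZ = 30.0
IMU_CUTOFF_HZ = 15.0


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification, applied forward-backward.

    The zero-phase (forward-backward) application avoids timing bias in
    contact-relative features; the effective attenuation is the squared
    magnitude response of the underlying filter, so a sine at the nominal
    cutoff emerges at ~0.5 amplitude rather than ~0.707.
    """

    order: int = 2
    cutoff: float = GRF_CUTOFF_HZ
    rate: float = 516.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if not 0.0 < self.cutoff < self.rate / 2.0:
            raise ValueError(
                f"cutoff must lie in (0, rate/2) = (0, {self.rate / 2}), got {self.cutoff}"
            )

    @property
    def sos(self) -> np.ndarray:
        return butter(self.order, self.cutoff, fs=self.rate, output="sos")


@dataclass
class AngleSeries:
    """A drift-corrected angular-displacement trace for one gyroscope axis.

    ``angle`` is in degrees on the same timeline as the source angular
    velocity stream; after :func:`remove_drift` it has zero mean and zero
    linear trend.
    """

    time: np.ndarray
    angle: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.time.shape != self.angle.shape:
            raise ValueError("time and angle must have the same shape")
        if not np.all(np.isfinite(self.angle)):
            raise ValueError("angle series contains non-finite values")


def butterworth_lowpass(signal: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase low-pass filter a uniformly sampled series.

    Linear, time-invariant, length-preserving, DC gain exactly 1.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if x.size < 3 * spec.order:
        raise ValueError(
            f"need at least {3 * spec.order} samples for an order-{spec.order} filter"
        )
    return sosfiltfilt(spec.sos, x)


def moving_average_breaths(breaths: pd.DataFrame, window: int = 11) -> pd.DataFrame:
    """Smooth breath-by-breath gas-exchange data with a centred moving mean.

    ``breaths`` holds one row per breath with columns ``time``, ``vo2``,
    ``vco2``, ``ve``. The default eleven-breath window is applied
    independently to each gas channel; at the series edges the window
    shrinks symmetrically (the first and last breaths are returned
    unchanged). Breath times are never modified.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    n = len(breaths)
    if n < 1:
        raise ValueError("need at least one breath")
    half = window // 2
    out = breaths.copy()
    idx = np.arange(n)
    k = np.minimum(np.minimum(idx, n - 1 - idx), half)
    lo = idx - k
    hi = idx + k + 1
    for col in ("vo2", "vco2", "ve"):
        v = breaths[col].to_numpy(dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(v)])
        out[col] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def integrate_gyro(omega: np.ndarray, rate: float) -> AngleSeries:
    """Angular displacement by cumulative trapezoidal integration.

    ``omega`` is one uniformly sampled angular-velocity axis in deg/s;
    the returned angle starts at 0 deg. Gyroscope bias accumulates as an
    (approximately linear) drift here and is removed afterwards by
    :func:`remove_drift`.
    """
    w = np.asarray(omega, dtype=float)
    if w.ndim != 1:
        raise ValueError("expected a 1-D angular-velocity series")
    if not np.all(np.isfinite(w)):
        raise ValueError("angular velocity contains non-finite samples")
    t = np.arange(w.size) / float(rate)
    angle = cumulative_trapezoid(w, dx=1.0 / float(rate), initial=0.0)
    return AngleSeries(time=t, angle=angle)


def remove_drift(series: AngleSeries) -> AngleSeries:
    """Remove integration drift with an ordinary least-squares line.

    A single straight line (angle vs time) is fitted over the whole trial
    and subtracted, which is exact when the drift source is a constant
    gyroscope bias. The residual has zero mean and zero linear trend, so
    the operation is idempotent.
    """
    if series.time.size < 2:
        raise ValueError("need at least 2 samples to fit a drift line")
    coef = np.polyfit(series.time, series.angle, deg=1)
    trend = np.polyval(coef, series.time)
    return AngleSeries(time=series.time.copy(), angle=series.angle - trend)
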