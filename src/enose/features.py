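"""Onboard feature computation: extrema, area, slope, relative response.

The firmware reduces each sensor's transient to three scalar features:

* area under the curve over the sampling phase, by the trapezoidal rule
  ``A = sum_t 0.5 * [f(t) + f(t+1)] * dt``;
* slope ``(max - min) / t_max`` with ``t_max`` the time from sampling start
  to the maximum;
* relative response ``(max - min) / min``.

The minimum is searched over baseline + sampling (it acts as the
pre-exposure baseline level); the maximum and ``t_max`` over the sampling
phase only.  All three features ignore the purge phase entirely.

The firmware integrated on a 1 s grid while acquiring at 15 Hz: with
``dt_s = 1.0`` (the default) the grid values f(0), f(1), ... are the
native samples at those times — f(t) is a point sample, so the sum keeps
the trapezoid rule's second-order accuracy — with the final grid point
clamped to the last sample of the phase, so a constant c over an n-second
phase integrates to exactly c*n.  With ``dt_s`` equal to the native
interval the computation is the plain trapezoid over the raw samples
(exact for piecewise-linear signals).

``baseline_correct`` implements differential baseline correction: the mean
of the last few seconds of the baseline phase is subtracted from the whole
curve, removing sensor-to-sensor offset before smellprint analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .device import ADC_MAX, VOLT_MAX, CycleConfig
from .simulator import ResponseCurve

#: One A/D count in volts — the floor the firmware uses for the relative
#: response denominator (an integer MCU never divides by zero counts).
_ADC_LSB_V = VOLT_MAX / ADC_MAX

__all__ = [
    "CurveExtrema",
    "SensorFeatures",
    "FeatureVector",
    "FeatureError",
    "extract_extrema",
    "area_under_curve",
    "slope",
    "relative_response",
    "baseline_correct",
    "featurize",
]


class FeatureError(ValueError):
    """A feature cannot be computed from the given curve or extrema."""


@dataclass(frozen=True)
class CurveExtrema:
    """Minimum, maximum and time-to-maximum of one response curve.

    ``min_v`` is taken over baseline + sampling, ``max_v`` over the
    sampling phase, ``t_max_s`` measured from the start of sampling.
    """

    min_v: float
    max_v: float
    t_max_s: float

    def __post_init__(self) -> None:
        if self.max_v < self.min_v:
            raise FeatureError(f"max_v {self.max_v} < min_v {self.min_v}")
        if self.t_max_s < 0:
            raise FeatureError(f"t_max_s must be >= 0, got {self.t_max_s}")


@dataclass(frozen=True)
class SensorFeatures:
    """The three features plus extrema provenance for one sensor."""

    area_vs: float
    slope_vps: float
    relative: float
    extrema: CurveExtrema


@dataclass(frozen=True)
class FeatureVector:
    """Per-sensor features of one measurement, keyed by sensor id."""

    sensors: Mapping[int, SensorFeatures]

    @property
    def sensor_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.sensors))

    def values(self, feature: str) -> np.ndarray:
        """One value per sensor in ascending sensor-id order.

        ``feature`` is one of "area", "slope", "relative".
        """
        attr = {"area": "area_vs", "slope": "slope_vps", "relative": "relative"}[feature]
        return np.array([getattr(self.sensors[i], attr) for i in self.sensor_ids])


def extract_extrema(curve: ResponseCurve) -> CurveExtrema:
    """Extract min (baseline+sampling), max (sampling) and time-to-max.

    Ties in the maximum resolve to the earliest sample.
    """
    samp = curve.sampling_slice
    if samp.stop - samp.start < 1:
        raise FeatureError("curve has an empty sampling phase")
    pre = curve.values_v[: samp.stop]  # baseline + sampling
    sampling_vals = curve.values_v[samp]
    i_max = int(np.argmax(sampling_vals))  # argmax returns first occurrence
    t_max = curve.times_s[samp.start + i_max] - curve.times_s[samp.start]
    return CurveExtrema(
        min_v=float(pre.min()),
        max_v=float(sampling_vals[i_max]),
        t_max_s=float(t_max),
    )


def area_under_curve(curve: ResponseCurve, dt_s: float = 1.0) -> float:
    """Trapezoidal area (V*s) under the sampling phase of a curve.

    See the module docstring for the two grid modes.  A ``dt_s`` larger
    than the phase itself raises.
    """
    if dt_s <= 0:
        raise FeatureError(f"dt_s must be > 0, got {dt_s}")
    samp = curve.sampling_slice
    vals = curve.values_v[samp]
    if len(vals) < 2:
        raise FeatureError("sampling phase too short to integrate")
    native_dt = curve.dt_s
    if abs(dt_s - native_dt) < 1e-12:
        return float(np.trapezoid(vals, dx=native_dt))
    per_step = dt_s / native_dt
    if abs(per_step - round(per_step)) > 1e-9:
        raise FeatureError(
            f"dt_s={dt_s} is not a multiple of the native interval {native_dt}"
        )
    per_step = round(per_step)
    m = len(vals) // per_step  # whole dt_s intervals covered by the phase
    if m < 1:
        raise FeatureError("dt_s exceeds the sampling-phase duration")
    # point samples at t = 0, dt, ..., m*dt; the final point clamps to the
    # last sample of the phase when m*dt falls one native step past it
    idx = np.minimum(np.arange(m + 1) * per_step, len(vals) - 1)
    return float(np.trapezoid(vals[idx], dx=dt_s))


def slope(extrema: CurveExtrema) -> float:
    """Slope feature (V/s): (max - min) / time-to-max.

    A flat curve (max == min) has slope 0 even at t_max == 0; a rise with
    t_max == 0 is contradictory and raises.
    """
    rng = extrema.max_v - extrema.min_v
    if extrema.t_max_s == 0:
        if rng == 0:
            return 0.0
        raise FeatureError("t_max_s == 0 with max_v > min_v")
    return rng / extrema.t_max_s


def relative_response(extrema: CurveExtrema) -> float:
    """Relative response (dimensionless): (max - min) / min."""
    if extrema.min_v <= 0:
        raise FeatureError(
            f"relative response undefined for min_v <= 0 (got {extrema.min_v}); "
            "compute it on uncorrected signals"
        )
    return (extrema.max_v - extrema.min_v) / extrema.min_v


def baseline_correct(curve: ResponseCurve, window_s: float = 5.0) -> ResponseCurve:
    """Differential baseline correction.

    Subtracts the mean of the last ``window_s`` seconds of the baseline
    phase from every sample of the curve; phase marks are preserved.
    """
    if window_s <= 0:
        raise FeatureError("window_s must be > 0")
    base = curve.baseline_slice
    n_base = base.stop - base.start
    n_win = round(window_s * curve.sampling_rate_hz)
    if n_base < n_win:
        raise FeatureError(
            f"baseline phase ({n_base} samples) shorter than window ({n_win} samples)"
        )
    offset = float(curve.values_v[base.stop - n_win : base.stop].mean())
    return replace(curve, values_v=curve.values_v - offset)


def featurize(
    curves: Sequence[ResponseCurve],
    cycle: CycleConfig,
    *,
    correct_baseline: bool = False,
    dt_s: float = 1.0,
    baseline_window_s: float = 5.0,
) -> FeatureVector:
    """Compute the three features for every sensor of one measurement.

    The firmware path (``correct_baseline=False``) works on raw signals.
    The analysis path first applies differential baseline correction; area
    is then computed on the corrected curve, slope is offset-invariant, and
    the relative response is always taken from the *uncorrected* extrema
    (its denominator, the pre-exposure minimum, is only meaningful on the
    raw signal).  A raw minimum at 0 V (hard-clipped signal) is floored to
    one A/D count, as the integer firmware would.
    """
    ids = [c.sensor_id for c in curves]
    if len(set(ids)) != len(ids):
        raise FeatureError(f"duplicate sensor ids in measurement: {ids}")
    out: dict[int, SensorFeatures] = {}
    for curve in curves:
        raw_ext = extract_extrema(curve)
        work = baseline_correct(curve, baseline_window_s) if correct_baseline else curve
        ext = extract_extrema(work) if correct_baseline else raw_ext
        rel_ext = raw_ext if raw_ext.min_v > 0 else replace(raw_ext, min_v=_ADC_LSB_V)
        # a noisy max on the very first sampling sample gives t_max = 0;
        # floor it to one sample interval so the quotient stays defined
        slope_ext = ext if ext.t_max_s > 0 else replace(ext, t_max_s=curve.dt_s)
        out[curve.sensor_id] = SensorFeatures(
            area_vs=area_under_curve(work, dt_s),
            slope_vps=slope(slope_ext),
            relative=relative_response(rel_ext),
            extrema=ext,
        )
    return FeatureVector(sensors=out)
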