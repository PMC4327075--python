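"""Synthetic MOS sensor response curves.

A real MOS sensor exposed to a reducing gas shows a flat baseline in clean
air, a saturating rise during odor exposure and an exponential recovery
during the purge.  The simulator reproduces that qualitative shape with a
first-order (single-exponential) transient:

* deterministic sampling-phase response
  ``baseline_v + A * (1 - exp(-t / rise_tau_s))``, where the plateau
  amplitude ``A`` sums a log-compressed term per chemical,
  ``sensitivity * log10(1 + conc / LDL)`` (LDL = the sensor's lower
  detection limit) — a simple stand-in for the power-law conductance
  response of MOS sensors;
* exponential decay toward the baseline during the purge with
  ``decay_tau_s``;
* additive white Gaussian noise, a linear drift term, and hard clipping to
  the 0-5 V circuit range.

All randomness flows from one caller-supplied seed through per-curve
substreams keyed by (seed, stream, sensor_id), so a whole experiment is
reproducible and individual curves are bit-stable regardless of the order
they are generated in.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator, Mapping

import numpy as np

from .device import ArraySpec, ConfigurationError, CycleConfig, SensorSpec, VOLT_MAX, default_array

__all__ = [
    "GasSample",
    "SensorGasModel",
    "PhaseMarks",
    "ResponseCurve",
    "ExperimentDesign",
    "simulate_curve",
    "simulate_measurement",
    "simulate_experiment",
    "plateau_amplitude",
    "healthy_onion_gas",
    "sour_skin_gas",
    "onion_model",
    "sour_skin_design",
]


@dataclass(frozen=True)
class GasSample:
    """A labelled headspace sample: chemical name -> concentration (ppm)."""

    label: str
    concentrations_ppm: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, c in self.concentrations_ppm.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}: {c}")


@dataclass(frozen=True)
class SensorGasModel:
    """Parametrization of the array's response to a gas sample.

    Parameters
    ----------
    sensitivity
        Map ``(sensor_id, chemical_name) -> volts`` contributed at the
        reference concentration scale (one decade above the sensor's lower
        detection limit contributes ``sensitivity * log10(11) ~ sensitivity``).
        Missing pairs contribute nothing.
    rise_tau_s, decay_tau_s
        First-order time constants of the sampling-phase rise and the
        purge-phase recovery, in seconds.
    baseline_v
        Clean-air signal level, volts.
    noise_sd_v
        Standard deviation of the additive white noise, volts.
    drift_v_per_s
        Linear baseline drift added throughout the cycle, volts/second.
    sample_scale_sigma
        Sigma of a lognormal per-measurement amplitude factor shared by all
        sensors of one measurement — replicate-to-replicate (e.g. bulb-to-
        bulb) variability in headspace strength.  0 disables it.
    """

    sensitivity: Mapping[tuple[int, str], float]
    rise_tau_s: float = 8.0
    decay_tau_s: float = 15.0
    baseline_v: float = 0.6
    noise_sd_v: float = 0.02
    drift_v_per_s: float = 0.0
    sample_scale_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("rise_tau_s and decay_tau_s must be > 0")
        if self.noise_sd_v < 0:
            raise ValueError("noise_sd_v must be >= 0")
        if self.baseline_v < 0:
            raise ValueError("baseline_v must be >= 0")
        for key, s in self.sensitivity.items():
            if s < 0:
                raise ValueError(f"negative sensitivity for {key}: {s}")


@dataclass(frozen=True)
class PhaseMarks:
    """Start indices of the three phases within a curve's sample arrays."""

    baseline: int
    sampling: int
    purge: int

    def __post_init__(self) -> None:
        if not (0 <= self.baseline <= self.sampling <= self.purge):
            raise ValueError(f"phase marks out of order: {self}")


@dataclass(frozen=True)
class ResponseCurve:
    """One sensor's signal across a three-phase measurement cycle."""

    sensor_id: int
    times_s: np.ndarray
    values_v: np.ndarray
    phase_marks: PhaseMarks
    sampling_rate_hz: float = 15.0

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.values_v):
            raise ValueError("times_s and values_v must have equal length")
        if len(self.times_s) and self.times_s[0] != 0:
            raise ValueError("times_s must start at 0")
        if self.phase_marks.purge > len(self.times_s):
            raise ValueError("phase marks beyond end of curve")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def baseline_slice(self) -> slice:
        return slice(self.phase_marks.baseline, self.phase_marks.sampling)

    @property
    def sampling_slice(self) -> slice:
        return slice(self.phase_marks.sampling, self.phase_marks.purge)

    @property
    def purge_slice(self) -> slice:
        return slice(self.phase_marks.purge, len(self.times_s))


def plateau_amplitude(model: SensorGasModel, sensor: SensorSpec, gas: GasSample) -> float:
    """Deterministic plateau amplitude A (volts) of the sampling-phase rise."""
    ldl = sensor.lower_detection_limit_ppm
    total = 0.0
    for chem, conc in gas.concentrations_ppm.items():
        s = model.sensitivity.get((sensor.sensor_id, chem), 0.0)
        if s > 0.0 and conc > 0.0:
            total += s * np.log10(1.0 + conc / ldl)
    return total


def _curve_rng(seed: int, stream: int, sensor_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream), int(sensor_id)]))


def simulate_curve(
    sensor: SensorSpec,
    gas: GasSample,
    model: SensorGasModel,
    cycle: CycleConfig,
    seed: int,
    *,
    sampling_rate_hz: float = 15.0,
    stream: int = 0,
    amplitude_scale: float = 1.0,
) -> ResponseCurve:
    """Simulate one sensor's response curve for one measurement cycle.

    ``stream`` selects an independent noise substream under the same seed
    (used by :func:`simulate_experiment` to give each measurement its own
    noise); ``amplitude_scale`` multiplies the plateau amplitude (used for
    per-measurement replicate variability).
    """
    if cycle.baseline_purge_s < 0 or cycle.sampling_s < 0 or cycle.purge_s < 0:
        raise ConfigurationError("phase durations must be non-negative")
    rate = float(sampling_rate_hz)
    n_b = round(cycle.baseline_purge_s * rate)
    n_s = round(cycle.sampling_s * rate)
    n_p = round(cycle.purge_s * rate)
    n = n_b + n_s + n_p
    t = np.arange(n) / rate

    amp = amplitude_scale * plateau_amplitude(model, sensor, gas)
    v = np.full(n, model.baseline_v)
    t_s0 = n_b / rate
    rise = t[n_b : n_b + n_s] - t_s0
    v[n_b : n_b + n_s] += amp * (1.0 - np.exp(-rise / model.rise_tau_s))
    if n_p:
        # decay starts from the deterministic level reached at the end of sampling
        level = amp * (1.0 - np.exp(-(n_s / rate) / model.rise_tau_s)) if n_s else 0.0
        t_p0 = (n_b + n_s) / rate
        v[n_b + n_s :] += level * np.exp(-(t[n_b + n_s :] - t_p0) / model.decay_tau_s)

    v = v + model.drift_v_per_s * t
    if model.noise_sd_v > 0:
        rng = _curve_rng(seed, stream, sensor.sensor_id)
        v = v + rng.normal(0.0, model.noise_sd_v, n)
    v = np.clip(v, 0.0, VOLT_MAX)

    return ResponseCurve(
        sensor_id=sensor.sensor_id,
        times_s=t,
        values_v=v,
        phase_marks=PhaseMarks(0, n_b, n_b + n_s),
        sampling_rate_hz=rate,
    )


def simulate_measurement(
    array: ArraySpec,
    gas: GasSample,
    model: SensorGasModel,
    cycle: CycleConfig,
    seed: int,
    *,
    stream: int = 0,
) -> list[ResponseCurve]:
    """Simulate one measurement: one curve per sensor of the array.

    If the model has ``sample_scale_sigma > 0`` a single lognormal amplitude
    factor is drawn per measurement and shared across the seven sensors.
    """
    scale = 1.0
    if model.sample_scale_sigma > 0:
        # sensor_id 0 is never a real sensor: reserved for the shared factor
        rng = _curve_rng(seed, stream, 0)
        scale = float(np.exp(rng.normal(0.0, model.sample_scale_sigma)))
    return [
        simulate_curve(
            s, gas, model, cycle, seed,
            sampling_rate_hz=array.sampling_rate_hz,
            stream=stream,
            amplitude_scale=scale,
        )
        for s in array.sensors
    ]


def simulate_experiment(
    groups: Mapping[str, GasSample],
    replicates_per_group: int,
    model: SensorGasModel,
    cycle: CycleConfig,
    seed: int,
    *,
    array: ArraySpec | None = None,
) -> list[tuple[str, list[ResponseCurve]]]:
    """Simulate ``replicates_per_group`` measurements of each group.

    Returns a list of (label, seven curves) with independent noise per
    measurement; total length ``len(groups) * replicates_per_group``.
    """
    if not groups:
        raise ValueError("groups must be non-empty")
    if replicates_per_group < 1:
        raise ValueError("replicates_per_group must be >= 1")
    array = array or default_array()
    out: list[tuple[str, list[ResponseCurve]]] = []
    stream = 0
    for label, gas in groups.items():
        for _ in range(replicates_per_group):
            out.append((label, simulate_measurement(array, gas, model, cycle, seed, stream=stream)))
            stream += 1
    return out


@dataclass(frozen=True)
class ExperimentDesign:
    """Enumerates the measurements of a repeated-measures study.

    ``groups`` x ``units_per_group`` (e.g. onion bulbs) x
    ``sessions_per_day`` x ``days`` measurements in total.
    """

    groups: tuple[str, ...]
    units_per_group: int = 8
    sessions_per_day: int = 3
    days: int = 2

    @property
    def replicates_per_group(self) -> int:
        return self.units_per_group * self.sessions_per_day * self.days

    @property
    def n_measurements(self) -> int:
        return len(self.groups) * self.replicates_per_group

    def __iter__(self) -> Iterator[tuple[str, int, int, int]]:
        """Yield (group, unit, day, session) for every planned measurement."""
        for g, u, d, s in product(
            self.groups,
            range(self.units_per_group),
            range(self.days),
            range(self.sessions_per_day),
        ):
            yield (g, u, d, s)


def sour_skin_design() -> ExperimentDesign:
    """The healthy-vs-sour-skin proof-of-concept design.

    Two groups of eight onion bulbs each, measured three times per day on
    two consecutive days: 96 measurements.
    """
    return ExperimentDesign(groups=("healthy", "sour_skin"))


# -- presets -----------------------------------------------------------------

# Target healthy plateau amplitudes per sensor (volts): TGS 826 and SB-AQ8
# respond most, TGS 813 least — mirroring the observed sensor ranking.
_HEALTHY_AMPL_V = {1: 0.25, 2: 0.45, 3: 0.50, 4: 0.70, 5: 0.50, 6: 0.40, 7: 0.80}
_BACKGROUND = "onion background volatiles"
_MPD = "methyl propyl disulfide"
_NONANONE = "2-nonanone"
_BACKGROUND_PPM = 100.0
# Disease-marker headspace levels follow the characterization work:
# 0.5 uL of each marker in a 0.5 L jar gives ~196 / ~145 ppm.
_MPD_PPM = 196.0
_NONANONE_PPM = 145.0
# Marker contributions sum to 1.4x the healthy amplitude, so diseased
# plateaus are 2.4x healthy — consistent with "more than twice".
_MPD_FRACTION = 0.8
_NONANONE_FRACTION = 0.6


def healthy_onion_gas() -> GasSample:
    """Headspace of a healthy onion bulb: background volatiles only."""
    return GasSample("healthy", {_BACKGROUND: _BACKGROUND_PPM})


def sour_skin_gas() -> GasSample:
    """Headspace of a sour-skin infected bulb: background plus the two
    disease markers (methyl propyl disulfide, 2-nonanone)."""
    return GasSample(
        "sour_skin",
        {_BACKGROUND: _BACKGROUND_PPM, _MPD: _MPD_PPM, _NONANONE: _NONANONE_PPM},
    )


def onion_model(
    *,
    noise_sd_v: float = 0.02,
    drift_v_per_s: float = 0.0002,
    sample_scale_sigma: float = 0.25,
    array: ArraySpec | None = None,
) -> SensorGasModel:
    """Default sensor-gas model for the onion disease study.

    Sensitivities are back-computed from the target plateau amplitudes so
    that the diseased preset responds 2.4x the healthy one on every sensor.
    """
    array = array or default_array()
    sens: dict[tuple[int, str], float] = {}
    for s in array.sensors:
        a_h = _HEALTHY_AMPL_V[s.sensor_id]
        ldl = s.lower_detection_limit_ppm
        sens[(s.sensor_id, _BACKGROUND)] = a_h / np.log10(1.0 + _BACKGROUND_PPM / ldl)
        sens[(s.sensor_id, _MPD)] = _MPD_FRACTION * a_h / np.log10(1.0 + _MPD_PPM / ldl)
        sens[(s.sensor_id, _NONANONE)] = (
            _NONANONE_FRACTION * a_h / np.log10(1.0 + _NONANONE_PPM / ldl)
        )
    return SensorGasModel(
        sensitivity=sens,
        noise_sd_v=noise_sd_v,
        drift_v_per_s=drift_v_per_s,
        sample_scale_sigma=sample_scale_sigma,
    )
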