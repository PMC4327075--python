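"""Static description of the sensor array and measurement-cycle configuration.

The instrument is an array of seven metal-oxide-semiconductor (MOS) gas
sensors — five Figaro TGS-series tin-dioxide sensors plus two FIS sensors
(one SnO2, one WO3) — housed in a chamber through which a pump draws either
clean air or sample headspace.  A measurement cycle has three phases:
baseline purging (clean air), sampling (odor exposure) and purging
(recovery).  Everything downstream (simulator, firmware emulation, feature
extraction) shares the types defined here.

Sensor signals are modelled in volts on [0, 5]; the instrument's 10-bit
A/D view (integer counts 0-1023) is available as an optional quantization
layer (:func:`adc_counts` / :func:`adc_volts`).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass
from enum import Enum, IntEnum
from importlib import resources
from pathlib import Path


import numpy as np

__all__ = [
    "Oxide",
    "PumpSpeed",
    "FeatureSelection",
    "SensorSpec",
    "ArraySpec",
    "CycleConfig",
    "ConfigurationError",
    "default_array",
    "characterization_config",
    "adc_counts",
    "adc_volts",
    "read_cycle_config",
    "write_cycle_config",
]

#: Supply voltage of the sensing circuit; signals live on [0, VOLT_MAX] volts.
VOLT_MAX = 5.0
#: Full-scale count of the 10-bit A/D converter.
ADC_MAX = 1023


class ConfigurationError(ValueError):
    """An invalid array or cycle configuration."""


class Oxide(str, Enum):
    """Sensing-layer chemistry of a MOS sensor."""

    SNO2 = "SnO2"
    WO3 = "WO3"


class PumpSpeed(IntEnum):
    """Diaphragm-pump speed: LOW = 850 mL/min, HIGH = 1700 mL/min."""

    LOW = 0
    HIGH = 1


class FeatureSelection(IntEnum):
    """Onboard feature-extraction choice (command digit)."""

    AREA = 1
    RELATIVE = 2
    SLOPE = 3
    ALL = 4


@dataclass(frozen=True)
class SensorSpec:
    """One MOS sensor: identity, target chemistry and detection limit.

    ``lower_detection_limit_ppm`` is the manufacturer's reported lower
    detection limit; the simulator uses it as the concentration scale of
    the sensor's log-compressed response.
    """

    sensor_id: int
    name: str
    oxide: Oxide
    specificity: str
    lower_detection_limit_ppm: float

    def __post_init__(self) -> None:
        if self.sensor_id < 1:
            raise ConfigurationError(f"sensor_id must be >= 1, got {self.sensor_id}")
        if self.lower_detection_limit_ppm <= 0:
            raise ConfigurationError(
                f"lower_detection_limit_ppm must be > 0, got "
                f"{self.lower_detection_limit_ppm}"
            )


@dataclass(frozen=True)
class ArraySpec:
    """The sensor array plus chamber geometry and acquisition rate.

    ``inlet_sensor_id`` / ``outlet_sensor_id`` record which sensors sit at
    the chamber's gas entry and exit points (the default geometry places
    TGS 813 at the inlet and TGS 825 at the outlet).
    """

    sensors: tuple[SensorSpec, ...]
    inlet_sensor_id: int = 1
    outlet_sensor_id: int = 3
    sampling_rate_hz: float = 15.0

    def __post_init__(self) -> None:
        ids = [s.sensor_id for s in self.sensors]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate sensor ids: {ids}")
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be > 0")
        for ref in (self.inlet_sensor_id, self.outlet_sensor_id):
            if ref not in ids:
                raise ConfigurationError(f"inlet/outlet sensor id {ref} not in array")

    @property
    def sensor_ids(self) -> tuple[int, ...]:
        return tuple(s.sensor_id for s in self.sensors)

    def sensor(self, sensor_id: int) -> SensorSpec:
        for s in self.sensors:
            if s.sensor_id == sensor_id:
                return s
        raise KeyError(f"no sensor with id {sensor_id}")


@dataclass(frozen=True)
class CycleConfig:
    """Durations of the three sampling phases plus pump and feature choices.

    Durations are whole seconds, matching the firmware's command protocol
    (three digits per phase).
    """

    baseline_purge_s: int
    sampling_s: int
    purge_s: int
    pump_speed: PumpSpeed = PumpSpeed.HIGH
    feature_selection: FeatureSelection = FeatureSelection.ALL

    def __post_init__(self) -> None:
        for name in ("baseline_purge_s", "sampling_s", "purge_s"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.sampling_s < 1:
            raise ConfigurationError("sampling_s must be >= 1")

    @property
    def total_duration_s(self) -> int:
        return self.baseline_purge_s + self.sampling_s + self.purge_s


def _load_sensor_table() -> tuple[SensorSpec, ...]:
    text = resources.files("enose.data").joinpath("sensors.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    sensors = []
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        sensors.append(
            SensorSpec(
                sensor_id=int(row["sensor_id"]),
                name=row["name"],
                oxide=Oxide(row["oxide"]),
                specificity=row["specificity"],
                lower_detection_limit_ppm=float(row["lower_detection_limit_ppm"]),
            )
        )
    return tuple(sensors)


def default_array() -> ArraySpec:
    """The seven-sensor array as built, in datasheet order.

    SB-AQ8's printed detection limit is a range (0.1–1 ppm); the
    conservative upper bound 1.0 ppm is stored.
    """
    return ArraySpec(sensors=_load_sensor_table())


def characterization_config() -> CycleConfig:
    """The cycle used for chemical characterization experiments.

    100 s baseline purge, 35 s sampling, 100 s purge, high pump speed,
    all three features extracted.
    """
    return CycleConfig(
        baseline_purge_s=100,
        sampling_s=35,
        purge_s=100,
        pump_speed=PumpSpeed.HIGH,
        feature_selection=FeatureSelection.ALL,
    )


def adc_counts(volts: np.ndarray | float) -> np.ndarray | int:
    """Quantize a voltage signal to 10-bit A/D counts (0-1023)."""
    counts = np.rint(np.clip(np.asarray(volts, dtype=float), 0.0, VOLT_MAX) / VOLT_MAX * ADC_MAX)
    counts = counts.astype(int)
    return int(counts) if counts.ndim == 0 else counts


def adc_volts(counts: np.ndarray | int) -> np.ndarray | float:
    """Convert 10-bit A/D counts back to volts."""
    v = np.asarray(counts, dtype=float) / ADC_MAX * VOLT_MAX
    return float(v) if v.ndim == 0 else v


# -- plain-text configuration file ------------------------------------------

_CYCLE_SECTION = "cycle"


def write_cycle_config(config: CycleConfig, path: str | Path) -> None:
    """Write a cycle configuration as a plain-text key=value file."""
    cp = configparser.ConfigParser()
    cp[_CYCLE_SECTION] = {
        "baseline_purge_s": str(config.baseline_purge_s),
        "sampling_s": str(config.sampling_s),
        "purge_s": str(config.purge_s),
        "pump_speed": config.pump_speed.name,
        "feature_selection": config.feature_selection.name,
    }
    with open(path, "w") as fh:
        cp.write(fh)


def read_cycle_config(path: str | Path) -> CycleConfig:
    """Read a cycle configuration written by :func:`write_cycle_config`."""
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise ConfigurationError(f"cannot read config file {path}")
    try:
        sec = cp[_CYCLE_SECTION]
        return CycleConfig(
            baseline_purge_s=int(sec["baseline_purge_s"]),
            sampling_s=int(sec["sampling_s"]),
            purge_s=int(sec["purge_s"]),
            pump_speed=PumpSpeed[sec.get("pump_speed", "HIGH")],
            feature_selection=FeatureSelection[sec.get("feature_selection", "ALL")],
        )
    except KeyError as exc:
        raise ConfigurationError(f"malformed config file {path}: missing {exc}") from exc
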