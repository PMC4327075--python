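"""Firmware emulation: command protocol, record codec, store, state machine.

The original instrument was driven by 12-digit numeric command strings and
stored results in a 1024 Kbit serial EEPROM as fixed 24-byte records, for a
capacity of 5461 records.  This module emulates that layer:

* 12-digit command layout (digit positions, 1-based):
  1-3 baseline purge (s), 4-6 sampling (s), 7-9 purge (s),
  10 pump speed (0=LOW, 1=HIGH), 11 feature code (1-4),
  12 command type (1=record, 2=download, 3=erase, 4=autorun,
  5=forced sampling, 6=forced purging);
* 24-byte record layout (little-endian):
  serial (uint16) + timestamp (6 bytes: year-2000, month, day, hour,
  minute, second) + feature code (1 byte) + 7 scaled uint16 feature values
  (14 bytes) + additive checksum (1 byte).  When all three features are
  selected, one record per feature is written per measurement (21 raw
  floats cannot fit in 24 bytes);
* feature quantization to uint16 with fixed full-scale ranges
  (area: 0-5*sampling_s V*s, slope: 0-5 V/s, relative response: 0-50);
* an append-only :class:`RecordStore` with the EEPROM's capacity arithmetic
  and save/load to a binary file of concatenated records;
* a :class:`SamplingController` running the three-phase cycle state
  machine (baseline purge -> sampling -> purge), with forced-sampling and
  forced-purging as the only legal phase overrides.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from datetime import datetime, timedelta
from enum import Enum, IntEnum
from pathlib import Path
from typing import Sequence

from .device import (
    ArraySpec,
    ConfigurationError,
    CycleConfig,
    FeatureSelection,
    PumpSpeed,
    default_array,
)
from .features import FeatureVector, featurize
from .simulator import GasSample, ResponseCurve, SensorGasModel, simulate_measurement

__all__ = [
    "CommandType",
    "ProtocolError",
    "EncodingError",
    "DecodingError",
    "CapacityError",
    "MeasurementRecord",
    "RecordStore",
    "Phase",
    "SamplingController",
    "parse_command",
    "encode_command",
    "encode_record",
    "decode_record",
    "store_capacity",
    "scale_feature",
    "unscale_feature",
    "feature_range",
]

RECORD_BYTES = 24
DEFAULT_CAPACITY_BITS = 1024 * 1024  # 1024 Kbit EEPROM
_STRUCT = struct.Struct("<H6BB7HB")
assert _STRUCT.size == RECORD_BYTES

_EPOCH_YEAR = 2000  # timestamp year stored as offset from 2000 in one byte


class ProtocolError(ValueError):
    """Malformed 12-digit command string."""


class EncodingError(ValueError):
    """A record cannot be encoded (value out of range)."""


class DecodingError(ValueError):
    """A byte string is not a valid 24-byte record."""


class CapacityError(RuntimeError):
    """The record store is full."""


class CommandType(IntEnum):
    RECORD = 1
    DOWNLOAD = 2
    ERASE = 3
    AUTORUN = 4
    FORCED_SAMPLING = 5
    FORCED_PURGING = 6


# -- 12-digit command protocol ----------------------------------------------

def encode_command(cycle: CycleConfig, command: CommandType) -> str:
    """Encode a cycle configuration + command type as 12 digits."""
    for name in ("baseline_purge_s", "sampling_s", "purge_s"):
        v = getattr(cycle, name)
        if v > 999:
            raise ProtocolError(f"{name}={v} does not fit in three digits")
    return (
        f"{cycle.baseline_purge_s:03d}{cycle.sampling_s:03d}{cycle.purge_s:03d}"
        f"{int(cycle.pump_speed)}{int(cycle.feature_selection)}{int(command)}"
    )


def parse_command(digits: str) -> tuple[CycleConfig, CommandType]:
    """Decode a 12-digit command string; inverse of :func:`encode_command`."""
    if len(digits) != 12:
        raise ProtocolError(f"command must be 12 digits, got {len(digits)}")
    if not digits.isdigit():
        raise ProtocolError(f"command must be decimal digits, got {digits!r}")
    pump = int(digits[9])
    if pump not in (0, 1):
        raise ProtocolError(f"pump-speed digit must be 0 or 1, got {pump}")
    feat = int(digits[10])
    if feat not in (1, 2, 3, 4):
        raise ProtocolError(f"feature code must be 1-4, got {feat}")
    ctype = int(digits[11])
    try:
        command = CommandType(ctype)
    except ValueError:
        raise ProtocolError(f"unknown command type digit {ctype}") from None
    try:
        cycle = CycleConfig(
            baseline_purge_s=int(digits[0:3]),
            sampling_s=int(digits[3:6]),
            purge_s=int(digits[6:9]),
            pump_speed=PumpSpeed(pump),
            feature_selection=FeatureSelection(feat),
        )
    except ConfigurationError as exc:
        raise ProtocolError(str(exc)) from exc
    return cycle, command


# -- feature quantization ----------------------------------------------------

def feature_range(feature: FeatureSelection, sampling_s: int) -> float:
    """Full-scale raw value mapped to uint16 65535 for one feature."""
    if feature == FeatureSelection.AREA:
        return 5.0 * sampling_s  # V*s at full-scale 5 V for the whole phase
    if feature == FeatureSelection.SLOPE:
        return 5.0  # V/s
    if feature == FeatureSelection.RELATIVE:
        return 50.0  # dimensionless
    raise ValueError(f"no scalar range for feature {feature!r}")


def scale_feature(raw: float, feature: FeatureSelection, sampling_s: int) -> int:
    """Quantize a raw feature value to a stored uint16."""
    full = feature_range(feature, sampling_s)
    if not (0.0 <= raw <= full):
        raise EncodingError(f"{feature.name} value {raw} outside [0, {full}]")
    return round(raw / full * 65535)


def unscale_feature(stored: int, feature: FeatureSelection, sampling_s: int) -> float:
    """Invert :func:`scale_feature` (up to quantization)."""
    return stored / 65535 * feature_range(feature, sampling_s)


# -- 24-byte record codec ----------------------------------------------------

@dataclass(frozen=True)
class MeasurementRecord:
    """One stored dataset: serial, 1 s timestamp, one feature x 7 sensors.

    ``feature_values`` are the quantized uint16 values in sensor order.
    ``feature_code`` is AREA, RELATIVE or SLOPE — a measurement taken with
    the ALL selection is stored as three records, one per feature.
    """

    serial: int
    timestamp: datetime
    feature_code: FeatureSelection
    feature_values: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.serial <= 0xFFFF):
            raise EncodingError(f"serial {self.serial} outside uint16 range")
        if self.feature_code == FeatureSelection.ALL:
            raise EncodingError("a stored record holds exactly one feature, not ALL")
        if len(self.feature_values) != 7:
            raise EncodingError(f"expected 7 feature values, got {len(self.feature_values)}")
        for v in self.feature_values:
            if not (0 <= v <= 0xFFFF):
                raise EncodingError(f"feature value {v} outside uint16 range")
        if not (_EPOCH_YEAR <= self.timestamp.year < _EPOCH_YEAR + 256):
            raise EncodingError(f"timestamp year {self.timestamp.year} not storable")
        if self.timestamp.microsecond:
            raise EncodingError("timestamps have 1 s resolution")


def encode_record(record: MeasurementRecord) -> bytes:
    """Serialize a record to exactly 24 bytes (little-endian, checksummed)."""
    ts = record.timestamp
    body = _STRUCT.pack(
        record.serial,
        ts.year - _EPOCH_YEAR, ts.month, ts.day, ts.hour, ts.minute, ts.second,
        int(record.feature_code),
        *record.feature_values,
        0,
    )[:-1]
    checksum = sum(body) % 256
    return body + bytes([checksum])


def decode_record(data: bytes) -> MeasurementRecord:
    """Inverse of :func:`encode_record`; validates length and checksum."""
    if len(data) != RECORD_BYTES:
        raise DecodingError(f"record must be {RECORD_BYTES} bytes, got {len(data)}")
    if sum(data[:-1]) % 256 != data[-1]:
        raise DecodingError("record checksum mismatch")
    serial, yr, mo, dy, hh, mm, ss, feat, *values, _ = _STRUCT.unpack(data)
    try:
        ts = datetime(_EPOCH_YEAR + yr, mo, dy, hh, mm, ss)
    except ValueError as exc:
        raise DecodingError(f"invalid timestamp fields: {exc}") from exc
    try:
        code = FeatureSelection(feat)
    except ValueError:
        raise DecodingError(f"invalid feature code {feat}") from None
    return MeasurementRecord(serial, ts, code, tuple(values))


def store_capacity(capacity_bits: int, record_bytes: int = RECORD_BYTES) -> int:
    """How many fixed-size records fit in a memory of ``capacity_bits``."""
    if capacity_bits <= 0 or record_bytes <= 0:
        raise ValueError("capacity_bits and record_bytes must be positive")
    return capacity_bits // 8 // record_bytes


# -- record store ------------------------------------------------------------

class RecordStore:
    """Append-only record memory with the EEPROM's capacity limit.

    ``download`` returns a copy (the memory is read-only from the PC side);
    ``erase`` empties it; ``save``/``load`` round-trip the store through a
    binary file of concatenated 24-byte records, emulating non-volatility.
    """

    def __init__(self, capacity_bits: int = DEFAULT_CAPACITY_BITS) -> None:
        self.capacity_bits = capacity_bits
        self._records: list[MeasurementRecord] = []

    @property
    def capacity(self) -> int:
        return store_capacity(self.capacity_bits, RECORD_BYTES)

    def __len__(self) -> int:
        return len(self._records)

    @property
    def next_serial(self) -> int:
        return self._records[-1].serial + 1 if self._records else 0

    def append(self, record: MeasurementRecord) -> None:
        self.extend([record])

    def extend(self, records: Sequence[MeasurementRecord]) -> None:
        """Append all records or none (capacity checked up front)."""
        if len(self._records) + len(records) > self.capacity:
            raise CapacityError(
                f"store holds {len(self._records)}/{self.capacity} records; "
                f"cannot append {len(records)} more"
            )
        self._records.extend(records)

    def download(self) -> list[MeasurementRecord]:
        return list(self._records)

    def erase(self) -> None:
        self._records.clear()

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            for rec in self._records:
                fh.write(encode_record(rec))

    @classmethod
    def load(cls, path: str | Path, capacity_bits: int = DEFAULT_CAPACITY_BITS) -> "RecordStore":
        store = cls(capacity_bits)
        data = Path(path).read_bytes()
        if len(data) % RECORD_BYTES:
            raise DecodingError(
                f"store file length {len(data)} is not a multiple of {RECORD_BYTES}"
            )
        store.extend(
            [decode_record(data[i : i + RECORD_BYTES]) for i in range(0, len(data), RECORD_BYTES)]
        )
        return store


# -- sampling state machine --------------------------------------------------

class Phase(Enum):
    IDLE = "idle"
    BASELINE_PURGE = "baseline_purge"
    SAMPLING = "sampling"
    PURGE = "purge"


_STORED_FEATURES = (FeatureSelection.AREA, FeatureSelection.RELATIVE, FeatureSelection.SLOPE)


def _records_for_measurement(
    fv: FeatureVector,
    cycle: CycleConfig,
    first_serial: int,
    timestamp: datetime,
) -> list[MeasurementRecord]:
    codes = (
        _STORED_FEATURES
        if cycle.feature_selection == FeatureSelection.ALL
        else (cycle.feature_selection,)
    )
    name = {FeatureSelection.AREA: "area", FeatureSelection.RELATIVE: "relative",
            FeatureSelection.SLOPE: "slope"}
    records = []
    for k, code in enumerate(codes):
        raw = fv.values(name[code])
        values = tuple(scale_feature(v, code, cycle.sampling_s) for v in raw)
        records.append(MeasurementRecord(first_serial + k, timestamp, code, values))
    return records


class SamplingController:
    """The measurement state machine over a simulated gas inlet.

    A normal recording cycle always runs baseline purge -> sampling ->
    purge; the only way to enter a phase out of order is an explicit
    forced-sampling or forced-purging command.  Phase transitions are
    logged in ``phase_log`` as (phase, duration_s) pairs.
    """

    def __init__(
        self,
        array: ArraySpec | None = None,
        model: SensorGasModel | None = None,
        store: RecordStore | None = None,
        clock_start: datetime = datetime(2015, 1, 1, 0, 0, 0),
    ) -> None:
        self.array = array or default_array()
        self.model = model
        self.store = store if store is not None else RecordStore()
        self.phase = Phase.IDLE
        self.phase_log: list[tuple[Phase, float]] = []
        self.clock = clock_start
        self._stream = 0

    def _enter(self, phase: Phase, duration_s: float) -> None:
        self.phase = phase
        self.phase_log.append((phase, duration_s))
        self.clock += timedelta(seconds=duration_s)

    def run_cycle(
        self,
        gas: GasSample,
        cycle: CycleConfig,
        seed: int,
    ) -> tuple[list[ResponseCurve], FeatureVector]:
        """Run one full recording cycle and append its record(s) to the store.

        The store is left unchanged if it cannot hold the measurement.
        """
        if self.model is None:
            raise ConfigurationError("controller has no sensor-gas model attached")
        timestamp = self.clock.replace(microsecond=0)
        curves = simulate_measurement(
            self.array, gas, self.model, cycle, seed, stream=self._stream
        )
        self._stream += 1
        # firmware path: raw signals, 1 s integration grid
        fv = featurize(curves, cycle, correct_baseline=False, dt_s=1.0)
        records = _records_for_measurement(fv, cycle, self.store.next_serial, timestamp)
        self.store.extend(records)  # atomic: raises CapacityError before any append
        self._enter(Phase.BASELINE_PURGE, cycle.baseline_purge_s)
        self._enter(Phase.SAMPLING, cycle.sampling_s)
        self._enter(Phase.PURGE, cycle.purge_s)
        self.phase = Phase.IDLE
        return curves, fv

    def autorun(
        self, gas: GasSample, cycle: CycleConfig, cycles: int, seed: int
    ) -> list[FeatureVector]:
        """Repeat ``cycles`` recording cycles with the stored configuration."""
        if cycles < 1:
            raise ConfigurationError("cycles must be >= 1")
        return [self.run_cycle(gas, cycle, seed)[1] for _ in range(cycles)]

    def force_sampling(self, duration_s: float) -> None:
        """Phase override: jump straight to the sampling phase."""
        self._enter(Phase.SAMPLING, duration_s)

    def force_purging(self, duration_s: float) -> None:
        """Phase override: jump straight to the purge phase."""
        self._enter(Phase.PURGE, duration_s)

    def execute(
        self,
        digits: str,
        gas: GasSample | None = None,
        seed: int = 0,
    ):
        """Dispatch a 12-digit command string, as the firmware would.

        RECORD and AUTORUN need a ``gas`` at the inlet; DOWNLOAD returns the
        stored records; ERASE clears the store; the forced commands override
        the phase for the corresponding configured duration.
        """
        cycle, command = parse_command(digits)
        if command in (CommandType.RECORD, CommandType.AUTORUN):
            if gas is None:
                raise ConfigurationError(f"{command.name} requires a gas sample")
            return self.run_cycle(gas, cycle, seed)
        if command == CommandType.DOWNLOAD:
            return self.store.download()
        if command == CommandType.ERASE:
            self.store.erase()
            return None
        if command == CommandType.FORCED_SAMPLING:
            self.force_sampling(cycle.sampling_s)
            return None
        if command == CommandType.FORCED_PURGING:
            self.force_purging(cycle.purge_s)
            return None
        raise ProtocolError(f"unhandled command {command}")
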