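"""The instrument's plain-text download log.

One tab-delimited line per measurement: serial number, timestamp, then a
sensor-major (area, slope, relative response) triple per sensor.  A single
header line documents the columns.  Values are written with 6 significant
digits; a stored record that did not include a feature is written as nan.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np

from .device import CycleConfig, FeatureSelection
from .controller import MeasurementRecord, unscale_feature

__all__ = ["LogRecord", "LogParseError", "write_log", "read_log", "records_to_log_records"]

_TS_FORMAT = "%Y-%m-%d %H:%M:%S"
_FEATURES = ("area", "slope", "relative")


class LogParseError(ValueError):
    """A malformed log line; the message names the 1-based line number."""


@dataclass(frozen=True)
class LogRecord:
    """One log line: serial, timestamp, per-sensor feature triples.

    ``features[k]`` is the (area, slope, relative) triple of the k-th
    sensor, in the order of ``sensor_ids``.
    """

    serial: int
    timestamp: datetime
    sensor_ids: tuple[int, ...]
    features: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.features) != len(self.sensor_ids):
            raise ValueError("one feature triple required per sensor")


def _header(sensor_ids: Sequence[int]) -> str:
    cols = ["serial", "timestamp"]
    for sid in sensor_ids:
        cols.extend(f"s{sid}_{f}" for f in _FEATURES)
    return "\t".join(cols)


def write_log(records: Sequence[LogRecord], sensor_ids: Sequence[int] | None = None) -> str:
    """Format log records as tab-delimited text (header + one line each)."""
    if sensor_ids is None:
        if not records:
            raise ValueError("sensor_ids required for an empty record list")
        sensor_ids = records[0].sensor_ids
    lines = [_header(sensor_ids)]
    for rec in records:
        if tuple(rec.sensor_ids) != tuple(sensor_ids):
            raise ValueError("inconsistent sensor ids across records")
        fields = [str(rec.serial), rec.timestamp.strftime(_TS_FORMAT)]
        for triple in rec.features:
            fields.extend(f"{v:.6g}" for v in triple)
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def read_log(text: str) -> list[LogRecord]:
    """Parse log text back into records; inverse of :func:`write_log`."""
    lines = text.splitlines()
    if not lines:
        raise LogParseError("line 1: empty log (missing header)")
    header = lines[0].split("\t")
    if header[:2] != ["serial", "timestamp"] or (len(header) - 2) % 3:
        raise LogParseError("line 1: malformed header")
    sensor_ids = []
    for k in range(2, len(header), 3):
        col = header[k]
        if not (col.startswith("s") and col.endswith("_area")):
            raise LogParseError(f"line 1: unexpected column {col!r}")
        sensor_ids.append(int(col[1:-5]))
    n_sensors = len(sensor_ids)
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2 + 3 * n_sensors:
            raise LogParseError(
                f"line {lineno}: expected {2 + 3 * n_sensors} fields, got {len(fields)}"
            )
        try:
            serial = int(fields[0])
            ts = datetime.strptime(fields[1], _TS_FORMAT)
            triples = tuple(
                (float(fields[2 + 3 * k]), float(fields[3 + 3 * k]), float(fields[4 + 3 * k]))
                for k in range(n_sensors)
            )
        except ValueError as exc:
            raise LogParseError(f"line {lineno}: {exc}") from exc
        records.append(
            LogRecord(serial=serial, timestamp=ts, sensor_ids=tuple(sensor_ids), features=triples)
        )
    return records


def records_to_log_records(
    records: Sequence[MeasurementRecord],
    cycle: CycleConfig,
    sensor_ids: Sequence[int],
) -> list[LogRecord]:
    """Convert stored 24-byte records to log lines ("download").

    Records sharing a timestamp (the per-feature records of one ALL-mode
    measurement) merge into one line; features never stored become nan.
    The merged line carries the smallest serial of its group.
    """
    groups: dict[datetime, dict] = {}
    order: list[datetime] = []
    for rec in records:
        if rec.timestamp not in groups:
            groups[rec.timestamp] = {"serial": rec.serial, "features": {}}
            order.append(rec.timestamp)
        g = groups[rec.timestamp]
        g["serial"] = min(g["serial"], rec.serial)
        g["features"][rec.feature_code] = [
            unscale_feature(v, rec.feature_code, cycle.sampling_s) for v in rec.feature_values
        ]
    out = []
    code_of = {"area": FeatureSelection.AREA, "slope": FeatureSelection.SLOPE,
               "relative": FeatureSelection.RELATIVE}
    for ts in order:
        g = groups[ts]
        triples = []
        for k in range(len(sensor_ids)):
            triples.append(tuple(
                g["features"].get(code_of[f], [np.nan] * len(sensor_ids))[k]
                for f in _FEATURES
            ))
        out.append(LogRecord(serial=g["serial"], timestamp=ts,
                             sensor_ids=tuple(sensor_ids), features=tuple(triples)))
    return out


def write_log_file(path: str | Path, records: Sequence[LogRecord],
                   sensor_ids: Sequence[int] | None = None) -> None:
    Path(path).write_text(write_log(records, sensor_ids))


def read_log_file(path: str | Path) -> list[LogRecord]:
    return read_log(Path(path).read_text())
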