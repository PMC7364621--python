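"""Run-directory ingestion: naming-convention validation, line cleaning,
and parsing of sensor/GPS/IMU streams into typed record tables.

A run directory holds one key = value metadata file
``<runid>_sensorrun.txt`` and one delimited log per sensor channel named
``<runid>_<sensortype>_<sensorid>.csv``.  Cleaning rejects lines that
contain bytes outside printable ASCII (+tab) or that split into fewer
comma-delimited fields than the sensor type requires; raw files are
never modified -- cleaned copies go to a ``clean/`` subfolder so that
bad characters and incomplete lines never reach the database.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import nmea

SENSOR_TYPES = ("ultrasonic", "irt", "reflectance", "gps", "imu")

# minimum comma-delimited fields per line, by sensor type
EXPECTED_FIELDS = {
    "ultrasonic": 2,   # timestamp, displacement d (m)
    "irt": 3,          # timestamp, canopy C, body C
    "reflectance": 4,  # timestamp, rho_nir, rho_vis, rho_re
    "gps": 2,          # timestamp, NMEA sentence (itself comma-laden)
    "imu": 4,          # timestamp, yaw, pitch, roll
}

_FILE_RE = re.compile(r"^(?P<runid>.+)_(?P<stype>[a-z]+)_(?P<sid>[A-Za-z0-9]+)\.csv$")
_PRINTABLE = frozenset(chr(c) for c in range(0x20, 0x7F)) | {"\t"}


class IngestError(ValueError):
    """Fatal run-directory problem (missing metadata, unknown files)."""


@dataclass(frozen=True)
class SensorOffset:
    """Mount offsets from the GPS antenna, metres (forward +ahead,
    lateral +right of travel)."""

    forward_m: float
    lateral_m: float

    def __post_init__(self):
        if not (np.isfinite(self.forward_m) and np.isfinite(self.lateral_m)):
            raise IngestError("sensor offset must be finite")
        if abs(self.forward_m) >= 10 or abs(self.lateral_m) >= 10:
            raise IngestError("sensor offset fails sanity bound (|offset| < 10 m)")


@dataclass
class SensorInfo:
    sensor_id: str
    sensor_type: str
    boom_arm: str
    offset: SensorOffset


@dataclass
class RunMetadata:
    run_id: str
    date: str = ""
    time: str = ""
    field_id: str = ""
    operator: str = ""
    boom_height_s: float = float("nan")
    wheel_spacing: float = float("nan")
    sensors: list[SensorInfo] = field(default_factory=list)
    notes: str = ""
    extras: dict = field(default_factory=dict)

    def sensor(self, sensor_id: str) -> SensorInfo:
        for s in self.sensors:
            if s.sensor_id == sensor_id:
                return s
        raise KeyError(sensor_id)


@dataclass
class RawRun:
    """Parsed streams of one collection plus its per-file cleaning report."""

    metadata: RunMetadata
    records: dict[str, pd.DataFrame]  # sensor_type -> record table
    gps: pd.DataFrame                 # logger_time, lat, lon, quality, fix_time
    attitude: pd.DataFrame            # logger_time, yaw, pitch, roll
    cleaning: pd.DataFrame            # per file: lines read / rejected / parsed


def clean_lines(lines, expected_field_count: int):
    """Split a text stream into clean lines and a rejection report.

    A line is rejected iff it contains non-printable or non-ASCII
    characters, or splits into fewer than ``expected_field_count``
    comma-delimited fields.  Surviving lines keep their order; trailing
    whitespace is tolerated (stripped before the field count).
    """
    if expected_field_count < 1:
        raise ValueError("expected_field_count must be >= 1")
    clean: list[str] = []
    report = {"bad_chars": 0, "incomplete": 0}
    for line in lines:
        body = line.rstrip("\r\n")
        if not set(body) <= _PRINTABLE:
            report["bad_chars"] += 1
            continue
        if len(body.rstrip().split(",")) < expected_field_count or not body.strip():
            report["incomplete"] += 1
            continue
        clean.append(body)
    return clean, report


def parse_metadata(path: Path) -> RunMetadata:
    meta = RunMetadata(run_id="")
    numeric = {"boom_height_s", "wheel_spacing"}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "sensor":
            parts = [p.strip() for p in value.split(",")]
            if len(parts) != 5:
                raise IngestError(f"bad sensor inventory line: {raw!r}")
            sid, stype, arm, fo, lo = parts
            if any(s.sensor_id == sid for s in meta.sensors):
                raise IngestError(f"duplicate sensor id {sid!r} in metadata")
            meta.sensors.append(SensorInfo(sid, stype, arm,
                                           SensorOffset(float(fo), float(lo))))
        elif key in numeric:
            setattr(meta, key, float(value))
        elif hasattr(meta, key) and key not in ("sensors", "extras"):
            setattr(meta, key, value)
        else:
            meta.extras[key] = value
    if not meta.run_id:
        raise IngestError(f"metadata file {path} lacks run_id")
    if not meta.boom_height_s > 0:
        raise IngestError("boom_height_s must be > 0")
    return meta


def _parse_sensor_table(lines: list[str], sensor_type: str, sensor_id: str):
    cols = {
        "ultrasonic": ["displacement_m"],
        "irt": ["canopy_temp_c", "body_temp_c"],
        "reflectance": ["rho_nir", "rho_vis", "rho_re"],
        "imu": ["yaw", "pitch", "roll"],
    }[sensor_type]
    n_fields = len(cols) + 1
    ts, data, bad = [], [], 0
    for line in lines:
        parts = line.split(",")
        try:
            vals = [float(v) for v in parts[1:n_fields]]
            t = pd.Timestamp(parts[0])
        except (ValueError, TypeError):
            bad += 1
            continue
        ts.append(t)
        data.append(vals)
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "logger_time", pd.to_datetime(ts) if ts else pd.Series([], dtype="datetime64[ns]"))
    df.insert(1, "sensor_id", sensor_id)
    return df, bad


def parse_gps_lines(lines: list[str]):
    """Decode logger-stamped GGA/RMC pairs to fixes.

    The logger timestamp (first field) is the stream-alignment key; the
    GGA sentence supplies the position and the RMC sentence the date.
    Sentences failing the checksum reject the whole pair (counted).
    """
    fixes, rejected = [], 0  # rejected counts individual sentences
    pending: Optional[tuple[str, str]] = None  # (logger_ts, gga)
    for line in lines:
        ts, _, sentence = line.partition(",")
        sentence = sentence.strip()
        if "GGA" in sentence[:7]:
            if pending is not None:
                rejected += 1  # orphan GGA without its RMC
            pending = (ts, sentence)
            continue
        if "RMC" in sentence[:7]:
            if pending is None or pending[0] != ts:
                rejected += 1 + (pending is not None)
                pending = None
                continue
            try:
                fix = nmea.parse_nmea_pair(pending[1], sentence)
            except nmea.NmeaError:
                rejected += 2
                pending = None
                continue
            fixes.append((pd.Timestamp(ts), fix.lat, fix.lon, fix.quality,
                          pd.Timestamp(fix.timestamp)))
            pending = None
        else:
            rejected += 1
    if pending is not None:
        rejected += 1
    df = pd.DataFrame(fixes, columns=["logger_time", "lat", "lon", "quality", "fix_time"])
    return df, rejected


def parse_run_directory(path, write_clean: bool = True) -> RawRun:
    """Read, validate, clean, and parse one run directory.

    Raw files are untouched; cleaned copies are written to ``clean/``
    (unless ``write_clean`` is False).  Unknown file-name patterns are
    fatal and reported together.
    """
    path = Path(path)
    if not path.is_dir():
        raise IngestError(f"run directory {path} does not exist")
    meta_files = sorted(path.glob("*_sensorrun.txt"))
    if not meta_files:
        raise IngestError(
            f"no run-metadata file in {path}: expected <runid>_sensorrun.txt")
    if len(meta_files) > 1:
        raise IngestError(f"multiple metadata files in {path}: {meta_files}")
    metadata = parse_metadata(meta_files[0])
    run_id = metadata.run_id

    offenders = []
    log_files = []
    for p in sorted(path.iterdir()):
        if p.is_dir() and p.name == "clean":
            continue
        if p == meta_files[0]:
            continue
        m = _FILE_RE.match(p.name)
        if not m or m.group("runid") != run_id or m.group("stype") not in SENSOR_TYPES:
            offenders.append(p.name)
            continue
        log_files.append((p, m.group("stype"), m.group("sid")))
    if offenders:
        raise IngestError(
            f"files violating the naming convention "
            f"<runid>_<sensortype>_<sensorid>.csv: {offenders}")
    if not log_files:
        raise IngestError(f"run directory {path} contains no sensor logs")

    clean_dir = path / "clean"
    if write_clean:
        clean_dir.mkdir(exist_ok=True)

    records: dict[str, list[pd.DataFrame]] = {}
    gps_frames, att_frames, cleaning_rows = [], [], []
    for p, stype, sid in log_files:
        raw_lines = p.read_text(errors="surrogateescape").splitlines()
        clean, report = clean_lines(raw_lines, EXPECTED_FIELDS[stype])
        if write_clean:
            (clean_dir / p.name).write_text(
                "\n".join(clean) + ("\n" if clean else ""))
        if stype == "gps":
            df, bad = parse_gps_lines(clean)
            gps_frames.append(df)
        elif stype == "imu":
            df, bad = _parse_sensor_table(clean, stype, sid)
            att_frames.append(df.drop(columns=["sensor_id"]))
        else:
            df, bad = _parse_sensor_table(clean, stype, sid)
            records.setdefault(stype, []).append(df)
        n_parsed = (len(df) * 2 if stype == "gps" else len(df))
        cleaning_rows.append({
            "file": p.name, "sensor_type": stype, "sensor_id": sid,
            "lines_read": len(raw_lines),
            "rejected_bad_chars": report["bad_chars"],
            "rejected_incomplete": report["incomplete"],
            "rejected_unparseable": bad,
            "records_parsed": n_parsed,
        })

    gps = pd.concat(gps_frames, ignore_index=True) if gps_frames else \
        pd.DataFrame(columns=["logger_time", "lat", "lon", "quality", "fix_time"])
    attitude = pd.concat(att_frames, ignore_index=True) if att_frames else \
        pd.DataFrame(columns=["logger_time", "yaw", "pitch", "roll"])
    rec = {k: pd.concat(v, ignore_index=True) for k, v in records.items()}
    cleaning = pd.DataFrame(cleaning_rows)
    return RawRun(metadata, rec, gps, attitude, cleaning)
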