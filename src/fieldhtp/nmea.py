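"""Minimal NMEA 0183 codec for the GGA/RMC sentence pairs logged by the
data-acquisition loop.

Only the fields the pipeline consumes are modelled: position and fix
quality from GGA, date (and sanity status) from RMC.  Coordinates use
the NMEA ``ddmm.mmmmmm`` / ``dddmm.mmmmmm`` convention; west and south
are negative after decoding.  Every sentence carries the standard XOR
checksum and sentences failing it are rejected (counted, never fatal).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone


class NmeaError(ValueError):
    """A sentence that cannot be decoded (bad checksum, bad field)."""


@dataclass(frozen=True)
class GpsFix:
    """One decoded GGA/RMC pair."""

    timestamp: datetime  # RMC date + GGA time (UTC)
    lat: float  # decimal degrees, +N
    lon: float  # decimal degrees, +E (west negative)
    quality: int  # GGA fix-quality code (4 = RTK fixed)


def checksum(body: str) -> str:
    """XOR of all characters between '$' and '*', as two hex digits."""
    c = 0
    for ch in body:
        c ^= ord(ch)
    return f"{c:02X}"


def _wrap(body: str) -> str:
    return f"${body}*{checksum(body)}"


def _encode_coord(value: float, is_lat: bool) -> tuple[str, str]:
    hemi = ("N" if value >= 0 else "S") if is_lat else ("E" if value >= 0 else "W")
    v = abs(value)
    deg = int(v)
    minutes = (v - deg) * 60.0
    if minutes >= 59.9999995:  # avoid 60.000000 after rounding
        deg += 1
        minutes = 0.0
    width = 2 if is_lat else 3
    return f"{deg:0{width}d}{minutes:09.6f}", hemi


def _decode_coord(field: str, hemi: str) -> float:
    if not field:
        raise NmeaError("empty coordinate field")
    try:
        dm = float(field)
    except ValueError as exc:
        raise NmeaError(f"unparseable coordinate {field!r}") from exc
    deg = int(dm // 100)
    minutes = dm - 100.0 * deg
    if minutes >= 60.0:
        raise NmeaError(f"minutes out of range in {field!r}")
    val = deg + minutes / 60.0
    if hemi in ("S", "W"):
        val = -val
    elif hemi not in ("N", "E"):
        raise NmeaError(f"bad hemisphere {hemi!r}")
    return val


def encode_gga(t: datetime, lat: float, lon: float, quality: int = 4,
               n_sat: int = 12, hdop: float = 0.8, alt_m: float = 361.0) -> str:
    lat_f, lat_h = _encode_coord(lat, True)
    lon_f, lon_h = _encode_coord(lon, False)
    body = (
        f"GPGGA,{t:%H%M%S}.{t.microsecond // 10000:02d},{lat_f},{lat_h},"
        f"{lon_f},{lon_h},{quality},{n_sat:02d},{hdop:.1f},{alt_m:.1f},M,0.0,M,,"
    )
    return _wrap(body)


def encode_rmc(t: datetime, lat: float, lon: float,
               speed_knots: float = 1.3, course: float = 0.0) -> str:
    lat_f, lat_h = _encode_coord(lat, True)
    lon_f, lon_h = _encode_coord(lon, False)
    body = (
        f"GPRMC,{t:%H%M%S}.{t.microsecond // 10000:02d},A,{lat_f},{lat_h},"
        f"{lon_f},{lon_h},{speed_knots:.2f},{course:.1f},{t:%d%m%y},,,A"
    )
    return _wrap(body)


def split_sentence(line: str) -> list[str]:
    """Checksum-validate a sentence and return its comma-split fields."""
    line = line.strip()
    if not line.startswith("$") or "*" not in line:
        raise NmeaError("not an NMEA sentence")
    body, _, cs = line[1:].rpartition("*")
    if checksum(body) != cs.strip().upper():
        raise NmeaError("checksum mismatch")
    return body.split(",")


def parse_nmea_pair(gga: str, rmc: str) -> GpsFix:
    """Decode a GGA/RMC pair into one fix.

    Position and fix quality come from GGA; the calendar date comes from
    RMC (GGA carries time-of-day only).
    """
    g = split_sentence(gga)
    r = split_sentence(rmc)
    if not g[0].endswith("GGA") or not r[0].endswith("RMC"):
        raise NmeaError(f"expected GGA+RMC, got {g[0]}/{r[0]}")
    lat = _decode_coord(g[2], g[3])
    lon = _decode_coord(g[4], g[5])
    if abs(lat) > 90.0 or abs(lon) > 180.0:
        raise NmeaError("coordinate out of range")
    try:
        quality = int(g[6])
    except ValueError as exc:
        raise NmeaError("bad fix quality") from exc
    time_str = g[1]
    date_str = r[9]
    try:
        hh, mm = int(time_str[0:2]), int(time_str[2:4])
        ss = float(time_str[4:])
        day, mon = int(date_str[0:2]), int(date_str[2:4])
        year = 2000 + int(date_str[4:6])
        ts = datetime(year, mon, day, hh, mm, int(ss),
                      int(round((ss % 1.0) * 1e6)), tzinfo=timezone.utc)
    except (ValueError, IndexError) as exc:
        raise NmeaError("bad time/date fields") from exc
    return GpsFix(ts, lat, lon, quality)
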