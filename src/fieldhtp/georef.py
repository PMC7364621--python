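"""Georeferencing: UTM projection and sensor-offset geometry.

Vehicle GPS fixes (WGS84 latitude/longitude) are projected to the
Universal Transverse Mercator grid so that all downstream geometry is
planar and metric.  The ground position of each boom-mounted sensor is
then obtained from the vehicle position, the IMU heading, and the
sensor's measured forward/lateral offsets from the GPS antenna.

The projection is the standard transverse Mercator mapping with UTM
constants (central scale 0.9996, false easting 500 000 m), implemented
with Karney's 6th-order Krueger series, which is accurate to well below
a millimetre anywhere inside a UTM zone.

Conventions
-----------
* Yaw is the vehicle heading in degrees clockwise from true north.
* A sensor's ``forward_m`` offset is positive ahead of the GPS antenna
  along the heading; ``lateral_m`` is positive to the *right* of travel.
* Pitch and roll are carried through for quality-control filtering only;
  no lever-arm tilt correction is applied to ground positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

# WGS84 ellipsoid
WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563

UTM_K0 = 0.9996
UTM_FALSE_EASTING = 500_000.0
UTM_FALSE_NORTHING_SOUTH = 10_000_000.0

_N3 = WGS84_F / (2.0 - WGS84_F)  # third flattening n
_E1 = math.sqrt(WGS84_F * (2.0 - WGS84_F))  # first eccentricity e

# Rectifying radius A = a/(1+n) (1 + n^2/4 + n^4/64 + n^6/256)
_RECT_A = WGS84_A / (1.0 + _N3) * (
    1.0 + _N3**2 / 4.0 + _N3**4 / 64.0 + _N3**6 / 256.0
)

_n = _N3
_ALPHA = (
    _n / 2 - 2 * _n**2 / 3 + 5 * _n**3 / 16 + 41 * _n**4 / 180
    - 127 * _n**5 / 288 + 7891 * _n**6 / 37800,
    13 * _n**2 / 48 - 3 * _n**3 / 5 + 557 * _n**4 / 1440
    + 281 * _n**5 / 630 - 1983433 * _n**6 / 1935360,
    61 * _n**3 / 240 - 103 * _n**4 / 140 + 15061 * _n**5 / 26880
    + 167603 * _n**6 / 181440,
    49561 * _n**4 / 161280 - 179 * _n**5 / 168 + 6601661 * _n**6 / 7257600,
    34729 * _n**5 / 80640 - 3418889 * _n**6 / 1995840,
    212378941 * _n**6 / 319334400,
)
_BETA = (
    _n / 2 - 2 * _n**2 / 3 + 37 * _n**3 / 96 - _n**4 / 360
    - 81 * _n**5 / 512 + 96199 * _n**6 / 604800,
    _n**2 / 48 + _n**3 / 15 - 437 * _n**4 / 1440 + 46 * _n**5 / 105
    - 1118711 * _n**6 / 3870720,
    17 * _n**3 / 480 - 37 * _n**4 / 840 - 209 * _n**5 / 4480
    + 5569 * _n**6 / 90720,
    4397 * _n**4 / 161280 - 11 * _n**5 / 504 - 830251 * _n**6 / 7257600,
    4583 * _n**5 / 161280 - 108847 * _n**6 / 3991680,
    20648693 * _n**6 / 638668800,
)
del _n


class ProjectionError(ValueError):
    """Raised for coordinates outside the UTM domain (|lat| > 84 deg)."""


@dataclass(frozen=True)
class UtmPoint:
    """A planar UTM position in metres."""

    easting: float
    northing: float
    zone: int
    hemisphere: str  # "N" or "S"


def utm_zone(lon: float) -> int:
    """UTM zone number for a longitude: floor((lon + 180)/6) + 1, in 1..60."""
    z = int(math.floor((lon + 180.0) / 6.0)) + 1
    return min(max(z, 1), 60)


def zone_central_meridian(zone: int) -> float:
    return -183.0 + 6.0 * zone


def _tm_forward(lat_rad, dlon_rad):
    """Karney-series transverse Mercator; returns (x, y) on the k0-scaled grid."""
    e = _E1
    tau = np.tan(lat_rad)
    sigma = np.sinh(e * np.arctanh(e * tau / np.sqrt(1.0 + tau**2)))
    taup = tau * np.sqrt(1.0 + sigma**2) - sigma * np.sqrt(1.0 + tau**2)
    xi_p = np.arctan2(taup, np.cos(dlon_rad))
    eta_p = np.arcsinh(np.sin(dlon_rad) / np.hypot(taup, np.cos(dlon_rad)))
    xi = np.asarray(xi_p, dtype=float).copy()
    eta = np.asarray(eta_p, dtype=float).copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi += a * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta += a * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)
    x = UTM_K0 * _RECT_A * eta
    y = UTM_K0 * _RECT_A * xi
    return x, y


def _tm_inverse(x, y):
    """Inverse of :func:`_tm_forward`; returns (lat_rad, dlon_rad)."""
    e = _E1
    xi = np.asarray(y, dtype=float) / (UTM_K0 * _RECT_A)
    eta = np.asarray(x, dtype=float) / (UTM_K0 * _RECT_A)
    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, b in enumerate(_BETA, start=1):
        xi_p -= b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p -= b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)
    taup = np.sin(xi_p) / np.hypot(np.sinh(eta_p), np.cos(xi_p))
    dlon = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    # Newton-iterate tau from tau' (conformal -> geographic latitude).
    tau = taup / (1.0 - e**2)
    for _ in range(6):
        sigma = np.sinh(e * np.arctanh(e * tau / np.sqrt(1.0 + tau**2)))
        f = tau * np.sqrt(1.0 + sigma**2) - sigma * np.sqrt(1.0 + tau**2) - taup
        dfdtau = (
            (np.sqrt(1.0 + sigma**2) * np.sqrt(1.0 + tau**2) - sigma * tau)
            * (1.0 - e**2)
            * np.sqrt(1.0 + tau**2)
            / (1.0 + (1.0 - e**2) * tau**2)
        )
        tau = tau - f / dfdtau
    lat = np.arctan(tau)
    return lat, dlon


def project_to_utm(lat: float, lon: float, forced_zone: Optional[int] = None) -> UtmPoint:
    """Project a WGS84 fix to UTM.

    Parameters
    ----------
    lat, lon : float
        Geodetic coordinates in decimal degrees (north/east positive).
    forced_zone : int, optional
        Project into this zone instead of the longitude's natural zone
        (used to keep one zone per run near zone boundaries).
    """
    if not (math.isfinite(lat) and math.isfinite(lon)):
        raise ProjectionError("non-finite coordinate")
    if abs(lat) > 84.0:
        raise ProjectionError(f"latitude {lat} outside UTM domain (|lat| <= 84)")
    zone = forced_zone if forced_zone is not None else utm_zone(lon)
    if not 1 <= zone <= 60:
        raise ProjectionError(f"invalid UTM zone {zone}")
    lon0 = zone_central_meridian(zone)
    x, y = _tm_forward(math.radians(lat), math.radians(lon - lon0))
    hemisphere = "N" if lat >= 0 else "S"
    northing = float(y) + (0.0 if hemisphere == "N" else UTM_FALSE_NORTHING_SOUTH)
    return UtmPoint(float(x) + UTM_FALSE_EASTING, northing, zone, hemisphere)


def project_many(lat, lon, forced_zone: Optional[int] = None):
    """Vectorised projection of fix arrays into a single zone.

    The zone is taken from the first fix unless ``forced_zone`` is given,
    so a run never straddles a zone boundary discontinuity.

    Returns ``(easting, northing, zone, hemisphere)``.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0:
        return np.array([]), np.array([]), forced_zone or 0, "N"
    if np.any(np.abs(lat) > 84.0):
        raise ProjectionError("latitude outside UTM domain (|lat| <= 84)")
    zone = forced_zone if forced_zone is not None else utm_zone(float(lon.flat[0]))
    hemisphere = "N" if float(lat.flat[0]) >= 0 else "S"
    lon0 = zone_central_meridian(zone)
    x, y = _tm_forward(np.radians(lat), np.radians(lon - lon0))
    northing = y + (0.0 if hemisphere == "N" else UTM_FALSE_NORTHING_SOUTH)
    return x + UTM_FALSE_EASTING, northing, zone, hemisphere


def utm_to_latlon(easting, northing, zone: int, hemisphere: str = "N"):
    """Inverse UTM projection back to WGS84 decimal degrees."""
    y = np.asarray(northing, dtype=float) - (
        0.0 if hemisphere.upper() == "N" else UTM_FALSE_NORTHING_SOUTH
    )
    x = np.asarray(easting, dtype=float) - UTM_FALSE_EASTING
    lat, dlon = _tm_inverse(x, y)
    return np.degrees(lat), np.degrees(dlon) + zone_central_meridian(zone)


def sensor_position(vehicle: UtmPoint, yaw: float, forward_m: float, lateral_m: float) -> UtmPoint:
    """Ground position of a sensor offset from the GPS antenna.

    With theta = yaw (degrees clockwise from north), forward offset f and
    right-positive lateral offset l::

        easting'  = easting  + f sin(theta) + l cos(theta)
        northing' = northing + f cos(theta) - l sin(theta)

    so the sensor is always sqrt(f^2 + l^2) metres from the antenna.
    """
    theta = math.radians(yaw)
    de = forward_m * math.sin(theta) + lateral_m * math.cos(theta)
    dn = forward_m * math.cos(theta) - lateral_m * math.sin(theta)
    return UtmPoint(vehicle.easting + de, vehicle.northing + dn,
                    vehicle.zone, vehicle.hemisphere)


def sensor_positions(easting, northing, yaw_deg, forward_m, lateral_m):
    """Vectorised :func:`sensor_position` on coordinate arrays."""
    theta = np.radians(np.asarray(yaw_deg, dtype=float))
    e = np.asarray(easting, dtype=float)
    n = np.asarray(northing, dtype=float)
    de = forward_m * np.sin(theta) + lateral_m * np.cos(theta)
    dn = forward_m * np.cos(theta) - lateral_m * np.sin(theta)
    return e + de, n + dn


def align_streams(
    records: pd.DataFrame,
    fixes: pd.DataFrame,
    attitudes: pd.DataFrame,
    max_gap_ms: float = 200.0,
) -> pd.DataFrame:
    """Pair each sensor record with the nearest-in-time GPS fix and attitude.

    All streams share the data-logger clock (``logger_time`` column,
    datetime64).  A record whose nearest fix or attitude lies further
    than ``max_gap_ms`` away is flagged ``matched = False`` and excluded
    from georeferencing by the caller.  An empty GPS stream leaves every
    record unmatched (a warning-level condition, not an error).
    """
    out = records.sort_values("logger_time", kind="stable").reset_index(drop=True)
    tol = pd.Timedelta(milliseconds=max_gap_ms)

    def _nearest(right: pd.DataFrame, cols, suffix):
        if right is None or len(right) == 0:
            for c in cols:
                out[c] = np.nan
            out[f"gap_ms_{suffix}"] = np.nan
            return
        r = right.sort_values("logger_time", kind="stable")
        r = r.rename(columns={"logger_time": f"t_{suffix}"})
        merged = pd.merge_asof(
            out[["logger_time"]],
            r[[f"t_{suffix}"] + cols],
            left_on="logger_time",
            right_on=f"t_{suffix}",
            direction="nearest",
            tolerance=tol,
        )
        for c in cols:
            out[c] = merged[c].to_numpy()
        gap = (merged["logger_time"] - merged[f"t_{suffix}"]).abs()
        out[f"gap_ms_{suffix}"] = gap.dt.total_seconds().to_numpy() * 1000.0

    _nearest(fixes, ["lat", "lon"], "gps")
    _nearest(attitudes, ["yaw", "pitch", "roll"], "imu")
    out["matched"] = out["lat"].notna() & out["yaw"].notna()
    return out
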