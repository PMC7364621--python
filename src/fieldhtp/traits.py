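"""Derived trait computation.

Three traits are derived per observation:

* adjusted plant height ``h = s - d``, where ``s`` is the recorded
  soil-line-to-boom height and ``d`` the ultrasonic displacement to the
  canopy;
* NDVI ``(rho_NIR - rho_VIS) / (rho_NIR + rho_VIS)`` with NIR at
  800 +/- 5 nm and VIS at 670 +/- 5 nm;
* NDRE ``(rho_NIR - rho_RE) / (rho_NIR + rho_RE)`` with the red edge at
  730 +/- 5 nm.

Degenerate observations (negative height, zero index denominator,
negative band, non-finite input) are *flagged, never dropped*: outlier
handling is the job of the QC stages, not the trait layer.  Reflectance
inputs are assumed band-calibrated by the sensor.
"""

from __future__ import annotations

import numpy as np

FLAG_OK = ""
FLAG_NEGATIVE_HEIGHT = "negative_height"
FLAG_ZERO_DENOMINATOR = "zero_denominator"
FLAG_NEGATIVE_BAND = "negative_band"
FLAG_INVALID = "invalid"


def adjusted_height(s, d):
    """Adjusted plant height ``h = s - d`` (metres).

    Accepts scalars or arrays.  Negative results are returned as-is
    (soil/hole returns); see :func:`height_flags`.
    """
    return np.asarray(s, dtype=float) - np.asarray(d, dtype=float)


def height_flags(s, d):
    s = np.asarray(s, dtype=float)
    d = np.asarray(d, dtype=float)
    h = s - d
    flags = np.full(h.shape, FLAG_OK, dtype=object)
    flags[h < 0] = FLAG_NEGATIVE_HEIGHT
    flags[~(np.isfinite(s) & np.isfinite(d))] = FLAG_INVALID
    return flags


def _normalized_difference(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(denom == 0.0, np.nan, (a - b) / denom)
    flags = np.full(np.shape(idx), FLAG_OK, dtype=object)
    flags[np.asarray(denom == 0.0)] = FLAG_ZERO_DENOMINATOR
    bad = (a < 0) | (b < 0)
    idx = np.where(bad, np.nan, idx)
    flags[np.asarray(bad)] = FLAG_NEGATIVE_BAND
    nonfinite = ~(np.isfinite(a) & np.isfinite(b))
    idx = np.where(nonfinite, np.nan, idx)
    flags[np.asarray(nonfinite)] = FLAG_INVALID
    if np.ndim(idx) == 0:
        return float(idx), str(flags[()])
    return idx, flags


def ndvi(rho_nir, rho_vis):
    """Normalized difference vegetation index; NaN where undefined."""
    return _normalized_difference(rho_nir, rho_vis)[0]


def ndre(rho_nir, rho_re):
    """Normalized difference red-edge index; NaN where undefined."""
    return _normalized_difference(rho_nir, rho_re)[0]


def ndvi_with_flags(rho_nir, rho_vis):
    return _normalized_difference(rho_nir, rho_vis)


def ndre_with_flags(rho_nir, rho_re):
    return _normalized_difference(rho_nir, rho_re)
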