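"""Independent reference implementations used only to check the package.

Each oracle is written from a different formulation than the code under
test: the UTM oracle uses the classic Snyder series (not the Krueger
series the package uses), containment uses brute-force even-odd ray
casting (not shapely), and studentized deleted residuals come from an
explicit leave-one-out refit (not the no-refit shortcut).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def snyder_utm(lat: float, lon: float, zone: int):
    """Transverse Mercator forward mapping, Snyder-series formulation."""
    a = 6378137.0
    f = 1.0 / 298.257223563
    e2 = f * (2.0 - f)
    ep2 = e2 / (1.0 - e2)
    k0 = 0.9996
    phi = math.radians(lat)
    lam = math.radians(lon)
    lam0 = math.radians(zone * 6 - 183)
    N = a / math.sqrt(1.0 - e2 * math.sin(phi) ** 2)
    T = math.tan(phi) ** 2
    C = ep2 * math.cos(phi) ** 2
    A = (lam - lam0) * math.cos(phi)
    M = a * (
        (1 - e2 / 4 - 3 * e2**2 / 64 - 5 * e2**3 / 256) * phi
        - (3 * e2 / 8 + 3 * e2**2 / 32 + 45 * e2**3 / 1024) * math.sin(2 * phi)
        + (15 * e2**2 / 256 + 45 * e2**3 / 1024) * math.sin(4 * phi)
        - (35 * e2**3 / 3072) * math.sin(6 * phi)
    )
    x = k0 * N * (
        A + (1 - T + C) * A**3 / 6
        + (5 - 18 * T + T**2 + 72 * C - 58 * ep2) * A**5 / 120
    ) + 500000.0
    y = k0 * (
        M + N * math.tan(phi) * (
            A**2 / 2 + (5 - T + 9 * C + 4 * C**2) * A**4 / 24
            + (61 - 58 * T + T**2 + 600 * C - 330 * ep2) * A**6 / 720
        )
    )
    if lat < 0:
        y += 10_000_000.0
    return x, y


def point_in_ring(px: float, py: float, ring, eps: float = 1e-12) -> bool:
    """Even-odd ray casting with boundary points counted inside."""
    n = len(ring)
    inside = False
    for i in range(n - 1):
        x1, y1 = ring[i]
        x2, y2 = ring[i + 1]
        # boundary: point on the closed segment
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) <= eps * max(1.0, abs(x2 - x1) + abs(y2 - y1)):
            dot = (px - x1) * (x2 - x1) + (py - y1) * (y2 - y1)
            sq = (x2 - x1) ** 2 + (y2 - y1) ** 2
            if -eps <= dot <= sq + eps:
                return True
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def assign_plots_raycast(points, plots) -> list:
    """Brute-force plot assignment; ``plots`` is [(plot_id, ring), ...].
    Overlap ties resolved by smallest plot_id (matching the package)."""
    out = []
    for px, py in points:
        hits = sorted(pid for pid, ring in plots if point_in_ring(px, py, ring))
        out.append(hits[0] if hits else None)
    return out


def design_cell_means(df: pd.DataFrame, factors) -> np.ndarray:
    first = df[factors[0]].astype(str).to_numpy()
    levels = sorted(set(first))
    X = (first[:, None] == np.array(levels)[None, :]).astype(float)
    for f in factors[1:]:
        vals = df[f].astype(str).to_numpy()
        for lv in sorted(set(vals))[1:]:
            X = np.column_stack([X, (vals == lv).astype(float)])
    return X


def loo_studentized_residuals(df: pd.DataFrame, response: str, factors) -> np.ndarray:
    """Studentized deleted residuals by explicit leave-one-out refits."""
    X = design_cell_means(df, factors)
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    t = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        beta, _, rank, _ = np.linalg.lstsq(Xi, yi, rcond=None)
        resid = yi - Xi @ beta
        dof = (n - 1) - rank
        if dof <= 0:
            t[i] = np.nan
            continue
        mse = float(resid @ resid) / dof
        xrow = X[i]
        v = float(xrow @ np.linalg.pinv(Xi.T @ Xi) @ xrow)
        pred = float(xrow @ beta)
        denom = mse * (1.0 + v)
        t[i] = (y[i] - pred) / math.sqrt(denom) if denom > 0 else np.nan
    return t
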