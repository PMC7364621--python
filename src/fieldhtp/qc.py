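"""QC step 1: per-run diagnostics.

Four checks, all report-only (whether a run is re-collected is the
operator's call): per-sensor summary statistics; drift of the current
run against the history of previous runs (robust median/MAD score);
record balance across the boom arms (a short arm flags a logging-loop
problem); and operational-range threshold checks with inclusive bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Conservative manufacturer-style defaults, editable per deployment;
# keys are sensor types, values (lower, upper) in trait units.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "ultrasonic": (0.0, 3.0),      # adjusted height, m
    "irt": (-10.0, 60.0),          # canopy temperature, C
    "reflectance": (-1.0, 1.0),    # normalized-difference indices
}

MAD_FLOOR_FRACTION = 1e-6  # floor = fraction * |median| (degenerate MAD guard)


@dataclass
class QcSummary:
    """Per-sensor summary statistics for one run."""

    run_id: str
    per_sensor: pd.DataFrame  # sensor_id, sensor_type, n, mean, sd, min, max, ...
    start: object = None
    end: object = None
    duration_s: float = float("nan")
    extras: dict = field(default_factory=dict)


def run_summary(observations: pd.DataFrame, run_id: str,
                ranges: dict | None = None) -> QcSummary:
    """Summaries per sensor over a run's trait observations.

    ``observations`` is the production-style long table (one row per
    sensor x tick x trait).  Deterministic and permutation-invariant.
    """
    obs = observations
    ranges = DEFAULT_RANGES if ranges is None else ranges
    rows = []
    for (sid, stype), sub in obs.groupby(["sensor_id", "sensor_type"], sort=True):
        v = pd.to_numeric(sub["value"], errors="coerce")
        n_missing = int(v.isna().sum())
        vv = v.dropna()
        lo, hi = ranges.get(stype, (-np.inf, np.inf))
        oob = float(((vv < lo) | (vv > hi)).mean()) if len(vv) else 0.0
        rows.append({
            "sensor_id": sid, "sensor_type": stype, "n": int(len(sub)),
            "mean": float(vv.mean()) if len(vv) else np.nan,
            "sd": float(vv.std(ddof=1)) if len(vv) > 1 else 0.0 if len(vv) else np.nan,
            "min": float(vv.min()) if len(vv) else np.nan,
            "max": float(vv.max()) if len(vv) else np.nan,
            "missing": n_missing,
            "out_of_range_frac": oob,
        })
    per_sensor = pd.DataFrame(rows)
    times = pd.to_datetime(obs["logger_time"]) if len(obs) else pd.Series(dtype="datetime64[ns]")
    start = times.min() if len(times) else None
    end = times.max() if len(times) else None
    dur = (end - start).total_seconds() if len(times) else float("nan")
    return QcSummary(run_id, per_sensor, start, end, dur)


def history_drift(current: QcSummary, history: list[QcSummary],
                  k: float = 3.0) -> pd.DataFrame:
    """Flag sensors whose run mean drifted from their run history.

    A sensor is flagged when |current mean - median(historical means)|
    exceeds ``k`` times the MAD of the historical means (MAD floored at
    ``1e-6 * |median|`` so constant histories still flag genuine jumps).
    Fewer than 3 historical runs yields status ``no assessment`` --
    gradual sensor degradation cannot be judged from one or two runs.
    """
    cur = current.per_sensor.set_index("sensor_id")
    hist_means: dict[str, list[float]] = {}
    for h in history:
        for _, r in h.per_sensor.iterrows():
            hist_means.setdefault(r["sensor_id"], []).append(r["mean"])
    rows = []
    for sid, r in cur.iterrows():
        means = np.asarray(hist_means.get(sid, []), dtype=float)
        means = means[np.isfinite(means)]
        if len(means) < 3:
            rows.append({"sensor_id": sid, "status": "no assessment",
                         "flagged": False, "score": np.nan})
            continue
        med = float(np.median(means))
        mad = float(np.median(np.abs(means - med)))
        mad = max(mad, MAD_FLOOR_FRACTION * abs(med), np.finfo(float).tiny)
        score = abs(float(r["mean"]) - med) / mad
        rows.append({"sensor_id": sid, "status": "assessed",
                     "flagged": bool(score > k), "score": score})
    return pd.DataFrame(rows)


def record_balance(observations: pd.DataFrame, tolerance: int = 0) -> pd.DataFrame:
    """Per sensor type, compare record counts across boom arms.

    An arm whose count falls short of the arm maximum by more than
    ``tolerance`` records flags a data-logging problem (loops not
    returning in time).
    """
    rows = []
    group_cols = ["sensor_type", "boom_arm", "sensor_id"]
    counts = (observations.groupby(group_cols, sort=True, dropna=False)
              .size().rename("n").reset_index())
    for stype, sub in counts.groupby("sensor_type", sort=True):
        arm_counts = sub.groupby("boom_arm", sort=True)["n"].sum()
        top = int(arm_counts.max())
        for arm, n in arm_counts.items():
            rows.append({
                "sensor_type": stype, "boom_arm": arm, "n_records": int(n),
                "deficit": top - int(n),
                "flagged": (top - int(n)) > tolerance,
            })
    return pd.DataFrame(rows)


def threshold_check(observations: pd.DataFrame,
                    ranges: dict | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag observations outside their sensor type's operational range.

    Bounds are inclusive: a value exactly on a bound is in range.
    Returns ``(observations + out_of_range column, per-sensor report)``.
    Sensor types with no configured range are skipped with a warning.
    """
    ranges = DEFAULT_RANGES if ranges is None else ranges
    out = observations.copy()
    flag = np.zeros(len(out), dtype=bool)
    stypes = out["sensor_type"].to_numpy()
    values = pd.to_numeric(out["value"], errors="coerce").to_numpy()
    for stype in pd.unique(stypes):
        mask = stypes == stype
        if stype not in ranges:
            warnings.warn(f"no operational range configured for sensor type "
                          f"{stype!r}; skipped", stacklevel=2)
            continue
        lo, hi = ranges[stype]
        v = values[mask]
        with np.errstate(invalid="ignore"):
            flag[mask] = (v < lo) | (v > hi)
    out["out_of_range"] = flag
    report = (out.groupby("sensor_id", sort=True)
              .agg(n=("out_of_range", "size"),
                   n_flagged=("out_of_range", "sum"),
                   out_of_range_frac=("out_of_range", "mean"))
              .reset_index())
    return out, report


def plot_temperature_series(observations: pd.DataFrame, plot_id: str,
                            out_path, ranges: dict | None = None) -> None:
    """Export a canopy-temperature time series for one plot with the
    operational-range threshold lines (body temperature dashed)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranges = DEFAULT_RANGES if ranges is None else ranges
    sub = observations[(observations["plot_id"] == plot_id)
                       & (observations["trait"] == "canopy_temp")]
    fig, ax = plt.subplots(figsize=(8, 4))
    t = pd.to_datetime(sub["logger_time"])
    ax.plot(t, sub["value"], ".", ms=3, label="canopy temperature")
    if "raw2" in sub.columns and sub["raw2"].notna().any():
        ax.plot(t, sub["raw2"], "-", color="tab:orange", lw=1,
                label="sensor body temperature")
    lo, hi = ranges.get("irt", (np.nan, np.nan))
    for bound in (lo, hi):
        ax.axhline(bound, color="red", ls="--", lw=1)
    ax.set_xlabel("time")
    ax.set_ylabel("temperature (C)")
    ax.set_title(f"plot {plot_id}")
    ax.legend(loc="best", fontsize=8)
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
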