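"""Synthetic tractor-run generator.

Emulates a 5 Hz multi-sensor collection by a high-clearance vehicle
driving a serpentine path over a rectangular grid of experimental plots
(default 40 rows x 6 columns = 240 plots of 12 m x 1.02 m, matching a
typical cotton breeding trial over six irrigation basins).  The emitted
artefacts follow the ingestion contract exactly -- one delimited log per
sensor channel, an NMEA GGA/RMC stream, an IMU yaw/pitch/roll stream,
and a key = value run-metadata file -- plus a GeoJSON plot map and a
ground-truth table so every downstream stage is testable without field
data.

Error injection knobs: a lateral sinusoidal "wobble" of the track,
short Gaussian pitch/roll events (holes and bumps), plant sparsity
(soil in the sensor field of view), corrupted log lines (NUL bytes or
truncation, *inserted* as extra lines so clean-record counts are
conserved), and value outliers at a configurable multiple of the noise
SD.  Identical config + seed produces byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nmea, traits
from .georef import utm_to_latlon

BASE_TIME = datetime(2015, 7, 30, 11, 0, 0)
TRAIT_NAMES = ("height", "canopy_temp", "ndvi", "ndre")

# Log-file numeric formats (shared with the ground-truth table so the
# ingest round-trip is exact).
_FMT_DISP = "%.4f"
_FMT_TEMP = "%.3f"
_FMT_BAND = "%.5f"
_FMT_ANGLE = "%.3f"


class ConfigError(ValueError):
    """A SimulationConfig violating its invariants."""


@dataclass
class SimulationConfig:
    """Full parameterization of one virtual collection run.

    Defaults state a realistic mid-season cotton collection: 240 plots
    of 12 m x 1.02 m, 0.67 m/s forward speed, 5 Hz logging, 120
    measurements per plot for 4 simultaneous traits, RTK-grade 1 cm GPS
    noise, and within-plot noise SDs of 4.3 cm (height), 0.5 C (canopy
    temperature) and 0.01 (reflectance bands).
    """

    n_plot_rows: int = 40
    n_plot_cols: int = 6
    plot_length: float = 12.0
    plot_width: float = 1.02
    speed: float = 0.67
    sample_rate: float = 5.0
    n_traits: int = 4
    measurements_per_plot: int = 120
    boom_height_s: float = 2.0
    # per-plot truths; None -> drawn uniformly from the ranges below
    true_height_per_plot: Optional[Sequence[float]] = None
    true_temp_per_plot: Optional[Sequence[float]] = None
    true_reflectance_per_plot: Optional[Sequence[Sequence[float]]] = None  # (nir, vis, re)
    height_range: tuple = (0.60, 1.10)
    temp_range: tuple = (28.0, 36.0)
    nir_range: tuple = (0.45, 0.60)
    vis_range: tuple = (0.05, 0.15)
    re_range: tuple = (0.20, 0.35)
    wobble_amplitude: float = 0.05
    pitch_roll_event_rate: int = 5  # events per run
    sparsity_fraction: float = 0.0
    corruption_rate: float = 0.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 10.0  # multiples of the channel noise SD
    noise_sd: dict = field(default_factory=lambda: {
        "height": 0.043, "canopy_temp": 0.5, "reflectance": 0.01})
    gps_noise_sd: float = 0.01
    attitude_noise_sd: float = 0.3
    yaw_noise_sd: float = 0.1
    seed: int = 42
    run_id: Optional[str] = None
    field_origin: tuple = (409000.0, 3660000.0)  # UTM metres (zone below)
    utm_zone: int = 12
    hemisphere: str = "N"
    sensor_forward: float = 2.0  # shared boom mount, metres ahead of antenna
    sensor_lateral: float = 0.0
    n_lines: int = 33  # breeding lines cycled over plots (plot-map attribute)

    @property
    def n_plots(self) -> int:
        return self.n_plot_rows * self.n_plot_cols

    @property
    def resolved_run_id(self) -> str:
        return self.run_id or f"sim{self.seed:08d}"

    def validate(self) -> None:
        if self.n_plot_rows < 0 or self.n_plot_cols < 0:
            raise ConfigError("plot counts must be >= 0")
        if self.plot_length <= 0 or self.plot_width <= 0:
            raise ConfigError("plot dimensions must be > 0")
        if not 1 <= self.n_traits <= 4:
            raise ConfigError("n_traits must be in 1..4")
        if self.measurements_per_plot < 0:
            raise ConfigError("measurements_per_plot must be >= 0")
        for name in ("sparsity_fraction", "corruption_rate", "outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.boom_height_s <= 0:
            raise ConfigError("boom_height_s must be > 0")
        if self.sample_rate <= 0 or self.speed <= 0:
            raise ConfigError("sample_rate and speed must be > 0")
        if self.wobble_amplitude < 0 or self.wobble_amplitude >= self.plot_width / 2:
            raise ConfigError("wobble_amplitude must be in [0, plot_width/2)")
        if self.hemisphere not in ("N", "S"):
            raise ConfigError("hemisphere must be N or S")


@dataclass
class SimulatedRun:
    """Paths and ground truth for one generated run."""

    run_dir: Path
    plot_map_path: Path
    ground_truth_path: Path
    config_path: Path
    ground_truth: pd.DataFrame
    config: SimulationConfig


def _plot_id(row: int, col: int) -> str:
    # field-style ids: column block * 1000 + row, e.g. 1001 .. 6040
    return str(1000 * (col + 1) + (row + 1))


def _format_ts(t: datetime) -> str:
    return f"{t:%Y-%m-%d %H:%M:%S}.{t.microsecond // 1000:03d}"


def _active_traits(cfg: SimulationConfig) -> tuple[str, ...]:
    return TRAIT_NAMES[: cfg.n_traits]


def _corrupt_line(line: str, mode: int, rng: np.random.Generator) -> str:
    if mode == 0:  # NUL-byte insertion ("bad character" rejection class)
        pos = int(rng.integers(0, max(len(line), 1)))
        return line[:pos] + "\x00" + line[pos:]
    # truncation ("incomplete line" rejection class): keep first field only
    return line.split(",", 1)[0]


def _write_log(path: Path, clean_lines: list[str], corrupt_after: dict[int, str]) -> None:
    with open(path, "w", newline="\n") as fh:
        for i, line in enumerate(clean_lines):
            fh.write(line + "\n")
            if i in corrupt_after:
                fh.write(corrupt_after[i] + "\n")


def simulate_run(config: SimulationConfig, out_dir) -> SimulatedRun:
    """Generate one complete run directory plus plot map and ground truth.

    Layout under ``out_dir``::

        <run_id>/                     raw logs + <run_id>_sensorrun.txt
        <run_id>_plots.geojson        plot-boundary map (UTM, EPSG-coded)
        <run_id>_groundtruth.csv      one record per emitted observation
        <run_id>_config.json          config echo (includes the seed)

    The total count of clean trait observations is exactly
    ``n_plots * measurements_per_plot * n_traits``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    run_id = config.resolved_run_id
    out_dir = Path(out_dir)
    run_dir = out_dir / run_id
    run_dir.mkdir(parents=True, exist_ok=True)

    cfg = config
    m = cfg.measurements_per_plot
    n_rows, n_cols = cfg.n_plot_rows, cfg.n_plot_cols
    n_plots = cfg.n_plots
    ticks = n_plots * m
    L, W = cfg.plot_length, cfg.plot_width
    origin_e, origin_n = cfg.field_origin
    active = _active_traits(cfg)

    # ------------------------------------------------------------------ truths
    if cfg.true_height_per_plot is not None:
        h_true = np.broadcast_to(np.asarray(cfg.true_height_per_plot, float), (n_plots,)).copy()
    else:
        h_true = rng.uniform(*cfg.height_range, n_plots)
    if cfg.true_temp_per_plot is not None:
        t_true = np.broadcast_to(np.asarray(cfg.true_temp_per_plot, float), (n_plots,)).copy()
    else:
        t_true = rng.uniform(*cfg.temp_range, n_plots)
    if cfg.true_reflectance_per_plot is not None:
        bands_true = np.broadcast_to(
            np.asarray(cfg.true_reflectance_per_plot, float), (n_plots, 3)).copy()
    else:
        bands_true = np.column_stack([
            rng.uniform(*cfg.nir_range, n_plots),
            rng.uniform(*cfg.vis_range, n_plots),
            rng.uniform(*cfg.re_range, n_plots),
        ])

    # ------------------------------------------------------------- path/ticks
    # Serpentine over plot columns; within each plot, measurements_per_plot
    # sensor ground points evenly spaced along the plot centreline.
    plot_index = np.empty(ticks, dtype=int)  # index into plot arrays (col*n_rows+row)
    row_idx = np.empty(ticks, dtype=int)
    col_idx = np.empty(ticks, dtype=int)
    s_track = np.empty(ticks, dtype=float)  # cumulative along-track distance
    sensor_n_arr = np.empty(ticks, dtype=float)
    direction = np.empty(ticks, dtype=float)  # +1 north, -1 south
    k = 0
    pass_len = n_rows * L
    within = (np.arange(m) + 0.5) * (L / m) if m else np.empty(0)
    for c in range(n_cols):
        northbound = (c % 2 == 0)
        rows = range(n_rows) if northbound else range(n_rows - 1, -1, -1)
        for j, r in enumerate(rows):
            sl = slice(k, k + m)
            along_in_pass = j * L + within
            s_track[sl] = c * pass_len + along_in_pass
            if northbound:
                sensor_n_arr[sl] = origin_n + r * L + within
            else:
                sensor_n_arr[sl] = origin_n + (r + 1) * L - within
            direction[sl] = 1.0 if northbound else -1.0
            plot_index[sl] = c * n_rows + r
            row_idx[sl] = r
            col_idx[sl] = c
            k += m

    col_center_e = origin_e + (col_idx + 0.5) * W
    if cfg.wobble_amplitude > 0 and L > 0:
        kw = 2.0 * math.pi / L  # wobble period ~ plot length
        wobble = cfg.wobble_amplitude * np.sin(kw * s_track)
        slope = cfg.wobble_amplitude * kw * np.cos(kw * s_track)
    else:
        wobble = np.zeros(ticks)
        slope = np.zeros(ticks)
    sensor_e_arr = col_center_e + wobble
    yaw_true = np.degrees(np.arctan2(slope, direction)) % 360.0

    theta = np.radians(yaw_true)
    f_off, l_off = cfg.sensor_forward, cfg.sensor_lateral
    vehicle_e = sensor_e_arr - (f_off * np.sin(theta) + l_off * np.cos(theta))
    vehicle_n = sensor_n_arr - (f_off * np.cos(theta) - l_off * np.sin(theta))

    dt = timedelta(seconds=1.0 / cfg.sample_rate)
    times = [BASE_TIME + i * dt for i in range(ticks)]
    ts_str = [_format_ts(t) for t in times]

    # ------------------------------------------------------------- attitude
    yaw_meas = (yaw_true + rng.normal(0.0, cfg.yaw_noise_sd, ticks)) % 360.0
    pitch = rng.normal(0.0, cfg.attitude_noise_sd, ticks)
    roll = rng.normal(0.0, cfg.attitude_noise_sd, ticks)
    n_events = int(cfg.pitch_roll_event_rate)
    event_peak = np.zeros(ticks)
    if ticks > 0:
        for _ in range(n_events):
            center = int(rng.integers(0, ticks))
            width = float(rng.uniform(3.0, 8.0))  # ticks (~0.6-1.6 s at 5 Hz)
            amp = float(rng.uniform(6.0, 12.0)) * (1 if rng.random() < 0.5 else -1)
            bump = amp * np.exp(-0.5 * ((np.arange(ticks) - center) / width) ** 2)
            if rng.random() < 0.5:
                pitch += bump
            else:
                roll += bump
            event_peak = np.maximum(event_peak, np.abs(bump))

    # --------------------------------------------------------------- values
    sd_h = cfg.noise_sd["height"]
    sd_t = cfg.noise_sd["canopy_temp"]
    sd_b = cfg.noise_sd["reflectance"]
    s_boom = cfg.boom_height_s

    h_tick_true = h_true[plot_index] if ticks else np.empty(0)
    d_vals = s_boom - (h_tick_true + rng.normal(0.0, sd_h, ticks))
    out_ult = rng.random(ticks) < cfg.outlier_fraction
    shift_mag = (cfg.outlier_shift + np.abs(rng.normal(0.0, 1.0, ticks))) * sd_h
    shift_sign = np.where(rng.random(ticks) < 0.5, -1.0, 1.0)
    d_vals = np.where(out_ult, s_boom - h_tick_true + shift_sign * shift_mag, d_vals)
    sparse = rng.random(ticks) < cfg.sparsity_fraction
    d_vals = np.where(sparse, s_boom - 0.02, d_vals)  # soil return
    d_vals = np.maximum(d_vals, 0.0)

    t_tick_true = t_true[plot_index] if ticks else np.empty(0)
    temp_vals = t_tick_true + rng.normal(0.0, sd_t, ticks)
    out_irt = rng.random(ticks) < cfg.outlier_fraction
    shift_mag_t = (cfg.outlier_shift + np.abs(rng.normal(0.0, 1.0, ticks))) * sd_t
    sign_t = np.where(rng.random(ticks) < 0.5, -1.0, 1.0)
    temp_vals = np.where(out_irt, t_tick_true + sign_t * shift_mag_t, temp_vals)
    body_vals = 40.0 + rng.normal(0.0, 0.2, ticks)  # sensor body temperature

    bt = bands_true[plot_index] if ticks else np.empty((0, 3))
    band_vals = np.clip(bt + rng.normal(0.0, sd_b, (ticks, 3)), 0.0, 1.0)
    out_refl = rng.random(ticks) < cfg.outlier_fraction
    # Shift NIR upward only: keeps |value - truth| >= shift*sd by
    # construction (no clipping can intervene for band truths < 1).
    shift_mag_b = (cfg.outlier_shift + np.abs(rng.normal(0.0, 1.0, ticks))) * sd_b
    band_vals[:, 0] = np.where(out_refl, bt[:, 0] + shift_mag_b, band_vals[:, 0]) if ticks else band_vals[:, 0]

    # ----------------------------------------------------------------- GPS
    gps_e = vehicle_e + rng.normal(0.0, cfg.gps_noise_sd, ticks)
    gps_n = vehicle_n + rng.normal(0.0, cfg.gps_noise_sd, ticks)
    lat, lon = utm_to_latlon(gps_e, gps_n, cfg.utm_zone, cfg.hemisphere)
    lat = np.atleast_1d(lat)
    lon = np.atleast_1d(lon)

    # ------------------------------------------------------------ log lines
    plot_ids = np.array([_plot_id(r, c) for r, c in zip(row_idx, col_idx)]) if ticks \
        else np.array([], dtype=object)

    sensors = []  # (sensor_id, sensor_type, arm, forward, lateral)
    logs: dict[str, list[str]] = {}
    if "height" in active:
        sensors.append(("US1", "ultrasonic", "center", f_off, l_off))
        logs["US1"] = [f"{ts},{_FMT_DISP % d}" for ts, d in zip(ts_str, d_vals)]
    if "canopy_temp" in active:
        sensors.append(("IRT1", "irt", "center", f_off, l_off))
        logs["IRT1"] = [
            f"{ts},{_FMT_TEMP % tv},{_FMT_TEMP % bv}"
            for ts, tv, bv in zip(ts_str, temp_vals, body_vals)
        ]
    if "ndvi" in active or "ndre" in active:
        sensors.append(("CC1", "reflectance", "center", f_off, l_off))
        logs["CC1"] = [
            f"{ts},{_FMT_BAND % b[0]},{_FMT_BAND % b[1]},{_FMT_BAND % b[2]}"
            for ts, b in zip(ts_str, band_vals)
        ]
    sensors.append(("GPS1", "gps", "mast", 0.0, 0.0))
    sensors.append(("IMU1", "imu", "mast", 0.0, 0.0))

    gps_lines = []
    for i in range(ticks):
        t = times[i]
        gga = nmea.encode_gga(t, float(lat[i]), float(lon[i]), quality=4)
        rmc = nmea.encode_rmc(t, float(lat[i]), float(lon[i]),
                              speed_knots=cfg.speed * 1.9438, course=float(yaw_true[i]))
        gps_lines.append(f"{ts_str[i]},{gga}")
        gps_lines.append(f"{ts_str[i]},{rmc}")
    imu_lines = [
        f"{ts},{_FMT_ANGLE % y},{_FMT_ANGLE % p},{_FMT_ANGLE % r}"
        for ts, y, p, r in zip(ts_str, yaw_meas, pitch, roll)
    ]

    # ------------------------------------------------------- corruption
    gt_corrupt_rows = []
    corrupt_after_by_sensor: dict[str, dict[int, str]] = {}
    for sensor_id, lines in logs.items():
        mask = rng.random(len(lines)) < cfg.corruption_rate
        inserts: dict[int, str] = {}
        for i in np.flatnonzero(mask):
            mode = int(rng.integers(0, 2))
            inserts[int(i)] = _corrupt_line(lines[int(i)], mode, rng)
            gt_corrupt_rows.append({
                "obs_id": f"{sensor_id}:corrupt:{int(i)}",
                "tick": int(i), "sensor_id": sensor_id, "trait": "",
                "logger_time": ts_str[int(i)], "plot_id": "",
                "true_value": np.nan, "value": np.nan,
                "outlier": 0, "corrupted": 1, "sparse": 0,
                "corruption_mode": "bad_chars" if mode == 0 else "incomplete",
                "wobble_m": np.nan, "yaw": np.nan, "pitch": np.nan,
                "roll": np.nan, "event_peak_deg": np.nan,
                "sensor_e": np.nan, "sensor_n": np.nan,
            })
        corrupt_after_by_sensor[sensor_id] = inserts

    # ----------------------------------------------------------- write files
    for sensor_id, stype, arm, fo, lo in sensors:
        if sensor_id in logs:
            _write_log(run_dir / f"{run_id}_{stype}_{sensor_id}.csv",
                       logs[sensor_id], corrupt_after_by_sensor.get(sensor_id, {}))
    _write_log(run_dir / f"{run_id}_gps_GPS1.csv", gps_lines, {})
    _write_log(run_dir / f"{run_id}_imu_IMU1.csv", imu_lines, {})

    meta_lines = [
        f"run_id = {run_id}",
        f"date = {BASE_TIME:%Y-%m-%d}",
        f"time = {BASE_TIME:%H:%M:%S}",
        "field_id = F1",
        "operator = simulator",
        f"boom_height_s = {s_boom:.3f}",
        "wheel_spacing = 2.040",
        f"utm_zone = {cfg.utm_zone}",
        f"hemisphere = {cfg.hemisphere}",
        f"seed = {cfg.seed}",
        f"speed = {cfg.speed:.3f}",
        f"sample_rate = {cfg.sample_rate:g}",
        "notes = synthetic run generated by fieldhtp.simulate",
    ]
    for sensor_id, stype, arm, fo, lo in sensors:
        meta_lines.append(f"sensor = {sensor_id},{stype},{arm},{fo:.3f},{lo:.3f}")
    (run_dir / f"{run_id}_sensorrun.txt").write_text("\n".join(meta_lines) + "\n")

    plot_map_path = out_dir / f"{run_id}_plots.geojson"
    _write_plot_map(plot_map_path, cfg)

    # ------------------------------------------------------- ground truth
    gt_frames = []
    base_cols = {
        "tick": np.arange(ticks), "logger_time": np.array(ts_str, dtype=object),
        "plot_id": plot_ids, "corrupted": 0,
        "wobble_m": wobble, "yaw": yaw_meas, "pitch": pitch, "roll": roll,
        "event_peak_deg": event_peak,
        "sensor_e": sensor_e_arr, "sensor_n": sensor_n_arr,
    }
    round4 = np.round(d_vals, 4)
    if "height" in active:
        gt_frames.append(pd.DataFrame({
            "obs_id": [f"US1:{i:06d}:height" for i in range(ticks)],
            "sensor_id": "US1", "trait": "height",
            "true_value": h_tick_true, "value": s_boom - round4,
            "outlier": (out_ult & ~sparse).astype(int), "sparse": sparse.astype(int),
            "corruption_mode": "", **base_cols,
        }))
    if "canopy_temp" in active:
        gt_frames.append(pd.DataFrame({
            "obs_id": [f"IRT1:{i:06d}:canopy_temp" for i in range(ticks)],
            "sensor_id": "IRT1", "trait": "canopy_temp",
            "true_value": t_tick_true, "value": np.round(temp_vals, 3),
            "outlier": out_irt.astype(int), "sparse": 0,
            "corruption_mode": "", **base_cols,
        }))
    band_r = np.round(band_vals, 5)
    if "ndvi" in active:
        gt_frames.append(pd.DataFrame({
            "obs_id": [f"CC1:{i:06d}:ndvi" for i in range(ticks)],
            "sensor_id": "CC1", "trait": "ndvi",
            "true_value": traits.ndvi(bt[:, 0], bt[:, 1]) if ticks else [],
            "value": traits.ndvi(band_r[:, 0], band_r[:, 1]) if ticks else [],
            "outlier": out_refl.astype(int), "sparse": 0,
            "corruption_mode": "", **base_cols,
        }))
    if "ndre" in active:
        gt_frames.append(pd.DataFrame({
            "obs_id": [f"CC1:{i:06d}:ndre" for i in range(ticks)],
            "sensor_id": "CC1", "trait": "ndre",
            "true_value": traits.ndre(bt[:, 0], bt[:, 2]) if ticks else [],
            "value": traits.ndre(band_r[:, 0], band_r[:, 2]) if ticks else [],
            "outlier": out_refl.astype(int), "sparse": 0,
            "corruption_mode": "", **base_cols,
        }))
    if gt_corrupt_rows:
        gt_frames.append(pd.DataFrame(gt_corrupt_rows))
    columns = ["obs_id", "tick", "sensor_id", "trait", "logger_time", "plot_id",
               "true_value", "value", "outlier", "corrupted", "sparse",
               "corruption_mode", "wobble_m", "yaw", "pitch", "roll",
               "event_peak_deg", "sensor_e", "sensor_n"]
    if gt_frames:
        ground_truth = pd.concat(gt_frames, ignore_index=True)
        ground_truth["corrupted"] = ground_truth.get("corrupted", 0)
        ground_truth = ground_truth.reindex(columns=columns)
    else:
        ground_truth = pd.DataFrame(columns=columns)
    gt_path = out_dir / f"{run_id}_groundtruth.csv"
    ground_truth.to_csv(gt_path, index=False, float_format="%.6f")

    config_path = out_dir / f"{run_id}_config.json"
    echo = asdict(cfg)
    for key in ("true_height_per_plot", "true_temp_per_plot", "true_reflectance_per_plot"):
        if echo[key] is not None:
            echo[key] = np.asarray(echo[key]).tolist()
    config_path.write_text(json.dumps(echo, sort_keys=True, indent=1) + "\n")

    return SimulatedRun(run_dir, plot_map_path, gt_path, config_path,
                        ground_truth, cfg)


def _write_plot_map(path: Path, cfg: SimulationConfig) -> None:
    origin_e, origin_n = cfg.field_origin
    L, W = cfg.plot_length, cfg.plot_width
    epsg = (32600 if cfg.hemisphere == "N" else 32700) + cfg.utm_zone
    features = []
    for c in range(cfg.n_plot_cols):
        for r in range(cfg.n_plot_rows):
            e0, n0 = origin_e + c * W, origin_n + r * L
            ring = [[round(e0, 3), round(n0, 3)],
                    [round(e0 + W, 3), round(n0, 3)],
                    [round(e0 + W, 3), round(n0 + L, 3)],
                    [round(e0, 3), round(n0 + L, 3)],
                    [round(e0, 3), round(n0, 3)]]
            idx = c * cfg.n_plot_rows + r
            features.append({
                "type": "Feature",
                "properties": {
                    "plot_id": _plot_id(r, c),
                    "line_id": f"L{(idx % cfg.n_lines) + 1:02d}",
                    "replicate": idx // cfg.n_lines + 1,
                    "treatment": "WW" if c % 2 == 0 else "WL",
                },
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            })
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": f"EPSG:{epsg}"}},
        "features": features,
    }
    path.write_text(json.dumps(doc, sort_keys=True) + "\n")


def simulate_manual_collection(n_plots: int, measurements_per_plot: int,
                               n_traits: int, seed: int = 0) -> pd.DataFrame:
    """Flat table emulating hand measurements.

    Returns exactly ``n_plots * measurements_per_plot * n_traits``
    records (plot_id, trait, measurement, value); used for throughput
    comparisons against the vehicle-based collection.
    """
    if min(n_plots, measurements_per_plot, n_traits) < 0:
        raise ConfigError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    names = [TRAIT_NAMES[i % len(TRAIT_NAMES)] for i in range(n_traits)]
    rows = []
    for p in range(n_plots):
        pid = str(1001 + p)
        for trait in names:
            for j in range(measurements_per_plot):
                rows.append((pid, trait, j + 1, round(float(rng.normal(0.0, 1.0)), 4)))
    return pd.DataFrame(rows, columns=["plot_id", "trait", "measurement", "value"])
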