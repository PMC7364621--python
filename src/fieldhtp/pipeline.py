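"""End-to-end pipeline: ingest -> georeference -> traits -> clip ->
store -> export -> QC1 -> QC2 -> plot means.

Each stage is a pure function of (inputs, config); a stage failure
stops the chain with the stage name attached and leaves the artefacts
of earlier stages intact.  The manifest lists every file produced with
its SHA-256 checksum, so a re-run on identical inputs is verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import georef, ingest, outliers, plotmap, qc, traits
from .outliers import ModelSpec
from .store import Store, file_inventory


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    run_dir: str
    plot_map: Optional[str] = None
    out_root: str = "out"
    store_path: Optional[str] = None  # default: <out_root>/fieldhtp.sqlite
    forced_zone: Optional[int] = None
    max_gap_ms: float = 200.0
    qc_ranges: Optional[dict] = None
    model: ModelSpec = field(default_factory=ModelSpec)
    max_pitch: Optional[float] = None
    max_roll: Optional[float] = None
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        model = doc.pop("model", None)
        cfg = cls(**doc)
        if model:
            cfg.model = ModelSpec(**model)
        return cfg

    def to_file(self, path) -> None:
        doc = {k: v for k, v in self.__dict__.items() if k != "model"}
        doc["model"] = dict(self.model.__dict__)
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def build_observations(raw: ingest.RawRun, forced_zone: Optional[int] = None,
                       max_gap_ms: float = 200.0) -> pd.DataFrame:
    """Georeference a parsed run and derive its traits (long table).

    One output row per sensor record per derived trait.  Records with
    no GPS fix or attitude sample within ``max_gap_ms`` keep their
    values but carry no coordinates (excluded from georeferencing and
    therefore from clipping).
    """
    meta = raw.metadata
    zone = forced_zone
    if zone is None and "utm_zone" in meta.extras:
        zone = int(meta.extras["utm_zone"])
    frames = []
    for stype, records in sorted(raw.records.items()):
        for sid, rec in records.groupby("sensor_id", sort=True):
            rec = rec.sort_values("logger_time", kind="stable").reset_index(drop=True)
            aligned = georef.align_streams(rec, raw.gps, raw.attitude, max_gap_ms)
            matched = aligned["matched"].to_numpy(dtype=bool)
            ve = np.full(len(aligned), np.nan)
            vn = np.full(len(aligned), np.nan)
            se = np.full(len(aligned), np.nan)
            sn = np.full(len(aligned), np.nan)
            used_zone = zone
            if matched.any():
                e, n, used_zone, hemi = georef.project_many(
                    aligned.loc[matched, "lat"].to_numpy(),
                    aligned.loc[matched, "lon"].to_numpy(),
                    forced_zone=zone)
                ve[matched] = e
                vn[matched] = n
                try:
                    off = meta.sensor(sid).offset
                except KeyError:
                    off = ingest.SensorOffset(0.0, 0.0)
                se_m, sn_m = georef.sensor_positions(
                    e, n, aligned.loc[matched, "yaw"].to_numpy(),
                    off.forward_m, off.lateral_m)
                se[matched] = se_m
                sn[matched] = sn_m
            else:
                hemi = meta.extras.get("hemisphere", "N")
            try:
                arm = meta.sensor(sid).boom_arm
            except KeyError:
                arm = ""
            base = pd.DataFrame({
                "sensor_id": sid, "sensor_type": stype, "boom_arm": arm,
                "logger_time": aligned["logger_time"],
                "vehicle_e": ve, "vehicle_n": vn,
                "sensor_e": se, "sensor_n": sn,
                "utm_zone": used_zone, "hemisphere": hemi,
                "yaw": aligned.get("yaw"), "pitch": aligned.get("pitch"),
                "roll": aligned.get("roll"),
                "matched": matched,
            })
            idx = np.arange(len(aligned))
            if stype == "ultrasonic":
                d = aligned["displacement_m"].to_numpy(dtype=float)
                h = traits.adjusted_height(meta.boom_height_s, d)
                df = base.copy()
                df["trait"] = "height"
                df["raw1"] = d
                df["raw2"] = np.nan
                df["raw3"] = np.nan
                df["value"] = h
                df["flag"] = traits.height_flags(meta.boom_height_s, d)
                df["obs_id"] = [f"{sid}:{i:06d}:height" for i in idx]
                frames.append(df)
            elif stype == "irt":
                df = base.copy()
                df["trait"] = "canopy_temp"
                df["raw1"] = aligned["canopy_temp_c"].to_numpy(dtype=float)
                df["raw2"] = aligned["body_temp_c"].to_numpy(dtype=float)
                df["raw3"] = np.nan
                df["value"] = df["raw1"]
                df["flag"] = np.where(np.isfinite(df["raw1"]), "", traits.FLAG_INVALID)
                df["obs_id"] = [f"{sid}:{i:06d}:canopy_temp" for i in idx]
                frames.append(df)
            elif stype == "reflectance":
                nir = aligned["rho_nir"].to_numpy(dtype=float)
                vis = aligned["rho_vis"].to_numpy(dtype=float)
                re_b = aligned["rho_re"].to_numpy(dtype=float)
                for trait_name, other, func in (
                        ("ndvi", vis, traits.ndvi_with_flags),
                        ("ndre", re_b, traits.ndre_with_flags)):
                    val, flg = func(nir, other)
                    df = base.copy()
                    df["trait"] = trait_name
                    df["raw1"] = nir
                    df["raw2"] = vis
                    df["raw3"] = re_b
                    df["value"] = val
                    df["flag"] = flg
                    df["obs_id"] = [f"{sid}:{i:06d}:{trait_name}" for i in idx]
                    frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["obs_id", "sensor_id", "sensor_type",
                                     "logger_time", "trait", "value"])
    obs = pd.concat(frames, ignore_index=True)
    cols = ["obs_id", "sensor_id", "sensor_type", "boom_arm", "logger_time",
            "trait", "raw1", "raw2", "raw3", "value", "flag",
            "vehicle_e", "vehicle_n", "sensor_e", "sensor_n",
            "utm_zone", "hemisphere", "yaw", "pitch", "roll", "matched"]
    return obs[cols]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain; returns the artifact manifest."""
    out_root = Path(config.out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []

    def _stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    raw = _stage("ingest", lambda: ingest.parse_run_directory(config.run_dir))
    run_id = raw.metadata.run_id
    cleaning_path = out_root / f"{run_id}_cleaning_report.csv"
    raw.cleaning.to_csv(cleaning_path, index=False)
    produced.append(cleaning_path)
    produced += sorted((Path(config.run_dir) / "clean").glob("*"))

    obs = _stage("process", lambda: build_observations(
        raw, config.forced_zone, config.max_gap_ms))

    pmap = None
    if config.plot_map is not None:
        def _clip():
            m = plotmap.load_plot_map(config.plot_map)
            clipped = plotmap.clip_observations(obs, m)
            clipped["row_deviation_m"] = plotmap.row_deviation(clipped, m)
            return m, clipped
        pmap, obs = _stage("clip", _clip)
    else:
        obs = obs.copy()
        obs["plot_id"] = None

    def _store_stage():
        store_path = config.store_path or str(out_root / "fieldhtp.sqlite")
        st = Store(store_path)
        inv = file_inventory(p for p in Path(config.run_dir).iterdir()
                             if p.is_file())
        st.stage_run(raw.metadata, obs, inventory=inv)
        st.promote_run(run_id)
        files = st.export_views(run_id, out_root)
        prod = st.fetch_production(run_id)
        st.close()
        return files, prod
    export_files, prod = _stage("store", _store_stage)
    produced += export_files

    def _qc1():
        qc_dir = out_root / "qc"
        qc_dir.mkdir(exist_ok=True)
        summary = qc.run_summary(prod, run_id, config.qc_ranges)
        flagged, report = qc.threshold_check(prod, config.qc_ranges)
        balance = qc.record_balance(prod)
        paths = []
        p = qc_dir / f"{run_id}_summary.csv"
        summary.per_sensor.to_csv(p, index=False)
        paths.append(p)
        p = qc_dir / f"{run_id}_threshold_report.csv"
        report.to_csv(p, index=False)
        paths.append(p)
        p = qc_dir / f"{run_id}_record_balance.csv"
        balance.to_csv(p, index=False)
        paths.append(p)
        p = qc_dir / f"{run_id}_qc1.json"
        p.write_text(json.dumps({
            "run_id": run_id,
            "duration_s": summary.duration_s,
            "sensors": summary.per_sensor.to_dict(orient="records"),
            "record_balance": balance.to_dict(orient="records"),
        }, indent=1, sort_keys=True, default=str) + "\n")
        paths.append(p)
        return paths
    produced += _stage("qc1", _qc1)

    def _qc2():
        cleaned_dir = out_root / "cleaned"
        cleaned_dir.mkdir(exist_ok=True)
        usable = prod[prod["value"].notna()]
        usable = usable[usable["plot_id"].notna()] if usable["plot_id"].notna().any() else usable
        kept_frames, diag_frames = [], []
        retained, removed_att = outliers.attitude_filter(
            usable, config.max_pitch, config.max_roll)
        for trait_name, sub in retained.groupby("trait", sort=True):
            spec = ModelSpec(response=config.model.response,
                             factors=list(config.model.factors),
                             tau=config.model.tau,
                             max_iterations=config.model.max_iterations,
                             bonferroni=config.model.bonferroni)
            cleaned, diag, _ = outliers.remove_outliers(sub, spec)
            kept_frames.append(cleaned)
            diag = diag.copy()
            diag.insert(0, "obs_id", sub["obs_id"].to_numpy())
            diag.insert(1, "trait", trait_name)
            diag_frames.append(diag)
        cleaned_all = pd.concat(kept_frames, ignore_index=True) if kept_frames else usable.iloc[0:0]
        diag_all = pd.concat(diag_frames, ignore_index=True) if diag_frames else pd.DataFrame()
        paths = []
        p = cleaned_dir / f"{run_id}_cleaned.csv"
        cleaned_all.to_csv(p, index=False, float_format="%.6f")
        paths.append(p)
        p = cleaned_dir / f"{run_id}_outlier_diagnostics.csv"
        diag_all.to_csv(p, index=False, float_format="%.6f")
        paths.append(p)
        if len(removed_att):
            p = cleaned_dir / f"{run_id}_attitude_removed.csv"
            removed_att.to_csv(p, index=False, float_format="%.6f")
            paths.append(p)
        return cleaned_all, paths
    cleaned_all, qc2_paths = _stage("qc2", _qc2)
    produced += qc2_paths

    def _means():
        universe = pmap.plot_ids if pmap is not None else None
        means = outliers.plot_means(cleaned_all, plot_universe=universe)
        p = out_root / f"{run_id}_plot_means.csv"
        means.to_csv(p, index=False, float_format="%.6f")
        return p
    produced.append(_stage("means", _means))

    manifest = {
        "run_id": run_id,
        "stages": ["ingest", "process", "clip" if pmap is not None else "clip(skipped)",
                   "store", "qc1", "qc2", "means"],
        "files": [{"path": str(p), "sha256": _sha256(Path(p))}
                  for p in produced if Path(p).is_file()],
    }
    mpath = out_root / f"{run_id}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
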