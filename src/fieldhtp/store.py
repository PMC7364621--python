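"""Transactional observation store: Staging -> Production -> Public.

A run is first *staged* (bulk insert of its cleaned, georeferenced
trait observations), then *promoted* in a single transaction that
creates the permanent ``sensorrun`` record, moves every staged row into
production linked to it, and empties staging -- all-or-nothing, so a
partial load can never contaminate analysis.  The Public area is a set
of read-only views over production.  Exports re-create the per-sensor
``processed/`` and ``clipped/`` CSV products deterministically.

The default backing engine is embedded SQLite; the DDL (shipped as
``schema.sql``) is kept portable to a PostgreSQL deployment.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from dataclasses import dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .ingest import RunMetadata

VERSION_TAG = "fieldhtp-0.1.0"

# sqlite3 does not bind numpy scalar types natively (np.float64 aside);
# register adapters once so DataFrame rows insert directly.
for _np_t, _py_t in ((np.int64, int), (np.int32, int), (np.intp, int),
                     (np.float64, float), (np.float32, float),
                     (np.bool_, bool)):
    sqlite3.register_adapter(_np_t, _py_t)

OBS_COLUMNS = [
    "obs_id", "run_id", "sensor_id", "sensor_type", "boom_arm", "logger_time",
    "trait", "raw1", "raw2", "raw3", "value", "flag", "vehicle_e", "vehicle_n",
    "sensor_e", "sensor_n", "utm_zone", "hemisphere", "plot_id",
    "yaw", "pitch", "roll",
]


class StoreError(RuntimeError):
    pass


class DuplicateRunError(StoreError):
    pass


@dataclass
class PromotionFailure(Exception):
    """Raised by an injected failpoint during promotion (testing hook)."""

    point: str


def schema_sql() -> str:
    return resources.files("fieldhtp").joinpath("schema.sql").read_text()


def file_inventory(paths) -> list[dict]:
    inv = []
    for p in sorted(Path(p) for p in paths):
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        inv.append({"file": p.name, "sha256": digest})
    return inv


class Store:
    """Embedded store with all-or-nothing staging and promotion."""

    def __init__(self, path=":memory:"):
        self.path = str(path)
        self._con = sqlite3.connect(self.path)
        self._con.isolation_level = None  # manual BEGIN/COMMIT
        self._con.execute("PRAGMA foreign_keys = ON")
        self._con.executescript(schema_sql())

    def close(self) -> None:
        self._con.close()

    # ------------------------------------------------------------- staging
    def stage_run(self, metadata: RunMetadata, observations: pd.DataFrame,
                  inventory: Optional[list[dict]] = None) -> int:
        """Insert a run's observations into staging, atomically.

        Nothing becomes visible in production.  A schema mismatch (a
        missing required column) stages nothing.
        """
        required = {"obs_id", "sensor_id", "sensor_type", "logger_time",
                    "trait", "value"}
        missing = required - set(observations.columns)
        if missing:
            raise StoreError(f"observation table lacks columns {sorted(missing)}")
        if self.staged_count(metadata.run_id):
            raise DuplicateRunError(f"run {metadata.run_id!r} already staged")
        if self._con.execute("SELECT 1 FROM sensorrun WHERE run_id = ?",
                             (metadata.run_id,)).fetchone():
            raise DuplicateRunError(f"run {metadata.run_id!r} already promoted")
        df = observations.copy()
        df["run_id"] = metadata.run_id
        for col in OBS_COLUMNS:
            if col not in df.columns:
                df[col] = None
        df = df[OBS_COLUMNS]
        if np.issubdtype(df["logger_time"].dtype, np.datetime64):
            df["logger_time"] = df["logger_time"].dt.strftime("%Y-%m-%d %H:%M:%S.%f")
        cur = self._con.cursor()
        try:
            cur.execute("BEGIN")
            cur.execute(
                "INSERT INTO staging_sensorrun VALUES (?,?,?,?,?,?,?,?,?)",
                (metadata.run_id, metadata.date, metadata.time,
                 metadata.field_id, metadata.operator, metadata.boom_height_s,
                 metadata.wheel_spacing, metadata.notes,
                 json.dumps(inventory or [])),
            )
            cur.executemany(
                f"INSERT INTO staging_observation VALUES "
                f"({','.join('?' * len(OBS_COLUMNS))})",
                df.itertuples(index=False, name=None),
            )
            cur.execute("COMMIT")
        except Exception:
            cur.execute("ROLLBACK")
            raise
        return len(df)

    # ----------------------------------------------------------- promotion
    def promote_run(self, run_id: str,
                    failpoint: Optional[Callable[[str], None]] = None) -> int:
        """Move a staged run into production, transactionally.

        Creates the permanent sensorrun record, copies every staged row
        into production linked to it, and deletes the staging rows.  On
        any failure (including injected ``failpoint`` callbacks, used to
        test atomicity) both areas are left exactly as they were.
        """
        fp = failpoint or (lambda point: None)
        cur = self._con.cursor()
        row = cur.execute(
            "SELECT * FROM staging_sensorrun WHERE run_id = ?", (run_id,)
        ).fetchone()
        if row is None:
            raise StoreError(f"run {run_id!r} is not staged")
        if cur.execute("SELECT 1 FROM sensorrun WHERE run_id = ?",
                       (run_id,)).fetchone():
            raise DuplicateRunError(f"run {run_id!r} already promoted")
        try:
            cur.execute("BEGIN")
            fp("begin")
            cur.execute(
                "INSERT INTO sensorrun SELECT run_id, collected_date, "
                "collected_time, field_id, operator, boom_height_s, "
                "wheel_spacing, notes, ?, ?, file_inventory "
                "FROM staging_sensorrun WHERE run_id = ?",
                (datetime.now(timezone.utc).isoformat(), VERSION_TAG, run_id),
            )
            fp("after_sensorrun")
            cur.execute(
                "INSERT INTO production_observation "
                "SELECT * FROM staging_observation WHERE run_id = ?",
                (run_id,),
            )
            fp("after_copy")
            n = cur.execute(
                "SELECT COUNT(*) FROM production_observation WHERE run_id = ?",
                (run_id,),
            ).fetchone()[0]
            cur.execute("DELETE FROM staging_observation WHERE run_id = ?", (run_id,))
            cur.execute("DELETE FROM staging_sensorrun WHERE run_id = ?", (run_id,))
            fp("after_clear")
            cur.execute("COMMIT")
        except Exception:
            cur.execute("ROLLBACK")
            raise
        return n

    # ------------------------------------------------------------- queries
    def staged_count(self, run_id: Optional[str] = None) -> int:
        q = "SELECT COUNT(*) FROM staging_observation"
        args: tuple = ()
        if run_id is not None:
            q += " WHERE run_id = ?"
            args = (run_id,)
        return self._con.execute(q, args).fetchone()[0]

    def production_count(self, run_id: Optional[str] = None) -> int:
        q = "SELECT COUNT(*) FROM production_observation"
        args: tuple = ()
        if run_id is not None:
            q += " WHERE run_id = ?"
            args = (run_id,)
        return self._con.execute(q, args).fetchone()[0]

    def run_ids(self) -> list[str]:
        rows = self._con.execute(
            "SELECT run_id FROM sensorrun ORDER BY run_id").fetchall()
        return [r[0] for r in rows]

    def fetch_production(self, run_id: str) -> pd.DataFrame:
        df = pd.read_sql_query(
            "SELECT * FROM production_observation WHERE run_id = ? "
            "ORDER BY trait, sensor_id, obs_id",
            self._con, params=(run_id,),
        )
        if len(df):
            df["logger_time"] = pd.to_datetime(df["logger_time"])
        return df

    def fetch_public(self, sensor_type: Optional[str] = None) -> pd.DataFrame:
        if sensor_type is None:
            return pd.read_sql_query(
                "SELECT * FROM public_observation ORDER BY run_id, trait, obs_id",
                self._con)
        return pd.read_sql_query(
            "SELECT * FROM public_observation WHERE sensor_type = ? "
            "ORDER BY run_id, trait, obs_id", self._con, params=(sensor_type,))

    # -------------------------------------------------------------- export
    def export_views(self, run_id: str, out_dir) -> list[Path]:
        """Write the per-sensor-type CSV products for a promoted run.

        ``processed/`` always; ``clipped/`` (rows inside a plot) only
        when any observation carries a plot assignment.  Row order and
        float formatting are fixed, so re-export is byte-identical.
        """
        if run_id not in self.run_ids():
            raise StoreError(f"unknown run {run_id!r}")
        out_dir = Path(out_dir)
        produced: list[Path] = []
        df = self.fetch_production(run_id)
        df = df.sort_values(["sensor_type", "trait", "sensor_id", "obs_id"],
                            kind="stable")
        has_plots = df["plot_id"].notna().any()
        (out_dir / "processed").mkdir(parents=True, exist_ok=True)
        if has_plots:
            (out_dir / "clipped").mkdir(parents=True, exist_ok=True)
        for stype, sub in df.groupby("sensor_type", sort=True):
            sub = sub.copy()
            sub["logger_time"] = sub["logger_time"].dt.strftime("%Y-%m-%d %H:%M:%S.%f")
            p = out_dir / "processed" / f"{run_id}_{stype}.csv"
            sub.to_csv(p, index=False, float_format="%.6f")
            produced.append(p)
            if has_plots:
                clipped = sub[sub["plot_id"].notna()]
                p2 = out_dir / "clipped" / f"{run_id}_{stype}.csv"
                clipped.to_csv(p2, index=False, float_format="%.6f")
                produced.append(p2)
        return produced
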