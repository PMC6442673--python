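"""Persistent storage of analyses in a single-file SQL database.

The schema keeps one row per experiment (source file and calibration), its
stages with their summary statistics, the serialized detection parameters,
one row per spark with a globally unique ID, and — for synthetic runs —
the ground-truth spark list.  Global spark IDs (UUIDs) make it safe to
pool sparks from many experiments in one database.  The file database is
created on first use; deleting an experiment cascades to all its rows.
"""

from __future__ import annotations

import csv
import json
import sqlite3
import uuid
from dataclasses import dataclass
from datetime import datetime, timezone

import pandas as pd

from .core import DetectionParams, ExperimentStage, StageStatistics

__all__ = ["SCHEMA_VERSION", "SparkDatabase"]

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS schema_version (version INTEGER NOT NULL);

CREATE TABLE IF NOT EXISTS experiment (
    id TEXT PRIMARY KEY,
    filename TEXT NOT NULL,
    pixel_size_um REAL NOT NULL,
    line_interval_ms REAL NOT NULL,
    dark_count REAL NOT NULL,
    created_at TEXT NOT NULL
);

CREATE TABLE IF NOT EXISTS stage (
    id TEXT PRIMARY KEY,
    experiment_id TEXT NOT NULL REFERENCES experiment(id) ON DELETE CASCADE,
    start_line INTEGER NOT NULL,
    end_line INTEGER NOT NULL,
    label TEXT,
    mean REAL, minimum REAL, maximum REAL, p001 REAL, p999 REAL
);

CREATE TABLE IF NOT EXISTS parameters (
    experiment_id TEXT PRIMARY KEY REFERENCES experiment(id) ON DELETE CASCADE,
    params_json TEXT NOT NULL
);

CREATE TABLE IF NOT EXISTS spark (
    id TEXT PRIMARY KEY,
    experiment_id TEXT NOT NULL REFERENCES experiment(id) ON DELETE CASCADE,
    stage_id TEXT REFERENCES stage(id) ON DELETE CASCADE,
    x0 INTEGER, x1 INTEGER, t0 INTEGER, t1 INTEGER,
    peak_x_px INTEGER, peak_t_px INTEGER,
    peak_x_um REAL, peak_t_ms REAL,
    amplitude REAL,
    fwhm_um REAL,
    fdhm_ms REAL,
    fit_params_json TEXT,
    accepted INTEGER NOT NULL DEFAULT 1
);

CREATE TABLE IF NOT EXISTS ground_truth (
    id TEXT PRIMARY KEY,
    experiment_id TEXT NOT NULL REFERENCES experiment(id) ON DELETE CASCADE,
    x_center_um REAL NOT NULL,
    t_center_ms REAL NOT NULL,
    amplitude REAL NOT NULL
);
"""

TABLES = ("experiment", "stage", "parameters", "spark", "ground_truth")


@dataclass
class SparkRecord:
    """Flat spark row for storage: ROI box, peak, fitted morphology."""

    x0: int
    x1: int
    t0: int
    t1: int
    peak_x_px: int
    peak_t_px: int
    peak_x_um: float
    peak_t_ms: float
    amplitude: float
    fwhm_um: float
    fdhm_ms: float
    fit_params: dict | None = None
    accepted: bool = True


class SparkDatabase:
    """A single-file spark analysis database.

    Opens (creating if necessary) an SQLite file; ``:memory:`` is accepted
    for ephemeral use.  Foreign keys and cascading deletes are enforced.
    """

    def __init__(self, path) -> None:
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        self.conn.executescript(_SCHEMA)
        cur = self.conn.execute("SELECT version FROM schema_version")
        row = cur.fetchone()
        if row is None:
            self.conn.execute("INSERT INTO schema_version VALUES (?)", (SCHEMA_VERSION,))
            self.conn.commit()
        elif row[0] != SCHEMA_VERSION:
            raise RuntimeError(
                f"database schema version {row[0]} != supported {SCHEMA_VERSION}; "
                "migrate before use"
            )

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "SparkDatabase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- writing ---------------------------------------------------------

    def save_analysis(
        self,
        filename: str,
        pixel_size_um: float,
        line_interval_ms: float,
        dark_count: float,
        stages: list[tuple[ExperimentStage, StageStatistics | None]],
        params: DetectionParams,
        sparks: list[SparkRecord],
        spark_stage_index: int = 0,
        ground_truth: pd.DataFrame | None = None,
    ) -> dict:
        """Insert one analyzed experiment transactionally.

        Re-saving an experiment with the same ``filename`` replaces it
        (and, through cascades, all its sparks).  Returns the new ids.
        """
        with self.conn:
            old = self.conn.execute(
                "SELECT id FROM experiment WHERE filename = ?", (filename,)
            ).fetchall()
            for (old_id,) in old:
                self.conn.execute("DELETE FROM experiment WHERE id = ?", (old_id,))
            exp_id = str(uuid.uuid4())
            self.conn.execute(
                "INSERT INTO experiment VALUES (?,?,?,?,?,?)",
                (
                    exp_id,
                    filename,
                    pixel_size_um,
                    line_interval_ms,
                    dark_count,
                    datetime.now(timezone.utc).isoformat(),
                ),
            )
            stage_ids = []
            for stage, stats in stages:
                sid = str(uuid.uuid4())
                stage_ids.append(sid)
                s = stats or StageStatistics(*(float("nan"),) * 5)
                self.conn.execute(
                    "INSERT INTO stage VALUES (?,?,?,?,?,?,?,?,?,?)",
                    (
                        sid,
                        exp_id,
                        stage.start_line,
                        stage.end_line,
                        stage.label,
                        s.mean,
                        s.minimum,
                        s.maximum,
                        s.p001,
                        s.p999,
                    ),
                )
            self.conn.execute(
                "INSERT INTO parameters VALUES (?,?)",
                (exp_id, json.dumps(params.to_dict())),
            )
            spark_stage = stage_ids[spark_stage_index] if stage_ids else None
            spark_ids = []
            for rec in sparks:
                spid = str(uuid.uuid4())
                spark_ids.append(spid)
                self.conn.execute(
                    "INSERT INTO spark VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                    (
                        spid,
                        exp_id,
                        spark_stage,
                        rec.x0,
                        rec.x1,
                        rec.t0,
                        rec.t1,
                        rec.peak_x_px,
                        rec.peak_t_px,
                        rec.peak_x_um,
                        rec.peak_t_ms,
                        rec.amplitude,
                        rec.fwhm_um,
                        rec.fdhm_ms,
                        json.dumps(rec.fit_params) if rec.fit_params else None,
                        int(rec.accepted),
                    ),
                )
            if ground_truth is not None:
                for _, row in ground_truth.iterrows():
                    self.conn.execute(
                        "INSERT INTO ground_truth VALUES (?,?,?,?,?)",
                        (
                            str(uuid.uuid4()),
                            exp_id,
                            float(row["x_center_um"]),
                            float(row["t_center_ms"]),
                            float(row["amplitude"]),
                        ),
                    )
        return {"experiment": exp_id, "stages": stage_ids, "sparks": spark_ids}

    def delete_experiment(self, experiment_id: str) -> None:
        with self.conn:
            self.conn.execute("DELETE FROM experiment WHERE id = ?", (experiment_id,))

    # -- reading ---------------------------------------------------------

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLES:
            raise ValueError(f"unknown table {name!r}; available: {', '.join(TABLES)}")
        return pd.read_sql_query(f"SELECT * FROM {name}", self.conn)

    def sparks(self, experiment_id: str | None = None) -> pd.DataFrame:
        q = "SELECT * FROM spark"
        args: tuple = ()
        if experiment_id is not None:
            q += " WHERE experiment_id = ?"
            args = (experiment_id,)
        return pd.read_sql_query(q, self.conn, params=args)

    def export_table(self, name: str, path) -> int:
        """Write one table as CSV (header row, full float precision).

        Returns the number of data rows written.
        """
        if name not in TABLES:
            raise ValueError(f"unknown table {name!r}; available: {', '.join(TABLES)}")
        cur = self.conn.execute(f"SELECT * FROM {name}")
        header = [c[0] for c in cur.description]
        n = 0
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for row in cur:
                writer.writerow([repr(v) if isinstance(v, float) else v for v in row])
                n += 1
        return n
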