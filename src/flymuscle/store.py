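"""Embedded relational store for stacks, ROIs, features, and tracks.

A single-file SQLite database mirrors the two-table-group layout of the
original MySQL design: a *metadata* group (stacks with their acquisition
parameters and identity, reference frames, environment readings) and a
*segmentation* group (ROI geometry, nuclear regions, features, tracks).
A stack is uniquely identified by its name together with the triple
(stock id, acquisition date, sample location).  Pixel data never enter the
database — only file paths relative to a root folder are stored.  Polygons
are serialized as JSON vertex arrays (queryable and diffable, unlike
opaque blobs) and masks as JSON run-length encodings.
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, MigrationError
from .imaging import AcquisitionMetadata, EnvironmentLog
from .segmentation import MuscleROI, NuclearRegion
from .morphometry import FEATURE_NAMES, FeatureVector
from .tracking import CellAnnotation, Track

SCHEMA_VERSION = 1

_SCHEMA = f"""
CREATE TABLE IF NOT EXISTS schema_meta (
    key TEXT PRIMARY KEY, value TEXT NOT NULL
);
-- metadata group -----------------------------------------------------------
CREATE TABLE IF NOT EXISTS stacks (
    stack_id INTEGER PRIMARY KEY,
    stack_name TEXT NOT NULL,
    stock_id TEXT NOT NULL,
    genotype TEXT NOT NULL,
    acquisition_date TEXT NOT NULL,
    sample_location TEXT NOT NULL,
    pixel_size_um REAL NOT NULL CHECK (pixel_size_um > 0),
    frame_interval_min REAL NOT NULL CHECK (frame_interval_min > 0),
    z_step_um REAL,
    magnification TEXT,
    bit_depth INTEGER,
    layout TEXT,
    image_path TEXT,
    UNIQUE (stack_name, stock_id, acquisition_date, sample_location)
);
CREATE TABLE IF NOT EXISTS reference_frames (
    stack_id INTEGER PRIMARY KEY REFERENCES stacks(stack_id),
    midline TEXT NOT NULL,
    anterior_point TEXT NOT NULL,
    thorax_abdomen_boundary TEXT NOT NULL,
    rotation_deg REAL NOT NULL,
    he_frame INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS environment_samples (
    stack_id INTEGER NOT NULL REFERENCES stacks(stack_id),
    timestamp TEXT NOT NULL,
    temperature_c REAL,
    humidity_rh REAL,
    UNIQUE (stack_id, timestamp)
);
-- segmentation group -------------------------------------------------------
CREATE TABLE IF NOT EXISTS rois (
    roi_id INTEGER PRIMARY KEY,
    stack_id INTEGER NOT NULL REFERENCES stacks(stack_id),
    frame_idx INTEGER NOT NULL,
    polygon TEXT NOT NULL,
    mask_rle TEXT NOT NULL,
    mask_shape TEXT NOT NULL,
    centroid_x REAL NOT NULL,
    centroid_y REAL NOT NULL,
    source TEXT NOT NULL CHECK (source IN ('levelset', 'manual')),
    cell_type TEXT,
    body_part TEXT,
    segment INTEGER,
    lateral TEXT
);
CREATE TABLE IF NOT EXISTS nuclear_regions (
    region_id INTEGER PRIMARY KEY,
    roi_id INTEGER NOT NULL REFERENCES rois(roi_id),
    mask_rle TEXT NOT NULL,
    mask_shape TEXT NOT NULL,
    area_px INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS features (
    roi_id INTEGER PRIMARY KEY REFERENCES rois(roi_id),
    {', '.join(f'{name} REAL' for name in FEATURE_NAMES)}
);
CREATE TABLE IF NOT EXISTS tracks (
    track_id INTEGER PRIMARY KEY,
    stack_id INTEGER NOT NULL REFERENCES stacks(stack_id)
);
CREATE TABLE IF NOT EXISTS track_elements (
    track_id INTEGER NOT NULL REFERENCES tracks(track_id),
    frame_idx INTEGER NOT NULL,
    roi_id INTEGER NOT NULL REFERENCES rois(roi_id),
    UNIQUE (track_id, frame_idx)
);
"""


def _rle_encode(mask: np.ndarray) -> str:
    flat = np.asarray(mask, bool).ravel()
    if flat.size == 0:
        return json.dumps([[], []])
    # runs of (start, length) over the flattened mask
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = []
    lengths = []
    prev = 0
    val = bool(flat[0]) if flat.size else False
    for c in np.concatenate([changes + 1, [flat.size]]):
        if val:
            starts.append(int(prev))
            lengths.append(int(c - prev))
        prev = int(c)
        val = not val
    return json.dumps([starts, lengths])


def _rle_decode(rle: str, shape: tuple[int, int]) -> np.ndarray:
    starts, lengths = json.loads(rle)
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for s, l in zip(starts, lengths):
        flat[s : s + l] = True
    return flat.reshape(shape)


class Store:
    """Handle on an open single-file pipeline database."""

    def __init__(self, conn: sqlite3.Connection):
        self.conn = conn
        self.conn.execute("PRAGMA foreign_keys = ON")

    # -- lifecycle ---------------------------------------------------------

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- stacks ------------------------------------------------------------

    def upsert_stack(self, meta: AcquisitionMetadata, image_path: str = "") -> int:
        """Insert a stack or return the key of an identical existing one.

        The same identity with conflicting non-identity metadata raises
        :class:`IntegrityError`.
        """
        cur = self.conn.execute(
            "SELECT * FROM stacks WHERE stack_name=? AND stock_id=? AND "
            "acquisition_date=? AND sample_location=?",
            meta.identity,
        )
        row = cur.fetchone()
        if row is not None:
            cols = [d[0] for d in cur.description]
            existing = dict(zip(cols, row))
            for key in ("genotype", "pixel_size_um", "frame_interval_min"):
                if existing[key] != getattr(meta, key):
                    raise IntegrityError(
                        f"stack {meta.identity} already stored with different {key}"
                    )
            return int(existing["stack_id"])
        cur = self.conn.execute(
            "INSERT INTO stacks (stack_name, stock_id, genotype, acquisition_date,"
            " sample_location, pixel_size_um, frame_interval_min, z_step_um,"
            " magnification, bit_depth, layout, image_path)"
            " VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
            (
                meta.stack_name,
                meta.stock_id,
                meta.genotype,
                meta.acquisition_date,
                meta.sample_location,
                meta.pixel_size_um,
                meta.frame_interval_min,
                meta.z_step_um,
                meta.magnification,
                meta.bit_depth,
                meta.layout,
                str(image_path),
            ),
        )
        self.conn.commit()
        return int(cur.lastrowid)

    def delete_stack(self, stack_id: int, cascade: bool = False) -> None:
        if not cascade:
            n = self.conn.execute(
                "SELECT COUNT(*) FROM rois WHERE stack_id=?", (stack_id,)
            ).fetchone()[0]
            if n:
                raise IntegrityError(
                    f"stack {stack_id} still has {n} ROIs; pass cascade=True to remove"
                )
        else:
            roi_ids = [
                r[0]
                for r in self.conn.execute(
                    "SELECT roi_id FROM rois WHERE stack_id=?", (stack_id,)
                )
            ]
            qmarks = ",".join("?" * len(roi_ids))
            if roi_ids:
                self.conn.execute(
                    f"DELETE FROM nuclear_regions WHERE roi_id IN ({qmarks})", roi_ids
                )
                self.conn.execute(f"DELETE FROM features WHERE roi_id IN ({qmarks})", roi_ids)
                self.conn.execute(
                    f"DELETE FROM track_elements WHERE roi_id IN ({qmarks})", roi_ids
                )
            self.conn.execute(
                "DELETE FROM tracks WHERE stack_id=?", (stack_id,)
            )
            self.conn.execute("DELETE FROM rois WHERE stack_id=?", (stack_id,))
        self.conn.execute("DELETE FROM reference_frames WHERE stack_id=?", (stack_id,))
        self.conn.execute("DELETE FROM environment_samples WHERE stack_id=?", (stack_id,))
        self.conn.execute("DELETE FROM stacks WHERE stack_id=?", (stack_id,))
        self.conn.commit()

    # -- reference frames / environment -------------------------------------

    def save_reference_frame(self, stack_id: int, frame) -> None:
        from .registration import ReferenceFrame  # local import to avoid cycle

        assert isinstance(frame, ReferenceFrame)
        self.conn.execute(
            "INSERT OR REPLACE INTO reference_frames VALUES (?,?,?,?,?,?)",
            (
                stack_id,
                json.dumps(frame.midline.tolist()),
                json.dumps(frame.anterior_point.tolist()),
                json.dumps(frame.thorax_abdomen_boundary.tolist()),
                float(frame.rotation_deg),
                int(frame.he_frame),
            ),
        )
        self.conn.commit()

    def load_reference_frame(self, stack_id: int):
        from .registration import ReferenceFrame

        row = self.conn.execute(
            "SELECT midline, anterior_point, thorax_abdomen_boundary, rotation_deg,"
            " he_frame FROM reference_frames WHERE stack_id=?",
            (stack_id,),
        ).fetchone()
        if row is None:
            raise KeyError(f"no reference frame for stack {stack_id}")
        interval = self.conn.execute(
            "SELECT frame_interval_min FROM stacks WHERE stack_id=?", (stack_id,)
        ).fetchone()[0]
        return ReferenceFrame(
            midline=np.array(json.loads(row[0])),
            anterior_point=np.array(json.loads(row[1])),
            thorax_abdomen_boundary=np.array(json.loads(row[2])),
            rotation_deg=float(row[3]),
            he_frame=int(row[4]),
            frame_interval_min=float(interval),
        )

    def save_environment_log(self, stack_id: int, log: EnvironmentLog) -> None:
        for _, row in log.samples.iterrows():
            self.conn.execute(
                "INSERT OR REPLACE INTO environment_samples VALUES (?,?,?,?)",
                (stack_id, str(row["timestamp"]), row["temperature_c"], row["humidity_rh"]),
            )
        self.conn.commit()

    # -- ROIs ----------------------------------------------------------------

    def save_rois(self, stack_id: int, rois: Sequence[MuscleROI]) -> None:
        exists = self.conn.execute(
            "SELECT 1 FROM stacks WHERE stack_id=?", (stack_id,)
        ).fetchone()
        if exists is None:
            raise IntegrityError(f"stack {stack_id} does not exist")
        for roi in rois:
            ann = roi.annotation
            self.conn.execute(
                "INSERT OR REPLACE INTO rois VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?)",
                (
                    roi.roi_id,
                    stack_id,
                    roi.frame_idx,
                    json.dumps(roi.polygon.tolist()),
                    _rle_encode(roi.mask),
                    json.dumps(list(roi.mask.shape)),
                    roi.centroid[0],
                    roi.centroid[1],
                    roi.source,
                    ann.cell_type if ann else None,
                    ann.body_part if ann else None,
                    ann.segment if ann else None,
                    ann.lateral if ann else None,
                ),
            )
        self.conn.commit()

    def load_rois(
        self, stack_id: int, frames: Iterable[int] | None = None
    ) -> list[MuscleROI]:
        exists = self.conn.execute(
            "SELECT 1, stack_name FROM stacks WHERE stack_id=?", (stack_id,)
        ).fetchone()
        if exists is None:
            raise KeyError(f"stack {stack_id} does not exist")
        stack_name = exists[1]
        q = "SELECT roi_id, frame_idx, polygon, mask_rle, mask_shape, centroid_x," \
            " centroid_y, source, cell_type, body_part, segment, lateral" \
            " FROM rois WHERE stack_id=?"
        args: list = [stack_id]
        if frames is not None:
            frames = list(frames)
            q += f" AND frame_idx IN ({','.join('?' * len(frames))})"
            args += frames
        q += " ORDER BY roi_id"
        out = []
        for row in self.conn.execute(q, args):
            ann = None
            if row[8] is not None:
                ann = CellAnnotation(
                    cell_type=row[8], body_part=row[9], segment=row[10], lateral=row[11]
                )
            shape = tuple(json.loads(row[4]))
            out.append(
                MuscleROI(
                    roi_id=row[0],
                    stack_name=stack_name,
                    frame_idx=row[1],
                    polygon=np.array(json.loads(row[2])),
                    mask=_rle_decode(row[3], shape),
                    centroid=(row[5], row[6]),
                    source=row[7],
                    annotation=ann,
                )
            )
        return out

    def save_nuclear_regions(self, regions: Sequence[NuclearRegion]) -> None:
        for r in regions:
            self.conn.execute(
                "INSERT INTO nuclear_regions (roi_id, mask_rle, mask_shape, area_px)"
                " VALUES (?,?,?,?)",
                (r.parent_roi, _rle_encode(r.mask), json.dumps(list(r.mask.shape)), r.area_px),
            )
        self.conn.commit()

    # -- features / tracks ---------------------------------------------------

    def save_features(self, vectors: Sequence[FeatureVector]) -> None:
        cols = ", ".join(FEATURE_NAMES)
        q = f"INSERT OR REPLACE INTO features (roi_id, {cols}) VALUES (?,{','.join('?' * len(FEATURE_NAMES))})"
        for v in vectors:
            roi_exists = self.conn.execute(
                "SELECT 1 FROM rois WHERE roi_id=?", (v.roi_id,)
            ).fetchone()
            if roi_exists is None:
                raise IntegrityError(f"feature row references missing ROI {v.roi_id}")
            self.conn.execute(q, (v.roi_id, *[getattr(v, n) for n in FEATURE_NAMES]))
        self.conn.commit()

    def save_tracks(self, stack_id: int, tracks: Sequence[Track]) -> None:
        for t in tracks:
            self.conn.execute(
                "INSERT OR REPLACE INTO tracks (track_id, stack_id) VALUES (?,?)",
                (t.track_id, stack_id),
            )
            self.conn.execute("DELETE FROM track_elements WHERE track_id=?", (t.track_id,))
            for f, rid in zip(t.frames, t.roi_ids):
                self.conn.execute(
                    "INSERT INTO track_elements VALUES (?,?,?)", (t.track_id, f, rid)
                )
        self.conn.commit()

    # -- queries -------------------------------------------------------------

    def query_features(
        self,
        genotype: str | None = None,
        cell_type: str | None = None,
        t_min_h: float | None = None,
        t_max_h: float | None = None,
    ) -> pd.DataFrame:
        """Tidy table joining stacks, ROIs, annotations, features and hours AHE.

        Time filters require a stored reference frame (hours AHE is computed
        from the head-eversion frame and the frame interval).
        """
        q = (
            "SELECT s.stack_name, s.genotype, s.pixel_size_um, r.roi_id, r.frame_idx,"
            " r.cell_type, r.body_part, r.segment, r.lateral,"
            " rf.he_frame, s.frame_interval_min, "
            + ", ".join(f"f.{n}" for n in FEATURE_NAMES)
            + " FROM rois r JOIN stacks s ON r.stack_id = s.stack_id"
            " JOIN features f ON f.roi_id = r.roi_id"
            " LEFT JOIN reference_frames rf ON rf.stack_id = s.stack_id WHERE 1=1"
        )
        args: list = []
        if genotype is not None:
            q += " AND s.genotype = ?"
            args.append(genotype)
        if cell_type is not None:
            q += " AND r.cell_type = ?"
            args.append(cell_type)
        df = pd.read_sql_query(q, self.conn, params=args)
        he = df["he_frame"].astype(float).fillna(0.0)
        df["hours_ahe"] = (df["frame_idx"] - he) * df["frame_interval_min"] / 60.0
        if t_min_h is not None:
            df = df[df["hours_ahe"] >= t_min_h]
        if t_max_h is not None:
            df = df[df["hours_ahe"] <= t_max_h]
        return df.drop(columns=["he_frame", "frame_interval_min"]).reset_index(drop=True)

    def export_table(self, table: str, path: str | Path) -> None:
        allowed = {
            "stacks",
            "reference_frames",
            "environment_samples",
            "rois",
            "nuclear_regions",
            "features",
            "tracks",
            "track_elements",
        }
        if table not in allowed:
            raise KeyError(f"unknown table {table!r}")
        pd.read_sql_query(f"SELECT * FROM {table}", self.conn).to_csv(path, index=False)


def init_store(path: str | Path | None = None) -> Store:
    """Create (idempotently) or open a pipeline database.

    ``path=None`` opens an in-memory store.  Opening a store written by a
    newer schema raises :class:`MigrationError`.
    """
    conn = sqlite3.connect(str(path) if path is not None else ":memory:")
    conn.execute("PRAGMA foreign_keys = ON")
    row = conn.execute(
        "SELECT name FROM sqlite_master WHERE type='table' AND name='schema_meta'"
    ).fetchone()
    if row is not None:
        version = int(
            conn.execute(
                "SELECT value FROM schema_meta WHERE key='schema_version'"
            ).fetchone()[0]
        )
        if version > SCHEMA_VERSION:
            conn.close()
            raise MigrationError(
                f"store written by schema version {version}, this build supports {SCHEMA_VERSION}"
            )
    conn.executescript(_SCHEMA)
    conn.execute(
        "INSERT OR IGNORE INTO schema_meta VALUES ('schema_version', ?)",
        (str(SCHEMA_VERSION),),
    )
    conn.commit()
    return Store(conn)
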