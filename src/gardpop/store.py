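"""Persist trajectories to SQLite and export flat CSV tables.

Schema (one database per run):

* ``run_meta(key, value)`` — configuration (JSON), volume, stop reason, etc.
* ``catalog(...)`` — the full species parameter table.
* ``vesicle_snapshots(iteration, time_s, vesicle_id, parent_id, generation,
  birth_time, total_lipids)``
* ``vesicle_classes(iteration, vesicle_id, lipid_class, count)``
* ``vesicle_properties(iteration, vesicle_id, avg_length, avg_unsaturation,
  charge, curvature, cf1, area)``
* ``vesicle_compositions(iteration, vesicle_id, species_id, count)`` — full
  per-species compositions, present for snapshots where they were stored.
* ``environment(iteration, time_s, species_id, free_count)``
* ``divisions(time_s, parent_id, child1_id, child2_id)``
* ``deaths(time_s, vesicle_id)``
"""

from __future__ import annotations

import dataclasses
import json
import sqlite3
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import CSV_FIELDS, Catalog, LipidSpecies
from .kinetics import KineticsConfig
from .simulate import SimulationConfig, Snapshot, Trajectory
from .vesicle import PROPERTY_NAMES

_TABLES = (
    "run_meta",
    "catalog",
    "vesicle_snapshots",
    "vesicle_classes",
    "vesicle_properties",
    "vesicle_compositions",
    "environment",
    "divisions",
    "deaths",
)

_SCHEMA = f"""
CREATE TABLE run_meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE catalog ({", ".join(CSV_FIELDS)});
CREATE TABLE vesicle_snapshots (
    iteration INTEGER, time_s REAL, vesicle_id INTEGER, parent_id INTEGER,
    generation INTEGER, birth_time REAL, total_lipids INTEGER);
CREATE TABLE vesicle_classes (
    iteration INTEGER, vesicle_id INTEGER, lipid_class TEXT, count INTEGER);
CREATE TABLE vesicle_properties (
    iteration INTEGER, vesicle_id INTEGER, {", ".join(f"{p} REAL" for p in PROPERTY_NAMES)});
CREATE TABLE vesicle_compositions (
    iteration INTEGER, vesicle_id INTEGER, species_id TEXT, count INTEGER);
CREATE TABLE environment (
    iteration INTEGER, time_s REAL, species_id TEXT, free_count INTEGER);
CREATE TABLE divisions (time_s REAL, parent_id INTEGER, child1_id INTEGER, child2_id INTEGER);
CREATE TABLE deaths (time_s REAL, vesicle_id INTEGER);
"""


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory to a new SQLite database at ``path``."""
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA)
        cfg_dict = dataclasses.asdict(traj.config)
        meta = {
            "config": json.dumps(cfg_dict),
            "volume_litres": repr(traj.volume),
            "area_ref_m2": repr(traj.area_ref),
            "stop_reason": traj.stop_reason,
        }
        con.executemany("INSERT INTO run_meta VALUES (?, ?)", sorted(meta.items()))
        con.executemany(
            f"INSERT INTO catalog VALUES ({','.join('?' * len(CSV_FIELDS))})",
            [
                (s.species_id, s.lipid_class, s.length, s.unsaturation,
                 s.charge, s.cf1, s.head_area, s.k_f, s.k_b)
                for s in traj.catalog
            ],
        )
        sids = [s.species_id for s in traj.catalog]
        classes = traj.catalog.classes
        for snap in traj.snapshots:
            it, t = snap.iteration, snap.time
            con.executemany(
                "INSERT INTO vesicle_snapshots VALUES (?,?,?,?,?,?,?)",
                zip(
                    [it] * snap.n_vesicles,
                    [t] * snap.n_vesicles,
                    snap.vesicle_id.tolist(),
                    snap.parent_id.tolist(),
                    snap.generation.tolist(),
                    snap.birth_time.tolist(),
                    snap.total.tolist(),
                ),
            )
            rows = [
                (it, int(vid), classes[c], int(snap.class_counts[v, c]))
                for v, vid in enumerate(snap.vesicle_id)
                for c in range(len(classes))
            ]
            con.executemany("INSERT INTO vesicle_classes VALUES (?,?,?,?)", rows)
            con.executemany(
                "INSERT INTO vesicle_properties VALUES (?,?,?,?,?,?,?,?)",
                [
                    (it, int(vid), *snap.properties[v].tolist())
                    for v, vid in enumerate(snap.vesicle_id)
                ],
            )
            if snap.counts is not None:
                nz_v, nz_s = np.nonzero(snap.counts)
                con.executemany(
                    "INSERT INTO vesicle_compositions VALUES (?,?,?,?)",
                    [
                        (it, int(snap.vesicle_id[v]), sids[s], int(snap.counts[v, s]))
                        for v, s in zip(nz_v.tolist(), nz_s.tolist())
                    ],
                )
            con.executemany(
                "INSERT INTO environment VALUES (?,?,?,?)",
                [(it, t, sid, int(c)) for sid, c in zip(sids, snap.env_free)],
            )
        con.executemany("INSERT INTO divisions VALUES (?,?,?,?)", traj.divisions)
        con.executemany("INSERT INTO deaths VALUES (?,?)", traj.deaths)
        con.commit()
    finally:
        con.close()


def load_trajectory(path: str | Path) -> Trajectory:
    """Reconstruct a :class:`Trajectory` from a database written by
    :func:`save_trajectory`."""
    con = sqlite3.connect(path)
    try:
        meta = dict(con.execute("SELECT key, value FROM run_meta"))
        cfg_dict = json.loads(meta["config"])
        kin = cfg_dict.pop("kinetics", None)
        cfg = SimulationConfig(
            kinetics=KineticsConfig(**kin) if kin else None, **cfg_dict
        )
        cat_rows = con.execute(f"SELECT {', '.join(CSV_FIELDS)} FROM catalog").fetchall()
        catalog = Catalog(tuple(LipidSpecies(*row) for row in cat_rows))
        sid_to_idx = catalog.index
        cls_to_idx = {c: k for k, c in enumerate(catalog.classes)}

        ves = pd.read_sql_query(
            "SELECT * FROM vesicle_snapshots ORDER BY rowid", con
        )
        cls_df = pd.read_sql_query("SELECT * FROM vesicle_classes ORDER BY rowid", con)
        prop_df = pd.read_sql_query("SELECT * FROM vesicle_properties ORDER BY rowid", con)
        comp_df = pd.read_sql_query("SELECT * FROM vesicle_compositions ORDER BY rowid", con)
        env_df = pd.read_sql_query("SELECT * FROM environment ORDER BY rowid", con)
        divisions = [tuple(r) for r in con.execute("SELECT * FROM divisions ORDER BY rowid")]
        deaths = [tuple(r) for r in con.execute("SELECT * FROM deaths ORDER BY rowid")]
    finally:
        con.close()

    snapshots: list[Snapshot] = []
    comp_iters = set(comp_df["iteration"].unique().tolist())
    # environment rows exist for every snapshot, including an extinct (empty) one
    for it in sorted(env_df["iteration"].unique().tolist()):
        g = ves[ves["iteration"] == it]
        vids = g["vesicle_id"].to_numpy(dtype=np.int64)
        pos = {int(v): k for k, v in enumerate(vids)}
        n = len(vids)
        cc = np.zeros((n, len(catalog.classes)), dtype=np.int64)
        gc = cls_df[cls_df["iteration"] == it]
        cc[
            [pos[int(v)] for v in gc["vesicle_id"]],
            [cls_to_idx[c] for c in gc["lipid_class"]],
        ] = gc["count"].to_numpy()
        gp = prop_df[prop_df["iteration"] == it].set_index("vesicle_id")
        props = gp.loc[vids, list(PROPERTY_NAMES)].to_numpy(dtype=float)
        counts = None
        if int(it) in comp_iters:
            counts = np.zeros((n, len(catalog)), dtype=np.int64)
            gcomp = comp_df[comp_df["iteration"] == it]
            counts[
                [pos[int(v)] for v in gcomp["vesicle_id"]],
                [sid_to_idx[s] for s in gcomp["species_id"]],
            ] = gcomp["count"].to_numpy()
        ge = env_df[env_df["iteration"] == it]
        env_free = np.zeros(len(catalog), dtype=np.int64)
        env_free[[sid_to_idx[s] for s in ge["species_id"]]] = ge["free_count"].to_numpy()
        time = float(ge["time_s"].iloc[0]) if len(ge) else float(g["time_s"].iloc[0])
        snapshots.append(
            Snapshot(
                iteration=int(it),
                time=time,
                vesicle_id=vids,
                parent_id=g["parent_id"].to_numpy(dtype=np.int64),
                generation=g["generation"].to_numpy(dtype=np.int64),
                birth_time=g["birth_time"].to_numpy(dtype=float),
                total=g["total_lipids"].to_numpy(dtype=np.int64),
                class_counts=cc,
                properties=props,
                env_free=env_free,
                counts=counts,
            )
        )
    snapshots.sort(key=lambda s: s.iteration)
    return Trajectory(
        config=cfg,
        catalog=catalog,
        snapshots=snapshots,
        divisions=divisions,
        deaths=deaths,
        volume=float(meta["volume_litres"]),
        area_ref=float(meta["area_ref_m2"]),
        stop_reason=meta["stop_reason"],
    )


def export_csv(db_path: str | Path, out_dir: str | Path) -> list[Path]:
    """Dump every table of a trajectory database to ``out_dir`` as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    con = sqlite3.connect(db_path)
    written = []
    try:
        for table in _TABLES:
            df = pd.read_sql_query(f"SELECT * FROM {table}", con)
            dest = out_dir / f"{table}.csv"
            df.to_csv(dest, index=False)
            written.append(dest)
    finally:
        con.close()
    return written
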