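"""SQLite trace database (event-sourced, one transaction per cycle) and SWC
export.

The database records everything needed to reconstruct the simulation at any
committed cycle: front creations (with full geometry and tree links),
retractions (death_cycle set, rows never deleted), soma migration history,
synapses, substrate sources and optional per-front attribute values.  A
``cycles`` table marks committed cycles so a truncated file is detectable.
"""

from __future__ import annotations

import sqlite3

import numpy as np

from .errors import UsageError
from .fronts import (_I_AXON_TIP, _I_DEATH, _I_FILI, _I_FLAGS, _N_FLOAT_BASE,
                     FrontID, pack_id, unpack_id)

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS cycles (cycle INTEGER PRIMARY KEY);
CREATE TABLE IF NOT EXISTS neuron_types (
    row INTEGER PRIMARY KEY, name TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS neurons (
    neuron_id INTEGER PRIMARY KEY,
    soma_row INTEGER, soma_idx INTEGER,
    name TEXT, birth_cycle INTEGER);
CREATE TABLE IF NOT EXISTS fronts (
    row INTEGER, idx INTEGER,
    parent_row INTEGER, parent_idx INTEGER,
    soma_row INTEGER, soma_idx INTEGER,
    ox REAL, oy REAL, oz REAL, ex REAL, ey REAL, ez REAL,
    radius REAL, shape INTEGER, ord INTEGER, path_length REAL,
    birth_cycle INTEGER, death_cycle INTEGER,
    swc_type INTEGER, flags INTEGER,
    fili INTEGER, axon_tip INTEGER,
    PRIMARY KEY (row, idx));
CREATE TABLE IF NOT EXISTS migration_history (
    soma_row INTEGER, soma_idx INTEGER, cycle INTEGER,
    x REAL, y REAL, z REAL);
CREATE TABLE IF NOT EXISTS synapses (
    syn_id INTEGER PRIMARY KEY,
    pre_row INTEGER, pre_idx INTEGER, post_row INTEGER, post_idx INTEGER,
    weight REAL, birth_cycle INTEGER, death_cycle INTEGER);
CREATE TABLE IF NOT EXISTS substrate (
    sub_id INTEGER PRIMARY KEY,
    name TEXT, x REAL, y REAL, z REAL,
    n_mol REAL, diffusion REAL, birth_cycle INTEGER);
CREATE TABLE IF NOT EXISTS attributes (
    row INTEGER, idx INTEGER, cycle INTEGER, name TEXT, value REAL);
"""


def open_database(path):
    conn = sqlite3.connect(path)
    conn.executescript(_SCHEMA)
    conn.commit()
    return conn


def write_meta(conn, items):
    with conn:
        conn.execute("DELETE FROM meta")
        conn.executemany("INSERT INTO meta VALUES (?, ?)",
                         [(k, str(v)) for k, v in items.items()])


def read_meta(conn):
    return dict(conn.execute("SELECT key, value FROM meta"))


def write_neuron_types(conn, names):
    with conn:
        conn.execute("DELETE FROM neuron_types")
        conn.executemany("INSERT INTO neuron_types VALUES (?, ?)",
                         list(enumerate(names, start=1)))


def _front_row_tuple(store, fid: FrontID):
    fr = store.get_front(fid)
    i = store._i[fid.row][fid.index]
    parent = fr.parent
    soma = fr.soma_id
    return (
        fid.row, fid.index,
        parent.row if parent else 0, parent.index if parent else 0,
        soma.row, soma.index,
        *(float(v) for v in fr.orig), *(float(v) for v in fr.end),
        fr.radius, int(i[0]), fr.order, fr.path_length,
        fr.birth_cycle, fr.death_cycle, fr.swc_type, fr.flags,
        int(i[_I_FILI]), int(i[_I_AXON_TIP]),
    )


def write_cycle(conn, cycle, events, store, synapses=None, substrate=None):
    """Persist one cycle's events in a single transaction.

    `events` is the per-cycle event stream: ("created", packed),
    ("retracted", packed), ("migrated", packed), ("flags", packed, value),
    ("synapse", idx), ("synapse_removed", idx), ("substrate", idx).
    Creations insert full rows; retractions set death_cycle; migrations
    append to the history and refresh the soma row.
    """
    cur = conn.cursor()
    cur.execute("BEGIN")
    try:
        for ev in events:
            kind = ev[0]
            if kind == "created":
                fid = unpack_id(ev[1])
                cur.execute(
                    "INSERT OR REPLACE INTO fronts VALUES "
                    "(" + ",".join("?" * 22) + ")",
                    _front_row_tuple(store, fid))
                cls = store.class_for_row(fid.row)
                for k, name in enumerate(cls.attributes):
                    val = float(store._f[fid.row][fid.index,
                                                  _N_FLOAT_BASE + k])
                    cur.execute("INSERT INTO attributes VALUES (?,?,?,?,?)",
                                (fid.row, fid.index, cycle, name, val))
            elif kind == "retracted":
                fid = unpack_id(ev[1])
                cur.execute(
                    "UPDATE fronts SET death_cycle=?, flags=? "
                    "WHERE row=? AND idx=?",
                    (int(store._i[fid.row][fid.index, _I_DEATH]),
                     int(store._i[fid.row][fid.index, _I_FLAGS]),
                     fid.row, fid.index))
            elif kind == "migrated":
                fid = unpack_id(ev[1])
                fr = store.get_front(fid)
                cur.execute(
                    "INSERT INTO migration_history VALUES (?,?,?,?,?,?)",
                    (fid.row, fid.index, cycle, *(float(v) for v in fr.orig)))
                cur.execute(
                    "UPDATE fronts SET ox=?,oy=?,oz=?,ex=?,ey=?,ez=?, "
                    "fili=?, axon_tip=?, flags=? WHERE row=? AND idx=?",
                    (*(float(v) for v in fr.orig),
                     *(float(v) for v in fr.end),
                     int(store._i[fid.row][fid.index, _I_FILI]),
                     int(store._i[fid.row][fid.index, _I_AXON_TIP]),
                     fr.flags, fid.row, fid.index))
            elif kind == "flags":
                fid = unpack_id(ev[1])
                cur.execute("UPDATE fronts SET flags=? WHERE row=? AND idx=?",
                            (ev[2], fid.row, fid.index))
            elif kind == "relocated":
                fid = unpack_id(ev[1])
                fr = store.get_front(fid)
                cur.execute(
                    "UPDATE fronts SET ox=?,oy=?,oz=?,ex=?,ey=?,ez=?, "
                    "path_length=? WHERE row=? AND idx=?",
                    (*(float(v) for v in fr.orig),
                     *(float(v) for v in fr.end),
                     fr.path_length, fid.row, fid.index))
            elif kind == "synapse":
                s = synapses.record(ev[1])
                cur.execute(
                    "INSERT OR REPLACE INTO synapses VALUES (?,?,?,?,?,?,?,?)",
                    (ev[1], *s))
            elif kind == "synapse_removed":
                s = synapses.record(ev[1])
                cur.execute("UPDATE synapses SET death_cycle=? "
                            "WHERE syn_id=?", (s[-1], ev[1]))
            elif kind == "substrate":
                rec = substrate.record(ev[1])
                cur.execute(
                    "INSERT OR REPLACE INTO substrate VALUES "
                    "(?,?,?,?,?,?,?,?)", (ev[1], *rec))
            # "gce"/"error"/"done" are diagnostics, not persisted rows
        cur.execute("INSERT OR REPLACE INTO cycles VALUES (?)", (cycle,))
        conn.commit()
    except BaseException:
        conn.rollback()
        raise


def write_neuron(conn, neuron_id, soma_fid, name, birth_cycle):
    with conn:
        conn.execute("INSERT OR REPLACE INTO neurons VALUES (?,?,?,?,?)",
                     (neuron_id, soma_fid.row, soma_fid.index, name,
                      birth_cycle))


def last_cycle(conn):
    row = conn.execute("SELECT MAX(cycle) FROM cycles").fetchone()
    return row[0] if row[0] is not None else 0


def read_simulation(conn):
    """Full state fragment at the last committed cycle.

    Returns a dict with meta, neuron type names, neuron list, front rows in
    insertion order, migration history, synapses, substrate and attribute
    values; raises UsageError on schema-version mismatch.
    """
    meta = read_meta(conn)
    if int(meta.get("schema_version", -1)) != SCHEMA_VERSION:
        raise UsageError(
            f"database schema version {meta.get('schema_version')} "
            f"does not match {SCHEMA_VERSION}")
    types = [name for _, name in conn.execute(
        "SELECT row, name FROM neuron_types ORDER BY row")]
    neurons = list(conn.execute(
        "SELECT neuron_id, soma_row, soma_idx, name, birth_cycle "
        "FROM neurons ORDER BY neuron_id"))
    fronts = list(conn.execute(
        "SELECT * FROM fronts ORDER BY rowid"))
    synapses = list(conn.execute("SELECT * FROM synapses ORDER BY syn_id"))
    substrate = list(conn.execute("SELECT * FROM substrate ORDER BY sub_id"))
    attributes = list(conn.execute(
        "SELECT row, idx, cycle, name, value FROM attributes ORDER BY rowid"))
    return {
        "meta": meta,
        "neuron_types": types,
        "neurons": neurons,
        "fronts": fronts,
        "synapses": synapses,
        "substrate": substrate,
        "attributes": attributes,
        "cycle": last_cycle(conn),
    }


# ---------------------------------------------------------------------------
# SWC export.

def export_swc(store, soma_fid: FrontID, path, comment=None):
    """Write one neuron as a standard 7-column SWC file.

    Sample 1 is the soma (type 1, its centre and radius); every live
    cylinder front contributes one sample at its *end* coordinate, linked to
    its parent's sample index.  Retracted fronts are skipped entirely.
    """
    soma = store.get_front(soma_fid)
    if not soma.is_sphere():
        raise UsageError("SWC export starts from a soma front")
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append("# id type x y z radius parent")
    sample_of = {pack_id(soma_fid): 1}
    x, y, z = soma.orig
    lines.append(f"1 1 {x:.6f} {y:.6f} {z:.6f} {soma.radius:.6f} -1")
    counter = 1
    stack = list(reversed(soma.children()))
    while stack:
        fr = stack.pop()
        if fr.is_retracted():
            continue
        counter += 1
        sample_of[pack_id(fr.id)] = counter
        parent_sample = sample_of[pack_id(fr.parent)]
        x, y, z = fr.end
        t = fr.swc_type if fr.swc_type else 3
        lines.append(f"{counter} {t} {x:.6f} {y:.6f} {z:.6f} "
                     f"{fr.radius:.6f} {parent_sample}")
        stack.extend(reversed(fr.children()))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_swc(path):
    """Parse an SWC file into a numpy record-like list of tuples
    (id, type, x, y, z, radius, parent)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            rows.append((int(parts[0]), int(parts[1]), float(parts[2]),
                         float(parts[3]), float(parts[4]), float(parts[5]),
                         int(parts[6])))
    return rows
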