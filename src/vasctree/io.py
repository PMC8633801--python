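"""Serialization: CSV edge tables, VTK legacy polydata, JSON-lines records.

The CSV edge table is the canonical lossless tree format (one row per
segment, coordinates printed with 17 significant digits so float64 round
trips exactly).  VTK output is legacy polydata with one polyline cell per
vessel and per-cell arrays; binary mode stores big-endian float64 and is
bit-lossless.
"""

from __future__ import annotations

import csv
import json
import struct
from pathlib import Path

import numpy as np

from .hemodynamics import FlowSolution
from .morphometry import strahler_orders
from .pdcco import InsertionRecord
from .vessel_tree import VascularTree, Vessel, generation_of

__all__ = [
    "write_tree_csv",
    "read_tree_csv",
    "write_vtk",
    "read_vtk_points",
    "write_records_jsonl",
    "read_records_jsonl",
    "TreeFormatError",
]

_CSV_COLUMNS = [
    "id", "parent_id", "xp_x", "xp_y", "xp_z", "xd_x", "xd_y", "xd_z",
    "r", "Q", "q_out", "mu", "stage",
]


class TreeFormatError(ValueError):
    """Malformed tree file; message carries the offending line number."""


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_tree_csv(tree: VascularTree, path) -> None:
    """Edge table with full-precision coordinates; header row carries the
    tree-level attributes as a comment."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# gamma={_fmt(tree.gamma)} Q_in={_fmt(tree.Q_in)} "
                 f"r0={_fmt(tree.r0)}\n")
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for v in tree.pre_order():
            writer.writerow([
                v.id, "" if v.parent is None else v.parent,
                *(_fmt(c) for c in v.x_p), *(_fmt(c) for c in v.x_d),
                _fmt(v.r), _fmt(v.Q), _fmt(v.q_out), _fmt(v.mu), v.stage,
            ])


def read_tree_csv(path) -> VascularTree:
    path = Path(path)
    with open(path, newline="") as fh:
        header = fh.readline()
        attrs = {}
        if header.startswith("#"):
            for tok in header[1:].split():
                k, _, val = tok.partition("=")
                attrs[k] = float(val)
        else:
            fh.seek(0)
        reader = csv.DictReader(fh)
        rows = list(reader)
    if not rows:
        raise TreeFormatError("empty tree file")
    tree = VascularTree(gamma=attrs.get("gamma", 3.0),
                        Q_in=attrs.get("Q_in", 1.0),
                        r0=attrs.get("r0", 0.1))
    children: dict[int, list[int]] = {}
    for lineno, row in enumerate(rows, start=3):
        try:
            vid = int(row["id"])
            parent = None if row["parent_id"] in ("", None) else int(row["parent_id"])
            v = Vessel(
                id=vid,
                x_p=[float(row[c]) for c in ("xp_x", "xp_y", "xp_z")],
                x_d=[float(row[c]) for c in ("xd_x", "xd_y", "xd_z")],
                r=float(row["r"]), parent=parent, Q=float(row["Q"]),
                q_out=float(row["q_out"]), mu=float(row["mu"]),
                stage=row.get("stage") or "",
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise TreeFormatError(f"line {lineno}: {exc}") from exc
        if vid in tree.vessels:
            raise TreeFormatError(f"line {lineno}: duplicate vessel id {vid}")
        tree.vessels[vid] = v
        if parent is None:
            if tree.root_id is not None:
                raise TreeFormatError(f"line {lineno}: multiple roots")
            tree.root_id = vid
        else:
            children.setdefault(parent, []).append(vid)
    if tree.root_id is None:
        raise TreeFormatError("no root vessel (cyclic parent references?)")
    for pid, kids in children.items():
        if pid not in tree.vessels:
            raise TreeFormatError(f"parent id {pid} does not exist")
        tree.vessels[pid].children = tuple(kids)
    tree._next_id = max(tree.vessels) + 1
    # subtended counts + structure check (detects cycles via reachability)
    try:
        tree.validate()
    except ValueError as exc:
        raise TreeFormatError(str(exc)) from exc
    for vid, count in tree.recount_subtended().items():
        tree.vessels[vid].n_term_sub = count
    return tree


# ------------------------------------------------------------------ VTK
def write_vtk(tree: VascularTree, path, flow: FlowSolution | None = None,
              binary: bool = False) -> None:
    """Legacy VTK polydata: one 2-point polyline per vessel with cell arrays
    radius, flow, generation, strahler and (if given) pressure."""
    if len(tree.vessels) == 0:
        raise ValueError("refusing to write an empty tree")
    path = Path(path)
    vessels = list(tree.pre_order())
    n = len(vessels)
    points = np.empty((2 * n, 3))
    for i, v in enumerate(vessels):
        points[2 * i] = v.x_p
        points[2 * i + 1] = v.x_d
    orders = strahler_orders(tree)
    arrays: list[tuple[str, np.ndarray]] = [
        ("radius", np.array([v.r for v in vessels])),
        ("flow", np.array([v.Q for v in vessels])),
        ("generation", np.array([float(generation_of(tree, v.id)) for v in vessels])),
        ("strahler", np.array([float(orders[v.id]) for v in vessels])),
    ]
    if flow is not None:
        arrays.append(("pressure", np.array([flow.p_dist[v.id] for v in vessels])))

    mode = "wb" if binary else "w"
    with open(path, mode) as fh:
        w = (lambda s: fh.write(s.encode())) if binary else fh.write
        w("# vtk DataFile Version 3.0\n")
        w("vascular network\n")
        w("BINARY\n" if binary else "ASCII\n")
        w("DATASET POLYDATA\n")
        w(f"POINTS {2 * n} double\n")
        if binary:
            fh.write(struct.pack(f">{6 * n}d", *points.ravel()))
            w("\n")
        else:
            for p in points:
                w(f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")
        w(f"LINES {n} {3 * n}\n")
        if binary:
            conn = np.empty(3 * n, dtype=">i4")
            conn[0::3] = 2
            conn[1::3] = np.arange(0, 2 * n, 2)
            conn[2::3] = np.arange(1, 2 * n, 2)
            fh.write(conn.tobytes())
            w("\n")
        else:
            for i in range(n):
                w(f"2 {2 * i} {2 * i + 1}\n")
        w(f"CELL_DATA {n}\n")
        for name, data in arrays:
            w(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            if binary:
                fh.write(data.astype(">f8").tobytes())
                w("\n")
            else:
                w("\n".join(_fmt(x) for x in data) + "\n")


def read_vtk_points(path) -> np.ndarray:
    """Point coordinates from a legacy VTK polydata file (ascii or binary);
    used for round-trip verification."""
    path = Path(path)
    raw = path.read_bytes()
    header, _, rest = raw.partition(b"POINTS ")
    binary = b"BINARY" in header
    count_s, _, rest = rest.partition(b"\n")
    count = int(count_s.split()[0])
    if binary:
        return np.frombuffer(rest[: count * 24], dtype=">f8").reshape(count, 3).astype(float)
    vals = rest.split()[: 3 * count]
    return np.array([float(v) for v in vals]).reshape(count, 3)


# ------------------------------------------------------------- record lists
def write_records_jsonl(records: list[InsertionRecord], path) -> None:
    """One JSON object per line; float64 coordinates survive exactly (JSON
    floats use shortest round-trip representation)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps({
                "sequence": rec.sequence,
                "subdomain": rec.subdomain,
                "x_new": [float(x) for x in rec.x_new],
                "x_bif": [float(x) for x in rec.x_bif],
                "parent_x_p": [float(x) for x in rec.parent_x_p],
                "parent_x_d": [float(x) for x in rec.parent_x_d],
            }) + "\n")


def read_records_jsonl(path) -> list[InsertionRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(InsertionRecord(
                x_new=np.array(obj["x_new"]),
                x_bif=np.array(obj["x_bif"]),
                parent_x_p=np.array(obj["parent_x_p"]),
                parent_x_d=np.array(obj["parent_x_d"]),
                sequence=int(obj["sequence"]),
                subdomain=int(obj["subdomain"]),
            ))
    return out
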