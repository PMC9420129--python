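"""Readers and writers for skeletons, connectivity, cilia, and cell tables.

On-disk formats
---------------
* SWC — standard 7 whitespace-separated columns
  ``id type x y z radius parent`` (parent ``-1`` = root, ``#`` comments).
* JSON skeleton dialect — mirrors a CATMAID-style compact-skeleton export:
  ``{"id": <cell id>, "nodes": [[id, parent, x, y, z, radius], ...],
  "connectors": [{"partner", "kind", "role", "count", "ml", "rc", "dv"}]}``.
* connectivity.csv — header ``pre_id, post_id, count, kind`` plus optional
  ``ml, rc, dv`` contact coordinates.
* cells.csv — ``cell_id, population, ml, rc, dv[, myelinated]``.
* cilia.csv — long format ``cell_id, structure, point_index, ml, rc, dv``
  with structure in {kinocilium, tallest_stereocilium, stereocilia_base}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    AxisMap,
    ConnectivityTable,
    FormatError,
    HairCell,
    Skeleton,
    StructuralError,
    ValidationError,
    split_components,
    validate_cells,
)

CILIA_STRUCTURES = ("kinocilium", "tallest_stereocilium", "stereocilia_base")


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------


def _parse_swc(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FormatError(f"{path}:{ln}: expected 7 SWC columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            xyz = [float(parts[2]), float(parts[3]), float(parts[4])]
            r = float(parts[5])
            pid = int(parts[6])
        except ValueError as e:
            raise FormatError(f"{path}:{ln}: {e}") from None
        rows.append((nid, pid, *xyz, r))
    if not rows:
        raise FormatError(f"{path}: no SWC node records")
    arr = np.array(rows, dtype=float)
    node_ids = arr[:, 0].astype(np.int64)
    if np.unique(node_ids).size != node_ids.size:
        raise FormatError(f"{path}: duplicate node_id")
    return node_ids, arr[:, 1].astype(np.int64), arr[:, 2:5], arr[:, 5]


def read_skeleton_swc(path, axis_map: AxisMap | None = None) -> Skeleton:
    """Read a single-component SWC file into a :class:`Skeleton`.

    Coordinates are mapped into the (ml, rc, dv) frame via ``axis_map``
    (identity / µm by default). Raises :class:`StructuralError` if the file
    holds more than one connected component (use :func:`read_forest_swc`).
    """
    node_ids, parent_ids, xyz, radius = _parse_swc(path)
    if axis_map is not None:
        xyz = axis_map.apply(xyz)
        radius = radius * axis_map.scale
    if np.sum(parent_ids == -1) > 1:
        raise StructuralError(
            f"{path}: multiple components; use read_forest_swc()"
        )
    return Skeleton(node_ids, parent_ids, xyz, radius, label=Path(path).stem)


def read_forest_swc(path, axis_map: AxisMap | None = None) -> list[Skeleton]:
    """Read an SWC file into one Skeleton per connected component."""
    node_ids, parent_ids, xyz, radius = _parse_swc(path)
    if axis_map is not None:
        xyz = axis_map.apply(xyz)
        radius = radius * axis_map.scale
    return split_components(node_ids, parent_ids, xyz, radius)


def write_skeleton_swc(skel: Skeleton, path) -> None:
    """Write a Skeleton as standard 7-column SWC (type column = 0)."""
    with open(path, "w") as fh:
        fh.write("# id type ml rc dv radius parent\n")
        for k in range(skel.n_nodes):
            pid = skel.parent_index[k]
            parent = -1 if pid == -1 else int(skel.node_ids[pid])
            x, y, z = skel.xyz[k]
            fh.write(
                f"{int(skel.node_ids[k])} 0 {x:.9g} {y:.9g} {z:.9g} "
                f"{skel.radius[k]:.9g} {parent}\n"
            )


# ---------------------------------------------------------------------------
# JSON skeleton dialect
# ---------------------------------------------------------------------------


def read_skeleton_json(path, axis_map: AxisMap | None = None):
    """Read the JSON skeleton dialect: a Skeleton plus its connector records.

    Returns ``(skeleton, contacts)`` where ``contacts`` is a list of dicts
    with keys pre_id, post_id, count, kind, ml, rc, dv — ready to be stacked
    into a :class:`~otomap.core.ConnectivityTable`.
    """
    doc = json.loads(Path(path).read_text())
    if "nodes" not in doc:
        raise FormatError(f"{path}: missing 'nodes' array")
    nodes = doc["nodes"]
    if len(nodes) == 0:
        raise StructuralError(f"{path}: empty node list")
    arr = []
    for rec in nodes:
        if len(rec) < 5:
            raise FormatError(f"{path}: node record missing coordinate field: {rec}")
        nid, pid, x, y, z = rec[:5]
        r = rec[5] if len(rec) > 5 else 0.0
        if x is None or y is None or z is None:
            raise FormatError(f"{path}: node {nid} missing coordinate field")
        arr.append((int(nid), -1 if pid is None else int(pid), float(x), float(y), float(z), float(r)))
    arr = np.array(arr, dtype=float)
    xyz = arr[:, 2:5]
    radius = arr[:, 5]
    if axis_map is not None:
        xyz = axis_map.apply(xyz)
        radius = radius * axis_map.scale
    cell_id = str(doc.get("id", Path(path).stem))
    skel = Skeleton(arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), xyz, radius, label=cell_id)

    contacts = []
    for con in doc.get("connectors", []):
        for key in ("partner", "kind", "role"):
            if key not in con:
                raise FormatError(f"{path}: connector missing field {key!r}")
        role = con["role"]
        if role not in ("pre", "post"):
            raise FormatError(f"{path}: connector role must be pre/post, got {role!r}")
        pre = cell_id if role == "pre" else str(con["partner"])
        post = str(con["partner"]) if role == "pre" else cell_id
        loc = [con.get(ax) for ax in ("ml", "rc", "dv")]
        if axis_map is not None and all(v is not None for v in loc):
            loc = axis_map.apply(np.array([loc], dtype=float))[0].tolist()
        contacts.append(
            {
                "pre_id": pre,
                "post_id": post,
                "count": int(con.get("count", 1)),
                "kind": con["kind"],
                "ml": np.nan if loc[0] is None else float(loc[0]),
                "rc": np.nan if loc[1] is None else float(loc[1]),
                "dv": np.nan if loc[2] is None else float(loc[2]),
            }
        )
    return skel, contacts


def write_skeleton_json(skel: Skeleton, contacts, path, cell_id: str | None = None) -> None:
    """Write a Skeleton plus connector records in the JSON dialect.

    ``contacts`` is an iterable of dicts as produced by
    :func:`read_skeleton_json`; rows are re-expressed relative to this cell
    (role = "pre" when the cell is presynaptic).
    """
    cid = cell_id or skel.label or "cell"
    nodes = []
    for k in range(skel.n_nodes):
        pid = skel.parent_index[k]
        nodes.append(
            [
                int(skel.node_ids[k]),
                None if pid == -1 else int(skel.node_ids[pid]),
                float(skel.xyz[k, 0]),
                float(skel.xyz[k, 1]),
                float(skel.xyz[k, 2]),
                float(skel.radius[k]),
            ]
        )
    cons = []
    for c in contacts:
        role = "pre" if str(c["pre_id"]) == cid else "post"
        partner = c["post_id"] if role == "pre" else c["pre_id"]
        rec = {
            "partner": str(partner),
            "kind": c["kind"],
            "role": role,
            "count": int(c["count"]),
        }
        for ax in ("ml", "rc", "dv"):
            v = c.get(ax)
            if v is not None and np.isfinite(v):
                rec[ax] = float(v)
        cons.append(rec)
    Path(path).write_text(json.dumps({"id": cid, "nodes": nodes, "connectors": cons}))


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------


def read_connectivity_csv(path) -> ConnectivityTable:
    """Read connectivity.csv into a :class:`ConnectivityTable`.

    Rows with identical (pre_id, post_id, kind) remain distinct contacts at
    storage level (they may carry distinct synapse locations); the table's
    ``aggregated`` view sums their counts. Total counts are conserved.
    """
    df = pd.read_csv(path)
    return ConnectivityTable(df)


def write_connectivity_csv(table: ConnectivityTable, path) -> None:
    table.df.to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    return validate_cells(pd.read_csv(path))


def read_cilia_csv(path, ribbon_counts: dict | None = None) -> dict[str, HairCell]:
    """Read cilia.csv into HairCell objects keyed by cell_id.

    ``ribbon_counts`` optionally supplies per-cell ribbon totals (normally
    the column sums of the ribbon rows of the connectivity table, keeping
    the HairCell invariant ribbon_count == Σ ribbon contacts).
    """
    df = pd.read_csv(path)
    required = {"cell_id", "structure", "point_index", "ml", "rc", "dv"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"cilia table missing columns {sorted(missing)}")
    bad = ~df["structure"].isin(CILIA_STRUCTURES)
    if bad.any():
        raise ValidationError(
            f"unknown cilia structure(s): {sorted(df.loc[bad, 'structure'].unique())}"
        )
    cells: dict[str, HairCell] = {}
    for cid, grp in df.groupby(df["cell_id"].astype(str)):
        parts = {}
        for structure, sub in grp.groupby("structure"):
            sub = sub.sort_values("point_index")
            parts[structure] = sub[["ml", "rc", "dv"]].to_numpy(dtype=float)
        if "kinocilium" not in parts:
            raise ValidationError(f"{cid}: missing kinocilium trace")
        if "stereocilia_base" not in parts:
            raise ValidationError(f"{cid}: missing stereocilia bases")
        cells[cid] = HairCell(
            cell_id=cid,
            kinocilium=parts["kinocilium"],
            tallest_stereocilium=parts.get("tallest_stereocilium", parts["kinocilium"][:1]),
            stereocilia_bases=parts["stereocilia_base"],
            ribbon_count=int(ribbon_counts.get(cid, 0)) if ribbon_counts else 0,
        )
    return cells


def write_cilia_csv(cells, path) -> None:
    rows = []
    for hc in cells.values() if isinstance(cells, dict) else cells:
        for structure, pts in (
            ("kinocilium", hc.kinocilium),
            ("tallest_stereocilium", hc.tallest_stereocilium),
            ("stereocilia_base", hc.stereocilia_bases),
        ):
            for i, p in enumerate(np.atleast_2d(pts)):
                rows.append((hc.cell_id, structure, i, p[0], p[1], p[2]))
    pd.DataFrame(
        rows, columns=["cell_id", "structure", "point_index", "ml", "rc", "dv"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Load a YAML run config (paths, axis map, analysis parameters)."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def axis_map_from_config(cfg: dict) -> AxisMap:
    spec = cfg.get("axis_map", {}) or {}
    return AxisMap(
        ml=spec.get("ml", "+x"),
        rc=spec.get("rc", "+y"),
        dv=spec.get("dv", "+z"),
        scale=float(spec.get("scale", 1.0)),
    )
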