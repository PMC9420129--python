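"""Domain containers for utricular-circuit connectome analysis.

Coordinate convention
---------------------
All geometry lives in a right-handed anatomical frame in micrometres:

* ``ml`` — mediolateral, positive = lateral (ipsilateral roll),
* ``rc`` — rostrocaudal, positive = rostral (nose-down pitch),
* ``dv`` — dorsoventral, positive = dorsal.

The horizontal plane is the (ml, rc) plane; tuning angles are measured in
the (rc, ml) plane with 0° = rostral and 90° = lateral, counterclockwise.

Input frames that differ from this (e.g. raw EM voxel frames) are declared
as an axis permutation + sign map (:class:`AxisMap`) in the run config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

AXES = ("ml", "rc", "dv")

POPULATIONS = (
    "hair_cell",
    "afferent",
    "mauthner",
    "commissural_escape",
    "svn",
    "tangential",
    "vs",
    "vs_med",
    "vs_vent",
    "other",
)

CONTACT_KINDS = ("ribbon", "central")

ROOT_SENTINEL = -1


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class StructuralError(ValueError):
    """A skeleton violates its tree structure (cycle, multiple roots, ...)."""


class ValidationError(ValueError):
    """A value violates a domain invariant (negative count, bad label, ...)."""


class DegeneratePolarityError(ValidationError):
    """A hair cell's polarity vector has no horizontal component."""


class UndefinedTuningError(ValidationError):
    """A neuron's weighted input vectors sum to the zero vector."""


class MissingInputError(ValidationError):
    """A neuron has no synaptic inputs of the required kind."""


# ---------------------------------------------------------------------------
# coordinate-frame mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AxisMap:
    """Affine isometry from an input (x, y, z) frame to the (ml, rc, dv) frame.

    Each anatomical axis is declared as a signed source axis, e.g.
    ``AxisMap(ml="+x", rc="-y", dv="+z")``, with an optional uniform scale
    converting input units to micrometres. Pairwise distances are preserved
    up to the scale factor.
    """

    ml: str = "+x"
    rc: str = "+y"
    dv: str = "+z"
    scale: float = 1.0

    def matrix(self) -> np.ndarray:
        cols = {"x": 0, "y": 1, "z": 2}
        M = np.zeros((3, 3))
        used = set()
        for row, spec_ in enumerate((self.ml, self.rc, self.dv)):
            spec_ = spec_.strip()
            sign = -1.0 if spec_.startswith("-") else 1.0
            name = spec_.lstrip("+-")
            if name not in cols or name in used:
                raise ValidationError(f"bad axis spec {spec_!r}")
            used.add(name)
            M[row, cols[name]] = sign * self.scale
        return M

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of input coordinates into (ml, rc, dv)."""
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.matrix().T


# ---------------------------------------------------------------------------
# skeletons
# ---------------------------------------------------------------------------


class Skeleton:
    """A neuron skeleton: a rooted tree of 3-D nodes with optional radii.

    Parameters
    ----------
    node_ids : (n,) int array of unique node identifiers.
    parent_ids : (n,) int array; ``-1`` marks the single root.
    xyz : (n, 3) float array of (ml, rc, dv) positions in µm.
    radius : optional (n,) nonnegative float array.

    Coincident consecutive nodes (zero-length edges) are merged with a
    warning rather than rejected. After construction the skeleton is a
    connected acyclic tree with ``n_edges == n_nodes - 1`` and every edge
    of strictly positive Euclidean length.
    """

    def __init__(self, node_ids, parent_ids, xyz, radius=None, label: str | None = None):
        node_ids = np.asarray(node_ids, dtype=np.int64)
        parent_ids = np.asarray(parent_ids, dtype=np.int64)
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if node_ids.size == 0:
            raise StructuralError("empty skeleton: no nodes")
        if not np.all(np.isfinite(xyz)):
            raise ValidationError("non-finite node coordinates")
        if np.unique(node_ids).size != node_ids.size:
            raise FormatError("duplicate node_id in skeleton")
        if radius is None:
            radius = np.zeros(node_ids.size)
        radius = np.asarray(radius, dtype=float)
        if np.any(radius < 0):
            raise ValidationError("negative node radius")

        node_ids, parent_ids, xyz, radius = _merge_coincident(
            node_ids, parent_ids, xyz, radius
        )

        id_to_index = {int(i): k for k, i in enumerate(node_ids)}
        parent_index = np.full(node_ids.size, ROOT_SENTINEL, dtype=np.int64)
        roots = 0
        for k, pid in enumerate(parent_ids):
            if pid == ROOT_SENTINEL:
                roots += 1
            else:
                if int(pid) not in id_to_index:
                    raise FormatError(f"parent id {pid} not present in skeleton")
                parent_index[k] = id_to_index[int(pid)]
        if roots != 1:
            raise StructuralError(f"skeleton must have exactly one root, found {roots}")

        self.node_ids = node_ids
        self.parent_index = parent_index
        self.xyz = xyz
        self.radius = radius
        self.label = label
        self._id_to_index = id_to_index
        self._validate_tree()

    # -- structure ---------------------------------------------------------

    def _validate_tree(self) -> None:
        n = self.n_nodes
        # cycle check by walking each node to the root with a step budget
        for start in range(n):
            k, steps = start, 0
            while self.parent_index[k] != ROOT_SENTINEL:
                k = self.parent_index[k]
                steps += 1
                if steps > n:
                    raise StructuralError("cycle detected in skeleton")
        child, parent = self.edges
        if child.size:
            lengths = np.linalg.norm(self.xyz[child] - self.xyz[parent], axis=1)
            if np.any(lengths <= 0):
                raise StructuralError("zero-length edge survived deduplication")
        # connectivity: every node reaches the root, and |E| = |V| - 1 holds
        assert child.size == n - 1

    @property
    def n_nodes(self) -> int:
        return self.node_ids.size

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parent_index == ROOT_SENTINEL)[0])

    @property
    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(child_index, parent_index) arrays for all edges."""
        child = np.flatnonzero(self.parent_index != ROOT_SENTINEL)
        return child, self.parent_index[child]

    @property
    def edge_lengths(self) -> np.ndarray:
        child, parent = self.edges
        return np.linalg.norm(self.xyz[child] - self.xyz[parent], axis=1)

    @property
    def cable_length(self) -> float:
        """Total cable length: Σ Euclidean edge lengths, in µm."""
        return float(self.edge_lengths.sum())

    def index_of(self, node_id: int) -> int:
        try:
            return self._id_to_index[int(node_id)]
        except KeyError:
            raise KeyError(f"node id {node_id} not in skeleton") from None

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for k, p in enumerate(self.parent_index):
            if p != ROOT_SENTINEL:
                out[p].append(k)
        return out

    def adjacency(self) -> csr_matrix:
        child, parent = self.edges
        w = self.edge_lengths
        n = self.n_nodes
        rows = np.concatenate([child, parent])
        cols = np.concatenate([parent, child])
        data = np.concatenate([w, w])
        return csr_matrix((data, (rows, cols)), shape=(n, n))

    def path_distance_to_root(self) -> np.ndarray:
        """Geodesic distance from every node to the root, in µm."""
        dist = np.zeros(self.n_nodes)
        order = self.topological_order()
        child, parent = self.edges
        elen = {int(c): float(l) for c, l in zip(child, self.edge_lengths)}
        for k in order:
            p = self.parent_index[k]
            if p != ROOT_SENTINEL:
                dist[k] = dist[p] + elen[int(k)]
        return dist

    def topological_order(self) -> np.ndarray:
        """Node indices ordered root-first (parents before children)."""
        children = self.children()
        order = np.empty(self.n_nodes, dtype=np.int64)
        stack = [self.root_index]
        i = 0
        while stack:
            k = stack.pop()
            order[i] = k
            i += 1
            stack.extend(children[k])
        return order

    def geodesic_matrix(self, indices=None) -> np.ndarray:
        """Pairwise along-arbor distances (µm) between nodes (all, or a
        subset given as node indices). On a tree the shortest path is the
        unique path, so Dijkstra on the weighted adjacency is exact."""
        adj = self.adjacency()
        if indices is None:
            return dijkstra(adj, directed=False)
        idx = np.asarray(indices, dtype=np.int64)
        return dijkstra(adj, directed=False, indices=idx)[:, idx]

    def geodesic_distance(self, node_a: int, node_b: int) -> float:
        """Along-arbor distance between two node ids, in µm."""
        ia, ib = self.index_of(node_a), self.index_of(node_b)
        return float(self.geodesic_matrix(np.array([ia, ib]))[0, 1])

    def __repr__(self) -> str:
        lbl = f" {self.label!r}" if self.label else ""
        return f"<Skeleton{lbl}: {self.n_nodes} nodes, {self.cable_length:.1f} µm cable>"


def _merge_coincident(node_ids, parent_ids, xyz, radius):
    """Merge children coincident with their parent (zero-length edges)."""
    id_to_index = {int(i): k for k, i in enumerate(node_ids)}
    drop: dict[int, int] = {}  # dropped node_id -> surviving node_id
    for k, pid in enumerate(parent_ids):
        if pid == ROOT_SENTINEL or int(pid) not in id_to_index:
            continue
        p = id_to_index[int(pid)]
        if np.all(xyz[k] == xyz[p]):
            drop[int(node_ids[k])] = int(pid)
    if not drop:
        return node_ids, parent_ids, xyz, radius
    warnings.warn(
        f"merged {len(drop)} coincident node(s) (zero-length edges)", stacklevel=3
    )

    def resolve(i: int) -> int:
        while i in drop:
            i = drop[i]
        return i

    keep = np.array([int(i) not in drop for i in node_ids])
    new_parents = np.array(
        [p if p == ROOT_SENTINEL else resolve(int(p)) for p in parent_ids],
        dtype=np.int64,
    )
    return node_ids[keep], new_parents[keep], xyz[keep], radius[keep]


def split_components(node_ids, parent_ids, xyz, radius=None) -> list[Skeleton]:
    """Build one :class:`Skeleton` per connected component of a node table."""
    node_ids = np.asarray(node_ids, dtype=np.int64)
    parent_ids = np.asarray(parent_ids, dtype=np.int64)
    xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
    if radius is None:
        radius = np.zeros(node_ids.size)
    radius = np.asarray(radius, dtype=float)
    id_to_index = {int(i): k for k, i in enumerate(node_ids)}
    n = node_ids.size
    rows, cols = [], []
    for k, pid in enumerate(parent_ids):
        if pid != ROOT_SENTINEL:
            if int(pid) not in id_to_index:
                raise FormatError(f"parent id {pid} not present")
            p = id_to_index[int(pid)]
            rows += [k, p]
            cols += [p, k]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    out = []
    for c in range(n_comp):
        mask = labels == c
        out.append(Skeleton(node_ids[mask], parent_ids[mask], xyz[mask], radius[mask]))
    return out


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

CONNECTIVITY_COLUMNS = ["pre_id", "post_id", "count", "kind"]


class ConnectivityTable:
    """Sparse pre→post synaptic contact table.

    Stores contact-level rows (each with a positive integer ``count`` and an
    optional (ml, rc, dv) location) and exposes an aggregated view with at
    most one row per (pre_id, post_id, kind). All weighted-tuning and
    composition operations use the aggregated counts; per-contact locations
    feed the synaptic-clustering analysis.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in CONNECTIVITY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"connectivity table missing columns {missing}")
        counts = pd.to_numeric(df["count"], errors="coerce")
        if counts.isna().any() or np.any(counts != counts.astype(int)):
            raise ValidationError("contact counts must be integers")
        if np.any(counts < 1):
            raise ValidationError("contact counts must be >= 1")
        df["count"] = counts.astype(int)
        bad = ~df["kind"].isin(CONTACT_KINDS)
        if bad.any():
            raise ValidationError(f"unknown contact kind(s): {sorted(df.loc[bad, 'kind'].unique())}")
        df["pre_id"] = df["pre_id"].astype(str)
        df["post_id"] = df["post_id"].astype(str)
        for ax in AXES:
            if ax not in df.columns:
                df[ax] = np.nan
        self.df = df.reset_index(drop=True)

    @property
    def aggregated(self) -> pd.DataFrame:
        """One row per (pre_id, post_id, kind) with summed counts."""
        return (
            self.df.groupby(["pre_id", "post_id", "kind"], as_index=False)["count"]
            .sum()
        )

    @property
    def total_count(self) -> int:
        return int(self.df["count"].sum())

    def by_pre(self, pre_id: str, kind: str | None = None) -> pd.DataFrame:
        agg = self.aggregated
        sel = agg[agg["pre_id"] == str(pre_id)]
        return sel if kind is None else sel[sel["kind"] == kind]

    def by_post(self, post_id: str, kind: str | None = None) -> pd.DataFrame:
        agg = self.aggregated
        sel = agg[agg["post_id"] == str(post_id)]
        return sel if kind is None else sel[sel["kind"] == kind]

    def kind(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["kind"] == kind]

    def locations(self, kind: str | None = None) -> pd.DataFrame:
        """Contact-level rows that carry coordinates."""
        sel = self.df if kind is None else self.kind(kind)
        return sel.dropna(subset=["ml", "rc", "dv"])

    def merge(self, other: "ConnectivityTable") -> "ConnectivityTable":
        return ConnectivityTable(pd.concat([self.df, other.df], ignore_index=True))

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"<ConnectivityTable: {len(self.df)} rows, {self.total_count} contacts>"


# ---------------------------------------------------------------------------
# cell metadata
# ---------------------------------------------------------------------------

CELLS_COLUMNS = ["cell_id", "population", "ml", "rc", "dv"]


def validate_cells(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell-metadata table (cells.csv layout).

    Columns: cell_id, population, ml, rc, dv, and optional boolean
    ``myelinated`` (meaningful for afferents only).
    """
    missing = [c for c in CELLS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cells table missing columns {missing}")
    df = df.copy()
    df["cell_id"] = df["cell_id"].astype(str)
    if df["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id in cells table")
    bad = ~df["population"].isin(POPULATIONS)
    if bad.any():
        raise ValidationError(
            f"unknown population label(s): {sorted(df.loc[bad, 'population'].unique())}"
        )
    if "myelinated" not in df.columns:
        df["myelinated"] = False
    df["myelinated"] = df["myelinated"].astype(bool)
    return df.reset_index(drop=True)


@dataclass
class HairCell:
    """A hair cell's apical geometry and synaptic bookkeeping.

    ``kinocilium`` and ``tallest_stereocilium`` are (n, 3) polylines in µm;
    ``stereocilia_bases`` is an (m, 3) array of base positions at the
    epithelial plane. The kinocilium base is the first kinocilium point.
    """

    cell_id: str
    kinocilium: np.ndarray
    tallest_stereocilium: np.ndarray
    stereocilia_bases: np.ndarray
    ribbon_count: int = 0
    maturity: str | None = None
    lpr_side: str | None = None
    apical_position: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.kinocilium = np.asarray(self.kinocilium, dtype=float).reshape(-1, 3)
        self.tallest_stereocilium = np.asarray(
            self.tallest_stereocilium, dtype=float
        ).reshape(-1, 3)
        self.stereocilia_bases = np.asarray(
            self.stereocilia_bases, dtype=float
        ).reshape(-1, 3)
        if self.kinocilium.shape[0] < 1:
            raise ValidationError(f"{self.cell_id}: empty kinocilium trace")
        if self.stereocilia_bases.shape[0] < 1:
            raise ValidationError(f"{self.cell_id}: no stereocilia bases")
        if self.ribbon_count < 0:
            raise ValidationError(f"{self.cell_id}: negative ribbon count")
        if self.apical_position is None:
            self.apical_position = self.kinocilium[0].copy()

    @property
    def kinocilium_base(self) -> np.ndarray:
        return self.kinocilium[0]
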