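"""Domain types and I/O for directed spatial networks.

A *spatial network* here is a binary directed graph whose nodes carry fixed
Euclidean coordinates (2-D or 3-D, arbitrary length units).  The graph is the
object being optimized and measured; the coordinates never change.  Node order
is canonical: the row order of the coordinate file defines the index of every
matrix used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


class NetworkFormatError(ValueError):
    """Raised when an input file or matrix violates the format contract."""


# ---------------------------------------------------------------------------
# Position tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionTable:
    """Node labels plus fixed spatial coordinates.

    Parameters
    ----------
    ids : tuple of str
        Unique node labels; their order is the canonical node order.
    coords : ndarray of shape (n, d)
        Euclidean coordinates, d in {1, 2, 3}, arbitrary length units.
    """

    ids: tuple
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2:
            raise NetworkFormatError("coords must be a 2-D array (n, d)")
        if coords.shape[1] not in (1, 2, 3):
            raise NetworkFormatError(
                f"coordinate dimensionality must be 1, 2 or 3, got {coords.shape[1]}")
        if len(self.ids) != coords.shape[0]:
            raise NetworkFormatError("number of ids does not match coordinate rows")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise NetworkFormatError(f"duplicate node ids: {dupes}")
        if not np.all(np.isfinite(coords)):
            raise NetworkFormatError("non-finite coordinate encountered")
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def index_of(self, node_id: str) -> int:
        return self.ids.index(str(node_id))


def _read_delimited(path, **kwargs) -> pd.DataFrame:
    """Delimiter-sniffing reader with exact (round-trip) float parsing."""
    with open(path) as fh:
        first = fh.readline()
    for sep in (",", "\t", ";"):
        if sep in first:
            return pd.read_csv(path, sep=sep,
                               float_precision="round_trip", **kwargs)
    return pd.read_csv(path, sep=r"\s+", engine="python", **kwargs)


def load_positions(path, dim: int | None = None) -> PositionTable:
    """Read a delimited coordinate table with header ``id,x,y[,z]``.

    The delimiter is sniffed (comma, tab, semicolon or whitespace).  Row
    order is kept as the canonical node order.
    """
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise NetworkFormatError(f"{path}: expected id plus >=1 coordinate columns")
    ids = [str(v) for v in df.iloc[:, 0]]
    if dim is not None and df.shape[1] - 1 != dim:
        raise NetworkFormatError(
            f"{path}: expected {dim} coordinate columns, found {df.shape[1] - 1}")
    coord_cols = df.iloc[:, 1:]
    try:
        coords = coord_cols.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for r in range(len(df)):
            try:
                coord_cols.iloc[r].to_numpy(dtype=float)
            except (TypeError, ValueError):
                raise NetworkFormatError(
                    f"{path}: non-numeric coordinate in row {r + 2} (id={ids[r]!r})"
                ) from None
        raise
    seen: dict[str, int] = {}
    for r, i in enumerate(ids):
        if i in seen:
            raise NetworkFormatError(
                f"{path}: duplicate node id {i!r} in rows {seen[i] + 2} and {r + 2}")
        seen[i] = r
    return PositionTable(tuple(ids), coords)


def write_positions(table: PositionTable, path) -> None:
    cols = ["x", "y", "z"][: table.dim]
    df = pd.DataFrame(table.coords, columns=cols)
    df.insert(0, "id", table.ids)
    df.to_csv(path, index=False, float_format="%.17g")  # exact round-trip


# ---------------------------------------------------------------------------
# Directed binary graphs
# ---------------------------------------------------------------------------

@dataclass
class Digraph:
    """Binary directed graph held as a dense n x n adjacency matrix.

    ``adjacency[i, j] = 1`` iff there is a directed link i -> j.  No
    self-loops; reciprocal links are two distinct links.
    """

    adjacency: np.ndarray

    def __post_init__(self):
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise NetworkFormatError("adjacency must be square")
        vals = np.unique(adj)
        if not np.all(np.isin(vals, (0, 1))):
            raise NetworkFormatError(f"adjacency entries must be 0/1, found {vals}")
        if np.any(np.diag(adj) != 0):
            bad = np.flatnonzero(np.diag(adj))
            raise NetworkFormatError(f"self-loop at node index {bad.tolist()}")
        self.adjacency = adj.astype(bool)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def K(self) -> int:
        """Total number of directed links."""
        return int(self.adjacency.sum())

    @property
    def out_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def in_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    @property
    def total_degree(self) -> np.ndarray:
        return self.in_degree + self.out_degree

    def edges(self) -> np.ndarray:
        """(K, 2) array of (source, target) index pairs, row-major order."""
        return np.argwhere(self.adjacency)

    def copy(self) -> "Digraph":
        return Digraph(self.adjacency.copy())

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[int, int]], n: int) -> "Digraph":
        adj = np.zeros((n, n), dtype=bool)
        for i, j in edges:
            if i == j:
                raise NetworkFormatError(f"self-loop {i}->{j} rejected")
            adj[i, j] = True
        return cls(adj)

    def to_networkx(self, positions: PositionTable | None = None):
        import networkx as nx

        g = nx.DiGraph()
        if positions is not None:
            for idx, nid in enumerate(positions.ids):
                g.add_node(idx, label=nid,
                           **{c: float(v) for c, v in
                              zip("xyz", positions.coords[idx])})
        else:
            g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges()))
        return g


def load_digraph(path, n: int | None = None, fmt: str = "auto",
                 ids: Sequence[str] | None = None) -> Digraph:
    """Load a directed binary network.

    ``fmt='edge_list'``: delimited rows ``source,target`` (node ids if *ids*
    given, else integer indices).  ``fmt='adjacency_csv'``: dense 0/1 matrix.
    ``fmt='auto'`` chooses by column count.
    """
    df = _read_delimited(path, header=None)
    first = str(df.iloc[0, 0])
    if first in ("source", "src", "from"):
        df = df.iloc[1:].reset_index(drop=True)
    if fmt == "auto":
        fmt = "edge_list" if df.shape[1] == 2 else "adjacency_csv"
    if fmt == "edge_list":
        if ids is not None:
            lookup = {str(v): k for k, v in enumerate(ids)}
            n = len(ids)
        elif n is not None:
            lookup = {str(k): k for k in range(n)}
        else:
            raise NetworkFormatError("edge list needs n or ids to size the graph")
        adj = np.zeros((n, n), dtype=bool)
        for r in range(len(df)):
            s, t = str(df.iloc[r, 0]), str(df.iloc[r, 1])
            if s not in lookup or t not in lookup:
                raise NetworkFormatError(f"{path}: unknown node id in row {r + 1}: "
                                         f"({s!r}, {t!r})")
            i, j = lookup[s], lookup[t]
            if i == j:
                raise NetworkFormatError(f"{path}: self-loop {s!r} in row {r + 1}")
            adj[i, j] = True
        return Digraph(adj)
    if fmt == "adjacency_csv":
        try:
            mat = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise NetworkFormatError(f"{path}: non-numeric adjacency entry: {exc}")
        if n is not None and mat.shape != (n, n):
            raise NetworkFormatError(
                f"{path}: expected {n}x{n} adjacency, got {mat.shape}")
        if not np.all(np.isin(mat, (0.0, 1.0))):
            raise NetworkFormatError(f"{path}: adjacency entries must be 0/1")
        return Digraph(mat.astype(bool))
    raise NetworkFormatError(f"unknown format {fmt!r}")


def write_edge_list(graph: Digraph, path, ids: Sequence[str] | None = None) -> None:
    edges = graph.edges()
    with open(path, "w") as fh:
        fh.write("source,target\n")
        for i, j in edges:
            if ids is not None:
                fh.write(f"{ids[i]},{ids[j]}\n")
            else:
                fh.write(f"{i},{j}\n")


def write_adjacency(graph: Digraph, path) -> None:
    np.savetxt(path, graph.adjacency.astype(int), fmt="%d", delimiter=",")


def export_graphml(graph: Digraph, positions: PositionTable, path) -> None:
    """GraphML export with node labels and coordinates as attributes."""
    import networkx as nx

    nx.write_graphml(graph.to_networkx(positions), path)


# ---------------------------------------------------------------------------
# Spatial network = graph + layout
# ---------------------------------------------------------------------------

@dataclass
class SpatialNetwork:
    """A directed graph embedded at fixed node positions.

    The pairwise Euclidean distance matrix is computed once and cached, along
    with ``d_max``, the largest pairwise distance (the reference scale for
    normalized radii).
    """

    graph: Digraph
    positions: PositionTable
    dist: np.ndarray = field(init=False, repr=False)
    d_max: float = field(init=False)

    def __post_init__(self):
        if self.graph.n != self.positions.n:
            raise NetworkFormatError(
                f"graph has {self.graph.n} nodes, positions {self.positions.n}")
        self.dist = distance_matrix(self.positions.coords)
        self.d_max = float(self.dist.max())
        n_dupe = int((self.dist[np.triu_indices(self.graph.n, k=1)] == 0).sum())
        if n_dupe:
            warnings.warn(f"{n_dupe} node pair(s) share identical coordinates "
                          "(zero distance)", stacklevel=2)

    @property
    def n(self) -> int:
        return self.graph.n

    def with_graph(self, graph: Digraph) -> "SpatialNetwork":
        """Same layout, different connectivity (distance matrix reused)."""
        if graph.n != self.positions.n:
            raise NetworkFormatError("node count mismatch")
        new = object.__new__(SpatialNetwork)
        new.graph = graph
        new.positions = self.positions
        new.dist = self.dist
        new.d_max = self.d_max
        return new


def distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix with an exactly zero diagonal."""
    d = cdist(coords, coords)
    np.fill_diagonal(d, 0.0)
    return d


def build_spatial_network(graph: Digraph, positions: PositionTable) -> SpatialNetwork:
    return SpatialNetwork(graph, positions)


# ---------------------------------------------------------------------------
# Reachability
# ---------------------------------------------------------------------------

def shortest_path_lengths(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs directed shortest-path step counts by level-synchronous BFS.

    Expands all BFS frontiers simultaneously through boolean matrix products;
    efficient for the small, small-diameter graphs optimized here.  Unreachable
    pairs get ``inf``.
    """
    adj = np.asarray(adjacency, dtype=bool)
    n = adj.shape[0]
    a = adj.astype(np.float32)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = np.eye(n, dtype=bool)
    frontier = reach
    d = 0
    while True:
        new = (frontier.astype(np.float32) @ a > 0) & ~reach
        if not new.any():
            break
        d += 1
        dist[new] = d
        reach |= new
        frontier = new
    return dist


def _reachable_from(adj: np.ndarray, start: int, reverse: bool = False) -> np.ndarray:
    """Boolean vector of nodes reachable from *start* (or reaching it)."""
    a = adj.T if reverse else adj
    a = a.astype(np.float32)
    visited = np.zeros(adj.shape[0], dtype=bool)
    visited[start] = True
    frontier = visited.astype(np.float32)
    while True:
        new = (frontier @ a > 0) & ~visited
        if not new.any():
            return visited
        visited |= new
        frontier = new.astype(np.float32)


def is_strongly_connected(adjacency: np.ndarray) -> bool:
    """True iff every ordered node pair is connected by a directed path."""
    adj = np.asarray(adjacency, dtype=bool)
    if adj.shape[0] <= 1:
        return True
    return bool(_reachable_from(adj, 0).all()
                and _reachable_from(adj, 0, reverse=True).all())


def check_strong_connectivity(graph: Digraph) -> tuple[bool, int]:
    """Strong-connectivity flag plus the number of unreachable ordered pairs."""
    if graph.n <= 1:
        return True, 0
    if is_strongly_connected(graph.adjacency):
        return True, 0
    dist = shortest_path_lengths(graph.adjacency)
    unreachable = int(np.isinf(dist).sum())
    return unreachable == 0, unreachable


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    """Assignment of every node to one of k non-empty groups (labels 1..k)."""

    labels: np.ndarray   # shape (n,), values 1..k

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1 or labels.size == 0:
            raise NetworkFormatError("labels must be a non-empty 1-D array")
        present = np.unique(labels)
        k = labels.max()
        if labels.min() < 1 or len(present) != k:
            raise NetworkFormatError(
                f"group labels must be exactly 1..k with no empty group, got {present}")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def k(self) -> int:
        return int(self.labels.max())

    def groups(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.labels == g) for g in range(1, self.k + 1)]

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "Partition":
        """Build from arbitrary hashable labels, compressed to 1..k by first
        appearance."""
        seen: dict = {}
        out = []
        for lab in labels:
            if lab not in seen:
                seen[lab] = len(seen) + 1
            out.append(seen[lab])
        return cls(np.array(out))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int], ids: Sequence[str]) -> "Partition":
        return cls.from_labels([mapping[str(i)] for i in ids])

    def to_frame(self, ids: Sequence[str] | None = None) -> pd.DataFrame:
        idx = list(ids) if ids is not None else list(range(self.n))
        return pd.DataFrame({"id": idx, "group": self.labels})


def write_partition(partition: Partition, path, ids: Sequence[str] | None = None) -> None:
    partition.to_frame(ids).to_csv(path, index=False)


def load_partition(path, ids: Sequence[str] | None = None) -> Partition:
    df = pd.read_csv(path)
    if ids is not None:
        order = {str(v): k for k, v in enumerate(ids)}
        df = df.assign(_o=[order[str(i)] for i in df["id"]]).sort_values("_o")
    return Partition.from_labels(df["group"].tolist())
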