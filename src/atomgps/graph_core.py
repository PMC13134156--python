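"""Atomistic graph data model, radius-cutoff construction, and file I/O.

A molecular or atomistic graph bundles atomic numbers, optional 3D
coordinates (Å), optional raw node/edge features and per-task targets.
Undirected edges are stored as *both ordered directions* internally, so
message passing can address each per-neighbor direction explicitly; file
writers emit each undirected edge once.

Conventions: 0-based node indices; coordinates in Å; a column ``(u, v)`` of
``edge_index`` is read as "v is a neighbor of u", i.e. row 0 holds the
receiving/center node of a message.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "AtomGraph",
    "DatasetSplit",
    "GraphInvalidError",
    "DEFAULT_RADIUS_CUTOFF",
    "build_radius_graph",
    "graph_distance",
    "read_xyz",
    "write_xyz",
    "read_container",
    "write_container",
    "symbol_to_z",
    "z_to_symbol",
    "make_split",
]

#: Default geometric cutoff (Å); appropriate for crystal/complex graphs where
#: metal-ligand and van der Waals contacts fall below ~5 Å.
DEFAULT_RADIUS_CUTOFF = 5.0


class GraphInvalidError(ValueError):
    """Raised when a graph cannot be constructed or featurized."""


def _load_symbols() -> dict[str, int]:
    import csv

    table = {}
    with resources.files("atomgps.data").joinpath("element_properties.csv").open() as fh:
        for row in csv.DictReader(fh):
            table[row["symbol"]] = int(row["z"])
    return table


_SYMBOL_TO_Z = _load_symbols()
_Z_TO_SYMBOL = {z: s for s, z in _SYMBOL_TO_Z.items()}


def symbol_to_z(symbol: str) -> int:
    try:
        return _SYMBOL_TO_Z[symbol]
    except KeyError:
        raise GraphInvalidError(f"unknown element symbol: {symbol!r}") from None


def z_to_symbol(z: int) -> str:
    try:
        return _Z_TO_SYMBOL[int(z)]
    except KeyError:
        raise GraphInvalidError(f"no element symbol for Z={z}") from None


@dataclass
class AtomGraph:
    """One molecular/atomistic graph.

    ``edge_index`` has shape (2, E) and contains both ordered directions of
    every undirected edge; ``edge_features`` (if present) is row-aligned with
    ``edge_index`` columns.
    """

    atomic_numbers: np.ndarray
    edge_index: np.ndarray
    coords: np.ndarray | None = None
    node_features: np.ndarray | None = None
    edge_features: np.ndarray | None = None
    targets: dict = field(default_factory=dict)
    graph_id: str = ""

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64).reshape(2, -1)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.node_features is not None:
            self.node_features = np.asarray(self.node_features, dtype=np.float64)
        if self.edge_features is not None:
            self.edge_features = np.asarray(self.edge_features, dtype=np.float64)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n = self.num_nodes
        if n < 1:
            raise GraphInvalidError("graph must have at least one node")
        e = self.edge_index
        if e.size:
            if e.min() < 0 or e.max() >= n:
                raise GraphInvalidError("edge index out of range")
            if np.any(e[0] == e[1]):
                raise GraphInvalidError("self-loops are not allowed")
            fwd = set(map(tuple, e.T.tolist()))
            if any((v, u) not in fwd for u, v in fwd):
                raise GraphInvalidError("edge list must contain both directions")
        if self.coords is not None and self.coords.shape != (n, 3):
            raise GraphInvalidError("coords must be N x 3")
        if self.node_features is not None and self.node_features.shape[0] != n:
            raise GraphInvalidError("node feature rows must match N")
        if self.edge_features is not None and self.edge_features.shape[0] != e.shape[1]:
            raise GraphInvalidError("edge feature rows must match edge count")

    @property
    def num_nodes(self) -> int:
        return int(self.atomic_numbers.shape[0])

    @property
    def num_edges(self) -> int:
        """Number of directed edge slots (2x the undirected count)."""
        return int(self.edge_index.shape[1])

    def undirected_edges(self) -> np.ndarray:
        """Each undirected edge once, as sorted (u, v) pairs with u < v."""
        if self.edge_index.size == 0:
            return np.empty((0, 2), dtype=np.int64)
        pairs = np.sort(self.edge_index.T, axis=1)
        return np.unique(pairs, axis=0)

    def neighbors(self, u: int) -> np.ndarray:
        return self.edge_index[1][self.edge_index[0] == u]


@dataclass
class DatasetSplit:
    """Graphs plus disjoint train/val/test index sets covering all graphs."""

    graphs: list
    split: dict

    def __post_init__(self):
        idx = [set(map(int, v)) for v in self.split.values()]
        total = set()
        for s in idx:
            if total & s:
                raise ValueError("split index sets must be disjoint")
            total |= s
        if total != set(range(len(self.graphs))):
            raise ValueError("split must cover all graphs exactly")

    def subset(self, part: str) -> list:
        return [self.graphs[i] for i in sorted(self.split[part])]


def make_split(n: int, seed: int, fractions=(0.8, 0.1, 0.1)) -> dict:
    """Random 80/10/10 (by default) train/val/test index split."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return {
        "train": order[:n_train].tolist(),
        "val": order[n_train:n_train + n_val].tolist(),
        "test": order[n_train + n_val:].tolist(),
    }


# -- construction ----------------------------------------------------------

def build_radius_graph(coords: np.ndarray, r_c: float) -> np.ndarray:
    """All ordered pairs (u, v), u != v, with strict ||r_u - r_v|| < r_c.

    Returns a (2, E) integer array containing both directions of every
    undirected edge, sorted lexicographically for determinism.  Pairs at
    exactly the cutoff distance are excluded (strict inequality).
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise GraphInvalidError("coords must be an N x 3 matrix with N >= 1")
    if not np.all(np.isfinite(coords)):
        raise GraphInvalidError("non-finite coordinates")
    if not r_c > 0:
        raise ValueError("r_c must be positive")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    n = coords.shape[0]
    mask = (dist < r_c) & ~np.eye(n, dtype=bool)
    u, v = np.nonzero(mask)
    return np.stack([u, v]).astype(np.int64)


def graph_distance(graph: AtomGraph, u: int, v: int) -> float:
    """Shortest-path hop count d_G(u, v); ``math.inf`` if disconnected."""
    n = graph.num_nodes
    if not (0 <= u < n and 0 <= v < n):
        raise IndexError("node index out of range")
    if u == v:
        return 0
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in graph.edge_index.T:
        adj[a].append(int(b))
    dist = {u: 0}
    q = deque([u])
    while q:
        cur = q.popleft()
        for nb in adj[cur]:
            if nb not in dist:
                dist[nb] = dist[cur] + 1
                if nb == v:
                    return dist[nb]
                q.append(nb)
    return math.inf


# -- XYZ I/O ---------------------------------------------------------------

def read_xyz(path, r_c: float = DEFAULT_RADIUS_CUTOFF) -> AtomGraph:
    """Read a standard XYZ file and build edges by radius cutoff."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GraphInvalidError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise GraphInvalidError(f"{path}: line 1: expected an atom count") from None
    zs, xyz = [], []
    for ln, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise GraphInvalidError(f"{path}: line {ln}: expected 'symbol x y z'")
        zs.append(symbol_to_z(parts[0]))
        try:
            xyz.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise GraphInvalidError(f"{path}: line {ln}: bad coordinate") from None
    if len(zs) != n:
        raise GraphInvalidError(f"{path}: expected {n} atom lines, found {len(zs)}")
    coords = np.asarray(xyz)
    return AtomGraph(atomic_numbers=np.asarray(zs),
                     edge_index=build_radius_graph(coords, r_c),
                     coords=coords, graph_id=str(path))


def write_xyz(graph: AtomGraph, path, comment: str = "") -> None:
    if graph.coords is None:
        raise GraphInvalidError("cannot write XYZ without coordinates")
    with open(path, "w") as fh:
        fh.write(f"{graph.num_nodes}\n{comment}\n")
        for z, (x, y, zz) in zip(graph.atomic_numbers, graph.coords):
            fh.write(f"{z_to_symbol(z)} {float(x)!r} {float(y)!r} "
                     f"{float(zz)!r}\n")


# -- line-delimited graph container ---------------------------------------
# One JSON object per line.  Schema per record:
#   graph_id : str
#   z        : [int]                       atomic numbers
#   coords   : [[x,y,z], ...]  (optional)
#   edges    : [[u,v], ...]   each undirected edge once, u < v
#   x        : [[...], ...]   (optional)   raw node features
#   e        : [[...], ...]   (optional)   raw edge features, aligned with
#                                          `edges` (per undirected edge)
#   targets  : {name: scalar | [..]}

def _directed_from_undirected(pairs: np.ndarray,
                              feats: np.ndarray | None):
    if pairs.size == 0:
        ei = np.empty((2, 0), dtype=np.int64)
        return ei, (np.empty((0, feats.shape[1])) if feats is not None else None)
    both = np.concatenate([pairs, pairs[:, ::-1]], axis=0)
    ef = np.concatenate([feats, feats], axis=0) if feats is not None else None
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    if ef is not None:
        ef = ef[order]
    return both.T.copy(), ef


def graph_to_record(graph: AtomGraph) -> dict:
    rec: dict = {"graph_id": graph.graph_id,
                 "z": graph.atomic_numbers.tolist()}
    if graph.coords is not None:
        rec["coords"] = graph.coords.tolist()
    pairs = graph.undirected_edges()
    rec["edges"] = pairs.tolist()
    if graph.node_features is not None:
        rec["x"] = graph.node_features.tolist()
    if graph.edge_features is not None and graph.num_edges:
        # emit the (u, v) row with u < v for each undirected edge
        lookup = {(int(a), int(b)): i for i, (a, b) in enumerate(graph.edge_index.T)}
        rows = [graph.edge_features[lookup[(int(u), int(v))]].tolist()
                for u, v in pairs]
        rec["e"] = rows
    if graph.targets:
        rec["targets"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                          for k, v in graph.targets.items()}
    return rec


def record_to_graph(rec: dict) -> AtomGraph:
    pairs = np.asarray(rec.get("edges", []), dtype=np.int64).reshape(-1, 2)
    feats = np.asarray(rec["e"], dtype=np.float64) if "e" in rec else None
    edge_index, edge_features = _directed_from_undirected(pairs, feats)
    targets = {k: (np.asarray(v) if isinstance(v, list) else v)
               for k, v in rec.get("targets", {}).items()}
    return AtomGraph(
        atomic_numbers=np.asarray(rec["z"], dtype=np.int64),
        edge_index=edge_index,
        coords=np.asarray(rec["coords"], dtype=np.float64) if "coords" in rec else None,
        node_features=np.asarray(rec["x"], dtype=np.float64) if "x" in rec else None,
        edge_features=edge_features,
        targets=targets,
        graph_id=str(rec.get("graph_id", "")),
    )


def write_container(graphs, path) -> None:
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(json.dumps(graph_to_record(g)) + "\n")


def read_container(path) -> list[AtomGraph]:
    graphs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise GraphInvalidError(f"{path}: line {ln}: malformed record "
                                        f"({exc.msg})") from None
            try:
                graphs.append(record_to_graph(rec))
            except (KeyError, GraphInvalidError) as exc:
                raise GraphInvalidError(f"{path}: line {ln}: {exc}") from None
    return graphs
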