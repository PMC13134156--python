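"""Synthetic molecular-graph generator with controlled locality structure.

Molecules are grown by sequential attachment: each new atom is placed at a
random bond-like distance from a randomly chosen anchor atom, with rejection
sampling enforcing a minimum interatomic distance.  Edges come either from
the attachment/bonding structure (connected, degree <= 4) or from a radius
cutoff in Cartesian space.

Target families expose different interaction ranges:

* ``local``          — graph-level sum of 1-hop-computable atomic terms.
* ``dispersion``     — pairwise London-dispersion-like energy
                       y = sum_{u<v} -C6(Z_u, Z_v) / r_uv^6, optionally
                       restricted to pairs *beyond* the radius cutoff
                       (``beyond_cutoff``), which no 1-hop local model can
                       see — the long-range stressor.
* ``node_charge``    — per-atom electronegativity imbalance vs neighbors
                       (partial-charge-like node regression).
* ``motif_class``    — banded triangle count (multi-class).
* ``multilabel``     — K independent threshold indicators on graph statistics.

Per-element C6 coefficients are free-atom-scale values with plausible
relative magnitudes (H < C < heavier); pair coefficients combine by
geometric mean.  Only the ratios matter for the learning tasks; no
quantitative dispersion physics is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .encoders import element_table
from .graph_core import AtomGraph, DatasetSplit, GraphInvalidError, \
    build_radius_graph, make_split

__all__ = [
    "C6_TABLE",
    "GenSpec",
    "gen_molecule",
    "generate_dataset",
    "dispersion_target",
    "local_target",
    "node_charge_target",
    "motif_class",
    "multilabel_target",
]

#: per-element dispersion coefficients (a.u.-scale free-atom magnitudes)
C6_TABLE = {
    1: 6.5,     # H
    6: 46.6,    # C
    7: 24.2,    # N
    8: 15.6,    # O
    9: 9.5,     # F
    14: 305.0,  # Si
    15: 185.0,  # P
    16: 134.0,  # S
    17: 94.6,   # Cl
    35: 162.0,  # Br
}


@dataclass
class GenSpec:
    """All knobs of the generator; the seed fully determines the output."""

    n_graphs: int = 100
    n_atoms: tuple = (10, 30)
    palette: tuple = (1, 6, 7, 8)       # H, C, N, O
    min_dist: float = 1.1               # Å, hard lower bound on any pair
    max_dist: float = 1.8               # Å, anchor attachment upper bound
    edge_mode: str = "radius"           # radius | bond
    r_c: float = 3.0                    # Å, radius-mode cutoff
    target: str = "local"               # local | dispersion | node_charge
    #                                   | motif_class | multilabel
    dispersion_mode: str = "all"        # all | beyond_cutoff
    n_labels: int = 5
    noise_sd: float = 0.0
    seed: int = 0
    schema: str = "plain"               # plain | ogb9 | ppa7

    def __post_init__(self):
        if self.min_dist <= 0:
            raise ValueError("min_dist must be positive")
        if self.edge_mode not in ("radius", "bond"):
            raise ValueError("edge_mode must be 'radius' or 'bond'")
        if self.schema not in ("plain", "ogb9", "ppa7"):
            raise ValueError("schema must be plain/ogb9/ppa7")
        for z in self.palette:
            element_table().row(z)  # validates the palette


_MAX_PLACEMENT_TRIES = 200


def _place_atoms(n: int, spec: GenSpec, rng: np.random.Generator):
    """Sequential growth; returns (coords, anchor edge list)."""
    coords = np.zeros((n, 3))
    anchors = []
    for i in range(1, n):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            a = int(rng.integers(i))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            d = rng.uniform(spec.min_dist, spec.max_dist)
            pos = coords[a] + d * direction
            if np.all(np.linalg.norm(coords[:i] - pos, axis=1) >= spec.min_dist):
                coords[i] = pos
                anchors.append((a, i))
                break
        else:
            raise GraphInvalidError(
                "atom placement failed after "
                f"{_MAX_PLACEMENT_TRIES} tries; loosen min_dist/max_dist")
    return coords, anchors


def _bond_edges(n: int, coords: np.ndarray, anchors: list,
                rng: np.random.Generator) -> np.ndarray:
    """Attachment tree plus short ring-closure edges, degree <= 4."""
    deg = np.zeros(n, dtype=int)
    edges = set()
    for a, b in anchors:
        edges.add((min(a, b), max(a, b)))
        deg[a] += 1
        deg[b] += 1
    # close small rings between spatially close non-bonded pairs
    dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    close = np.argwhere((dist > 0) & (dist < 2.0))
    for u, v in close[rng.permutation(len(close))]:
        u, v = int(min(u, v)), int(max(u, v))
        if (u, v) in edges or deg[u] >= 4 or deg[v] >= 4:
            continue
        if rng.random() < 0.3:
            edges.add((u, v))
            deg[u] += 1
            deg[v] += 1
    pairs = np.asarray(sorted(edges), dtype=np.int64)
    both = np.concatenate([pairs, pairs[:, ::-1]], axis=0)
    order = np.lexsort((both[:, 1], both[:, 0]))
    return both[order].T.copy()


def _ogb9_features(graph_edges: np.ndarray, zs: np.ndarray, palette,
                   rng: np.random.Generator) -> np.ndarray:
    """OGB-style 9-channel integer atom features."""
    n = len(zs)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, graph_edges.T.tolist()))
    in_ring = np.zeros(n)
    for cycle in nx.cycle_basis(g):
        in_ring[cycle] = 1.0
    deg = np.asarray([g.degree(i) for i in range(n)], dtype=float)
    feats = np.column_stack([
        zs.astype(float),                      # atomic number
        deg,                                   # degree
        np.zeros(n),                           # formal charge
        rng.integers(0, 4, n).astype(float),   # attached hydrogens
        rng.integers(0, 4, n).astype(float),   # chirality tag
        rng.integers(0, 4, n).astype(float),   # hybridization
        (rng.random(n) < 0.2).astype(float),   # aromaticity flag
        in_ring,                               # ring membership
        np.zeros(n),                           # radical electrons
    ])
    return feats


def _ppa7_features(n_directed: int, rng: np.random.Generator) -> np.ndarray:
    """7-channel binary edge evidence vectors (>= 1 bit set per edge)."""
    n_und = n_directed // 2
    feats = (rng.random((n_und, 7)) < 0.3).astype(float)
    empty = feats.sum(axis=1) == 0
    feats[empty, rng.integers(0, 7, int(empty.sum()))] = 1.0
    return feats


def gen_molecule(spec: GenSpec, index: int) -> AtomGraph:
    """Deterministically generate molecule ``index`` of the spec."""
    rng = np.random.default_rng([spec.seed, index])
    n = int(rng.integers(spec.n_atoms[0], spec.n_atoms[1] + 1))
    zs = rng.choice(np.asarray(spec.palette, dtype=np.int64), size=n)
    coords, anchors = _place_atoms(n, spec, rng)
    if spec.edge_mode == "radius":
        edge_index = build_radius_graph(coords, spec.r_c)
    else:
        edge_index = _bond_edges(n, coords, anchors, rng)
    node_features = None
    edge_features = None
    if spec.schema in ("plain", "ogb9"):
        # interatomic distance as a continuous edge attribute
        d = np.linalg.norm(coords[edge_index[0]] - coords[edge_index[1]],
                           axis=1)
        edge_features = d.reshape(-1, 1)
    if spec.schema == "ogb9":
        node_features = _ogb9_features(edge_index, zs, spec.palette, rng)
    elif spec.schema == "ppa7":
        und = _ppa7_features(edge_index.shape[1], rng)
        # both directed rows of an undirected edge share one evidence vector
        pairs = np.sort(edge_index.T, axis=1)
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        edge_features = und[inverse]
    graph = AtomGraph(atomic_numbers=zs, edge_index=edge_index, coords=coords,
                      node_features=node_features, edge_features=edge_features,
                      graph_id=f"synth-{spec.seed}-{index}")
    _attach_targets(graph, spec, rng)
    return graph


# -- target families -------------------------------------------------------

def _c6(z: int) -> float:
    try:
        return C6_TABLE[int(z)]
    except KeyError:
        raise GraphInvalidError(f"no C6 coefficient for Z={z}") from None


def dispersion_target(graph: AtomGraph, mode: str = "all",
                      r_c: float | None = None) -> float:
    """y = sum over pairs of -sqrt(C6_u C6_v) / r_uv^6.

    ``beyond_cutoff`` restricts to pairs with r_uv >= r_c, a contribution
    invisible to 1-hop local aggregation on the radius graph.
    """
    if graph.coords is None:
        raise GraphInvalidError("dispersion target needs coordinates")
    if mode not in ("all", "beyond_cutoff"):
        raise ValueError("mode must be 'all' or 'beyond_cutoff'")
    if mode == "beyond_cutoff" and r_c is None:
        raise ValueError("beyond_cutoff mode needs r_c")
    zs = graph.atomic_numbers
    c6 = np.asarray([_c6(z) for z in zs])
    total = 0.0
    n = graph.num_nodes
    for u in range(n):
        for v in range(u + 1, n):
            r = float(np.linalg.norm(graph.coords[u] - graph.coords[v]))
            if r == 0.0:
                raise GraphInvalidError("coincident atoms")
            if mode == "beyond_cutoff" and r < r_c:
                continue
            total -= np.sqrt(c6[u] * c6[v]) / r ** 6
    return float(total)


def local_target(graph: AtomGraph) -> float:
    """Sum over atoms of f(Z_u, mean neighbor distance): 1-hop computable."""
    if graph.coords is None:
        raise GraphInvalidError("local target needs coordinates")
    total = 0.0
    for u in range(graph.num_nodes):
        nbrs = graph.neighbors(u)
        mean_r = float(np.mean(np.linalg.norm(
            graph.coords[nbrs] - graph.coords[u], axis=1))) if len(nbrs) else 0.0
        total += np.sqrt(_c6(graph.atomic_numbers[u])) * np.exp(-mean_r / 2.0)
    return float(total)


def node_charge_target(graph: AtomGraph) -> np.ndarray:
    """EN(Z_u) minus mean neighbor EN: partial-charge-like, node-level."""
    table = element_table()
    en = np.asarray([table.value(z, "en_pauling")
                     for z in graph.atomic_numbers])
    out = np.zeros(graph.num_nodes)
    for u in range(graph.num_nodes):
        nbrs = graph.neighbors(u)
        out[u] = en[u] - float(np.mean(en[nbrs])) if len(nbrs) else 0.0
    return out


def motif_class(graph: AtomGraph) -> int:
    """Banded triangle count: 0 / 1-2 / 3-5 / 6+ triangles -> class 0..3."""
    g = nx.Graph()
    g.add_nodes_from(range(graph.num_nodes))
    g.add_edges_from(map(tuple, graph.undirected_edges().tolist()))
    t = sum(nx.triangles(g).values()) // 3
    if t == 0:
        return 0
    if t <= 2:
        return 1
    if t <= 5:
        return 2
    return 3


def multilabel_target(graph: AtomGraph, k: int = 5) -> np.ndarray:
    """K independent threshold indicators on graph statistics."""
    g = nx.Graph()
    g.add_nodes_from(range(graph.num_nodes))
    g.add_edges_from(map(tuple, graph.undirected_edges().tolist()))
    degs = [d for _, d in g.degree()]
    stats = [
        graph.num_nodes > 18,
        float(np.mean(degs)) > 3.0,
        sum(nx.triangles(g).values()) > 0,
        bool(np.any(graph.atomic_numbers == 8)),
        nx.is_connected(g) and nx.diameter(g) > 5,
    ]
    if k > len(stats):
        raise ValueError(f"at most {len(stats)} labels supported")
    return np.asarray(stats[:k], dtype=np.float64)


def _attach_targets(graph: AtomGraph, spec: GenSpec,
                    rng: np.random.Generator) -> None:
    if spec.target == "local":
        y = local_target(graph) + rng.normal(0.0, spec.noise_sd) \
            if spec.noise_sd else local_target(graph)
        graph.targets["local"] = float(y)
    elif spec.target == "dispersion":
        y = dispersion_target(graph, spec.dispersion_mode, spec.r_c)
        if spec.noise_sd:
            y += rng.normal(0.0, spec.noise_sd)
        graph.targets["dispersion"] = float(y)
    elif spec.target == "node_charge":
        q = node_charge_target(graph)
        if spec.noise_sd:
            q = q + rng.normal(0.0, spec.noise_sd, size=q.shape)
        graph.targets["node_charge"] = q
    elif spec.target == "motif_class":
        graph.targets["motif_class"] = int(motif_class(graph))
    elif spec.target == "multilabel":
        graph.targets["multilabel"] = multilabel_target(graph, spec.n_labels)
    else:
        raise ValueError(f"unknown target family {spec.target!r}")


def generate_dataset(spec: GenSpec) -> list[AtomGraph]:
    return [gen_molecule(spec, i) for i in range(spec.n_graphs)]


def generate_split(spec: GenSpec, split_seed: int | None = None) -> DatasetSplit:
    graphs = generate_dataset(spec)
    return DatasetSplit(graphs=graphs,
                        split=make_split(len(graphs),
                                         spec.seed if split_seed is None
                                         else split_seed))
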