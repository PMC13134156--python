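"""Pre-computed per-graph feature channels and their standardization.

Four channels are computed per graph:

* **CE** — a 15-dimensional per-atom chemical descriptor vector looked up from
  an embedded element-property table (Z = 1..86): atomic weight, group,
  period, block (s/p/d/f as ordinal 0..3), valence electron count, covalent
  radius, van der Waals radius, Pauling and Allen electronegativities,
  electron affinity, first ionization energy, melting point, boiling point,
  density, and atomic volume.
* **TE (nodes)** — 9 classic centrality/structure measures: degree,
  closeness, betweenness, eigenvector centrality, PageRank, local clustering
  coefficient, k-core number, harmonic centrality, eccentricity.
* **TE (edges)** — 4 measures per edge: edge betweenness, Jaccard
  coefficient, Adamic-Adar score, preferential attachment.
* **LPE** — the k smallest *nonzero* eigenpairs of the combinatorial
  Laplacian L = D - A, unit-norm eigenvectors with a deterministic sign fix.

Graphs whose channels contain non-finite entries, or with fewer than the
requested number of nontrivial Laplacian eigenvectors, are discarded with a
reason code.  All channels are standardized (zero mean, unit variance) with
statistics fitted on the training split only.

Topological measures are computed unweighted on the undirected graph even
when edges carry distances; disconnected graphs use within-component
conventions for closeness/eccentricity and reachable-only sums for harmonic
centrality.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import scipy.linalg

from .graph_core import AtomGraph, GraphInvalidError

__all__ = [
    "CHEMICAL_PROPERTY_NAMES",
    "NODE_TOPOLOGY_NAMES",
    "EDGE_TOPOLOGY_NAMES",
    "ElementTable",
    "element_table",
    "chemical_descriptors",
    "node_topological_encodings",
    "edge_topological_encodings",
    "laplacian_pe",
    "EncodingBundle",
    "compute_bundle",
    "filter_invalid",
    "StandardizerStats",
    "fit_standardizer",
    "apply_standardizer",
]

CHEMICAL_PROPERTY_NAMES = (
    "atomic_weight", "group", "period", "block", "valence_electrons",
    "covalent_radius", "vdw_radius", "en_pauling", "en_allen",
    "electron_affinity", "ionization_energy", "melting_point",
    "boiling_point", "density", "atomic_volume",
)

NODE_TOPOLOGY_NAMES = (
    "degree", "closeness", "betweenness", "eigenvector", "pagerank",
    "clustering", "k_core", "harmonic", "eccentricity",
)

EDGE_TOPOLOGY_NAMES = (
    "edge_betweenness", "jaccard", "adamic_adar", "preferential_attachment",
)

_BLOCK_ORDINAL = {"s": 0, "p": 1, "d": 2, "f": 3}


class ElementTable:
    """Mapping Z -> 15 real properties; missing physical values are NaN."""

    def __init__(self, rows: dict[int, np.ndarray]):
        self._rows = rows
        self.max_z = max(rows)

    def row(self, z: int) -> np.ndarray:
        z = int(z)
        if z not in self._rows:
            raise GraphInvalidError(
                f"atomic number Z={z} outside the embedded element table "
                f"(1..{self.max_z})")
        return self._rows[z]

    def value(self, z: int, prop: str) -> float:
        return float(self.row(z)[CHEMICAL_PROPERTY_NAMES.index(prop)])


def _load_table() -> ElementTable:
    rows: dict[int, np.ndarray] = {}
    path = resources.files("atomgps.data").joinpath("element_properties.csv")
    with path.open() as fh:
        for rec in csv.DictReader(fh):
            vals = []
            for name in CHEMICAL_PROPERTY_NAMES:
                if name == "block":
                    vals.append(float(_BLOCK_ORDINAL[rec["block"]]))
                    continue
                key = {"covalent_radius": "covalent_radius_pm",
                       "vdw_radius": "vdw_radius_pm",
                       "electron_affinity": "electron_affinity_ev",
                       "ionization_energy": "ionization_energy_ev",
                       "melting_point": "melting_point_k",
                       "boiling_point": "boiling_point_k",
                       "density": "density_g_cm3",
                       "atomic_volume": "atomic_volume_cm3_mol",
                       }.get(name, name)
                raw = rec[key].strip()
                vals.append(float(raw) if raw else np.nan)
            rows[int(rec["z"])] = np.asarray(vals, dtype=np.float64)
    return ElementTable(rows)


_TABLE: ElementTable | None = None


def element_table() -> ElementTable:
    global _TABLE
    if _TABLE is None:
        _TABLE = _load_table()
    return _TABLE


def chemical_descriptors(atomic_numbers) -> np.ndarray:
    """N x 15 matrix of element properties, row v = properties of Z_v."""
    table = element_table()
    zs = np.asarray(atomic_numbers, dtype=np.int64)
    return np.stack([table.row(z) for z in zs])


# -- topological encodings -------------------------------------------------

def _to_networkx(graph: AtomGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.num_nodes))
    g.add_edges_from(map(tuple, graph.undirected_edges().tolist()))
    return g


def _eccentricity(g: nx.Graph) -> dict[int, float]:
    ecc = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        ecc.update(nx.eccentricity(sub))
    return ecc


def node_topological_encodings(graph: AtomGraph) -> np.ndarray:
    """N x 9 matrix; columns in the fixed NODE_TOPOLOGY_NAMES order.

    A convergence failure (e.g. eigenvector centrality on an edgeless graph)
    yields NaN entries, which trigger the downstream discard rule.
    """
    g = _to_networkx(graph)
    n = graph.num_nodes
    cols = {}
    cols["degree"] = dict(g.degree())
    cols["closeness"] = nx.closeness_centrality(g)
    cols["betweenness"] = nx.betweenness_centrality(g, normalized=True)
    try:
        if n == 1:
            cols["eigenvector"] = {0: 1.0}
        else:
            cols["eigenvector"] = nx.eigenvector_centrality(
                g, max_iter=10000, tol=1e-12)
    except (nx.PowerIterationFailedConvergence, nx.NetworkXException):
        cols["eigenvector"] = {v: np.nan for v in g}
    cols["pagerank"] = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=1000)
    cols["clustering"] = nx.clustering(g)
    cols["k_core"] = nx.core_number(g)
    cols["harmonic"] = nx.harmonic_centrality(g)
    cols["eccentricity"] = _eccentricity(g)
    out = np.empty((n, len(NODE_TOPOLOGY_NAMES)))
    for j, name in enumerate(NODE_TOPOLOGY_NAMES):
        out[:, j] = [cols[name][v] for v in range(n)]
    return out


def edge_topological_encodings(graph: AtomGraph) -> np.ndarray:
    """E x 4 matrix aligned with the columns of ``graph.edge_index``.

    All four measures are symmetric, so both directed rows of an undirected
    edge carry the same values.
    """
    if graph.num_edges == 0:
        raise GraphInvalidError("edge topological encodings need >= 1 edge")
    g = _to_networkx(graph)
    pairs = [tuple(p) for p in graph.undirected_edges().tolist()]
    ebc = nx.edge_betweenness_centrality(g, normalized=True)
    jac = {(u, v): s for u, v, s in nx.jaccard_coefficient(g, pairs)}
    aa = {(u, v): s for u, v, s in nx.adamic_adar_index(g, pairs)}
    pa = {(u, v): s for u, v, s in nx.preferential_attachment(g, pairs)}
    per_pair = {}
    for u, v in pairs:
        row = [ebc.get((u, v), ebc.get((v, u))), jac[(u, v)], aa[(u, v)],
               pa[(u, v)]]
        per_pair[(u, v)] = row
        per_pair[(v, u)] = row
    return np.asarray([per_pair[(int(a), int(b))]
                       for a, b in graph.edge_index.T], dtype=np.float64)


# -- Laplacian positional encodings ---------------------------------------

#: eigenvalues below this fraction of the largest are treated as zero
_ZERO_TOL_REL = 1e-8


def laplacian_pe(graph: AtomGraph, k: int):
    """N x k matrix of the k smallest-nonzero Laplacian eigenvectors.

    Columns are unit-norm eigenvectors of L = D - A, sorted by ascending
    eigenvalue; the sign of each column is fixed by making its
    largest-magnitude entry positive (ties broken by lowest index).  Returns
    ``None`` ("insufficient") when the graph has fewer than k nonzero
    eigenpairs.  The accompanying eigenvalues are returned for diagnostics.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = graph.num_nodes
    a = np.zeros((n, n))
    for u, v in graph.edge_index.T:
        a[u, v] = 1.0
    lap = np.diag(a.sum(axis=1)) - a
    w, vecs = scipy.linalg.eigh(lap)
    tol = _ZERO_TOL_REL * max(w[-1], 1.0)
    nz = np.nonzero(w > tol)[0]
    if len(nz) < k:
        return None
    sel = nz[:k]
    out = vecs[:, sel].copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out, w[sel].copy()


# -- bundle computation and the discard rule -------------------------------

@dataclass
class EncodingBundle:
    """Per-graph computed channels: C (N x 15), P (N x 9), G (E x 4), L (N x k)."""

    C: np.ndarray
    P: np.ndarray
    G: np.ndarray
    L: np.ndarray


def compute_bundle(graph: AtomGraph, d_l: int):
    """Compute all channels; returns (bundle, None) or (None, reason)."""
    if graph.coords is not None and not np.all(np.isfinite(graph.coords)):
        return None, "non-finite coords"
    try:
        c = chemical_descriptors(graph.atomic_numbers)
    except GraphInvalidError as exc:
        return None, f"CE failed: {exc}"
    if not np.all(np.isfinite(c)):
        return None, "non-finite CE"
    p = node_topological_encodings(graph)
    if not np.all(np.isfinite(p)):
        return None, "non-finite node TE"
    try:
        g = edge_topological_encodings(graph)
    except GraphInvalidError:
        return None, "no edges for edge TE"
    if not np.all(np.isfinite(g)):
        return None, "non-finite edge TE"
    lpe = laplacian_pe(graph, d_l)
    if lpe is None:
        return None, "insufficient LPE"
    l_mat, _ = lpe
    return EncodingBundle(C=c, P=p, G=g, L=l_mat), None


def filter_invalid(graphs, d_l: int):
    """Retain graphs with fully finite bundles and sufficient LPE columns.

    Returns (retained_graphs, bundles, discard_log) where discard_log is a
    list of (graph_id, reason) pairs.
    """
    kept, bundles, log = [], [], []
    for g in graphs:
        bundle, reason = compute_bundle(g, d_l)
        if bundle is None:
            log.append((g.graph_id, reason))
        else:
            kept.append(g)
            bundles.append(bundle)
    return kept, bundles, log


# -- standardization -------------------------------------------------------

@dataclass
class StandardizerStats:
    """Per-column mean/std fitted on one split; constant columns flagged."""

    mean: np.ndarray
    std: np.ndarray
    constant: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.constant is None:
            self.constant = np.zeros_like(self.mean, dtype=bool)


_CONST_EPS = 1e-12


def fit_standardizer(matrices) -> StandardizerStats:
    """Fit per-column mean/std on stacked rows of the given matrices."""
    mats = [np.asarray(m, dtype=np.float64) for m in matrices if m is not None]
    if not mats or sum(m.shape[0] for m in mats) == 0:
        raise ValueError("cannot fit a standardizer on an empty split")
    stacked = np.concatenate(mats, axis=0)
    mean = stacked.mean(axis=0)
    std = stacked.std(axis=0, ddof=1) if stacked.shape[0] > 1 \
        else np.zeros(stacked.shape[1])
    constant = std <= _CONST_EPS
    std = np.where(constant, 1.0, std)
    return StandardizerStats(mean=mean, std=std, constant=constant)


def apply_standardizer(matrix: np.ndarray, stats: StandardizerStats) -> np.ndarray:
    """(x - mean) / std per column; constant columns map to exactly zero."""
    out = (np.asarray(matrix, dtype=np.float64) - stats.mean) / stats.std
    out[:, stats.constant] = 0.0
    return out
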