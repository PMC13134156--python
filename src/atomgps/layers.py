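"""Learnable building blocks: MPNN layers, geometric messages, global
multi-head attention, hybrid local/global (GPS-style) layers, and pooling.

Message passing follows the aggregate-update form: per-edge messages are a
linear transform of the sender state (optionally edge-conditioned), reduced
over each node's neighborhood by sum / mean / max / neighbor-attention, then
combined with the previous state by an MLP or GRU-style gated update.
Isolated nodes receive a zero aggregate and are transformed by the update
alone.

The geometric path embeds interatomic distances (Gaussian radial basis on
[0, r_c]) and neighbor angles (cosine features cos(n*theta), n = 0..7) into a
latent edge representation; only distances and angles enter, so outputs are
invariant under rigid motions of the coordinates.

Global attention is computed strictly within each graph of a batch (block
masking by graph membership), with the divided per-head width convention
d_head = d_model / heads.

A hybrid layer sums the local (MPNN) and global (attention) branch outputs
elementwise and fuses them with an MLP; the edge state passes through the
local branch unchanged.  No residual connections or normalization are applied
unless explicitly enabled.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .autodiff import (Tensor, concat, segment_max, segment_mean, segment_min,
                       segment_softmax, segment_sum, softmax)
from .graph_core import GraphInvalidError

__all__ = [
    "Linear",
    "MLP",
    "MPNNLayer",
    "GeomEdgeState",
    "geometric_features",
    "GeometricEdgeEmbedding",
    "GeometricMPNNLayer",
    "MultiHeadAttention",
    "GPSLayer",
    "pool",
    "AGGREGATORS",
    "POOL_MODES",
]

AGGREGATORS = ("sum", "mean", "max", "attention")
POOL_MODES = ("min", "max", "sum", "mean")


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        bound = 1.0 / np.sqrt(d_in)
        self.W = Tensor(rng.uniform(-bound, bound, (d_in, d_out)),
                        requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, (d_out,)),
                        requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y if self.b is None else y + self.b

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class MLP:
    """Fully connected stack with ReLU between layers (none after the last)."""

    def __init__(self, widths: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class MPNNLayer:
    """Generic message-passing layer.

    Messages to node u from neighbor v: ``m = h_v W_m (+ e_uv W_e)``;
    aggregation over the neighborhood by ``aggregator``; update by an MLP on
    ``[aggregate || h_u]`` or a GRU-style gate.  ``message_fn``/``update_fn``
    may override the defaults (used for hand-computed checks).
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 d_edge: int = 0, aggregator: str = "sum", update: str = "mlp",
                 message_fn=None, update_fn=None):
        if aggregator not in AGGREGATORS:
            raise ValueError(f"aggregator must be one of {AGGREGATORS}")
        self.aggregator = aggregator
        self.d_in, self.d_out, self.d_edge = d_in, d_out, d_edge
        self.message_fn = message_fn
        self.update_fn = update_fn
        self._params: list[Tensor] = []
        if message_fn is None:
            self.W_m = Linear(d_in, d_out, rng, bias=False)
            self._params += self.W_m.parameters()
            self.W_e = None
            if d_edge > 0:
                self.W_e = Linear(d_edge, d_out, rng, bias=False)
                self._params += self.W_e.parameters()
        if aggregator == "attention":
            self.att = Linear(d_in + d_out, 1, rng, bias=False)
            self._params += self.att.parameters()
        if update_fn is None:
            if update == "mlp":
                self.upd = MLP([d_out + d_in, d_out, d_out], rng)
                self._params += self.upd.parameters()
                self._update = self._update_mlp
            elif update == "gru":
                self.Wz = Linear(d_out + d_in, d_out, rng)
                self.Wc = Linear(d_out + d_in, d_out, rng)
                self.Wh = None
                if d_in != d_out:
                    self.Wh = Linear(d_in, d_out, rng, bias=False)
                    self._params += self.Wh.parameters()
                self._params += self.Wz.parameters() + self.Wc.parameters()
                self._update = self._update_gru
            else:
                raise ValueError("update must be 'mlp' or 'gru'")

    def _update_mlp(self, agg: Tensor, h: Tensor) -> Tensor:
        return self.upd(concat([agg, h], axis=-1))

    def _update_gru(self, agg: Tensor, h: Tensor) -> Tensor:
        z = self.Wz(concat([agg, h], axis=-1)).sigmoid()
        cand = self.Wc(concat([agg, h], axis=-1)).tanh()
        h0 = self.Wh(h) if self.Wh is not None else h
        return (1.0 - z) * h0 + z * cand

    def __call__(self, H: Tensor, edge_index: np.ndarray, E=None) -> Tensor:
        n = H.shape[0]
        recv, send = edge_index[0], edge_index[1]
        if E is not None and self.message_fn is None and self.W_e is None \
                and self.d_edge == 0:
            E = None  # layer was built without an edge channel
        if E is not None and E.shape[-1] != self.d_edge and self.message_fn is None:
            raise ValueError(f"edge feature width {E.shape[-1]} != "
                             f"layer d_edge {self.d_edge}")
        if edge_index.size == 0:
            agg = Tensor(np.zeros((n, self.d_out)))
        else:
            if self.message_fn is not None:
                msg = self.message_fn(H[recv], H[send], E)
            else:
                msg = self.W_m(H[send])
                if E is not None and self.W_e is not None:
                    msg = msg + self.W_e(E if isinstance(E, Tensor) else Tensor(E))
            if self.aggregator == "sum":
                agg = segment_sum(msg, recv, n)
            elif self.aggregator == "mean":
                agg = segment_mean(msg, recv, n)
            elif self.aggregator == "max":
                agg = segment_max(msg, recv, n)
            else:  # neighbor attention, softmax per receiving node
                logits = self.att(concat([H[recv], msg], axis=-1)) \
                    .leaky_relu(0.2).reshape(-1)
                alpha = segment_softmax(logits, recv, n)
                agg = segment_sum(alpha.reshape(-1, 1) * msg, recv, n)
        if self.update_fn is not None:
            return self.update_fn(agg, H)
        return self._update(agg, H)

    def neighbor_attention_weights(self, H: Tensor, edge_index: np.ndarray,
                                   E=None) -> np.ndarray:
        """Per-edge attention coefficients (diagnostics; attention aggregator)."""
        recv, send = edge_index[0], edge_index[1]
        msg = self.W_m(H[send])
        if E is not None and self.W_e is not None:
            msg = msg + self.W_e(E if isinstance(E, Tensor) else Tensor(E))
        logits = self.att(concat([H[recv], msg], axis=-1)).leaky_relu(0.2) \
            .reshape(-1)
        return segment_softmax(logits, recv, H.shape[0]).data

    def parameters(self):
        return list(self._params)


# -- geometric path --------------------------------------------------------

@dataclass
class GeomEdgeState:
    """Distances r_uv (Å) and neighbor angles theta_uvw (radians) per edge.

    ``angles[j]`` holds the angles at u between (u -> v) and (u -> w) for
    every other neighbor w of u, for edge column j = (u, v).
    """

    edge_index: np.ndarray
    distances: np.ndarray
    angles: list


def geometric_features(coords: np.ndarray, edge_index: np.ndarray) -> GeomEdgeState:
    coords = np.asarray(coords, dtype=np.float64)
    vec = coords[edge_index[1]] - coords[edge_index[0]]
    dist = np.linalg.norm(vec, axis=1)
    if np.any(dist == 0.0):
        raise GraphInvalidError("coincident atoms on an edge (r_uv = 0)")
    nbrs: dict[int, list[int]] = defaultdict(list)
    for u, v in edge_index.T:
        nbrs[int(u)].append(int(v))
    angles = []
    for u, v in edge_index.T:
        u, v = int(u), int(v)
        a = coords[v] - coords[u]
        na = np.linalg.norm(a)
        th = []
        for w in nbrs[u]:
            if w == v:
                continue
            b = coords[w] - coords[u]
            cosang = np.dot(a, b) / (na * np.linalg.norm(b))
            th.append(np.arccos(np.clip(cosang, -1.0, 1.0)))
        angles.append(np.asarray(th))
    return GeomEdgeState(edge_index=edge_index, distances=dist, angles=angles)


class GeometricEdgeEmbedding:
    """e_uv = phi_l(r_uv) + sum_w phi_a(theta_uvw).

    phi_l: Gaussian radial basis (n_radial centers uniform on [0, r_c], width
    = spacing) followed by a learnable linear map; phi_a: cosine features
    cos(n*theta), n = 0..n_angular-1, followed by a learnable linear map.
    Both maps share the output width.
    """

    def __init__(self, d_out: int, rng: np.random.Generator,
                 r_c: float = 5.0, n_radial: int = 16, n_angular: int = 8):
        self.r_c = r_c
        self.centers = np.linspace(0.0, r_c, n_radial)
        self.width = self.centers[1] - self.centers[0] if n_radial > 1 else r_c
        self.n_angular = n_angular
        self.W_r = Linear(n_radial, d_out, rng, bias=False)
        self.W_a = Linear(n_angular, d_out, rng, bias=False)

    def basis(self, state: GeomEdgeState) -> tuple[np.ndarray, np.ndarray]:
        r = state.distances[:, None]
        rbf = np.exp(-((r - self.centers) ** 2) / (2.0 * self.width ** 2))
        nvec = np.arange(self.n_angular)
        ang = np.zeros((len(state.angles), self.n_angular))
        for j, th in enumerate(state.angles):
            if th.size:
                ang[j] = np.cos(np.outer(th, nvec)).sum(axis=0)
        return rbf, ang

    def __call__(self, state: GeomEdgeState) -> Tensor:
        rbf, ang = self.basis(state)
        return self.W_r(Tensor(rbf)) + self.W_a(Tensor(ang))

    def parameters(self):
        return self.W_r.parameters() + self.W_a.parameters()


class GeometricMPNNLayer:
    """Messages m_{u<-v} = xi(h_u, h_v, e_uv), aggregated (sum by default)
    and combined with h_u by an MLP update."""

    def __init__(self, d_in: int, d_out: int, d_geo: int,
                 rng: np.random.Generator, aggregator: str = "sum"):
        if aggregator not in ("sum", "mean", "max"):
            raise ValueError("geometric aggregator must be sum/mean/max")
        self.aggregator = aggregator
        self.d_out = d_out
        self.xi = MLP([2 * d_in + d_geo, d_out, d_out], rng)
        self.upd = MLP([d_out + d_in, d_out, d_out], rng)

    def __call__(self, H: Tensor, edge_index: np.ndarray, e_bar: Tensor) -> Tensor:
        n = H.shape[0]
        if edge_index.size == 0:
            agg = Tensor(np.zeros((n, self.d_out)))
        else:
            recv, send = edge_index[0], edge_index[1]
            msg = self.xi(concat([H[recv], H[send], e_bar], axis=-1))
            if self.aggregator == "sum":
                agg = segment_sum(msg, recv, n)
            elif self.aggregator == "mean":
                agg = segment_mean(msg, recv, n)
            else:
                agg = segment_max(msg, recv, n)
        return self.upd(concat([agg, H], axis=-1))

    def parameters(self):
        return self.xi.parameters() + self.upd.parameters()


# -- global attention ------------------------------------------------------

class MultiHeadAttention:
    """Scaled dot-product self-attention over the nodes of each graph.

    ``d_model`` must be divisible by ``heads``; per-head width is
    d_model / heads and head outputs are concatenated then projected by W_O.
    Attention is blocked by graph membership: attention mass across graphs in
    a batch is exactly zero.
    """

    def __init__(self, d_model: int, heads: int, rng: np.random.Generator):
        if heads < 1 or d_model % heads != 0:
            raise ValueError(
                f"hidden width {d_model} not divisible by heads {heads}")
        self.d_model, self.heads = d_model, heads
        self.d_head = d_model // heads
        self.W_Q = Linear(d_model, d_model, rng, bias=False)
        self.W_K = Linear(d_model, d_model, rng, bias=False)
        self.W_V = Linear(d_model, d_model, rng, bias=False)
        self.W_O = Linear(d_model, d_model, rng, bias=False)
        self.last_attention: np.ndarray | None = None
        self._last = None

    @staticmethod
    def _padding(member: np.ndarray):
        """Pack each graph's nodes into padded rows of width n_max."""
        num_graphs = int(member.max()) + 1 if member.size else 0
        counts = np.bincount(member, minlength=num_graphs)
        n_max = int(counts.max())
        pad_idx = np.zeros((num_graphs, n_max), dtype=np.intp)
        valid = np.zeros((num_graphs, n_max), dtype=bool)
        slot = np.zeros(member.size, dtype=np.intp)
        fill = np.zeros(num_graphs, dtype=np.intp)
        for i, g in enumerate(member):
            pad_idx[g, fill[g]] = i
            valid[g, fill[g]] = True
            slot[i] = g * n_max + fill[g]
            fill[g] += 1
        return pad_idx, valid, slot, n_max

    def __call__(self, H: Tensor, graph_membership: np.ndarray) -> Tensor:
        n = H.shape[0]
        member = np.asarray(graph_membership)
        pad_idx, valid, slot, n_max = self._padding(member)
        num_graphs = pad_idx.shape[0]

        def split(x: Tensor) -> Tensor:
            # (G*n_max, d) -> (G, heads, n_max, d_head)
            return x[pad_idx.reshape(-1)] \
                .reshape(num_graphs, n_max, self.heads, self.d_head) \
                .transpose(0, 2, 1, 3)

        q, k, v = split(self.W_Q(H)), split(self.W_K(H)), split(self.W_V(H))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        # padding slots are excluded; cross-graph mass is structurally zero
        col_mask = np.where(valid, 0.0, -np.inf)[:, None, None, :]
        attn = softmax(scores + Tensor(col_mask), axis=-1)
        self._last = (attn.data, pad_idx, valid, member)
        out = (attn @ v).transpose(0, 2, 1, 3) \
            .reshape(num_graphs * n_max, self.d_model)[slot]
        return self.W_O(out)

    def last_attention_dense(self) -> np.ndarray:
        """(heads, N, N) attention weights of the last call (diagnostics);
        entries across graph boundaries are exactly zero."""
        attn, pad_idx, valid, member = self._last
        n = member.size
        dense = np.zeros((self.heads, n, n))
        for g in range(pad_idx.shape[0]):
            rows = pad_idx[g][valid[g]]
            block = attn[g][:, valid[g]][:, :, valid[g]]
            dense[np.ix_(range(self.heads), rows, rows)] = block
        self.last_attention = dense
        return dense

    def parameters(self):
        return (self.W_Q.parameters() + self.W_K.parameters()
                + self.W_V.parameters() + self.W_O.parameters())


class GPSLayer:
    """Hybrid layer: X' = MLP(local(X) + global(X)); edge state from the
    local branch only (identity here).  Optional residual + layer norm are
    off by default, matching the bare additive-fusion form."""

    def __init__(self, mpnn_block, attn_block, mlp_block,
                 residual: bool = False):
        self.mpnn = mpnn_block
        self.attn = attn_block
        self.mlp = mlp_block
        self.residual = residual

    def __call__(self, X: Tensor, edge_index: np.ndarray,
                 graph_membership: np.ndarray, E=None, e_bar=None):
        if isinstance(self.mpnn, GeometricMPNNLayer):
            xm = self.mpnn(X, edge_index, e_bar)
        else:
            xm = self.mpnn(X, edge_index, E)
        xt = self.attn(X, graph_membership)
        out = self.mlp(xm + xt)
        if self.residual:
            out = out + X
        return out, E

    def parameters(self):
        return (self.mpnn.parameters() + self.attn.parameters()
                + self.mlp.parameters())


# -- pooling ---------------------------------------------------------------

def pool(H: Tensor, graph_membership: np.ndarray, num_graphs: int,
         mode: str = "mean") -> Tensor:
    """Permutation-invariant reduction of node states per graph."""
    if mode not in POOL_MODES:
        raise ValueError(f"pooling mode must be one of {POOL_MODES}")
    member = np.asarray(graph_membership)
    counts = np.bincount(member, minlength=num_graphs)
    if np.any(counts == 0):
        raise ValueError("cannot pool an empty graph")
    if mode == "sum":
        return segment_sum(H, member, num_graphs)
    if mode == "mean":
        return segment_mean(H, member, num_graphs)
    if mode == "max":
        return segment_max(H, member, num_graphs)
    return segment_min(H, member, num_graphs)
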