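"""Scheme-specific model assembly, multitask heads, losses, and metrics.

Four controlled configurations share one code path:

* S1 — plain message passing on raw features (no learned embeddings).
* S2 — message passing over fused chemical/topological/spectral encodings.
* S3 — hybrid layers (local messages + global attention) with [X || LPE]
  node inputs and the LPE-difference edge channel.
* S4 — fully fused: hybrid layers over all encodings.

S1/S2 stack plain MPNN layers; S3/S4 stack hybrid (GPS-style) layers.  A
shared trunk feeds task-specific decoder heads (hard parameter sharing);
graph-level heads pool node states first, node-level heads do not.  The
global objective is a weighted sum of per-task losses: squared error for
regression, cross-entropy for multi-class, per-label binary cross-entropy
with missing-label masking for multi-label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.stats
from sklearn.metrics import average_precision_score

from .autodiff import Tensor
from . import encoders as enc
from .embeddings import (EdgeEmbedding, EmbeddingSpec, NodeEmbedding,
                         edge_input_channels, flags_to_scheme,
                         node_input_channels, scheme_flags)
from .graph_core import AtomGraph, DatasetSplit
from .layers import (GPSLayer, GeometricEdgeEmbedding, GeometricMPNNLayer,
                     MLP, MPNNLayer, MultiHeadAttention, geometric_features,
                     pool)

__all__ = [
    "TaskSpec",
    "ModelConfig",
    "ChannelLayout",
    "MPNN_TYPES",
    "AtomGraphModel",
    "GraphBatch",
    "PreparedDataset",
    "multitask_loss",
    "metrics",
    "parameter_count",
    "save_checkpoint",
    "load_checkpoint",
]

#: implemented backbone menu, conditioned on coordinate availability
MPNN_TYPES = {
    "geometric-mpnn": {"needs_coords": True},
    "edgecond-sum": {"aggregator": "sum"},
    "edgecond-mean": {"aggregator": "mean"},
    "neighbor-attention": {"aggregator": "attention"},
}


@dataclass
class TaskSpec:
    """One prediction task: level (graph/node), type, loss weight, metric."""

    name: str
    level: str = "graph"           # graph | node
    kind: str = "regression"       # regression | multiclass | multilabel
    out_dim: int = 1
    weight: float = 1.0

    def __post_init__(self):
        if self.level not in ("graph", "node"):
            raise ValueError("task level must be 'graph' or 'node'")
        if self.kind not in ("regression", "multiclass", "multilabel"):
            raise ValueError("task kind must be regression/multiclass/multilabel")
        if self.weight <= 0:
            raise ValueError("task weights must be positive")

    @property
    def metric(self) -> str:
        return {"regression": "mae", "multiclass": "accuracy",
                "multilabel": "map"}[self.kind]


@dataclass
class ModelConfig:
    """Architecture switchboard; field names follow the run-config keys."""

    mpnn_type: str = "edgecond-sum"
    num_conv_layers: int = 2
    hidden_dim: int = 16
    edge_embed_dim: int = 0
    global_attn_engine: bool = False
    use_encodings: bool = False
    global_attn_heads: int = 0
    has_pos: bool = False
    pooling: str = "mean"
    lpe_dim: int = 2
    learning_rate: float = 1e-3
    update: str = "mlp"
    tasks: list = field(default_factory=lambda: [TaskSpec("y")])

    def __post_init__(self):
        self.tasks = [t if isinstance(t, TaskSpec) else TaskSpec(**t)
                      for t in self.tasks]
        if self.mpnn_type not in MPNN_TYPES:
            raise ValueError(f"unknown mpnn_type {self.mpnn_type!r}; "
                             f"choose from {sorted(MPNN_TYPES)}")
        if MPNN_TYPES[self.mpnn_type].get("needs_coords") and not self.has_pos:
            raise ValueError("geometric-mpnn requires has_pos=True")
        if self.global_attn_engine:
            if self.global_attn_heads < 1:
                raise ValueError("attention enabled but global_attn_heads = 0")
            if self.hidden_dim % self.global_attn_heads != 0:
                raise ValueError(
                    f"hidden_dim {self.hidden_dim} not divisible by "
                    f"global_attn_heads {self.global_attn_heads}")
        elif self.global_attn_heads != 0:
            raise ValueError("global_attn_heads must be 0 when attention is off")
        if self.num_conv_layers < 1:
            raise ValueError("num_conv_layers must be >= 1")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")

    @property
    def scheme(self) -> str:
        return flags_to_scheme(self.global_attn_engine, self.use_encodings)

    @classmethod
    def for_scheme(cls, scheme: str, **kw) -> "ModelConfig":
        attn, encd = scheme_flags(scheme)
        kw.setdefault("global_attn_heads", 2 if attn else 0)
        return cls(global_attn_engine=attn, use_encodings=encd, **kw)


@dataclass
class ChannelLayout:
    """Widths of the raw channels a dataset provides."""

    p: int          # raw node feature width
    f: int = 0      # raw edge feature width (0 = absent)
    d_l: int = 0    # LPE columns (0 = not computed)


# -- batching --------------------------------------------------------------

def _raw_x(g: AtomGraph) -> np.ndarray:
    """Raw node features; atomic number Z as the fallback base attribute."""
    if g.node_features is not None:
        return g.node_features
    return g.atomic_numbers.astype(np.float64).reshape(-1, 1)

@dataclass
class GraphBatch:
    """Block-diagonal concatenation of prepared graphs."""

    X: np.ndarray
    edge_index: np.ndarray
    membership: np.ndarray
    num_graphs: int
    L: np.ndarray | None = None
    P: np.ndarray | None = None
    C: np.ndarray | None = None
    E: np.ndarray | None = None
    G: np.ndarray | None = None
    coords: np.ndarray | None = None
    targets: dict = field(default_factory=dict)

    @property
    def num_nodes(self) -> int:
        return self.X.shape[0]


def collate(prepared: list[dict]) -> GraphBatch:
    """Stack prepared per-graph arrays with node-index offsets."""
    def cat(key):
        vals = [g[key] for g in prepared]
        if any(v is None for v in vals):
            return None
        return np.concatenate(vals, axis=0)

    offsets = np.cumsum([0] + [g["X"].shape[0] for g in prepared[:-1]])
    ei = np.concatenate([g["edge_index"] + off
                         for g, off in zip(prepared, offsets)], axis=1)
    member = np.concatenate([np.full(g["X"].shape[0], i)
                             for i, g in enumerate(prepared)])
    # _prepare normalizes every target to 2-D (graph-level: (1, d);
    # node-level: (N, d)), so concatenation along axis 0 suffices
    targets = {name: np.concatenate([g["targets"][name] for g in prepared],
                                    axis=0)
               for name in prepared[0]["targets"]}
    return GraphBatch(X=cat("X"), edge_index=ei, membership=member,
                      num_graphs=len(prepared), L=cat("L"), P=cat("P"),
                      C=cat("C"), E=cat("E"), G=cat("G"), coords=cat("coords"),
                      targets=targets)


class PreparedDataset:
    """Encodings + standardization over a train/val/test split.

    Encoding channels and regression targets are standardized with
    statistics fitted on the training split only and applied unchanged to
    val/test.
    """

    def __init__(self, split: DatasetSplit, config: ModelConfig):
        self.config = config
        need_enc = config.use_encodings or config.global_attn_engine
        graphs = {part: split.subset(part) for part in ("train", "val", "test")}
        bundles = {}
        if need_enc:
            for part, gs in graphs.items():
                bs = []
                for g in gs:
                    bundle, reason = enc.compute_bundle(g, config.lpe_dim)
                    if bundle is None:
                        raise ValueError(
                            f"graph {g.graph_id!r} invalid ({reason}); run "
                            "encoders.filter_invalid before building the split")
                    bs.append(bundle)
                bundles[part] = bs
        self._fit_standardizers(graphs, bundles, need_enc)
        self.prepared = {part: [self._prepare(g, bundles[part][i] if need_enc else None)
                                for i, g in enumerate(gs)]
                         for part, gs in graphs.items()}

    def _fit_standardizers(self, graphs, bundles, need_enc):
        train = graphs["train"]
        self.stats = {}
        self.stats["X"] = enc.fit_standardizer([_raw_x(g) for g in train])
        if train and train[0].edge_features is not None:
            self.stats["E"] = enc.fit_standardizer(
                [g.edge_features for g in train])
        if need_enc:
            for key in ("C", "P", "G", "L"):
                self.stats[key] = enc.fit_standardizer(
                    [getattr(b, key) for b in bundles["train"]])
        self.target_stats = {}
        for task in self.config.tasks:
            if task.kind != "regression":
                continue
            vals = [np.asarray(g.targets[task.name], dtype=np.float64)
                    .reshape(-1, 1) if np.asarray(g.targets[task.name]).ndim <= 1
                    else np.asarray(g.targets[task.name], dtype=np.float64)
                    for g in train]
            self.target_stats[task.name] = enc.fit_standardizer(vals)

    def _prepare(self, g: AtomGraph, bundle) -> dict:
        def std(key, arr):
            if arr is None:
                return None
            return enc.apply_standardizer(arr, self.stats[key]) \
                if key in self.stats else np.asarray(arr, dtype=np.float64)

        out = {
            "X": std("X", _raw_x(g)),
            "edge_index": g.edge_index,
            "coords": g.coords,
            "E": std("E", g.edge_features),
            "C": std("C", bundle.C) if bundle else None,
            "P": std("P", bundle.P) if bundle else None,
            "G": std("G", bundle.G) if bundle else None,
            "L": std("L", bundle.L) if bundle else None,
            "targets": {},
        }
        for task in self.config.tasks:
            y = np.asarray(g.targets[task.name], dtype=np.float64)
            if task.kind == "regression":
                y2 = y.reshape(-1, 1) if y.ndim <= 1 else y
                y2 = enc.apply_standardizer(y2, self.target_stats[task.name])
            elif task.level == "graph":
                y2 = y.reshape(1, -1)          # class label or label vector
            else:
                y2 = y.reshape(g.num_nodes, -1)
            out["targets"][task.name] = y2
        return out

    def layout(self) -> ChannelLayout:
        g0 = self.prepared["train"][0]
        return ChannelLayout(
            p=g0["X"].shape[1],
            f=0 if g0["E"] is None else g0["E"].shape[1],
            d_l=0 if g0["L"] is None else g0["L"].shape[1])

    def batch(self, part: str) -> GraphBatch:
        return collate(self.prepared[part])

    def minibatches(self, part: str, batch_size: int,
                    rng: np.random.Generator | None = None):
        items = self.prepared[part]
        order = np.arange(len(items)) if rng is None else rng.permutation(len(items))
        for start in range(0, len(items), batch_size):
            yield collate([items[i] for i in order[start:start + batch_size]])


# -- model -----------------------------------------------------------------

class AtomGraphModel:
    """Shared trunk (embeddings + conv stack) with task-specific heads."""

    def __init__(self, config: ModelConfig, layout: ChannelLayout, seed: int = 0):
        self.config = config
        self.layout = layout
        rng = np.random.default_rng(seed)
        scheme = config.scheme
        d_h = config.hidden_dim

        # node embedding
        node_widths = self._node_widths(scheme, layout)
        self.emb_spec = EmbeddingSpec(scheme=scheme, d_h=d_h,
                                      d_e=config.edge_embed_dim)
        self.node_embed = NodeEmbedding(self.emb_spec, node_widths, rng)
        trunk_in = layout.p if scheme == "S1" else d_h

        # edge side
        self.geo_embed = None
        self._edge_width = 0
        if config.mpnn_type == "geometric-mpnn":
            d_geo = config.edge_embed_dim or d_h
            self.geo_embed = GeometricEdgeEmbedding(d_geo, rng)
            self._edge_width = d_geo
            self.edge_embed = None
        else:
            widths = self._edge_widths(scheme, layout, config.edge_embed_dim)
            self.edge_embed = EdgeEmbedding(self.emb_spec, widths, rng) \
                if widths else None
            if widths:
                self._edge_width = config.edge_embed_dim \
                    if config.edge_embed_dim > 0 and scheme != "S1" \
                    else sum(widths)

        # conv stack
        agg = MPNN_TYPES[config.mpnn_type].get("aggregator", "sum")
        self.convs = []
        d_in = trunk_in
        for _ in range(config.num_conv_layers):
            if config.mpnn_type == "geometric-mpnn":
                block = GeometricMPNNLayer(d_in, d_h, self._edge_width, rng)
            else:
                block = MPNNLayer(d_in, d_h, rng, d_edge=self._edge_width,
                                  aggregator=agg, update=config.update)
            if config.global_attn_engine:
                attn = MultiHeadAttention(d_h, config.global_attn_heads, rng)
                fuse = MLP([d_h, d_h, d_h], rng)
                self.convs.append(GPSLayer(block, attn, fuse))
            else:
                self.convs.append(block)
            d_in = d_h

        # task heads
        self.heads = {t.name: MLP([d_h, d_h, t.out_dim], rng)
                      for t in config.tasks}

    @staticmethod
    def _node_widths(scheme: str, layout: ChannelLayout) -> list[int]:
        if scheme == "S1":
            return [layout.p]
        if scheme == "S3":
            return [layout.p, layout.d_l]
        return [layout.p, layout.d_l, 9, 15]

    @staticmethod
    def _edge_widths(scheme: str, layout: ChannelLayout,
                     d_e: int) -> list[int]:
        if scheme == "S1":
            return [layout.f] if layout.f else []
        if d_e == 0:
            return [layout.f] if layout.f else []
        if scheme == "S3":
            return ([layout.f] if layout.f else []) + [layout.d_l]
        return ([layout.f] if layout.f else []) + [4]

    # -- forward ----------------------------------------------------------
    def _node_input(self, batch: GraphBatch) -> Tensor:
        chans = node_input_channels(self.config.scheme, batch.X, batch.L,
                                    batch.P, batch.C)
        return self.node_embed(chans)

    def _edge_input(self, batch: GraphBatch):
        if self.geo_embed is not None:
            state = geometric_features(batch.coords, batch.edge_index)
            return self.geo_embed(state)
        if self.edge_embed is None:
            return None
        d_e = self.config.edge_embed_dim if self.config.scheme != "S1" else 0
        if d_e == 0:
            chans = [batch.E] if batch.E is not None else []
        else:
            chans = edge_input_channels(self.emb_spec, batch.E, batch.G,
                                        batch.L, batch.edge_index)
        if not chans:
            return None
        return self.edge_embed(chans)

    def node_states(self, batch: GraphBatch) -> Tensor:
        h = self._node_input(batch)
        e = self._edge_input(batch)
        for conv in self.convs:
            if isinstance(conv, GPSLayer):
                h, e = conv(h, batch.edge_index, batch.membership,
                            E=None if self.geo_embed is not None else e,
                            e_bar=e if self.geo_embed is not None else None)
            elif isinstance(conv, GeometricMPNNLayer):
                h = conv(h, batch.edge_index, e)
            else:
                h = conv(h, batch.edge_index, e)
        return h

    def forward(self, batch: GraphBatch) -> dict:
        h = self.node_states(batch)
        out = {}
        for task in self.config.tasks:
            if task.level == "graph":
                g = pool(h, batch.membership, batch.num_graphs,
                         self.config.pooling)
                out[task.name] = self.heads[task.name](g)
            else:
                out[task.name] = self.heads[task.name](h)
        return out

    __call__ = forward

    def parameters(self) -> list[Tensor]:
        params = list(self.node_embed.parameters())
        if self.geo_embed is not None:
            params += self.geo_embed.parameters()
        if self.edge_embed is not None:
            params += self.edge_embed.parameters()
        for conv in self.convs:
            params += conv.parameters()
        for name in sorted(self.heads):
            params += self.heads[name].parameters()
        return params


def parameter_count(model: AtomGraphModel) -> int:
    return int(sum(p.size for p in model.parameters()))


# -- losses ----------------------------------------------------------------

def mse_loss(pred: Tensor, truth: np.ndarray) -> Tensor:
    diff = pred - Tensor(truth)
    return (diff * diff).mean()


def cross_entropy_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    labels = np.asarray(labels).astype(np.intp).reshape(-1)
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    logsumexp = z.exp().sum(axis=1, keepdims=True).log()
    picked = z[np.arange(len(labels)), labels]
    return (logsumexp.reshape(-1) - picked).mean()


def bce_with_logits_loss(logits: Tensor, truth: np.ndarray) -> Tensor:
    """Per-label binary cross-entropy; NaN labels are masked out."""
    truth = np.asarray(truth, dtype=np.float64)
    mask = np.isfinite(truth)
    y = np.where(mask, truth, 0.0)
    w = mask.astype(np.float64)
    # log(1 + exp(-|x|)) + max(x, 0) - x*y, numerically stable
    x = logits
    ax = x.abs()
    softplus = ((-ax).exp() + 1.0).log() + (x + ax) * 0.5
    loss = softplus - x * Tensor(y)
    total = (loss * Tensor(w)).sum()
    return total / max(w.sum(), 1.0)


_LOSS = {"regression": mse_loss, "multiclass": cross_entropy_loss,
         "multilabel": bce_with_logits_loss}


def task_losses(preds: dict, batch: GraphBatch, tasks: list[TaskSpec]) -> dict:
    return {t.name: _LOSS[t.kind](preds[t.name], batch.targets[t.name])
            for t in tasks}


def multitask_loss(losses: dict, weights: dict | None = None) -> Tensor:
    """Weighted sum of per-task losses (weights default to 1)."""
    total = None
    for name, loss in losses.items():
        w = 1.0 if weights is None else weights[name]
        term = loss * w
        total = term if total is None else total + term
    return total


# -- metrics ---------------------------------------------------------------

def metrics(pred: np.ndarray, truth: np.ndarray, kind: str) -> dict:
    """MSE/MAE/Pearson r for regression, top-1 accuracy (percent) for
    multi-class, label-mean average precision for multi-label."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if kind == "regression":
        p, t = pred.reshape(-1), truth.reshape(-1)
        err = p - t
        if p.size < 2 or np.std(p) == 0.0 or np.std(t) == 0.0:
            r = np.nan
        else:
            r = float(scipy.stats.pearsonr(p, t).statistic)
        return {"mse": float(np.mean(err ** 2)),
                "mae": float(np.mean(np.abs(err))),
                "pearson_r": r}
    if kind == "multiclass":
        labels = truth.reshape(-1).astype(int)
        top1 = pred.argmax(axis=1)
        return {"accuracy": float(100.0 * np.mean(top1 == labels))}
    if kind == "multilabel":
        aps = []
        for j in range(truth.shape[1]):
            m = np.isfinite(truth[:, j])
            col = truth[m, j]
            if m.sum() == 0 or col.max() == col.min():
                continue  # label absent or single-class: excluded
            aps.append(average_precision_score(col, pred[m, j]))
        return {"map": float(np.mean(aps)) if aps else np.nan}
    raise ValueError(f"unknown metric kind {kind!r}")


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: AtomGraphModel, path, extra: dict | None = None) -> None:
    """Self-describing checkpoint: config + channel layout + all weights."""
    cfg = asdict(model.config)
    cfg["tasks"] = [asdict(t) for t in model.config.tasks]
    meta = {"config": cfg, "layout": asdict(model.layout),
            "extra": extra or {}}
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> AtomGraphModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        config = ModelConfig(**{**meta["config"],
                                "tasks": [TaskSpec(**t)
                                          for t in meta["config"]["tasks"]]})
        model = AtomGraphModel(config, ChannelLayout(**meta["layout"]))
        params = model.parameters()
        for i, p in enumerate(params):
            p.data = data[f"param_{i}"].copy()
    return model
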