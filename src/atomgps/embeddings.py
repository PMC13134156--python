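"""Fusion of raw features and encodings into node/edge model inputs.

Each side (nodes, edges) uses a *single bias-free linear projection* of the
concatenated active channels; the four schemes route channels as follows:

* S1 — no attention, no encoders: raw X and raw E pass through unchanged.
* S2 — encoders only: nodes [X || L || P || C], edges [E || G].
* S3 — attention only: nodes [X || L], edges [E || |L_i - L_j|], where the
  absolute LPE difference is a sign- and direction-invariant spectral
  displacement channel.
* S4 — both: like S2 (edge topological encodings take precedence over the
  LPE-difference channel; a flag can add the latter as well).

Concatenation order is fixed as X, L, P, C.  With ``edge_embed_dim = 0`` in
the no-attention schemes raw edge features pass through unprojected (and for
geometric backbones the raw interatomic distance remains the sole edge
attribute, preserving invariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "SCHEMES",
    "scheme_flags",
    "flags_to_scheme",
    "EmbeddingSpec",
    "LinearNoBias",
    "node_input_channels",
    "edge_input_channels",
    "lpe_edge_difference",
    "NodeEmbedding",
    "EdgeEmbedding",
    "embedding_flops",
]

SCHEMES = ("S1", "S2", "S3", "S4")

#: scheme -> (global_attn_engine, use_encodings)
_SCHEME_FLAGS = {
    "S1": (False, False),
    "S2": (False, True),
    "S3": (True, False),
    "S4": (True, True),
}


def scheme_flags(scheme: str) -> tuple[bool, bool]:
    try:
        return _SCHEME_FLAGS[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}") \
            from None


def flags_to_scheme(global_attn_engine: bool, use_encodings: bool) -> str:
    for s, fl in _SCHEME_FLAGS.items():
        if fl == (bool(global_attn_engine), bool(use_encodings)):
            return s
    raise AssertionError  # unreachable


@dataclass
class EmbeddingSpec:
    """Widths and routing for the fusion embeddings of one model."""

    scheme: str
    d_h: int
    d_e: int  # edge embed width; 0 = raw-edge pass-through (no-attention schemes)
    lpe_diff_with_encoders: bool = False  # S4: also append |L_i - L_j| to [E||G]

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme != "S1" and self.d_h < 1:
            raise ValueError("d_h must be >= 1 for schemes S2-S4")


def node_input_channels(scheme: str, X, L, P, C) -> list:
    """Active node channels, in the fixed X, L, P, C order."""
    if scheme == "S1":
        chans = [X]
    elif scheme == "S3":
        chans = [X, L]
    else:  # S2 / S4: all available encodings
        chans = [X, L, P, C]
    chans = [c for c in chans if c is not None]
    if not chans:
        raise ValueError(f"scheme {scheme}: no active node channels")
    return chans


def lpe_edge_difference(L: np.ndarray, edge_index: np.ndarray) -> np.ndarray:
    """|L_i - L_j| per edge column (i, j); symmetric in edge direction."""
    return np.abs(L[edge_index[0]] - L[edge_index[1]])


def edge_input_channels(spec: EmbeddingSpec, E, G, L, edge_index) -> list:
    """Active edge channels for the given scheme."""
    if spec.scheme == "S1":
        return [E] if E is not None else []
    if spec.scheme == "S3":
        chans = [E] if E is not None else []
        if L is None:
            if not chans:
                raise ValueError("S3 edge embedding needs raw E or LPE")
        else:
            chans.append(lpe_edge_difference(np.asarray(L), edge_index))
        return chans
    # S2 / S4: encoders on -> G directly
    chans = [E] if E is not None else []
    if G is not None:
        chans.append(G)
    if spec.scheme == "S4" and spec.lpe_diff_with_encoders and L is not None:
        chans.append(lpe_edge_difference(np.asarray(L), edge_index))
    if not chans:
        raise ValueError(f"scheme {spec.scheme}: no active edge channels")
    return chans


class LinearNoBias:
    """y = x W with W initialized uniform(-1/sqrt(d_in), 1/sqrt(d_in))."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(d_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(d_in, d_out)),
                        requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W

    def parameters(self):
        return [self.W]


class NodeEmbedding:
    """Single bias-free projection of the concatenated node channels."""

    def __init__(self, spec: EmbeddingSpec, channel_widths: list[int],
                 rng: np.random.Generator):
        self.spec = spec
        self.channel_widths = list(channel_widths)
        if spec.scheme == "S1":
            self.proj = None
        else:
            self.proj = LinearNoBias(sum(channel_widths), spec.d_h, rng)

    def __call__(self, channels: list) -> Tensor:
        chans = [c if isinstance(c, Tensor) else Tensor(c) for c in channels]
        if self.proj is None:
            return chans[0]  # S1: identity on X
        z = concat(chans, axis=-1) if len(chans) > 1 else chans[0]
        return self.proj(z)

    def parameters(self):
        return [] if self.proj is None else self.proj.parameters()


class EdgeEmbedding:
    """Single bias-free projection producing the model's edge attributes A."""

    def __init__(self, spec: EmbeddingSpec, channel_widths: list[int],
                 rng: np.random.Generator):
        self.spec = spec
        self.channel_widths = list(channel_widths)
        if spec.scheme == "S1" or spec.d_e == 0 or not channel_widths:
            self.proj = None
        else:
            self.proj = LinearNoBias(sum(channel_widths), spec.d_e, rng)

    def __call__(self, channels: list):
        if not channels:
            return None
        chans = [c if isinstance(c, Tensor) else Tensor(c) for c in channels]
        z = concat(chans, axis=-1) if len(chans) > 1 else chans[0]
        if self.proj is None:
            return z  # raw pass-through (S1, or edge_embed_dim = 0)
        return self.proj(z)

    def parameters(self):
        return [] if self.proj is None else self.proj.parameters()


def embedding_flops(n_nodes: int, n_edges: int, d_node_in: int, d_h: int,
                    d_edge_in: int, d_e: int, d_l: int = 0,
                    lpe_diff: bool = False) -> dict:
    """Dominant embedding costs: the two dense products (+ LPE difference)."""
    return {
        "node": n_nodes * d_node_in * d_h,
        "edge": n_edges * d_edge_in * d_e,
        "lpe_diff": n_edges * d_l if lpe_diff else 0,
    }
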