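"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tensor engine: enough operations to express linear
embeddings, message-passing layers, masked multi-head attention, hybrid
local/global layers, pooling and the standard losses, together with an Adam
optimizer.  Gradients are accumulated by a topological-order backward sweep.

All data is float64.  Determinism: operations are pure numpy with no threading
surprises, so identical inputs give bitwise-identical outputs and gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "segment_sum",
    "segment_mean",
    "segment_max",
    "segment_min",
    "segment_softmax",
    "softmax",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- autodiff core -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._parents:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out = Tensor(np.tanh(self.data), requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data ** 2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)),
                     requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0),
                     requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0.0))
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def leaky_relu(self, alpha: float = 0.2):
        out = Tensor(np.where(self.data > 0.0, self.data, alpha * self.data),
                     requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accum(g * np.where(self.data > 0.0, 1.0, alpha))
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), requires_grad=self.requires_grad,
                     _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        ax = axes if axes else None
        out = Tensor(self.data.transpose(ax) if ax else self.data.T,
                     requires_grad=self.requires_grad, _parents=(self,))
        inv = np.argsort(ax) if ax else None
        out._backward = lambda g: self._accum(
            g.transpose(inv) if inv is not None else g.T)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, _parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, _parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        val = self.data.max(axis=axis, keepdims=True)
        out_data = val if keepdims else np.squeeze(val, axis=axis) if axis is not None \
            else val.reshape(())
        out = Tensor(out_data, requires_grad=self.requires_grad, _parents=(self,))

        def bwd(g):
            mask = (self.data == val).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
            gg = g if keepdims or axis is None else np.expand_dims(g, axis)
            self._accum(mask * gg)

        out._backward = bwd
        return out


# -- free functions --------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad or t._parents:
                t._accum(piece)

    out._backward = bwd
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Scatter-add rows of ``x`` into ``num_segments`` buckets."""
    x = Tensor._lift(x)
    seg = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, seg, x.data)
    out = Tensor(out_data, requires_grad=x.requires_grad, _parents=(x,))
    out._backward = lambda g: x._accum(g[seg])
    return out


def segment_mean(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    seg = np.asarray(segment_ids, dtype=np.intp)
    counts = np.bincount(seg, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)  # empty segments stay zero
    s = segment_sum(x, seg, num_segments)
    shape = (num_segments,) + (1,) * (s.data.ndim - 1)
    return s * Tensor(1.0 / counts.reshape(shape))


def _segment_extreme(x: Tensor, segment_ids: np.ndarray, num_segments: int,
                     mode: str) -> Tensor:
    x = Tensor._lift(x)
    seg = np.asarray(segment_ids, dtype=np.intp)
    fill = -np.inf if mode == "max" else np.inf
    ufunc = np.maximum if mode == "max" else np.minimum
    out_data = np.full((num_segments,) + x.data.shape[1:], fill, dtype=np.float64)
    ufunc.at(out_data, seg, x.data)
    out_data[~np.isfinite(out_data)] = 0.0  # empty segments -> zero aggregate
    out = Tensor(out_data, requires_grad=x.requires_grad, _parents=(x,))

    def bwd(g):
        mask = (x.data == out_data[seg]).astype(np.float64)
        denom = np.zeros_like(out_data)
        np.add.at(denom, seg, mask)
        denom = np.maximum(denom, 1.0)
        x._accum(g[seg] * mask / denom[seg])

    out._backward = bwd
    return out


def segment_max(x, segment_ids, num_segments):
    return _segment_extreme(x, segment_ids, num_segments, "max")


def segment_min(x, segment_ids, num_segments):
    return _segment_extreme(x, segment_ids, num_segments, "min")


def segment_softmax(logits: Tensor, segment_ids: np.ndarray,
                    num_segments: int) -> Tensor:
    """Softmax of a 1-D logit vector normalized within each segment."""
    seg = np.asarray(segment_ids, dtype=np.intp)
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, seg, logits.data)
    seg_max[~np.isfinite(seg_max)] = 0.0
    shifted = logits - Tensor(seg_max[seg])  # constant shift, grad-safe
    e = shifted.exp()
    denom = segment_sum(e, seg, num_segments)
    return e / denom[seg]


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
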