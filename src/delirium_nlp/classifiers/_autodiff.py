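"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the sentence classifiers need: broadcast
add/mul, batched matmul, pointwise nonlinearities, last-axis softmax,
layer norm, embedding lookup, axis-1 stack/index/flip, reshape /
transpose / slice, and a weighted softmax cross-entropy loss.  Gradients
flow through a topologically sorted tape; everything is float64 for
deterministic, portable numerics on CPU.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(np.asarray(x, dtype=np.float64))


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], None]) -> Tensor:
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents,
                  backward=backward if req else None)


# ---------------------------------------------------------------------------
# primitive operations

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    """Batched matrix product; operands must be >= 2-D."""
    a, b = _wrap(a), _wrap(b)
    if a.data.ndim < 2 or b.data.ndim < 2:
        raise ValueError("matmul operands must be at least 2-D")
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return _make(out_data, (a, b), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _wrap(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accumulate(g * s * (1.0 - s))

    return _make(s, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    x = _wrap(x)
    t = np.tanh(x.data)

    def backward(g):
        x._accumulate(g * (1.0 - t * t))

    return _make(t, (x,), backward)


def relu(x: Tensor) -> Tensor:
    x = _wrap(x)
    out_data = np.maximum(x.data, 0.0)

    def backward(g):
        x._accumulate(g * (x.data > 0.0))

    return _make(out_data, (x,), backward)


def softmax_last(x: Tensor) -> Tensor:
    """Softmax over the last axis (numerically shifted)."""
    x = _wrap(x)
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=-1, keepdims=True)
        x._accumulate(s * (g - dot))

    return _make(s, (x,), backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    x, gain, bias = _wrap(x), _wrap(gain), _wrap(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gain.data + bias.data

    def backward(g):
        n = x.data.shape[-1]
        if gain.requires_grad:
            gain._accumulate(_unbroadcast(g * xhat, gain.shape))
        if bias.requires_grad:
            bias._accumulate(_unbroadcast(g, bias.shape))
        if x.requires_grad:
            gx = g * gain.data
            dxhat = gx - gx.mean(axis=-1, keepdims=True) \
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(dxhat * inv)

    return _make(out_data, (x, gain, bias), backward)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup: ``table[ids]`` with scatter-add gradient."""
    table = _wrap(table)
    ids = np.asarray(ids)
    out_data = table.data[ids]

    def backward(g):
        grad = np.zeros_like(table.data)
        np.add.at(grad, ids.reshape(-1), g.reshape(-1, table.data.shape[1]))
        table._accumulate(grad)

    return _make(out_data, (table,), backward)


def stack_axis1(parts: Sequence[Tensor]) -> Tensor:
    """Stack (B, H) tensors into (B, T, H)."""
    parts = [_wrap(p) for p in parts]
    out_data = np.stack([p.data for p in parts], axis=1)

    def backward(g):
        for t, p in enumerate(parts):
            if p.requires_grad:
                p._accumulate(g[:, t])

    return _make(out_data, tuple(parts), backward)


def index_axis1(x: Tensor, t: int) -> Tensor:
    """Select timestep ``t``: (B, T, H) -> (B, H)."""
    x = _wrap(x)
    out_data = x.data[:, t]

    def backward(g):
        grad = np.zeros_like(x.data)
        grad[:, t] = g
        x._accumulate(grad)

    return _make(out_data, (x,), backward)


def flip_axis1(x: Tensor) -> Tensor:
    x = _wrap(x)
    out_data = x.data[:, ::-1].copy()

    def backward(g):
        x._accumulate(g[:, ::-1])

    return _make(out_data, (x,), backward)


def concat_last(parts: Sequence[Tensor]) -> Tensor:
    parts = [_wrap(p) for p in parts]
    out_data = np.concatenate([p.data for p in parts], axis=-1)
    sizes = [p.data.shape[-1] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, a, b in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                p._accumulate(g[..., a:b])

    return _make(out_data, tuple(parts), backward)


def slice_last(x: Tensor, a: int, b: int) -> Tensor:
    x = _wrap(x)
    out_data = x.data[..., a:b]

    def backward(g):
        grad = np.zeros_like(x.data)
        grad[..., a:b] = g
        x._accumulate(grad)

    return _make(out_data, (x,), backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    x = _wrap(x)
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.shape))

    return _make(out_data, (x,), backward)


def transpose(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    x = _wrap(x)
    out_data = np.transpose(x.data, axes)
    inverse = tuple(np.argsort(axes))

    def backward(g):
        x._accumulate(np.transpose(g, inverse))

    return _make(out_data, (x,), backward)


def cross_entropy_logits(logits: Tensor, targets: np.ndarray,
                         sample_weights: np.ndarray | None = None) -> Tensor:
    """Weighted mean softmax cross-entropy; targets are class indices."""
    logits = _wrap(logits)
    targets = np.asarray(targets)
    n = logits.data.shape[0]
    w = np.ones(n) if sample_weights is None else np.asarray(sample_weights, float)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    loss = -(w * logp[np.arange(n), targets]).sum() / w.sum()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), targets] -= 1.0
        logits._accumulate(g * p * (w / w.sum())[:, None])

    return _make(np.asarray(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
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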