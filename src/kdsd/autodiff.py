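"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the fusion classifier needs: broadcasting
add/multiply, matrix product, transpose, ReLU, row softmax, row gather,
column slicing/concatenation, and a numerically stable binary cross-entropy
with logits. Gradients are float64 throughout so they can be validated
against central finite differences.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph: a value plus an optional gradient."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad = np.zeros_like(self.value)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.ones_like(self.value))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()


def _node(value: np.ndarray, parents: tuple, backward) -> Tensor:
    out = Tensor(value, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = parents
        out._backward = backward
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value + b.value

    def backward():
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad, b.value.shape))

    out = _node(out_val, (a, b), backward)
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value * b.value

    def backward():
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad * b.value, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad * a.value, b.value.shape))

    out = _node(out_val, (a, b), backward)
    return out


def scale(a, c: float) -> Tensor:
    a = as_tensor(a)

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad * c)

    out = _node(a.value * c, (a,), backward)
    return out


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value @ b.value

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad @ b.value.T)
        if b.requires_grad:
            b._accumulate(a.value.T @ out.grad)

    out = _node(out_val, (a, b), backward)
    return out


def transpose(a) -> Tensor:
    a = as_tensor(a)

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad.T)

    out = _node(a.value.T, (a,), backward)
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.value > 0

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad * mask)

    out = _node(a.value * mask, (a,), backward)
    return out


def softmax_rows(a) -> Tensor:
    """Softmax along the last axis of a 2-D tensor."""
    a = as_tensor(a)
    z = a.value - a.value.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)

    def backward():
        if a.requires_grad:
            g = out.grad
            dot = (g * s).sum(axis=-1, keepdims=True)
            a._accumulate(s * (g - dot))

    out = _node(s, (a,), backward)
    return out


def take_rows(a, idx) -> Tensor:
    """Gather rows of a 2-D tensor; gradient scatter-adds (embedding lookup)."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)

    def backward():
        if a.requires_grad:
            g = np.zeros_like(a.value)
            np.add.at(g, idx, out.grad)
            a._accumulate(g)

    out = _node(a.value[idx], (a,), backward)
    return out


def cols(a, start: int, stop: int) -> Tensor:
    """Slice columns [start:stop] of a 2-D tensor."""
    a = as_tensor(a)

    def backward():
        if a.requires_grad:
            g = np.zeros_like(a.value)
            g[:, start:stop] = out.grad
            a._accumulate(g)

    out = _node(a.value[:, start:stop], (a,), backward)
    return out


def concat_cols(parts: list) -> Tensor:
    parts = [as_tensor(p) for p in parts]
    widths = [p.value.shape[1] for p in parts]
    out_val = np.concatenate([p.value for p in parts], axis=1)

    def backward():
        off = 0
        for p, w in zip(parts, widths):
            if p.requires_grad:
                p._accumulate(out.grad[:, off:off + w])
            off += w

    out = _node(out_val, tuple(parts), backward)
    return out


def mean_rows(a) -> Tensor:
    """Mean over rows of a 2-D tensor -> 1-D tensor."""
    a = as_tensor(a)
    n = a.value.shape[0]

    def backward():
        if a.requires_grad:
            a._accumulate(np.broadcast_to(out.grad / n, a.value.shape).copy())

    out = _node(a.value.mean(axis=0), (a,), backward)
    return out


def bce_with_logits(logits, targets) -> Tensor:
    """Mean element-wise binary cross-entropy, numerically stable.

    loss = mean( max(z,0) - z*y + log(1+exp(-|z|)) );  dL/dz = (sigmoid(z)-y)/n
    """
    logits = as_tensor(logits)
    y = np.asarray(targets, dtype=np.float64)
    z = logits.value
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward():
        if logits.requires_grad:
            ez = np.exp(-np.abs(z))
            sig = np.where(z >= 0, 1.0 / (1.0 + ez), ez / (1.0 + ez))
            logits._accumulate(out.grad * (sig - y) / n)

    out = _node(per.mean(), (logits,), backward)
    return out


class Adam:
    """Adam optimizer over a fixed list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
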