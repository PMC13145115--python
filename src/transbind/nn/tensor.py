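"""Reverse-mode automatic differentiation on numpy arrays.

A minimal tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
records the operation that produced it. Calling :meth:`Tensor.backward` on a
scalar walks the graph in reverse topological order and accumulates gradients
into every leaf created with ``requires_grad=True``.

Only the operations the binding-site models need are provided; each fused op
(convolution, max-pool, layer norm, softmax, dropout) carries a hand-written
backward that is verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv1d",
    "dropout",
    "layer_norm",
    "matmul",
    "max_pool1d",
    "relu",
    "sigmoid",
    "softmax",
    "softplus",
    "tanh",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs from LSTMs are deep
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # ---------------------------------------------------------------- algebra
    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(_unbroadcast(-g, self.shape))

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            self._accum(_unbroadcast(g * e * self.data ** (e - 1.0), self.shape))

        return Tensor._make(self.data ** e, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        a, b = self.data, other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(a @ b, (self, other), backward)

    __matmul__ = matmul

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(np.float64))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ----------------------------------------------------------------- shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            self._accum(g.reshape(self.shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        # basic indexing (ints/slices) addresses unique positions, so a
        # vectorized += is valid and much faster than np.add.at
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, np.integer, slice)) for p in parts)

        def backward(g):
            full = np.zeros(self.shape, dtype=np.float64)
            if basic:
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)

    return Tensor._make(np.where(mask, x.data, 0.0), (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g):
        x._accum(g * (1.0 - out_data ** 2))

    return Tensor._make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # numerically stable logistic

    def backward(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), backward)


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)) computed without overflow; gradient is the logistic."""
    out_data = np.maximum(x.data, 0.0) + np.log1p(np.exp(-np.abs(x.data)))

    def backward(g):
        x._accum(g * 0.5 * (1.0 + np.tanh(0.5 * x.data)))

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accum(out_data * (g - dot))

    return Tensor._make(out_data, (x,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor._lift(a).matmul(b)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """'Valid' 1-D convolution (cross-correlation, as in deep learning).

    x: (B, L, C_in); weight: (F, K, C_in); bias: (F,). Output (B, L-K+1, F).
    Implemented as im2col + matmul so BLAS does the heavy lifting.
    """
    B, L, C = x.shape
    F, K, Cw = weight.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    if L < K:
        raise ValueError(f"input length {L} shorter than kernel {K}")
    Lo = L - K + 1
    # accumulate one matmul per kernel offset: avoids the large im2col copy
    xd = x.data
    wd = weight.data  # (F, K, C)
    out_data = xd[:, 0:Lo, :] @ wd[:, 0, :].T
    for k in range(1, K):
        out_data += xd[:, k : k + Lo, :] @ wd[:, k, :].T
    if bias is not None:
        out_data = out_data + bias.data

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if weight.requires_grad:
            dw = np.empty_like(wd)
            for k in range(K):
                dw[:, k, :] = np.tensordot(g, xd[:, k : k + Lo, :],
                                           axes=([0, 1], [0, 1]))
            weight._accum(dw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1)))
        if x.requires_grad:
            dx = np.zeros((B, L, C), dtype=np.float64)
            for k in range(K):
                dx[:, k : k + Lo, :] += g @ wd[:, k, :]
            x._accum(dx)

    return Tensor._make(out_data, parents, backward)


def max_pool1d(x: Tensor, window: int) -> Tensor:
    """Non-overlapping max pooling along axis 1; trailing remainder dropped.

    x: (B, L, C) -> (B, L // window, C).
    """
    B, L, C = x.shape
    n = L // window
    if n < 1:
        raise ValueError(f"length {L} shorter than pool window {window}")
    blocks = x.data[:, : n * window, :].reshape(B, n, window, C)
    arg = blocks.argmax(axis=2)  # (B, n, C)
    out_data = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):
        dblocks = np.zeros((B, n, window, C), dtype=np.float64)
        np.put_along_axis(dblocks, arg[:, :, None, :], g[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C), dtype=np.float64)
        dx[:, : n * window, :] = dblocks.reshape(B, n * window, C)
        x._accum(dx)

    return Tensor._make(out_data, (x,), backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gain.data + bias.data
    n = x.shape[-1]

    def backward(g):
        if gain.requires_grad:
            red = tuple(range(g.ndim - 1))
            gain._accum((g * xhat).sum(axis=red))
        if bias.requires_grad:
            red = tuple(range(g.ndim - 1))
            bias._accum(g.sum(axis=red))
        if x.requires_grad:
            gh = g * gain.data
            dx = (
                gh - gh.mean(axis=-1, keepdims=True)
                - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            x._accum(dx)

    return Tensor._make(out_data, (x, gain, bias), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    keep = rng.random(x.shape) >= p
    scale = 1.0 / (1.0 - p)
    mask = keep * scale

    def backward(g):
        x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)
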