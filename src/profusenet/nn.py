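"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations required by the sequence classifier:
dense layers, 1-D "same" convolution, max pooling, LSTM-style gated
recurrences, masked global average pooling, dropout, and a fused
softmax cross-entropy loss.  Gradients flow to any :class:`Tensor`,
which is what both training and input attribution rely on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "tanh",
    "concat",
    "getcols",
    "select_time",
    "stack_time",
    "scale",
    "conv1d",
    "maxpool1d",
    "masked_mean",
    "sum_all",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Tensor:
    """A node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def zero_grad(self):
        self.grad = None

    def backward(self):
        """Reverse-accumulate gradients from this (scalar or not) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deeper than the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # Operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return scale(self, -1.0)

    def __sub__(self, other):
        return add(self, scale(other, -1.0))

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(parents)
    out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64, copy=True)
    else:
        t.grad += g


def _grad_buffer(t: Tensor) -> np.ndarray:
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    return t.grad


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward():
        _accum(a, _unbroadcast(out.grad, a.data.shape))
        _accum(b, _unbroadcast(out.grad, b.data.shape))

    out = _node(out_data, (a, b), backward)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward():
        _accum(a, _unbroadcast(out.grad * b.data, a.data.shape))
        _accum(b, _unbroadcast(out.grad * a.data, b.data.shape))

    out = _node(out_data, (a, b), backward)
    return out


def scale(a: Tensor, c) -> Tensor:
    """Multiply by a constant (scalar or ndarray); no gradient w.r.t. ``c``."""
    c = np.asarray(c, dtype=np.float64)
    out_data = a.data * c

    def backward():
        _accum(a, _unbroadcast(out.grad * c, a.data.shape))

    out = _node(out_data, (a,), backward)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward():
        _accum(a, out.grad @ b.data.T)
        _accum(b, a.data.T @ out.grad)

    out = _node(out_data, (a, b), backward)
    return out


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0.0)

    def backward():
        _accum(a, out.grad * (a.data > 0))

    out = _node(out_data, (a,), backward)
    return out


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward():
        _accum(a, out.grad * out_data * (1.0 - out_data))

    out = _node(out_data, (a,), backward)
    return out


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward():
        _accum(a, out.grad * (1.0 - out_data * out_data))

    out = _node(out_data, (a,), backward)
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * out_data.ndim
            idx[axis] = slice(start, stop)
            _accum(t, out.grad[tuple(idx)])

    out = _node(out_data, tuple(tensors), backward)
    return out


def getcols(a: Tensor, start: int, stop: int) -> Tensor:
    """Slice the last axis; used to split fused LSTM gate activations."""
    out_data = a.data[..., start:stop]

    def backward():
        buf = _grad_buffer(a)
        buf[..., start:stop] += out.grad

    out = _node(out_data, (a,), backward)
    return out


def select_time(a: Tensor, t: int) -> Tensor:
    """Select time step ``t`` from a (N, T, C) tensor -> (N, C)."""
    out_data = a.data[:, t, :]

    def backward():
        buf = _grad_buffer(a)
        buf[:, t, :] += out.grad

    out = _node(out_data, (a,), backward)
    return out


def stack_time(tensors: list[Tensor]) -> Tensor:
    """Stack T tensors of shape (N, C) into (N, T, C)."""
    out_data = np.stack([t.data for t in tensors], axis=1)

    def backward():
        for i, t in enumerate(tensors):
            _accum(t, out.grad[:, i, :])

    out = _node(out_data, tuple(tensors), backward)
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D convolution, stride 1, "same" zero padding.

    ``x``: (N, L, C_in); ``w``: (k, C_in, F); ``b``: (F,) -> (N, L, F).
    """
    n, length, c_in = x.data.shape
    k, c_in_w, n_filters = w.data.shape
    if c_in_w != c_in:
        raise ValueError(f"conv1d channel mismatch: input {c_in}, kernel {c_in_w}")
    pad_left = k // 2
    pad_right = k - 1 - pad_left
    xp = np.pad(x.data, ((0, 0), (pad_left, pad_right), (0, 0)))
    # (N, L, k, C_in) windows flattened for a single GEMM
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))
    cols2 = cols.reshape(n * length, k * c_in)
    w2 = w.data.reshape(k * c_in, n_filters)
    out_data = (cols2 @ w2 + b.data).reshape(n, length, n_filters)

    def backward():
        g2 = out.grad.reshape(n * length, n_filters)
        _accum(w, (cols2.T @ g2).reshape(k, c_in, n_filters))
        _accum(b, g2.sum(axis=0))
        dcols = (g2 @ w2.T).reshape(n, length, k, c_in)
        dxp = np.zeros_like(xp)
        for m in range(k):
            dxp[:, m : m + length, :] += dcols[:, :, m, :]
        _accum(x, dxp[:, pad_left : pad_left + length, :])

    out = _node(out_data, (x, w, b), backward)
    return out


def maxpool1d(x: Tensor, size: int = 2, stride: int = 2) -> Tensor:
    """Non-overlapping 1-D max pooling over the time axis (floor semantics)."""
    if size != stride:
        raise ValueError("only non-overlapping pooling (size == stride) supported")
    n, length, c = x.data.shape
    t2 = length // size
    xv = x.data[:, : t2 * size, :].reshape(n, t2, size, c)
    idx = xv.argmax(axis=2)
    out_data = np.take_along_axis(xv, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward():
        dxv = np.zeros((n, t2, size, c))
        np.put_along_axis(dxv, idx[:, :, None, :], out.grad[:, :, None, :], axis=2)
        dx = np.zeros_like(x.data)
        dx[:, : t2 * size, :] = dxv.reshape(n, t2 * size, c)
        _accum(x, dx)

    out = _node(out_data, (x,), backward)
    return out


def masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over the time axis restricted to mask==1 steps.

    ``x``: (N, T, C); ``mask``: (N, T) constant -> (N, C).
    """
    mask = np.asarray(mask, dtype=np.float64)
    counts = mask.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("masked_mean: a sample has no unmasked steps")
    weights = mask / counts[:, None]  # (N, T)
    out_data = np.einsum("ntc,nt->nc", x.data, weights)

    def backward():
        _accum(x, out.grad[:, None, :] * weights[:, :, None])

    out = _node(out_data, (x,), backward)
    return out


def sum_all(a: Tensor) -> Tensor:
    out_data = np.asarray(a.data.sum())

    def backward():
        _accum(a, np.broadcast_to(out.grad, a.data.shape))

    out = _node(out_data, (a,), backward)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis (plain numpy)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy with integrated softmax.

    ``logits``: (N, C) Tensor; ``onehot``: (N, C) constant label matrix.
    """
    y = np.asarray(onehot, dtype=np.float64)
    if y.shape != logits.data.shape:
        raise ValueError(f"label shape {y.shape} != logits shape {logits.data.shape}")
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    out_data = np.asarray(-(y * logp).sum() / n)
    probs = np.exp(logp)

    def backward():
        _accum(logits, out.grad * (probs - y) / n)

    out = _node(out_data, (logits,), backward)
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
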