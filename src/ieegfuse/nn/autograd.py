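"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the recurrent, convolutional and
fully-connected branches need: elementwise arithmetic, matmul, the
standard activations, reductions, shaping, 1-D convolution, max
pooling, batch normalization and a numerically stable binary
cross-entropy on logits. Gradients are accumulated by a topological
backward pass, micrograd-style.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self.requires_grad and self._accum(_unbroadcast(g, self.data.shape))
            other.requires_grad and other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self.requires_grad and self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self.requires_grad and self._accum(_unbroadcast(g * other.data, self.data.shape))
            other.requires_grad and other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, p: float):
        def bw(g):
            self.requires_grad and self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def sqrt(self):
        return self.pow(0.5)

    def matmul(self, other: "Tensor"):
        other = self._wrap(other)

        def bw(g):
            self.requires_grad and self._accum(g @ other.data.T)
            other.requires_grad and other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    __matmul__ = matmul

    # -- activations -------------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)

        def bw(g):
            self.requires_grad and self._accum(g * (1 - y * y))

        return self._make(y, (self,), bw)

    def sigmoid(self):
        y = np.empty_like(self.data)
        pos = self.data >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        y[~pos] = ex / (1.0 + ex)

        def bw(g):
            self.requires_grad and self._accum(g * y * (1 - y))

        return self._make(y, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self.requires_grad and self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def exp(self):
        y = np.exp(self.data)

        def bw(g):
            self.requires_grad and self._accum(g * y)

        return self._make(y, (self,), bw)

    def log(self):
        def bw(g):
            self.requires_grad and self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    # -- reductions and shaping --------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            self.requires_grad and self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self.requires_grad and self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return self._make(self.data[key], (self,), bw)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0):
        tensors = [Tensor._wrap(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(a, b)
                    t._accum(g[tuple(idx)])

        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
        )

    @staticmethod
    def stack(tensors: list["Tensor"], axis: int = 0):
        tensors = [Tensor._wrap(t) for t in tensors]

        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis))

        return Tensor._make(
            np.stack([t.data for t in tensors], axis=axis), tuple(tensors), bw
        )

    # -- network primitives ------------------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor", padding: int = 0):
        """1-D convolution, stride 1. self: (B,C,L), weight: (O,C,K)."""
        x, w = self.data, weight.data
        B, C, L = x.shape
        O, _, K = w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
        win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,C,Lo,K)
        out = np.einsum("bclk,ock->bol", win, w, optimize=True) + bias.data[None, :, None]
        Lo = out.shape[2]

        def bw(g):
            if weight.requires_grad:
                weight._accum(np.einsum("bclk,bol->ock", win, g, optimize=True))
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for k in range(K):
                    gxp[:, :, k : k + Lo] += np.einsum(
                        "bol,oc->bcl", g, w[:, :, k], optimize=True
                    )
                self._accum(gxp[:, :, padding : padding + L] if padding else gxp)

        return self._make(out, (self, weight, bias), bw)

    def maxpool1d(self, size: int = 2):
        """Non-overlapping max pooling along the last axis (trailing remainder dropped)."""
        B, C, L = self.data.shape
        Lp = (L // size) * size
        v = self.data[:, :, :Lp].reshape(B, C, L // size, size)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

        def bw(g):
            if not self.requires_grad:
                return
            gv = np.zeros_like(v)
            np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
            full = np.zeros_like(self.data)
            full[:, :, :Lp] = gv.reshape(B, C, Lp)
            self._accum(full)

        return self._make(out, (self,), bw)

    def adaptive_maxpool1d(self, n_bins: int):
        """Max over ``n_bins`` near-equal chunks of the last axis."""
        B, C, L = self.data.shape
        edges = np.linspace(0, L, n_bins + 1).astype(int)
        outs, idxs = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            chunk = self.data[:, :, a:b]
            idxs.append(a + chunk.argmax(axis=-1))
            outs.append(chunk.max(axis=-1))
        out = np.stack(outs, axis=-1)

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            bi, ci = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
            for j, idx in enumerate(idxs):
                np.add.at(full, (bi, ci, idx), g[:, :, j])
            self._accum(full)

        return self._make(out, (self,), bw)

    def batchnorm1d(
        self,
        gamma: "Tensor",
        beta: "Tensor",
        running: dict,
        training: bool,
        eps: float = 1e-5,
        momentum: float = 0.1,
    ):
        """Batch normalization over (batch, length) per channel; self: (B,C,L)."""
        x = self.data
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
            running["var"] = (1 - momentum) * running["var"] + momentum * var
        else:
            mu, var = running["mean"], running["var"]
        std = np.sqrt(var + eps)
        xhat = (x - mu[None, :, None]) / std[None, :, None]
        out = gamma.data[None, :, None] * xhat + beta.data[None, :, None]
        m = x.shape[0] * x.shape[2]

        def bw(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2)))
            if not self.requires_grad:
                return
            dxhat = g * gamma.data[None, :, None]
            if training:
                t1 = dxhat.sum(axis=(0, 2))[None, :, None]
                t2 = (dxhat * xhat).sum(axis=(0, 2))[None, :, None]
                self._accum((dxhat - t1 / m - xhat * t2 / m) / std[None, :, None])
            else:
                self._accum(dxhat / std[None, :, None])

        return self._make(out, (self, gamma, beta), bw)

    def dropout(self, p: float, rng: np.random.Generator, training: bool):
        if not training or p <= 0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)

        def bw(g):
            self.requires_grad and self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def bce_with_logits(self, targets: np.ndarray):
        """Mean binary cross-entropy on logits (numerically stable)."""
        z, y = self.data, np.asarray(targets, float)
        loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))

        def bw(g):
            if self.requires_grad:
                p = np.empty_like(z)
                pos = z >= 0
                p[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
                ex = np.exp(z[~pos])
                p[~pos] = ex / (1.0 + ex)
                self._accum(g * (p - y) / z.size)

        return self._make(loss.mean(), (self,), bw)
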