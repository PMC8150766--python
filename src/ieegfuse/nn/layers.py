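"""Network building blocks: linear, LSTM, bidirectional stacks, attention,
convolution blocks, plus the Adam optimizer used to train every branch."""

from __future__ import annotations

import copy

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "LSTM",
    "BiLSTM",
    "AdditiveAttention",
    "ConvBlock",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery and a train/eval flag."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        for obj in (self, *self.modules()):
            for v in obj.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
                elif isinstance(v, (list, tuple)):
                    params.extend(p for p in v if isinstance(p, Parameter))
        return params

    def train(self):
        for obj in (self, *self.modules()):
            obj.training = True
        return self

    def eval(self):
        for obj in (self, *self.modules()):
            obj.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.copy()


def _uniform(rng: np.random.Generator, shape, k: float) -> np.ndarray:
    return rng.uniform(-k, k, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        k = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(_uniform(rng, (out_features, in_features), k))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight.transpose(1, 0)) + self.bias


class LSTM(Module):
    """Single-direction LSTM (gate order: input, forget, cell, output)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        k = 1.0 / np.sqrt(hidden_size)
        self.w_ih = Parameter(_uniform(rng, (4 * hidden_size, input_size), k))
        self.w_hh = Parameter(_uniform(rng, (4 * hidden_size, hidden_size), k))
        self.b = Parameter(np.zeros(4 * hidden_size))

    def __call__(self, xs: list[Tensor], reverse: bool = False) -> list[Tensor]:
        """xs: list over time of (batch, input) tensors -> hidden states."""
        H = self.hidden_size
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, H)))
        c = Tensor(np.zeros((batch, H)))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out: list[Tensor | None] = [None] * len(xs)
        for t in order:
            z = (
                xs[t].matmul(self.w_ih.transpose(1, 0))
                + h.matmul(self.w_hh.transpose(1, 0))
                + self.b
            )
            i = z[:, 0 * H : 1 * H].sigmoid()
            f = z[:, 1 * H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out[t] = h
        return out  # type: ignore[return-value]


class BiLSTM(Module):
    """Bidirectional LSTM layer; per-timestep output is [forward ‖ backward]."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(input_size, hidden_size, rng)
        self.bwd = LSTM(input_size, hidden_size, rng)

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        hf = self.fwd(xs)
        hb = self.bwd(xs, reverse=True)
        return [Tensor.concat([f, b], axis=1) for f, b in zip(hf, hb)]


class AdditiveAttention(Module):
    """Additive attention pooling over a sequence of encoder outputs.

    Scores ``u_t = tanh(W_w e_t + b_w)`` are projected on a trainable
    context vector ``u_w`` and softmax-normalized over time; the pooled
    output is the weighted sum of the encoder outputs.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        k = 1.0 / np.sqrt(dim)
        self.w_w = Parameter(_uniform(rng, (dim, dim), k))
        self.b_w = Parameter(np.zeros(dim))
        self.u_w = Parameter(_uniform(rng, (dim, 1), k))

    def __call__(self, es: list[Tensor]) -> tuple[Tensor, Tensor]:
        scores = []
        for e in es:
            u = (e.matmul(self.w_w.transpose(1, 0)) + self.b_w).tanh()
            scores.append(u.matmul(self.u_w))  # (B, 1)
        s = Tensor.concat(scores, axis=1)  # (B, T)
        shift = s.data.max(axis=1, keepdims=True)  # constant shift for stability
        ex = (s - Tensor(shift)).exp()
        w = ex * ex.sum(axis=1, keepdims=True).pow(-1.0)  # (B, T) softmax
        v = None
        for t, e in enumerate(es):
            term = w[:, t : t + 1] * e
            v = term if v is None else v + term
        return v, w


class ConvBlock(Module):
    """conv1d -> batchnorm -> ReLU -> maxpool(2), the repeated CNN unit."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        padding: int,
        rng: np.random.Generator,
        pool: int = 2,
    ):
        super().__init__()
        k = 1.0 / np.sqrt(in_ch * kernel)
        self.weight = Parameter(_uniform(rng, (out_ch, in_ch, kernel), k))
        self.bias = Parameter(np.zeros(out_ch))
        self.gamma = Parameter(np.ones(out_ch))
        self.beta = Parameter(np.zeros(out_ch))
        self.padding = padding
        self.pool = pool
        self.running = {"mean": np.zeros(out_ch), "var": np.ones(out_ch)}

    def __call__(self, x: Tensor) -> Tensor:
        y = x.conv1d(self.weight, self.bias, padding=self.padding)
        y = y.batchnorm1d(self.gamma, self.beta, self.running, self.training)
        return y.relu().maxpool1d(self.pool)

    def state_extra(self):
        return copy.deepcopy(self.running)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
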