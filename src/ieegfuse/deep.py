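"""End-to-end 1D-CNN branch on the raw (preprocessed) segment.

Four convolution blocks — each convolution + batch normalization +
ReLU + max pooling — with channel progression 1→16→32→32→32, followed
by an adaptive max-pool to 4 positions per channel (so the flattened
automatic embedding is 32×4 = 128 for any input length) and a two-layer
MLP head ending in a sigmoid unit. Dual-channel inputs are averaged to
one channel; each input trace is z-scored per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classical import TrainedBranch, _check_two_classes, _train_loop
from .nn import Adam, ConvBlock, Linear, Module, Tensor

__all__ = ["CnnConfig", "Cnn1dModel", "train_cnn", "activation_maps"]


@dataclass
class CnnConfig:
    #: (in, out, kernel, stride, padding) per block
    conv_layers: tuple = (
        (1, 16, 3, 1, 1),
        (16, 32, 3, 1, 1),
        (32, 32, 3, 1, 1),
        (32, 32, 2, 1, 1),
    )
    pool_size: int = 2
    embed_len: int = 4  # adaptive-pool positions per channel
    hidden_size: int = 64
    batch_size: int = 32
    epochs: int = 100
    learning_rate: float = 1e-3


class Cnn1dModel(Module):
    def __init__(self, cfg: CnnConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.blocks = []
        for in_ch, out_ch, kernel, stride, padding in cfg.conv_layers:
            if stride != 1:
                raise ValueError("only stride-1 convolutions are supported")
            self.blocks.append(ConvBlock(in_ch, out_ch, kernel, padding, rng, cfg.pool_size))
        out_ch = cfg.conv_layers[-1][1]
        self.embed_dim = out_ch * cfg.embed_len
        self.fc1 = Linear(self.embed_dim, cfg.hidden_size, rng)
        self.fc2 = Linear(cfg.hidden_size, 1, rng)

    def _features(self, x: np.ndarray) -> list[Tensor]:
        """Per-block activations for a (B, L) input batch."""
        if x.ndim != 2:
            raise ValueError("expected (batch, length) input")
        min_len = 2 ** len(self.blocks)
        if x.shape[1] < max(16, min_len):
            raise ValueError("input too short for the convolution stack")
        t = Tensor(x[:, None, :])
        acts = []
        for block in self.blocks:
            t = block(t)
            acts.append(t)
        return acts

    def forward(self, x: np.ndarray) -> tuple[Tensor, Tensor]:
        """x: (B, L) -> (logits (B,), embedding (B, 128))."""
        t = self._features(np.asarray(x, float))[-1]
        emb = t.adaptive_maxpool1d(self.cfg.embed_len).reshape(x.shape[0], self.embed_dim)
        z = self.fc1(emb).relu()
        logits = self.fc2(z).reshape(-1)
        return logits, emb


def _normalize(x: np.ndarray) -> np.ndarray:
    """Per-segment z-scoring of raw traces."""
    x = np.asarray(x, float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


class TrainedCnn(TrainedBranch):
    def standardize(self, x: np.ndarray) -> np.ndarray:
        return _normalize(x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        self.model.eval()
        logits, _ = self.model.forward(self.standardize(x))
        return 1.0 / (1.0 + np.exp(-logits.data))

    def embed(self, x: np.ndarray) -> np.ndarray:
        self.model.eval()
        _, emb = self.model.forward(self.standardize(x))
        return emb.data


def train_cnn(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: CnnConfig | None = None,
    seed: int = 0,
) -> TrainedCnn:
    """Train the 1D-CNN branch; ``x_train`` is (n, L) raw traces."""
    cfg = cfg or CnnConfig()
    y_train = np.asarray(y_train, float)
    _check_two_classes(y_train)
    rng = np.random.default_rng(seed)
    model = Cnn1dModel(cfg, rng)
    branch = TrainedCnn(model=model, mean=np.zeros(1), sd=np.ones(1))
    _train_loop(
        model, _normalize(x_train), y_train, _normalize(x_val), np.asarray(y_val, float),
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        lr=cfg.learning_rate, rng=rng, history=branch.history,
        forward=lambda m, xb: m.forward(xb)[0],
    )
    return branch


def activation_maps(branch: TrainedCnn, x: np.ndarray, layer: int) -> np.ndarray:
    """Per-channel activation sequences at conv block ``layer`` (1-based)."""
    model: Cnn1dModel = branch.model  # type: ignore[assignment]
    if not 1 <= layer <= len(model.blocks):
        raise ValueError(f"layer must be in 1..{len(model.blocks)}")
    model.eval()
    x = np.atleast_2d(np.asarray(x, float))
    acts = model._features(_normalize(x))
    return acts[layer - 1].data[0]
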