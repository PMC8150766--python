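"""Bi-LSTM-attention branch over the 4x70 feature sequence.

A two-layer bidirectional LSTM (hidden size 64 per direction) encodes
the per-timestep feature vectors; additive attention pools the
per-timestep encoder outputs into a single 128-dimensional embedding,
which a 256-unit fully connected layer maps to a sigmoid class
probability. Features are standardized with train-set statistics before
the recurrence, since entropy and energy features differ by orders of
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, AdditiveAttention, BiLSTM, Linear, Module, Tensor

__all__ = [
    "ClassicalBranchConfig",
    "BiLSTMAttentionModel",
    "TrainedBranch",
    "attention_pool",
    "train_classical",
]


@dataclass
class ClassicalBranchConfig:
    hidden_size: int = 64
    num_layers: int = 2
    lstm_dropout: float = 0.1
    hidden_linear_size: int = 256
    linear_dropout: float = 0.3
    batch_size: int = 20
    epochs: int = 100
    learning_rate: float = 1e-3


def attention_pool(
    e: np.ndarray, w_w: np.ndarray, b_w: np.ndarray, u_w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form additive attention on a (T, D) sequence.

    ``u_t = tanh(W_w e_t + b_w)``; weights are the softmax over t of
    ``u_t . u_w``; the output is ``sum_t h_t e_t``. Returns ``(v, h)``.
    """
    e = np.atleast_2d(np.asarray(e, float))
    u = np.tanh(e @ w_w.T + b_w)
    scores = u @ np.asarray(u_w, float).reshape(-1)
    scores = scores - scores.max()
    h = np.exp(scores)
    h /= h.sum()
    return h @ e, h


class BiLSTMAttentionModel(Module):
    def __init__(self, n_features: int, cfg: ClassicalBranchConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        H = cfg.hidden_size
        self.layers = []
        in_dim = n_features
        for _ in range(cfg.num_layers):
            self.layers.append(BiLSTM(in_dim, H, rng))
            in_dim = 2 * H
        self.attention = AdditiveAttention(2 * H, rng)
        self.fc1 = Linear(2 * H, cfg.hidden_linear_size, rng)
        self.fc2 = Linear(cfg.hidden_linear_size, 1, rng)
        self._rng = rng

    @property
    def embedding_dim(self) -> int:
        return 2 * self.cfg.hidden_size

    def forward(self, x: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        """x: (B, T, F) standardized features -> (logits, embedding, attn weights)."""
        x = np.asarray(x, dtype=float)
        if not np.isfinite(x).all():
            raise ValueError("non-finite feature input")
        seq = [Tensor(x[:, t, :]) for t in range(x.shape[1])]
        for li, layer in enumerate(self.layers):
            seq = layer(seq)
            if li < len(self.layers) - 1 and self.cfg.lstm_dropout > 0:
                seq = [
                    s.dropout(self.cfg.lstm_dropout, self._rng, self.training)
                    for s in seq
                ]
        v, h = self.attention(seq)
        z = self.fc1(v).relu().dropout(self.cfg.linear_dropout, self._rng, self.training)
        logits = self.fc2(z).reshape(-1)
        return logits, v, h


@dataclass
class TrainedBranch:
    """A trained branch plus its input standardizer and training history."""

    model: Module
    mean: np.ndarray
    sd: np.ndarray
    history: list[dict] = field(default_factory=list)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.mean) / self.sd

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        self.model.eval()
        logits, _, _ = self.model.forward(self.standardize(x))
        return 1.0 / (1.0 + np.exp(-logits.data))

    def embed(self, x: np.ndarray) -> np.ndarray:
        self.model.eval()
        _, v, _ = self.model.forward(self.standardize(x))
        return v.data


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")


def train_classical(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: ClassicalBranchConfig | None = None,
    seed: int = 0,
) -> TrainedBranch:
    """Train the Bi-LSTM-attention branch with Adam on binary cross-entropy.

    ``x_train``: (n, T, 70) raw (unstandardized) feature sequences.
    Returns the best-on-validation weights and a per-epoch history.
    """
    cfg = cfg or ClassicalBranchConfig()
    y_train = np.asarray(y_train, float)
    y_val = np.asarray(y_val, float)
    _check_two_classes(y_train)
    x_train = np.asarray(x_train, float)
    flat = x_train.reshape(-1, x_train.shape[-1])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd[sd == 0] = 1.0
    rng = np.random.default_rng(seed)
    model = BiLSTMAttentionModel(x_train.shape[-1], cfg, rng)
    branch = TrainedBranch(model=model, mean=mean, sd=sd)
    _train_loop(
        model, branch.standardize(x_train), y_train,
        branch.standardize(x_val), y_val,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        lr=cfg.learning_rate, rng=rng, history=branch.history,
        forward=lambda m, xb: m.forward(xb)[0],
    )
    return branch


def _train_loop(model, xt, yt, xv, yv, epochs, batch_size, lr, rng, history, forward):
    """Shared minibatch Adam loop keeping the best-on-validation weights."""
    opt = Adam(model.parameters(), lr=lr)
    best_acc, best_state = -1.0, None
    n = xt.shape[0]
    for epoch in range(epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            model.zero_grad()
            logits = forward(model, xt[idx])
            loss = logits.bce_with_logits(yt[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        pv = forward(model, xv).data
        val_acc = float(np.mean((pv >= 0) == (yv == 1)))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": val_acc}
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
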