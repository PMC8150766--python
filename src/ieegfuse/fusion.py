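"""Feature fusion: concatenate the two frozen 128-d branch embeddings into
a 256-d fusion feature and classify it with a small MLP head trained
under binary cross-entropy."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classical import TrainedBranch, _check_two_classes, _train_loop
from .features import FeatureConfig, extract_feature_sequence
from .nn import Linear, Module, Tensor
from .preprocess import PreprocessConfig, preprocess_signal
from .types import Label, Segment

__all__ = [
    "FusionConfig",
    "FusionFeature",
    "fuse",
    "bce_loss",
    "FusionHead",
    "FusionPipeline",
    "train_fusion",
]

EPS = 1e-7


@dataclass
class FusionConfig:
    hidden_size: int = 64
    dropout: float = 0.3
    batch_size: int = 32
    epochs: int = 60
    learning_rate: float = 1e-3


@dataclass
class FusionFeature:
    classical: np.ndarray
    automatic: np.ndarray

    @property
    def fused(self) -> np.ndarray:
        return fuse(self.classical, self.automatic)


def fuse(classical: np.ndarray, automatic: np.ndarray) -> np.ndarray:
    """End-to-end concatenation [classical ‖ automatic] along the last axis."""
    classical = np.asarray(classical, float)
    automatic = np.asarray(automatic, float)
    if classical.shape[-1] != automatic.shape[-1]:
        raise ValueError("branch embeddings must have equal dimension")
    if not (np.isfinite(classical).all() and np.isfinite(automatic).all()):
        raise ValueError("non-finite embedding")
    return np.concatenate([classical, automatic], axis=-1)


def bce_loss(y, y_hat) -> float:
    """Binary cross-entropy ``-[y ln p + (1-y) ln(1-p)]`` (mean over a batch)."""
    y = np.asarray(y, float)
    p = np.clip(np.asarray(y_hat, float), EPS, 1.0 - EPS)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


class FusionHead(Module):
    """MLP 256 -> hidden -> 1 sigmoid over the fused feature."""

    def __init__(self, in_dim: int, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.fc1 = Linear(in_dim, cfg.hidden_size, rng)
        self.fc2 = Linear(cfg.hidden_size, 1, rng)
        self._rng = rng

    def forward(self, x: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(x, float))
        z = self.fc1(t).relu().dropout(self.cfg.dropout, self._rng, self.training)
        return self.fc2(z).reshape(-1)


@dataclass
class FusionPipeline:
    """Both frozen branches plus the trained fusion head."""

    classical_branch: TrainedBranch
    cnn_branch: TrainedBranch
    head: FusionHead
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    pcfg: PreprocessConfig = field(default_factory=PreprocessConfig)
    fcfg: FeatureConfig = field(default_factory=FeatureConfig)
    history: list[dict] = field(default_factory=list)

    def fused_features(self, x_seq: np.ndarray, x_raw: np.ndarray) -> np.ndarray:
        return fuse(self.classical_branch.embed(x_seq), self.cnn_branch.embed(x_raw))

    def predict_proba(self, x_seq: np.ndarray, x_raw: np.ndarray) -> np.ndarray:
        self.head.eval()
        f = (self.fused_features(x_seq, x_raw) - self.feat_mean) / self.feat_sd
        return 1.0 / (1.0 + np.exp(-self.head.forward(f).data))

    def predict_segment(
        self, segment: Segment
    ) -> tuple[Label, float, FusionFeature]:
        """Single-segment inference; p >= 0.5 -> ES (sensitivity-favouring tie)."""
        seq = extract_feature_sequence(segment, self.pcfg.n_timesteps, self.pcfg, self.fcfg)
        raw = preprocess_signal(segment, self.pcfg)
        x_seq = seq.values[None, :, :]
        x_raw = raw[None, :]
        feat = FusionFeature(
            classical=self.classical_branch.embed(x_seq)[0],
            automatic=self.cnn_branch.embed(x_raw)[0],
        )
        p = float(self.predict_proba(x_seq, x_raw)[0])
        return (Label.ES if p >= 0.5 else Label.NES), p, feat


def train_fusion(
    classical_branch: TrainedBranch,
    cnn_branch: TrainedBranch,
    x_seq_train: np.ndarray,
    x_raw_train: np.ndarray,
    y_train: np.ndarray,
    x_seq_val: np.ndarray,
    x_raw_val: np.ndarray,
    y_val: np.ndarray,
    cfg: FusionConfig | None = None,
    seed: int = 0,
    pcfg: PreprocessConfig | None = None,
    fcfg: FeatureConfig | None = None,
) -> FusionPipeline:
    """Freeze both branches, extract embeddings, train the fusion head.

    Branch weights are never touched: embeddings are computed in eval
    mode and only the head's parameters enter the optimizer.
    """
    cfg = cfg or FusionConfig()
    if not classical_branch.history or not cnn_branch.history:
        raise ValueError("both branches must be trained before fusion")
    y_train = np.asarray(y_train, float)
    _check_two_classes(y_train)
    ft = fuse(classical_branch.embed(x_seq_train), cnn_branch.embed(x_raw_train))
    fv = fuse(classical_branch.embed(x_seq_val), cnn_branch.embed(x_raw_val))
    mean = ft.mean(axis=0)
    sd = ft.std(axis=0)
    sd[sd == 0] = 1.0
    rng = np.random.default_rng(seed)
    head = FusionHead(ft.shape[1], cfg, rng)
    pipeline = FusionPipeline(
        classical_branch=classical_branch,
        cnn_branch=cnn_branch,
        head=head,
        feat_mean=mean,
        feat_sd=sd,
        pcfg=pcfg or PreprocessConfig(),
        fcfg=fcfg or FeatureConfig(),
    )
    _train_loop(
        head, (ft - mean) / sd, y_train, (fv - mean) / sd, np.asarray(y_val, float),
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        lr=cfg.learning_rate, rng=rng, history=pipeline.history,
        forward=lambda m, xb: m.forward(xb),
    )
    return pipeline
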