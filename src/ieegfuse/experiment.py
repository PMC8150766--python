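"""End-to-end experiment orchestration on synthetic data.

Builds a labelled two-class segment set, extracts the 4x70 feature
sequences and the preprocessed raw traces, trains both branches and the
fusion head, and reports validation metrics. This is the path exercised
by the command line, the learnability tests and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classical import ClassicalBranchConfig, TrainedBranch, train_classical
from .deep import CnnConfig, train_cnn
from .evaluation import compute_metrics, confusion_from_pairs
from .features import FeatureConfig, extract_feature_sequence
from .fusion import FusionConfig, FusionPipeline, train_fusion
from .preprocess import PreprocessConfig, preprocess_signal
from .synthetic import SynthConfig, generate_segment
from .types import Label, Segment

__all__ = ["ExperimentConfig", "ExperimentResult", "build_dataset", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Problem sizes and training lengths for one synthetic run.

    Defaults are sized for a single-CPU run: 400 segments per class of
    10 s at 512 Hz (4 timesteps of 2.5 s), 30 / 12 / 40 epochs for the
    classical / CNN / fusion stages.
    """

    n_per_class: int = 400
    duration: float = 10.0
    fs: float = 512.0
    val_fraction: float = 0.25
    classical_epochs: int = 30
    cnn_epochs: int = 12
    fusion_epochs: int = 40
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    pcfg: PreprocessConfig = field(default_factory=PreprocessConfig)
    fcfg: FeatureConfig = field(default_factory=FeatureConfig)


@dataclass
class ExperimentResult:
    classical_branch: TrainedBranch
    cnn_branch: TrainedBranch
    pipeline: FusionPipeline
    val_acc_classical: float
    val_acc_cnn: float
    val_acc_fused: float
    val_metrics_fused: dict


def build_dataset(cfg: ExperimentConfig) -> dict:
    """Generate segments, features and raw traces for both classes.

    Returns arrays ``x_seq`` (n, T, 70), ``x_raw`` (n, L at the analysis
    rate) and ``y`` (1 = ES), plus the segments themselves.
    """
    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(0, 2**31 - 1, size=2 * cfg.n_per_class)
    segments: list[Segment] = []
    for i in range(2 * cfg.n_per_class):
        label = Label.ES if i < cfg.n_per_class else Label.NES
        scfg = replace(
            cfg.synth,
            sampling_rate=cfg.fs,
            duration=cfg.duration,
            class_label=label,
            seed=int(seeds[i]),
        )
        segments.append(generate_segment(scfg))
    x_seq = np.stack(
        [
            extract_feature_sequence(s, cfg.pcfg.n_timesteps, cfg.pcfg, cfg.fcfg).values
            for s in segments
        ]
    )
    x_raw = np.stack([preprocess_signal(s, cfg.pcfg) for s in segments])
    y = np.array([1.0 if s.label is Label.ES else 0.0 for s in segments])
    return {"segments": segments, "x_seq": x_seq, "x_raw": x_raw, "y": y}


def _split(n: int, val_fraction: float, y: np.ndarray, rng: np.random.Generator):
    """Label-stratified train/validation index split."""
    val_idx = []
    for cls in (0.0, 1.0):
        idx = rng.permutation(np.where(y == cls)[0])
        val_idx.extend(idx[: int(round(val_fraction * idx.size))])
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    return ~val_mask, val_mask


def run_experiment(cfg: ExperimentConfig | None = None, data: dict | None = None) -> ExperimentResult:
    """Train both branches and the fusion head; report validation accuracy."""
    cfg = cfg or ExperimentConfig()
    data = data or build_dataset(cfg)
    y = data["y"]
    rng = np.random.default_rng(cfg.seed + 1)
    tr, va = _split(y.size, cfg.val_fraction, y, rng)

    classical = train_classical(
        data["x_seq"][tr], y[tr], data["x_seq"][va], y[va],
        ClassicalBranchConfig(epochs=cfg.classical_epochs), seed=cfg.seed + 2,
    )
    cnn = train_cnn(
        data["x_raw"][tr], y[tr], data["x_raw"][va], y[va],
        CnnConfig(epochs=cfg.cnn_epochs), seed=cfg.seed + 3,
    )
    pipeline = train_fusion(
        classical, cnn,
        data["x_seq"][tr], data["x_raw"][tr], y[tr],
        data["x_seq"][va], data["x_raw"][va], y[va],
        FusionConfig(epochs=cfg.fusion_epochs), seed=cfg.seed + 4,
        pcfg=cfg.pcfg, fcfg=cfg.fcfg,
    )

    def acc(p: np.ndarray) -> float:
        return float(np.mean((p >= 0.5) == (y[va] == 1)))

    p_fused = pipeline.predict_proba(data["x_seq"][va], data["x_raw"][va])
    metrics = compute_metrics(confusion_from_pairs(y[va], p_fused >= 0.5))
    return ExperimentResult(
        classical_branch=classical,
        cnn_branch=cnn,
        pipeline=pipeline,
        val_acc_classical=acc(classical.predict_proba(data["x_seq"][va])),
        val_acc_cnn=acc(cnn.predict_proba(data["x_raw"][va])),
        val_acc_fused=acc(p_fused),
        val_metrics_fused={"ACC": metrics.ACC, "SE": metrics.SE, "SP": metrics.SP},
    )
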