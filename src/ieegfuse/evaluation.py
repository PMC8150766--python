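"""Splits, confusion counts, ACC/SE/SP metrics and fold aggregation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "Scheme",
    "SplitPlan",
    "compute_metrics",
    "confusion_from_pairs",
    "make_split",
    "aggregate_folds",
    "report",
    "round_half_up",
    "format_percent",
]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricSet:
    """Accuracy, sensitivity (ES recall) and specificity (NES recall)."""

    ACC: float
    SE: float
    SP: float


def round_half_up(x: float, decimals: int = 2) -> float:
    """Half-up decimal rounding for report formatting."""
    q = 10**decimals
    return math.floor(x * q + 0.5) / q


def format_percent(x: float) -> str:
    """Proportion -> printed percentage, e.g. 0.976 -> '97.60%'."""
    return f"{round_half_up(100 * x):.2f}%"


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """ACC=(TP+TN)/total, SE=TP/(TP+FN), SP=TN/(TN+FP).

    A zero denominator raises rather than silently reporting 0.
    """
    if c.total == 0:
        raise ZeroDivisionError("empty confusion table")
    if c.TP + c.FN == 0:
        raise ZeroDivisionError("no positive examples; sensitivity undefined")
    if c.TN + c.FP == 0:
        raise ZeroDivisionError("no negative examples; specificity undefined")
    return MetricSet(
        ACC=(c.TP + c.TN) / c.total,
        SE=c.TP / (c.TP + c.FN),
        SP=c.TN / (c.TN + c.FP),
    )


def confusion_from_pairs(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts from binary (label, prediction) arrays (1 = ES)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


class Scheme(str, Enum):
    RANDOM_HOLDOUT = "random_holdout"
    INTRA_SUBJECT = "intra_subject"
    CROSS_SUBJECT = "cross_subject"


@dataclass
class SplitPlan:
    scheme: Scheme
    fractions: tuple[float, ...] = (0.7, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        self.scheme = Scheme(self.scheme)
        if self.scheme is not Scheme.CROSS_SUBJECT and abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _stratified_assign(
    labels: np.ndarray, fractions: tuple[float, ...], rng: np.random.Generator
) -> np.ndarray:
    """Per-class proportional random assignment to len(fractions) folds."""
    names = ["train", "val", "test"] if len(fractions) == 3 else ["train", "test"]
    out = np.empty(labels.size, dtype=object)
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        idx = rng.permutation(idx)
        bounds = np.round(np.cumsum(fractions) * idx.size).astype(int)
        start = 0
        for name, stop in zip(names, bounds):
            out[idx[start:stop]] = name
            start = stop
    return out


def make_split(
    labels, patients=None, plan: SplitPlan | None = None
) -> dict:
    """Assign segments to folds.

    * random_holdout / intra_subject: seeded, label-stratified assignment
      to train(/val)/test by ``plan.fractions``;
    * cross_subject: one fold per patient, each a dict of boolean
      train/test masks with no patient shared between them.
    """
    plan = plan or SplitPlan(scheme=Scheme.RANDOM_HOLDOUT)
    labels = np.asarray(labels)
    rng = np.random.default_rng(plan.seed)
    if plan.scheme is Scheme.CROSS_SUBJECT:
        if patients is None:
            raise ValueError("cross_subject split requires patient ids")
        patients = np.asarray(patients)
        uniq = sorted(set(patients.tolist()))
        if len(uniq) < 2:
            raise ValueError("cross_subject split requires at least 2 patients")
        return {
            "scheme": plan.scheme,
            "folds": [
                {"held_out": p, "train": patients != p, "test": patients == p}
                for p in uniq
            ],
        }
    return {
        "scheme": plan.scheme,
        "assignment": _stratified_assign(labels, plan.fractions, rng),
    }


def aggregate_folds(per_fold: list[MetricSet]) -> dict:
    """Mean, standard error of the mean, and range per metric over folds."""
    if not per_fold:
        raise ValueError("no folds to aggregate")
    out = {}
    for name in ("ACC", "SE", "SP"):
        vals = np.array([getattr(m, name) for m in per_fold], float)
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out[name] = {
            "mean": float(vals.mean()),
            "sem": sem,
            "min": float(vals.min()),
            "max": float(vals.max()),
            "single_fold": vals.size == 1,
        }
    return out


def report(results: list[dict]) -> pd.DataFrame:
    """Result table keyed by (method, feature set), percent-formatted.

    ``results`` rows carry ``method``, ``features`` and a ``metrics``
    MetricSet; row order follows the input, columns mirror the standard
    ACC/SE/SP layout.
    """
    rows = []
    for r in results:
        m: MetricSet = r["metrics"]
        rows.append(
            {
                "method": r["method"],
                "features": r.get("features", ""),
                "ACC": format_percent(m.ACC),
                "SE": format_percent(m.SE),
                "SP": format_percent(m.SP),
            }
        )
    return pd.DataFrame(rows, columns=["method", "features", "ACC", "SE", "SP"])
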