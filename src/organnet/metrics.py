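"""Per-organ confusion counts and accuracy / precision / recall / F1.

Conventions: a positive is an *unhealthy* organ call (label 1).  TP counts
correctly identified unhealthy conditions, FP incorrect unhealthy calls
(type I error), FN missed unhealthy conditions (type II error), TN correct
healthy calls.

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Zero-denominator precision/recall/F1 are reported as 0.0 and flagged in the
:class:`MetricsReport` warnings; all-zero confusion counts are an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "build_report",
    "ORGANS",
]

ORGANS = ("heart", "lung", "liver", "spleen", "kidney")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(pred, truth) -> ConfusionCounts:
    """Confusion counts of binary predictions against binary truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("cannot build confusion counts from an empty input")
    if not (np.isin(pred, (0, 1)).all() and np.isin(truth, (0, 1)).all()):
        raise ValueError("predictions and truth must be binary")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(pred & truth)),
        TN=int(np.sum(~pred & ~truth)),
        FP=int(np.sum(pred & ~truth)),
        FN=int(np.sum(~pred & truth)),
    )


def _check_nonempty(c: ConfusionCounts) -> None:
    if c.total == 0:
        raise ValueError("metrics are undefined for all-zero confusion counts")


def accuracy(c: ConfusionCounts) -> float:
    _check_nonempty(c)
    return (c.TP + c.TN) / c.total


def precision(c: ConfusionCounts) -> float:
    _check_nonempty(c)
    denom = c.TP + c.FP
    return c.TP / denom if denom else 0.0


def recall(c: ConfusionCounts) -> float:
    _check_nonempty(c)
    denom = c.TP + c.FN
    return c.TP / denom if denom else 0.0


def f1(c: ConfusionCounts) -> float:
    _check_nonempty(c)
    p, r = precision(c), recall(c)
    return 2.0 * p * r / (p + r) if (p + r) else 0.0


@dataclass
class MetricsReport:
    """Per-organ confusion counts and metrics plus unweighted macro averages."""

    counts: dict[str, ConfusionCounts]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for organ, c in self.counts.items():
            if c.TP + c.FP == 0:
                self.warnings.append(f"{organ}: no positive predictions, precision set to 0")
            if c.TP + c.FN == 0:
                self.warnings.append(f"{organ}: no positive truth, recall set to 0")

    def metric(self, organ: str, name: str) -> float:
        fn = {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}[name]
        return fn(self.counts[organ])

    @property
    def macro_accuracy(self) -> float:
        return float(np.mean([accuracy(c) for c in self.counts.values()]))

    @property
    def macro_f1(self) -> float:
        return float(np.mean([f1(c) for c in self.counts.values()]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for organ, c in self.counts.items():
            rows.append({
                "organ": organ, "TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN,
                "accuracy": accuracy(c), "precision": precision(c),
                "recall": recall(c), "f1": f1(c),
            })
        return pd.DataFrame(rows).set_index("organ")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "organs": {o: row for o, row in self.to_frame().to_dict("index").items()},
            "macro_accuracy": self.macro_accuracy,
            "macro_f1": self.macro_f1,
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def build_report(pred: np.ndarray, truth: np.ndarray,
                 organs: tuple[str, ...] = ORGANS) -> MetricsReport:
    """Per-organ report from ``n x len(organs)`` prediction/truth matrices."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 2 or pred.shape[1] != len(organs):
        raise ValueError("predictions/truth must both be n x organs matrices")
    counts = {o: confusion(pred[:, i], truth[:, i]) for i, o in enumerate(organs)}
    return MetricsReport(counts)
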