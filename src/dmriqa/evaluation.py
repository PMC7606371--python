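"""Confusion matrices and classification metrics for volume/subject ratings.

Sensitivity and specificity are computed one-vs-rest per class:

    SEN = TP / (TP + FN),   SPE = TN / (FP + TN)

and the single reported accuracy is the overall multi-class accuracy
(trace of the confusion matrix over the total count).  Undefined metrics
(zero denominator) are returned as NaN rather than raised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import QualityLabel

__all__ = ["ConfusionMatrix", "confusion", "metrics", "metrics_from_csv"]

CLASS_NAMES = ("pass", "questionable", "fail")


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 integer counts; rows = actual, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(c < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    actual: Sequence[QualityLabel], predicted: Sequence[QualityLabel]
) -> ConfusionMatrix:
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    if len(actual) == 0:
        raise ValueError("need at least one pair")
    c = np.zeros((3, 3), dtype=int)
    for a, p in zip(actual, predicted):
        c[int(a), int(p)] += 1
    return ConfusionMatrix(c)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cm: ConfusionMatrix) -> dict:
    """Per-class one-vs-rest SEN/SPE plus overall accuracy.

    Returns ``{"sen": {class: val}, "spe": {...}, "acc": val}``; values are
    NaN where the defining denominator is zero (e.g. SEN of an absent class).
    """
    c = cm.counts.astype(float)
    total = c.sum()
    out = {"sen": {}, "spe": {}}
    for k, name in enumerate(CLASS_NAMES):
        tp = c[k, k]
        fn = c[k, :].sum() - tp
        fp = c[:, k].sum() - tp
        tn = total - tp - fn - fp
        out["sen"][name] = _safe_div(tp, tp + fn)
        out["spe"][name] = _safe_div(tn, fp + tn)
    out["acc"] = _safe_div(np.trace(c), total)
    return out


def metrics_from_csv(path: str | Path) -> dict:
    """Compute metrics from a prediction table with columns actual, predicted."""
    df = pd.read_csv(path)
    actual = [QualityLabel.from_string(s) for s in df["actual"]]
    predicted = [QualityLabel.from_string(s) for s in df["predicted"]]
    return metrics(confusion(actual, predicted))


def format_metrics(m: dict, ndigits: int = 4) -> str:
    """Human-readable table of per-class SEN/SPE and overall ACC."""
    lines = [f"{'class':<14}{'SEN':>8}{'SPE':>8}"]
    for name in CLASS_NAMES:
        lines.append(f"{name:<14}{m['sen'][name]:>8.{ndigits}f}{m['spe'][name]:>8.{ndigits}f}")
    lines.append(f"{'ACC':<14}{m['acc']:>8.{ndigits}f}")
    return "\n".join(lines)
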