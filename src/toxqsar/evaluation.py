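"""Classification metrics: confusion counts, ACC, F1, SE/SP, ROC-AUC, banding.

ACC = (TP + TN) / (TP + FP + TN + FN). F1 is the harmonic mean of precision
and recall, 2TP / (2TP + FP + FN); sensitivity SE = TP/(TP+FN) and
specificity SP = TN/(TN+FP) are reported alongside it. ROC-AUC is the
threshold-free headline metric, equal to the Mann-Whitney probability that
a random active compound outscores a random inactive one (ties credited
0.5).

AUC bands follow the common interpretive convention: >= 0.8 excellent,
0.7-0.8 good, 0.6-0.7 fair, 0.5-0.6 poor; below 0.5 the classifier ranks
worse than random.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """Confusion counts plus the derived metrics for one evaluation."""

    counts: ConfusionCounts
    acc: float
    f1: float
    se: float
    sp: float
    auc: float
    threshold: float
    band: str
    worse_than_random: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv_row(
        self,
        endpoint: str = "",
        algorithm: str = "",
        descriptor_set: str = "",
        n_features: int = 0,
    ) -> dict:
        """Flat row for grid-style result tables."""
        return {
            "endpoint": endpoint,
            "algorithm": algorithm,
            "descriptor_set": descriptor_set,
            "n_features": n_features,
            "ACC": self.acc,
            "F1": self.f1,
            "SE": self.se,
            "SP": self.sp,
            "AUC": self.auc,
            "band": self.band,
        }


def confusion_counts(y, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/FP/TN/FN calling active iff score >= threshold."""
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {scores.shape} scores")
    if y.size == 0:
        raise ValueError("empty input")
    calls = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(calls & (y == 1))),
        fp=int(np.sum(calls & (y == 0))),
        tn=int(np.sum(~calls & (y == 0))),
        fn=int(np.sum(~calls & (y == 1))),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("cannot compute accuracy of zero samples")
    return (c.tp + c.tn) / c.total


def f1_score(c: ConfusionCounts) -> float:
    """Standard F1 = 2TP / (2TP + FP + FN); degenerate tables return 0."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("F1 undefined (no positives predicted or present); returning 0.0")
        return 0.0
    return 2 * c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0


def specificity(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0


def roc_auc(y, scores) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties = 0.5)."""
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape:
        raise ValueError("length mismatch between labels and scores")
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(y, scores))


_BANDS = [(0.8, "excellent"), (0.7, "good"), (0.6, "fair"), (0.0, "poor")]


def auc_band(auc: float) -> str:
    """Map an AUC to its qualitative performance band."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {auc}")
    for cutoff, band in _BANDS:
        if auc >= cutoff:
            return band
    return "poor"  # pragma: no cover


def evaluate(y, scores, threshold: float = 0.5) -> EvalReport:
    """Full evaluation report from labels and scores."""
    c = confusion_counts(y, scores, threshold)
    auc = roc_auc(y, scores)
    return EvalReport(
        counts=c,
        acc=accuracy(c),
        f1=f1_score(c) if (2 * c.tp + c.fp + c.fn) else 0.0,
        se=sensitivity(c),
        sp=specificity(c),
        auc=auc,
        threshold=threshold,
        band=auc_band(auc),
        worse_than_random=auc < 0.5,
    )
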