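"""Information-gain ranking and recursive backward feature elimination.

Descriptors are scored by the information gain of the binary activity label
after discretizing each feature into equal-width bins:

    IG(X) = H(Y) - sum_b p(b) * H(Y | b),   base-2 logarithms,

so a perfectly class-separating feature scores H(Y) bits and a constant
feature scores 0. The elimination loop trains a model on the full feature
set, then repeatedly drops the lowest-ranked surviving feature(s), retrains,
and records the validation AUC of every subset down to ``min_features``.
By default the ranking is recomputed on the surviving features each round
(true backward elimination); a rank-once mode is available for large p.

The best subset is the one with maximal validation AUC, ties resolved
toward the smaller subset. Because the full feature set is itself a trace
entry, screening can never select something worse (on the validation split)
than no screening at all.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_features import DescriptorMatrix
from .errors import AlignmentError
from .evaluation import roc_auc
from .models import ModelSpec, predict_scores, train


# ---------------------------------------------------------------------------
# information gain
# ---------------------------------------------------------------------------

def _entropy_bits(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(x, y, bins: int = 10) -> float:
    """Information gain (bits) of labels ``y`` given feature ``x``.

    ``x`` is discretized into ``bins`` equal-width intervals spanning
    [min(x), max(x)]; the maximum lands in the last bin. A constant feature
    carries no partition information and returns 0. The result lies in
    [0, H(Y)].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    idx = np.minimum((bins * (x - lo) / (hi - lo)).astype(int), bins - 1)
    h_y = _entropy_bits(y)
    h_cond = 0.0
    for b in np.unique(idx):
        mask = idx == b
        h_cond += mask.mean() * _entropy_bits(y[mask])
    return max(h_y - h_cond, 0.0)


@dataclass
class FeatureRanking:
    """Features with their information gain, best first; ties keep column order."""

    scores: list[tuple[str, float]]

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.scores]


def rank_features(m: DescriptorMatrix, y, bins: int = 10) -> FeatureRanking:
    """Score every column of ``m`` by information gain and sort descending."""
    if m.n_features == 0:
        raise ValueError("cannot rank an empty matrix")
    y = np.asarray(y)
    if len(y) != m.n_compounds:
        raise ValueError("label count does not match matrix rows")
    gains = [information_gain(m.values[:, j], y, bins=bins) for j in range(m.n_features)]
    order = sorted(range(m.n_features), key=lambda j: (-gains[j], j))
    return FeatureRanking([(m.feature_names[j], gains[j]) for j in order])


# ---------------------------------------------------------------------------
# recursive elimination
# ---------------------------------------------------------------------------

@dataclass
class SelectionConfig:
    bins: int = 10
    min_features: int = 2
    step: int = 1
    rerank_each_iteration: bool = True

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass(frozen=True)
class SelectionEntry:
    features: tuple[str, ...]
    validation_auc: float
    removed: tuple[str, ...]  # features eliminated to reach this subset


@dataclass
class SelectionTrace:
    """The sequence of nested feature subsets with their validation AUCs."""

    entries: list[SelectionEntry]
    algorithm: str
    split_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": range(len(self.entries)),
                "n_features": [len(e.features) for e in self.entries],
                "removed_feature": [";".join(e.removed) for e in self.entries],
                "validation_auc": [e.validation_auc for e in self.entries],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "algorithm": self.algorithm,
            "split_id": self.split_id,
            "entries": [
                {
                    "features": list(e.features),
                    "validation_auc": e.validation_auc,
                    "removed": list(e.removed),
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def recursive_select(
    m_train: DescriptorMatrix,
    y_train,
    m_valid: DescriptorMatrix,
    y_valid,
    model: ModelSpec,
    cfg: SelectionConfig | None = None,
) -> SelectionTrace:
    """Backward-eliminate features by information-gain rank, tracking AUC.

    Starting from the full feature set, each round removes the ``step``
    lowest-ranked surviving features, retrains ``model`` on the training
    split and records the AUC on the validation split, until only
    ``min_features`` remain.
    """
    cfg = cfg or SelectionConfig()
    if list(m_train.feature_names) != list(m_valid.feature_names):
        raise AlignmentError("train and validation matrices must share feature names")
    p = m_train.n_features
    if p < cfg.min_features:
        raise ValueError(f"matrix has {p} features, fewer than min_features={cfg.min_features}")
    y_train = np.asarray(y_train, dtype=int)
    y_valid = np.asarray(y_valid, dtype=int)
    if len(np.unique(y_valid)) < 2:
        raise ValueError("validation split is single-class; AUC is undefined on it")

    def _auc_for(features: list[str]) -> float:
        sub_train = m_train.select(features)
        fitted = train(model, sub_train, y_train)
        auc = roc_auc(y_valid, predict_scores(fitted, m_valid.select(features)))
        if not np.isfinite(auc):  # pragma: no cover - guarded by roc_auc
            raise ValueError(f"non-finite AUC on validation split {model.seed}")
        return auc

    # keep subsets in ranked order (most important first) so the tail is
    # always the elimination candidate
    ranking = rank_features(m_train, y_train, bins=cfg.bins)
    current = ranking.names
    entries = [SelectionEntry(tuple(current), _auc_for(current), ())]
    while len(current) > cfg.min_features:
        if cfg.rerank_each_iteration and len(entries) > 1:
            current = rank_features(
                m_train.select(current), y_train, bins=cfg.bins
            ).names
        k = min(cfg.step, len(current) - cfg.min_features)
        removed = tuple(current[-k:])
        current = current[:-k]
        entries.append(SelectionEntry(tuple(current), _auc_for(current), removed))
    return SelectionTrace(entries=entries, algorithm=model.algorithm, split_id=str(model.seed))


def best_subset(trace: SelectionTrace) -> list[str]:
    """Subset with the highest validation AUC; ties go to the smaller subset."""
    if not trace.entries:
        raise ValueError("empty selection trace")
    best = max(trace.entries, key=lambda e: (e.validation_auc, -len(e.features)))
    return list(best.features)
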