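"""Shapley-style feature attribution and top-k percentage share tables.

Attributions are interventional Shapley values of the model's activity
score: the payoff of a feature coalition S for a sample x is the model
score averaged over background rows whose S-features are replaced by x's
values. Two estimators are provided, both satisfying local additivity
(base value + sum of attributions = model score of the sample) exactly:

``exact``
    Enumerates all 2^p coalitions and applies the Shapley weights; exact
    for any model but only feasible for small p (<= ~14).
``sampling``
    Seeded permutation sampling. Each sampled permutation contributes a
    telescoping sum of marginal effects, so additivity is exact for any
    number of permutations while individual attributions converge to the
    Shapley value as permutations grow.

Importance summaries are the mean absolute attribution per feature; the
share table normalizes the top-k importances to percentages summing to
100 (one decimal), the convention used for reporting the dominant
descriptors of a toxicity endpoint model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_features import DescriptorMatrix
from .models import TrainedModel, _align, _raw_scores

_EXACT_MAX_FEATURES = 14


@dataclass
class ShapSummary:
    """Per-feature attribution summary plus the raw per-sample values."""

    mean_abs: dict[str, float]
    base_value: float
    n_samples: int
    method: str
    feature_names: list[str]
    attributions: np.ndarray  # (n_samples, p)
    sample_scores: np.ndarray  # (n_samples,)


def shap_importance(
    model: TrainedModel,
    X: DescriptorMatrix,
    n_background: int = 100,
    seed: int = 0,
    method: str = "auto",
    n_permutations: int = 30,
    max_samples: int | None = 50,
) -> ShapSummary:
    """Attribute model scores to features over the samples of ``X``.

    ``n_background`` rows of ``X`` (seeded sample) form the reference
    distribution; up to ``max_samples`` rows are explained. ``method`` is
    ``"exact"``, ``"sampling"`` or ``"auto"`` (exact when p is small).
    """
    X = _align(model, X)
    n, p = X.values.shape
    if n_background > n:
        raise ValueError(f"n_background={n_background} exceeds available rows ({n})")
    if method == "auto":
        method = "exact" if p <= _EXACT_MAX_FEATURES else "sampling"
    if method not in ("exact", "sampling"):
        raise ValueError(f"unknown attribution method {method!r}")

    rng = np.random.default_rng(seed)
    background = X.values[rng.choice(n, size=n_background, replace=False)]
    if max_samples is not None and n > max_samples:
        explained = X.values[np.sort(rng.choice(n, size=max_samples, replace=False))]
    else:
        explained = X.values

    base = float(_raw_scores(model, background).mean())
    if method == "exact":
        phi = np.vstack(
            [_exact_shapley(model, x, background) for x in explained]
        )
    else:
        phi = np.vstack(
            [
                _sampled_shapley(model, x, background, n_permutations, rng)
                for x in explained
            ]
        )
    scores = _raw_scores(model, explained)
    mean_abs = {
        name: float(np.abs(phi[:, j]).mean()) for j, name in enumerate(X.feature_names)
    }
    return ShapSummary(
        mean_abs=mean_abs,
        base_value=base,
        n_samples=len(explained),
        method=method,
        feature_names=list(X.feature_names),
        attributions=phi,
        sample_scores=scores,
    )


def _coalition_values(model: TrainedModel, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Mean model score for every coalition mask (background features swapped to x)."""
    p = x.size
    n_b = background.shape[0]
    values = np.empty(1 << p)
    # batch all coalitions into one predict call
    stacked = np.tile(background, (1 << p, 1))
    for mask in range(1 << p):
        block = stacked[mask * n_b : (mask + 1) * n_b]
        for j in range(p):
            if mask >> j & 1:
                block[:, j] = x[j]
    scores = _raw_scores(model, stacked)
    for mask in range(1 << p):
        values[mask] = scores[mask * n_b : (mask + 1) * n_b].mean()
    return values


def _exact_shapley(model: TrainedModel, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    p = x.size
    if p > _EXACT_MAX_FEATURES:
        raise ValueError(
            f"exact attribution enumerates 2^p coalitions; p={p} is too large, use sampling"
        )
    v = _coalition_values(model, x, background)
    sizes = np.array([bin(m).count("1") for m in range(1 << p)])
    weights = np.array(
        [math.factorial(s) * math.factorial(p - s - 1) / math.factorial(p) for s in range(p)]
    )
    phi = np.zeros(p)
    for mask in range(1 << p):
        s = sizes[mask]
        for j in range(p):
            if not mask >> j & 1:
                phi[j] += weights[s] * (v[mask | (1 << j)] - v[mask])
    return phi


def _sampled_shapley(
    model: TrainedModel,
    x: np.ndarray,
    background: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    p = x.size
    n_b = background.shape[0]
    phi = np.zeros(p)
    for _ in range(n_permutations):
        order = rng.permutation(p)
        # stacked[k] = background with the first k features (in this order)
        # replaced by x; evaluated in a single batched call
        stacked = np.tile(background, (p + 1, 1))
        current = background.copy()
        for k, j in enumerate(order, start=1):
            current[:, j] = x[j]
            stacked[k * n_b : (k + 1) * n_b] = current
        step_means = _raw_scores(model, stacked).reshape(p + 1, n_b).mean(axis=1)
        phi[order] += np.diff(step_means)
    return phi / n_permutations


# ---------------------------------------------------------------------------
# share tables
# ---------------------------------------------------------------------------

@dataclass
class ShareTable:
    """Top-k features with their percentage share of summed importance."""

    rows: list[tuple[str, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.rows) + 1),
                "feature": [r[0] for r in self.rows],
                "share_percent": [r[1] for r in self.rows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {feature: share for feature, share in self.rows}


def top_k_share_table(summary: ShapSummary, k: int = 6) -> ShareTable:
    """Normalize the k largest mean-|attribution| values to percent shares.

    Shares are rounded to one decimal and sum to 100 within rounding error.
    Fewer than k features simply uses them all; an all-zero summary falls
    back to equal shares.
    """
    if not summary.mean_abs:
        raise ValueError("empty attribution summary")
    items = sorted(
        summary.mean_abs.items(),
        key=lambda kv: (-kv[1], summary.feature_names.index(kv[0])),
    )[:k]
    total = sum(v for _, v in items)
    if total == 0:
        shares = [(name, round(100.0 / len(items), 1)) for name, _ in items]
    else:
        shares = [(name, round(100.0 * v / total, 1)) for name, v in items]
    return ShareTable(rows=shares)
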