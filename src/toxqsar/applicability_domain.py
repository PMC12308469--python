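"""Centroid-distance applicability domain for QSAR predictions.

The domain is defined in min-max normalized descriptor space: features are
scaled to the training range (constant features map to 0, query values are
not clamped), the centroid mu is the mean of the normalized training rows,
and a query compound's distance is the Euclidean norm

    D_E(x, mu) = sqrt((x - mu)^T (x - mu)).

The decision threshold is the maximum distance observed on the training
set, so every training compound is in-domain by construction; a query
strictly beyond that maximum is flagged out-of-domain and its prediction
should be treated as an extrapolation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_features import (
    DescriptorMatrix,
    NormalizationParams,
    apply_normalizer,
    fit_normalizer,
)
from .errors import SchemaError


@dataclass
class ADModel:
    """Normalizer, centroid and distance threshold defining the domain."""

    normalizer: NormalizationParams
    centroid: np.ndarray
    threshold: float
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if not np.isfinite(self.centroid).all():
            raise ValueError("centroid must be finite")
        if list(self.feature_names) != list(self.normalizer.feature_names):
            raise ValueError("feature names must match the normalizer")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "x_min": self.normalizer.x_min.tolist(),
            "x_max": self.normalizer.x_max.tolist(),
            "centroid": self.centroid.tolist(),
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ADModel":
        payload = json.loads(Path(path).read_text())
        normalizer = NormalizationParams(
            np.array(payload["x_min"]), np.array(payload["x_max"]), payload["feature_names"]
        )
        return cls(
            normalizer,
            np.array(payload["centroid"]),
            float(payload["threshold"]),
            payload["feature_names"],
        )


@dataclass(frozen=True)
class ADResult:
    compound_id: str
    distance: float
    in_domain: bool


def fit_ad(m_train: DescriptorMatrix) -> ADModel:
    """Fit the applicability domain on the (clean) training matrix."""
    if m_train.n_compounds == 0 or m_train.n_features == 0:
        raise SchemaError("cannot fit an applicability domain on an empty matrix")
    normalizer = fit_normalizer(m_train)
    normalized = apply_normalizer(normalizer, m_train)
    centroid = normalized.values.mean(axis=0)
    distances = np.linalg.norm(normalized.values - centroid, axis=1)
    return ADModel(
        normalizer=normalizer,
        centroid=centroid,
        threshold=float(distances.max()),
        feature_names=list(m_train.feature_names),
    )


def ad_distances(ad: ADModel, m: DescriptorMatrix) -> np.ndarray:
    """Euclidean distance of each row to the training centroid (normalized space)."""
    aligned = m.select(ad.feature_names) if list(m.feature_names) != ad.feature_names else m
    normalized = apply_normalizer(ad.normalizer, aligned)
    return np.linalg.norm(normalized.values - ad.centroid, axis=1)


def ad_distance(ad: ADModel, x) -> float:
    """Distance for a single raw feature row aligned to the AD's features."""
    x = np.asarray(x, dtype=float).reshape(1, -1)
    m = DescriptorMatrix(x, list(ad.feature_names), ["query"])
    return float(ad_distances(ad, m)[0])


def check_domain(ad: ADModel, m: DescriptorMatrix) -> list[ADResult]:
    """Per-compound distance and in/out decision (boundary counts as inside)."""
    if m.n_compounds == 0:
        return []
    dists = ad_distances(ad, m)
    return [
        ADResult(cid, float(d), bool(d <= ad.threshold))
        for cid, d in zip(m.compound_ids, dists)
    ]


def domain_frame(results: list[ADResult]) -> pd.DataFrame:
    """Tabular view of check_domain output (compound_id, distance, in_domain)."""
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in results],
            "distance": [r.distance for r in results],
            "in_domain": [r.in_domain for r in results],
        }
    )
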