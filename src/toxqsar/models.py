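"""Train/test splitting and a uniform interface over seven classifier families.

The registry covers the standard QSAR benchmark set: decision tree (DT),
Gaussian naive Bayes (NB), support-vector machine (SVM), k-nearest
neighbors (kNN), random forest (RF), gradient boosting (XGB) and a
multilayer perceptron (MLP). All expose the same train/score contract:
``predict_scores`` returns a value in [0, 1] per compound, higher meaning
more likely active. Probability-like outputs are used where the estimator
provides them natively; the SVM margin is squashed through a logistic so
its ranking (all that AUC needs) is preserved.

Hyperparameters default to the library defaults for each estimator and can
be overridden per spec; seeds are pinned everywhere a learner is stochastic.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import joblib
import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .chem_features import DescriptorMatrix, NormalizationParams
from .errors import AlignmentError, BundleError, RegistryError

ALGORITHMS = ("DT", "NB", "SVM", "kNN", "RF", "XGB", "MLP")

_BUNDLE_FORMAT = "toxqsar-bundle/1"


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """A reproducible train/test partition of n samples."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    ratio: float
    seed: int
    stratified: bool


def split_dataset(
    n: int,
    ratio: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
    labels=None,
) -> SplitSpec:
    """Randomly partition ``n`` samples into train and test sets.

    The train size is round(ratio * n). Stratified splitting (the default)
    keeps per-class train counts within one compound of proportional and
    guarantees both classes appear on both sides; it requires ``labels``.
    """
    if n < 5:
        raise ValueError(f"need at least 5 samples to split, got {n}")
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must lie strictly in (0, 1), got {ratio}")
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)

    if not stratified:
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
    else:
        if labels is None:
            raise ValueError("stratified split requires labels")
        y = np.asarray(labels)
        if len(y) != n:
            raise ValueError("labels length must equal n")
        classes, inverse = np.unique(y, return_inverse=True)
        counts = np.bincount(inverse)
        if np.any(counts < 2):
            small = [classes[i] for i in range(len(classes)) if counts[i] < 2]
            raise ValueError(
                f"class(es) {small} have fewer than 2 members; "
                "they cannot appear in both train and test"
            )
        alloc = _proportional_allocation(counts, n_train)
        train_parts = []
        test_parts = []
        for ci in range(len(classes)):
            members = rng.permutation(np.flatnonzero(inverse == ci))
            train_parts.append(members[: alloc[ci]])
            test_parts.append(members[alloc[ci]:])
        train = np.sort(np.concatenate(train_parts))
        test = np.sort(np.concatenate(test_parts))
    return SplitSpec(
        tuple(int(i) for i in train),
        tuple(int(i) for i in test),
        ratio,
        seed,
        stratified,
    )


def _proportional_allocation(counts: np.ndarray, n_train: int) -> np.ndarray:
    """Largest-remainder apportionment of train slots, each class kept on both sides."""
    ideal = counts * n_train / counts.sum()
    alloc = np.floor(ideal).astype(int)
    remainder = ideal - alloc
    for ci in np.argsort(-remainder, kind="stable")[: n_train - alloc.sum()]:
        alloc[ci] += 1
    # clamp so every class has >=1 member on each side, rebalancing elsewhere
    for ci in range(len(counts)):
        alloc[ci] = min(max(alloc[ci], 1), counts[ci] - 1)
    diff = n_train - alloc.sum()
    order = np.argsort(-remainder, kind="stable") if diff > 0 else np.argsort(remainder, kind="stable")
    for ci in list(order) * 2:
        if diff == 0:
            break
        step = 1 if diff > 0 else -1
        new = alloc[ci] + step
        if 1 <= new <= counts[ci] - 1:
            alloc[ci] = new
            diff -= step
    return alloc


# ---------------------------------------------------------------------------
# model specs and training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which algorithm to train, with hyperparameter overrides and a seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise RegistryError(
                f"unknown algorithm {self.algorithm!r}; registered: {list(ALGORITHMS)}"
            )


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if spec.algorithm == "NB":
        return GaussianNB(**hp)
    if spec.algorithm == "SVM":
        return SVC(random_state=seed, **hp)
    if spec.algorithm == "kNN":
        return KNeighborsClassifier(**hp)
    if spec.algorithm == "RF":
        hp.setdefault("n_jobs", 1)
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.algorithm == "XGB":
        hp.setdefault("n_jobs", 1)
        hp.setdefault("eval_metric", "logloss")
        return XGBClassifier(random_state=seed, **hp)
    if spec.algorithm == "MLP":
        hp.setdefault("max_iter", 300)
        return MLPClassifier(random_state=seed, **hp)
    raise RegistryError(f"unknown algorithm {spec.algorithm!r}")  # pragma: no cover


@dataclass
class TrainedModel:
    """A fitted classifier plus the exact feature layout it expects."""

    spec: ModelSpec
    feature_names: tuple[str, ...]
    estimator: object
    n_training: int
    class_balance: float
    created: str
    normalizer: NormalizationParams | None = None
    ad_model: object | None = None  # ADModel; kept loose to avoid a cycle


def train(spec: ModelSpec, X: DescriptorMatrix, y) -> TrainedModel:
    """Fit one classifier on a clean descriptor matrix."""
    y = np.asarray(y, dtype=int)
    if len(y) != X.n_compounds:
        raise ValueError("label count does not match matrix rows")
    if not np.isfinite(X.values).all():
        raise ValueError("training matrix contains non-finite values; clean it first")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = _build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X.values, y)
    return TrainedModel(
        spec=spec,
        feature_names=tuple(X.feature_names),
        estimator=est,
        n_training=int(len(y)),
        class_balance=float(np.mean(y)),
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


def _align(model: TrainedModel, X: DescriptorMatrix) -> DescriptorMatrix:
    if tuple(X.feature_names) == model.feature_names:
        return X
    have = set(X.feature_names)
    want = set(model.feature_names)
    missing = sorted(want - have)
    extra = sorted(have - want)
    if missing or extra:
        raise AlignmentError(f"feature mismatch: missing {missing}, extra {extra}")
    return X.select(model.feature_names)


def _raw_scores(model: TrainedModel, values: np.ndarray) -> np.ndarray:
    """Score a plain array already laid out in the model's feature order."""
    est = model.estimator
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(values)
        pos = list(est.classes_).index(1)
        return np.clip(proba[:, pos], 0.0, 1.0)
    margin = est.decision_function(values)
    if list(est.classes_) != [0, 1]:  # pragma: no cover - binary by construction
        margin = -margin
    return expit(margin)


def predict_scores(model: TrainedModel, X: DescriptorMatrix) -> np.ndarray:
    """Activity scores in [0, 1], one per row, higher = more likely active."""
    X = _align(model, X)
    return _raw_scores(model, X.values)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Persist a model as a bundle directory (manifest + fitted estimator)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": _BUNDLE_FORMAT,
        "algorithm": model.spec.algorithm,
        "hyperparameters": model.spec.hyperparameters,
        "seed": model.spec.seed,
        "feature_names": list(model.feature_names),
        "n_training": model.n_training,
        "class_balance": model.class_balance,
        "created": model.created,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(model.estimator, path / "model.joblib")
    if model.normalizer is not None:
        model.normalizer.to_json(path / "normalizer.json")
    if model.ad_model is not None:
        model.ad_model.to_json(path / "ad_model.json")
    return path


def load_model(path: str | Path) -> TrainedModel:
    """Load a bundle written by :func:`save_model`."""
    from .applicability_domain import ADModel

    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise BundleError(f"not a model bundle (no manifest.json): {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise BundleError(f"corrupted manifest in {path}: {exc}") from exc
    if manifest.get("format") != _BUNDLE_FORMAT:
        raise BundleError(
            f"unsupported bundle format {manifest.get('format')!r} (expected {_BUNDLE_FORMAT})"
        )
    try:
        estimator = joblib.load(path / "model.joblib")
    except Exception as exc:
        raise BundleError(f"could not load fitted model from {path}: {exc}") from exc
    normalizer = None
    if (path / "normalizer.json").exists():
        normalizer = NormalizationParams.from_json(path / "normalizer.json")
    ad_model = None
    if (path / "ad_model.json").exists():
        ad_model = ADModel.from_json(path / "ad_model.json")
    return TrainedModel(
        spec=ModelSpec(
            manifest["algorithm"], dict(manifest["hyperparameters"]), manifest["seed"]
        ),
        feature_names=tuple(manifest["feature_names"]),
        estimator=estimator,
        n_training=manifest["n_training"],
        class_balance=manifest["class_balance"],
        created=manifest["created"],
        normalizer=normalizer,
        ad_model=ad_model,
    )
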