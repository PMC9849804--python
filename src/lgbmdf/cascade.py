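"""The cascade-forest meta-learner.

Each layer holds a group of estimators (by default three GOSS-boosted tree
classifiers and three extremely randomized tree ensembles). During
training, every estimator produces an out-of-fold class-probability vector
for each training instance via stratified k-fold cross-validation: an
instance is scored only by the one fold model that excluded it, so the
stacked features leak no label information. The layer's class vectors are
concatenated with the original features to form the next layer's input.
Layers are grown until the cascade's accuracy on a held-out validation
split stops improving; the retained model ends at the best-scoring depth.

At inference each estimator's output is the mean of its k fold models'
probabilities, and the cascade's prediction is the mean class vector of the
final layer's estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from lgbmdf.gbdt import GBDTClassifier

__all__ = [
    "EstimatorSpec",
    "CascadeConfig",
    "CascadeLayer",
    "CascadeModel",
    "PRESETS",
    "preset_specs",
    "build_estimator",
    "oof_class_vectors",
    "augment_features",
    "fit_cascade",
    "predict_cascade",
    "save_cascade",
    "load_cascade",
]

_KINDS = ("goss_gbdt", "extra_trees", "random_forest")

# Grid-searched per-estimator operating points used throughout.
_DEFAULTS = {
    "goss_gbdt": {"n_estimators": 400, "max_depth": 11, "num_leaves": 200},
    "extra_trees": {"n_estimators": 500},
    "random_forest": {"n_estimators": 400},
}


@dataclass(frozen=True)
class EstimatorSpec:
    """Kind plus hyperparameter overrides for one cascade estimator."""

    kind: str
    hyperparameters: tuple = ()  # tuple of (name, value) pairs; hashable

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown estimator kind {self.kind!r}; expected one of {_KINDS}")

    @classmethod
    def make(cls, kind: str, **hyperparameters) -> "EstimatorSpec":
        return cls(kind=kind, hyperparameters=tuple(sorted(hyperparameters.items())))

    def params(self) -> dict:
        p = dict(_DEFAULTS[self.kind])
        p.update(dict(self.hyperparameters))
        return p


def preset_specs(name: str, overrides: Optional[dict] = None) -> list[EstimatorSpec]:
    """Named estimator-group presets; ``overrides`` maps kind -> param dict."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(PRESETS)}")
    overrides = overrides or {}
    specs = []
    for kind in PRESETS[name]:
        params = dict(overrides.get(kind, {}))
        specs.append(EstimatorSpec.make(kind, **params))
    return specs


PRESETS: dict[str, list[str]] = {
    "3LGB-3ET": ["goss_gbdt"] * 3 + ["extra_trees"] * 3,
    "2LGB-2RF-2ET": ["goss_gbdt"] * 2 + ["random_forest"] * 2 + ["extra_trees"] * 2,
    "3LGB-3RF": ["goss_gbdt"] * 3 + ["random_forest"] * 3,
}


def build_estimator(spec: EstimatorSpec, seed: int):
    params = spec.params()
    if spec.kind == "goss_gbdt":
        return GBDTClassifier(seed=seed, **params)
    if spec.kind == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    return RandomForestClassifier(random_state=seed, n_jobs=1, **params)


def _derive_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence(entropy=master, spawn_key=key).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# out-of-fold class vectors
# ---------------------------------------------------------------------------


def _stratified_folds(y: np.ndarray, k: int, seed: int):
    """Stratified folds, redrawn with the next seed if a training side lacks a class."""
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros_like(y), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return folds
    raise ValueError("could not construct stratified folds containing both classes")


def oof_class_vectors(
    spec: EstimatorSpec,
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    seed: int,
    folds: Optional[list] = None,
):
    """Out-of-fold class vectors plus the k retained fold models.

    Each instance's vector comes from the single fold model that did not
    see it during training; at inference the k models' probabilities are
    averaged.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(np.int64)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(y)) != 2:
        raise ValueError("y must contain both classes")
    if folds is None:
        folds = _stratified_folds(y, k, seed)
    oof = np.zeros((X.shape[0], 2), dtype=np.float64)
    models = []
    for fold_idx, (train_idx, test_idx) in enumerate(folds):
        est = build_estimator(spec, seed=_derive_seed(seed, fold_idx))
        est.fit(X[train_idx], y[train_idx])
        oof[test_idx] = est.predict_proba(X[test_idx])
        models.append(est)
    return oof, models


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------


@dataclass
class CascadeConfig:
    """Layer-growth settings.

    Growth stops once validation accuracy fails to improve on the best
    layer by at least ``tolerance`` for ``patience`` consecutive layers, or
    at ``max_layers``; the retained cascade ends at the best-scoring layer.
    """

    k_folds: int = 5
    max_layers: int = 10
    tolerance: float = 1e-4
    patience: int = 1
    validation_fraction: float = 0.2
    threshold: float = 0.5
    seed: int = 0


@dataclass
class CascadeLayer:
    fitted_estimators: list  # per spec: list of k fold models
    specs: list
    oof_class_vectors: np.ndarray  # (n_train, 2 * n_estimators)
    validation_score: float = float("nan")


@dataclass
class CascadeModel:
    layers: list
    original_feature_dim: int
    stop_record: dict
    k_folds: int
    config: CascadeConfig


def augment_features(X_original: np.ndarray, class_vectors: np.ndarray | CascadeLayer) -> np.ndarray:
    """Concatenate original features with a layer's per-estimator class vectors.

    Output width is ``D + 2 * n_estimators``; the original features occupy
    the leading columns, followed by (p0, p1) blocks in estimator order.
    """
    X_original = np.asarray(X_original, dtype=np.float64)
    cv = class_vectors.oof_class_vectors if isinstance(class_vectors, CascadeLayer) else np.asarray(class_vectors)
    if cv.size == 0:
        return X_original.copy()
    if cv.shape[0] != X_original.shape[0]:
        raise ValueError("row-count mismatch between features and class vectors")
    return np.hstack([X_original, cv])


def _layer_predict(layer: CascadeLayer, X: np.ndarray) -> np.ndarray:
    """Per-estimator class vectors on new data: mean over the k fold models."""
    blocks = []
    for fold_models in layer.fitted_estimators:
        probs = np.mean([m.predict_proba(X) for m in fold_models], axis=0)
        blocks.append(probs)
    return np.hstack(blocks)


def _propagate(layers: Sequence[CascadeLayer], X_original: np.ndarray) -> np.ndarray:
    """Run data through the cascade; final (n, 2) class-probability matrix."""
    X_cur = X_original
    layer_cv = None
    for layer in layers:
        layer_cv = _layer_predict(layer, X_cur)
        X_cur = augment_features(X_original, layer_cv)
    n_est = layer_cv.shape[1] // 2
    return layer_cv.reshape(X_original.shape[0], n_est, 2).mean(axis=1)


def fit_cascade(
    X: np.ndarray,
    y: np.ndarray,
    specs: list[EstimatorSpec],
    k: int = 5,
    config: Optional[CascadeConfig] = None,
) -> CascadeModel:
    """Grow an early-stopped cascade.

    A stratified validation split (``validation_fraction``) is held out
    before any layer is trained; each new layer is scored by the accuracy
    of the cascade-so-far on that split at the configured threshold.
    """
    config = config or CascadeConfig(k_folds=k)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(np.int64)
    if len(np.unique(y)) != 2:
        raise ValueError("y must contain both classes")
    if not specs:
        raise ValueError("need at least one estimator spec")

    X_train, X_val, y_train, y_val = train_test_split(
        X,
        y,
        test_size=config.validation_fraction,
        stratify=y,
        random_state=config.seed,
    )

    layers: list[CascadeLayer] = []
    scores: list[float] = []
    best_score = -np.inf
    bad_streak = 0
    stop_reason = "max_layers"
    X_cur = X_train
    for layer_idx in range(config.max_layers):
        oof_blocks = []
        fitted = []
        for est_idx, spec in enumerate(specs):
            seed = _derive_seed(config.seed, layer_idx, est_idx)
            oof, models = oof_class_vectors(spec, X_cur, y_train, k, seed)
            oof_blocks.append(oof)
            fitted.append(models)
        layer = CascadeLayer(
            fitted_estimators=fitted,
            specs=list(specs),
            oof_class_vectors=np.hstack(oof_blocks),
        )
        layers.append(layer)
        val_probs = _propagate(layers, X_val)
        val_pred = (val_probs[:, 1] >= config.threshold).astype(np.int64)
        score = float(np.mean(val_pred == y_val))
        layer.validation_score = score
        scores.append(score)
        if score > best_score + config.tolerance:
            best_score = score
            bad_streak = 0
        else:
            bad_streak += 1
            if bad_streak >= config.patience:
                stop_reason = "no_improvement"
                break
        X_cur = augment_features(X_train, layer)

    best_idx = int(np.argmax(scores))  # first maximum
    retained = layers[: best_idx + 1]
    return CascadeModel(
        layers=retained,
        original_feature_dim=X.shape[1],
        stop_record={
            "validation_scores": scores,
            "stopping_reason": stop_reason,
            "retained_layers": len(retained),
        },
        k_folds=k,
        config=config,
    )


def predict_cascade(model: CascadeModel, X_new: np.ndarray) -> np.ndarray:
    """Class-probability matrix (p0, p1) of the cascade on new pairs."""
    X_new = np.asarray(X_new, dtype=np.float64)
    if X_new.ndim != 2 or X_new.shape[1] != model.original_feature_dim:
        raise ValueError(
            f"feature-width mismatch: cascade expects {model.original_feature_dim} columns"
        )
    return _propagate(model.layers, X_new)


_ARCHIVE_FORMAT = "lgbmdf-cascade"
_ARCHIVE_VERSION = 1


def save_cascade(model: CascadeModel, path) -> None:
    """Persist a fitted cascade to a single self-describing archive."""
    joblib.dump({"format": _ARCHIVE_FORMAT, "version": _ARCHIVE_VERSION, "model": model}, path)


def load_cascade(path) -> CascadeModel:
    payload = joblib.load(path)
    if not (isinstance(payload, dict) and payload.get("format") == _ARCHIVE_FORMAT):
        raise ValueError("not a cascade archive")
    if payload.get("version") != _ARCHIVE_VERSION:
        raise ValueError(f"unsupported archive version {payload.get('version')}")
    return payload["model"]
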