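"""Experiment orchestration: configuration, cross-validated evaluation,
grid search, and estimator-combination comparison.

All runs are deterministic functions of (configuration, seed): reports are
written with repr-exact floats, sorted keys and no timestamps, so a rerun
reproduces byte-identical artifacts.
"""

from __future__ import annotations

import itertools
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from lgbmdf.cascade import (
    CascadeConfig,
    EstimatorSpec,
    PRESETS,
    build_estimator,
    fit_cascade,
    predict_cascade,
    preset_specs,
)
from lgbmdf.metrics import (
    MetricsReport,
    evaluate_run,
    pr_curve,
    roc_curve,
    write_curve,
    write_report,
)
from lgbmdf.synthdata import (
    DTIDataset,
    generate_dti,
    make_cv_splits,
    pair_feature_matrix,
    read_features,
    read_pairs,
    write_split_manifest,
)

__all__ = [
    "RunConfig",
    "GridSpec",
    "TABLE1_RANGES",
    "grid_points",
    "run_cv_experiment",
    "grid_search",
    "compare_presets",
    "load_dataset",
]

logger = logging.getLogger("lgbmdf")

# Published grid-search ranges for the three estimator families.
TABLE1_RANGES: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [100, 200, 400, 500, 600]},
    "goss_gbdt": {
        "n_estimators": [100, 200, 400, 500],
        "max_depth": [7, 8, 9, 10, 11],
        "num_leaves": [100, 200, 300, 400, 500],
    },
    "extra_trees": {"n_estimators": [100, 200, 400, 500, 600]},
}


@dataclass
class RunConfig:
    """Full description of one evaluation run.

    Exactly one of (``drug_features_path`` + ``target_features_path`` +
    ``pairs_path``) or ``generator`` may be supplied; the generator dict
    holds :func:`lgbmdf.synthdata.generate_dti` keyword arguments.
    """

    generator: Optional[dict] = None
    drug_features_path: Optional[str] = None
    target_features_path: Optional[str] = None
    pairs_path: Optional[str] = None
    preset: str = "3LGB-3ET"
    estimator_overrides: dict = field(default_factory=dict)
    k_folds: int = 5
    max_layers: int = 10
    tolerance: float = 1e-4
    patience: int = 1
    validation_fraction: float = 0.2
    threshold: float = 0.5
    seed: int = 0
    out_dir: str = "lgbmdf_run"
    overwrite: bool = False
    resample_negatives: bool = True

    def __post_init__(self) -> None:
        paths = (self.drug_features_path, self.target_features_path, self.pairs_path)
        have_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.generator is not None and some_paths:
            raise ValueError("supply either input paths or generator parameters, not both")
        if self.generator is None and not have_paths:
            if some_paths:
                raise ValueError("all three input paths are required together")
            self.generator = {}
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        for p in paths:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def cascade_config(self) -> CascadeConfig:
        return CascadeConfig(
            k_folds=self.k_folds,
            max_layers=self.max_layers,
            tolerance=self.tolerance,
            patience=self.patience,
            validation_fraction=self.validation_fraction,
            threshold=self.threshold,
            seed=self.seed,
        )

    def specs(self) -> list[EstimatorSpec]:
        return preset_specs(self.preset, self.estimator_overrides)


def load_dataset(config: RunConfig) -> tuple[DTIDataset, Optional[list]]:
    """Dataset plus (for file inputs) the labelled pair list."""
    if config.generator is not None:
        params = dict(config.generator)
        params.setdefault("seed", config.seed)
        return generate_dti(**params), None
    drug_ids, drug_feat = read_features(config.drug_features_path)
    target_ids, target_feat = read_features(config.target_features_path)
    dataset = DTIDataset(
        drug_ids=drug_ids,
        target_ids=target_ids,
        drug_features=drug_feat,
        target_features=target_feat,
        positive_pairs=[],
        seed=config.seed,
    )
    pairs = read_pairs(config.pairs_path, dataset)
    dataset.positive_pairs = [(d, t) for d, t, label in pairs if label == 1]
    dataset.__post_init__()
    return dataset, pairs


def _prepare_out_dir(out_dir: str, overwrite: bool) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(f"output directory {out} is not empty (pass overwrite to replace)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_cv_experiment(config: RunConfig) -> list[MetricsReport]:
    """The full k-fold protocol: split, fit a cascade per fold, score, report.

    Writes per-fold metric reports, the aggregate report (mean and sd), the
    fold manifests, and ROC/PR curve point dumps into ``config.out_dir``.
    On failure, partial outputs are removed.
    """
    out = _prepare_out_dir(config.out_dir, config.overwrite)
    try:
        return _run_cv_experiment_inner(config, out)
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise


def _run_cv_experiment_inner(config: RunConfig, out: Path) -> list[MetricsReport]:
    logger.info("stage=load seed=%d", config.seed)
    dataset, _ = load_dataset(config)
    splits = make_cv_splits(
        dataset, config.k_folds, seed=config.seed, resample_negatives=config.resample_negatives
    )
    write_split_manifest(out / "splits.tsv", dataset, splits)
    specs = config.specs()
    reports: list[MetricsReport] = []
    for sp in splits:
        logger.info("stage=fit fold=%d seed=%d", sp.fold_id, config.seed)
        X_train, y_train = pair_feature_matrix(dataset, sp.train_pairs)
        X_test, y_test = pair_feature_matrix(dataset, sp.test_pairs)
        cconf = config.cascade_config()
        cconf.seed = _fold_seed(config.seed, sp.fold_id)
        model = fit_cascade(X_train, y_train, specs, k=config.k_folds, config=cconf)
        scores = predict_cascade(model, X_test)[:, 1]
        report = evaluate_run(y_test, scores, threshold=config.threshold)
        reports.append(report)
        write_curve(out / f"fold{sp.fold_id}_roc.tsv", roc_curve(y_test, scores))
        write_curve(out / f"fold{sp.fold_id}_pr.tsv", pr_curve(y_test, scores))
        write_report(out / f"fold{sp.fold_id}_metrics.json", [report], fmt="json")
    write_report(out / "metrics.json", reports, fmt="json")
    write_report(out / "metrics.tsv", reports, fmt="tsv")
    logger.info("stage=done folds=%d", len(reports))
    return reports


def _fold_seed(seed: int, fold_id: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(997, fold_id)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


@dataclass
class GridSpec:
    """Exhaustive parameter grid for one estimator kind, scored by accuracy."""

    kind: str
    grid: dict  # parameter name -> list of candidate values
    scoring: str = "accuracy"

    def __post_init__(self) -> None:
        if self.scoring != "accuracy":
            raise ValueError("only accuracy scoring is supported")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid candidate lists must be non-empty")


def grid_points(grid: dict) -> list[dict]:
    """The Cartesian product of a parameter grid, in first-listed order."""
    names = list(grid)
    return [dict(zip(names, combo)) for combo in itertools.product(*(grid[n] for n in names))]


def grid_search(
    spec: GridSpec,
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    seed: int,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search by stratified k-fold mean accuracy.

    Each grid point fits the single estimator (not the full cascade) on
    every training fold; ties break toward the first-listed candidate.
    Returns (best parameters, full score table).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(np.int64)
    points = grid_points(spec.grid)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    rows = []
    for params in points:
        accs = []
        for fold_idx, (tr, te) in enumerate(folds):
            est = build_estimator(EstimatorSpec.make(spec.kind, **params), seed=seed + fold_idx)
            est.fit(X[tr], y[tr])
            accs.append(float(np.mean(est.predict(X[te]) == y[te])))
        rows.append({**params, "mean_accuracy": float(np.mean(accs))})
    table = pd.DataFrame(rows)
    best_idx = int(table["mean_accuracy"].to_numpy().argmax())  # first maximum
    best = points[best_idx]
    return best, table


# ---------------------------------------------------------------------------
# preset comparison
# ---------------------------------------------------------------------------


def compare_presets(config: RunConfig, presets: list[str]) -> pd.DataFrame:
    """Evaluate several estimator combinations on literally identical splits.

    Returns one row per preset with the mean Sn/Sp/MCC/AUC/AUPR across
    folds. Per-preset run artifacts land in ``<out_dir>/<preset>/``.
    """
    if len(presets) < 2:
        raise ValueError("need at least 2 presets to compare")
    out = _prepare_out_dir(config.out_dir, config.overwrite)
    rows = []
    for preset in presets:
        sub = RunConfig(
            **{
                **asdict(config),
                "preset": preset,
                "out_dir": str(out / preset),
                "overwrite": True,
            }
        )
        reports = run_cv_experiment(sub)
        rows.append(
            {
                "preset": preset,
                "Sn": float(np.mean([r.Sn for r in reports])),
                "Sp": float(np.mean([r.Sp for r in reports])),
                "MCC": float(np.mean([r.MCC for r in reports])),
                "AUC": float(np.mean([r.AUC for r in reports])),
                "AUPR": float(np.mean([r.AUPR for r in reports])),
            }
        )
    table = pd.DataFrame(rows).set_index("preset")
    table.to_csv(out / "comparison.tsv", sep="\t")
    return table
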