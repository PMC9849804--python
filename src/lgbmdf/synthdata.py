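"""Synthetic drug-target interaction data with learnable latent structure.

Real DTI feature pipelines embed drugs and protein targets from multiple
biological networks into dense low-dimensional vectors; interactions are
then predicted from the concatenated pair vector. This module emulates that
setting at desk scale: drugs and targets receive latent factors drawn from
a standard normal, the interaction propensity of a pair is the inner
product of its factors, and the top ``density`` fraction of all pairs is
labelled positive. Observed per-entity features are the latent factors
embedded into ``feature_dim`` dimensions through a random orthonormal map
plus Gaussian noise, so labels are learnable from features but not
trivially linearly separable.

The evaluation protocol matches the standard DTI benchmark design: all
known positives plus an equal number of negatives sampled uniformly from
the unknown pairs, k-fold cross-validated over the positives (at k = 5,
each fold trains on 80% of positives and tests on the held-out 20%, each
side paired with its own freshly drawn, disjoint negatives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DTIDataset",
    "PairSplit",
    "generate_dti",
    "make_cv_splits",
    "pair_feature_matrix",
    "write_features",
    "read_features",
    "write_pairs",
    "read_pairs",
    "write_split_manifest",
    "read_split_manifest",
]


@dataclass
class DTIDataset:
    """Per-entity feature matrices plus the labelled pair universe."""

    drug_ids: list[str]
    target_ids: list[str]
    drug_features: np.ndarray  # (n_drugs, d_drug)
    target_features: np.ndarray  # (n_targets, d_target)
    positive_pairs: list[tuple[int, int]]  # (drug_row, target_row)
    seed: int = 0

    _positive_set: set = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._positive_set = set(self.positive_pairs)
        if len(self._positive_set) != len(self.positive_pairs):
            raise ValueError("positive pairs must be unique")

    @property
    def n_drugs(self) -> int:
        return self.drug_features.shape[0]

    @property
    def n_targets(self) -> int:
        return self.target_features.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n_drugs * self.n_targets

    def is_positive(self, drug: int, target: int) -> bool:
        return (drug, target) in self._positive_set


@dataclass
class PairSplit:
    """One cross-validation fold of labelled (drug, target) pairs."""

    fold_id: int
    train_pairs: list[tuple[int, int, int]]  # (drug_row, target_row, label)
    test_pairs: list[tuple[int, int, int]]


def _orthonormal_map(rng: np.random.Generator, out_dim: int, in_dim: int) -> np.ndarray:
    """Random (out_dim, in_dim) matrix with orthonormal columns."""
    M = rng.standard_normal((out_dim, in_dim))
    Q, R = np.linalg.qr(M)
    # fix the sign ambiguity of QR so the map is a deterministic function of M
    Q = Q * np.sign(np.diag(R))[np.newaxis, :]
    return Q


def generate_dti(
    n_drugs: int = 100,
    n_targets: int = 150,
    latent_dim: int = 8,
    feature_dim: int = 32,
    density: float = 0.02,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> DTIDataset:
    """Generate a synthetic DTI dataset.

    Exactly ``ceil(density * n_drugs * n_targets)`` pairs — those of
    highest latent propensity ``U V^T`` — are positive. Identical seeds
    reproduce the dataset bitwise.
    """
    if not (0.0 < density < 0.5):
        raise ValueError("density must lie in (0, 0.5)")
    if latent_dim > feature_dim:
        raise ValueError("latent_dim must not exceed feature_dim")
    if n_drugs < 1 or n_targets < 1:
        raise ValueError("need at least one drug and one target")
    rng = np.random.default_rng(seed)
    U = rng.standard_normal((n_drugs, latent_dim))
    V = rng.standard_normal((n_targets, latent_dim))
    propensity = U @ V.T

    n_pos = math.ceil(density * n_drugs * n_targets)
    flat = np.argsort(-propensity.ravel(), kind="stable")[:n_pos]
    positives = [(int(i // n_targets), int(i % n_targets)) for i in flat]

    Qd = _orthonormal_map(rng, feature_dim, latent_dim)
    Qt = _orthonormal_map(rng, feature_dim, latent_dim)
    drug_features = U @ Qd.T + noise_sd * rng.standard_normal((n_drugs, feature_dim))
    target_features = V @ Qt.T + noise_sd * rng.standard_normal((n_targets, feature_dim))

    drug_ids = [f"D{i:04d}" for i in range(n_drugs)]
    target_ids = [f"T{i:04d}" for i in range(n_targets)]
    return DTIDataset(
        drug_ids=drug_ids,
        target_ids=target_ids,
        drug_features=drug_features,
        target_features=target_features,
        positive_pairs=positives,
        seed=seed,
    )


def make_cv_splits(
    dataset: DTIDataset,
    k: int,
    seed: int,
    resample_negatives: bool = True,
) -> list[PairSplit]:
    """Partition the positives into k folds and pair each side with negatives.

    Per fold: train = the other k-1 positive folds plus an equal number of
    negatives sampled uniformly without replacement from the unknown pairs;
    test = the held-out positives plus an equal number of fresh negatives
    disjoint from that fold's training negatives. With
    ``resample_negatives=False`` a single global negative draw is made once
    and partitioned alongside the positives, so every fold shares one
    negative universe.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n_pos = len(dataset.positive_pairs)
    if n_pos < k:
        raise ValueError("fewer positives than folds")
    n_pairs = dataset.n_pairs
    if n_pairs - n_pos < 2 * n_pos:
        raise ValueError("not enough unknown pairs to sample negatives")

    rng = np.random.default_rng(seed)
    pos = np.array(dataset.positive_pairs, dtype=np.int64)
    perm = rng.permutation(n_pos)
    fold_assignment = np.empty(n_pos, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold_assignment[chunk] = f

    pos_flat = pos[:, 0] * dataset.n_targets + pos[:, 1]
    unknown_mask = np.ones(n_pairs, dtype=bool)
    unknown_mask[pos_flat] = False
    unknown_flat = np.nonzero(unknown_mask)[0]

    def to_pairs(flat: np.ndarray, label: int) -> list[tuple[int, int, int]]:
        return [(int(i // dataset.n_targets), int(i % dataset.n_targets), label) for i in flat]

    global_negs = None
    if not resample_negatives:
        global_negs = rng.choice(unknown_flat, size=n_pos, replace=False)

    splits: list[PairSplit] = []
    for f in range(k):
        test_mask = fold_assignment == f
        train_pos = pos_flat[~test_mask]
        test_pos = pos_flat[test_mask]
        if resample_negatives:
            draw = rng.choice(unknown_flat, size=train_pos.size + test_pos.size, replace=False)
            train_neg = draw[: train_pos.size]
            test_neg = draw[train_pos.size :]
        else:
            train_neg = global_negs[~test_mask]
            test_neg = global_negs[test_mask]
        splits.append(
            PairSplit(
                fold_id=f,
                train_pairs=to_pairs(train_pos, 1) + to_pairs(train_neg, 0),
                test_pairs=to_pairs(test_pos, 1) + to_pairs(test_neg, 0),
            )
        )
    return splits


def pair_feature_matrix(
    dataset: DTIDataset,
    pairs: list[tuple[int, int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Row per pair: drug features then target features; aligned label vector."""
    if not pairs:
        raise ValueError("empty pair list")
    arr = np.asarray(pairs, dtype=np.int64)
    d, t, y = arr[:, 0], arr[:, 1], arr[:, 2]
    bad_d = (d < 0) | (d >= dataset.n_drugs)
    if bad_d.any():
        raise ValueError(f"unknown drug row index {int(d[bad_d][0])}")
    bad_t = (t < 0) | (t >= dataset.n_targets)
    if bad_t.any():
        raise ValueError(f"unknown target row index {int(t[bad_t][0])}")
    X = np.hstack([dataset.drug_features[d], dataset.target_features[t]])
    return X, y.copy()


# ---------------------------------------------------------------------------
# delimited-text readers/writers (exact round-trip via float repr)
# ---------------------------------------------------------------------------


def write_features(path, ids: list[str], features: np.ndarray, id_column: str = "id") -> None:
    # floats written via repr so reading parses back to the identical value
    header = "\t".join([id_column] + [f"f{i}" for i in range(features.shape[1])])
    lines = [header]
    for entity_id, row in zip(ids, features):
        lines.append("\t".join([entity_id] + [repr(float(v)) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_features(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ids = df.iloc[:, 0].astype(str).tolist()
    return ids, df.iloc[:, 1:].to_numpy(dtype=np.float64)


def write_pairs(path, dataset: DTIDataset, pairs: list[tuple[int, int, int]]) -> None:
    rows = [(dataset.drug_ids[d], dataset.target_ids[t], label) for d, t, label in pairs]
    pd.DataFrame(rows, columns=["drug_id", "target_id", "label"]).to_csv(path, sep="\t", index=False)


def read_pairs(path, dataset: DTIDataset) -> list[tuple[int, int, int]]:
    df = pd.read_csv(path, sep="\t")
    d_index = {d: i for i, d in enumerate(dataset.drug_ids)}
    t_index = {t: i for i, t in enumerate(dataset.target_ids)}
    out = []
    for drug, target, label in df.itertuples(index=False):
        if drug not in d_index:
            raise ValueError(f"unknown drug id {drug!r}")
        if target not in t_index:
            raise ValueError(f"unknown target id {target!r}")
        out.append((d_index[drug], t_index[target], int(label)))
    return out


def write_split_manifest(path, dataset: DTIDataset, splits: list[PairSplit]) -> None:
    rows = []
    for sp in splits:
        for role, pairs in (("train", sp.train_pairs), ("test", sp.test_pairs)):
            for d, t, label in pairs:
                rows.append((sp.fold_id, role, dataset.drug_ids[d], dataset.target_ids[t], label))
    pd.DataFrame(rows, columns=["fold", "role", "drug_id", "target_id", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_split_manifest(path, dataset: DTIDataset) -> list[PairSplit]:
    df = pd.read_csv(path, sep="\t")
    d_index = {d: i for i, d in enumerate(dataset.drug_ids)}
    t_index = {t: i for i, t in enumerate(dataset.target_ids)}
    splits: dict[int, PairSplit] = {}
    for fold, role, drug, target, label in df.itertuples(index=False):
        sp = splits.setdefault(int(fold), PairSplit(fold_id=int(fold), train_pairs=[], test_pairs=[]))
        triple = (d_index[str(drug)], t_index[str(target)], int(label))
        (sp.train_pairs if role == "train" else sp.test_pairs).append(triple)
    return [splits[f] for f in sorted(splits)]
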