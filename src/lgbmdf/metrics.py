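"""Binary-classification metrics for drug-target interaction evaluation.

Confusion-matrix summaries (sensitivity, specificity, MCC, precision,
recall) and threshold-sweep curves (ROC, PR) with trapezoidal areas. All
formulas are evaluated exactly as defined from the 2x2 confusion matrix:

    Sn = TP / (TP + FN)          Sp = TN / (TN + FP)
    Precision = TP / (TP + FP)   Recall = TP / (TP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Degenerate denominators return 0 (and an MCC with any zero factor in its
denominator is 0), keeping every metric bounded. The trapezoidal AUC of
the ROC sweep equals the Mann-Whitney concordance statistic with ties
counted one half.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Curve",
    "MetricsReport",
    "confusion",
    "sensitivity",
    "specificity",
    "mcc",
    "tpr",
    "fpr",
    "precision",
    "recall",
    "roc_curve",
    "auc",
    "pr_curve",
    "aupr",
    "evaluate_run",
    "write_report",
    "write_curve",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, arr in (("y_true", t), ("y_pred", p)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 labels")
    return ConfusionCounts(
        TP=int(np.count_nonzero((t == 1) & (p == 1))),
        FP=int(np.count_nonzero((t == 0) & (p == 1))),
        TN=int(np.count_nonzero((t == 0) & (p == 0))),
        FN=int(np.count_nonzero((t == 1) & (p == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.TP, c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.TN, c.TN + c.FP)


def mcc(c: ConfusionCounts) -> float:
    f1, f2, f3, f4 = c.TP + c.FP, c.TP + c.FN, c.TN + c.FP, c.TN + c.FN
    if min(f1, f2, f3, f4) == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(float(f1) * f2 * f3 * f4)


# The true-positive rate of the ROC sweep and the recall of the PR sweep are
# the same quantity as sensitivity; exposed under each conventional name.
tpr = sensitivity


def fpr(c: ConfusionCounts) -> float:
    return _ratio(c.FP, c.TN + c.FP)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.TP, c.TP + c.FP)


recall = sensitivity


@dataclass
class Curve:
    """An ordered threshold-sweep curve (ROC or PR)."""

    points: np.ndarray  # (m, 2) of (x, y)
    kind: str  # "ROC" | "PR"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("curve points must be an (m, 2) array")
        if self.kind not in ("ROC", "PR"):
            raise ValueError("curve kind must be 'ROC' or 'PR'")


def _sweep_counts(y_true: np.ndarray, scores: np.ndarray):
    """Cumulative TP/FP after each distinct score threshold, descending.

    All instances sharing a score move together (tie handling by distinct
    thresholds only).
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = y_true[order]
    tps = np.cumsum(t)
    fps = np.cumsum(1 - t)
    # last index of each distinct-score block
    last = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    return tps[last], fps[last]


def _check_curve_inputs(y_true, scores):
    t = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    if t.shape != s.shape or t.ndim != 1:
        raise ValueError("y_true and scores must be equal-length vectors")
    if not np.isin(t, (0, 1)).all():
        raise ValueError("y_true must contain only 0/1 labels")
    if t.min() == t.max():
        raise ValueError("curves require both classes in y_true")
    return t.astype(np.int64), s


def roc_curve(y_true: Sequence[int], scores: Sequence[float]) -> Curve:
    """ROC points (FPR, TPR) over descending distinct thresholds.

    Anchored at (0, 0) and ending at (1, 1).
    """
    t, s = _check_curve_inputs(y_true, scores)
    tps, fps = _sweep_counts(t, s)
    P = t.sum()
    N = t.size - P
    xs = np.concatenate(([0.0], fps / N))
    ys = np.concatenate(([0.0], tps / P))
    return Curve(points=np.column_stack([xs, ys]), kind="ROC")


def auc(curve: Curve) -> float:
    """Trapezoidal area under a curve sorted by x."""
    pts = curve.points
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points to integrate")
    dx = np.diff(pts[:, 0])
    ysum = pts[1:, 1] + pts[:-1, 1]
    return float(0.5 * np.sum(dx * ysum))


def pr_curve(y_true: Sequence[int], scores: Sequence[float]) -> Curve:
    """PR points (Recall, Precision) over descending distinct thresholds.

    The left endpoint is anchored at recall 0 with the precision of the
    top-scored block; no non-linear interpolation is applied.
    """
    t, s = _check_curve_inputs(y_true, scores)
    tps, fps = _sweep_counts(t, s)
    P = t.sum()
    rec = tps / P
    prec = tps / (tps + fps)
    xs = np.concatenate(([0.0], rec))
    ys = np.concatenate(([prec[0]], prec))
    return Curve(points=np.column_stack([xs, ys]), kind="PR")


def aupr(curve: Curve) -> float:
    return auc(curve)


@dataclass
class MetricsReport:
    """The seven headline metrics of one evaluation run."""

    Sn: float
    Sp: float
    MCC: float
    AUC: float
    AUPR: float
    Precision: float
    Recall: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_run(y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.5) -> MetricsReport:
    """Assemble the full report: hard labels at ``threshold``, curves from scores."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    t = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    y_pred = (s >= threshold).astype(np.int64)
    c = confusion(t, y_pred)
    return MetricsReport(
        Sn=sensitivity(c),
        Sp=specificity(c),
        MCC=mcc(c),
        AUC=auc(roc_curve(t, s)),
        AUPR=aupr(pr_curve(t, s)),
        Precision=precision(c),
        Recall=recall(c),
    )


_FIELDS = ("Sn", "Sp", "MCC", "AUC", "AUPR", "Precision", "Recall")


def write_report(path, fold_reports: Sequence[MetricsReport], fmt: str = "json") -> None:
    """Write per-fold metrics plus mean and sd across folds.

    ``fmt`` is ``"json"`` or ``"tsv"``. Output is fully deterministic
    (float repr, sorted keys, no timestamps).
    """
    rows = [r.to_dict() for r in fold_reports]
    agg = {
        "mean": {f: float(np.mean([r[f] for r in rows])) for f in _FIELDS},
        "sd": {f: float(np.std([r[f] for r in rows], ddof=1)) if len(rows) > 1 else 0.0 for f in _FIELDS},
    }
    if fmt == "json":
        payload = {"folds": rows, "aggregate": agg}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "tsv":
        lines = ["fold\t" + "\t".join(_FIELDS)]
        for i, r in enumerate(rows):
            lines.append(str(i) + "\t" + "\t".join(repr(r[f]) for f in _FIELDS))
        lines.append("mean\t" + "\t".join(repr(agg["mean"][f]) for f in _FIELDS))
        lines.append("sd\t" + "\t".join(repr(agg["sd"][f]) for f in _FIELDS))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError("fmt must be 'json' or 'tsv'")


def write_curve(path, curve: Curve) -> None:
    """Two-column delimited dump of curve points for plotting."""
    header = {"ROC": "fpr\ttpr", "PR": "recall\tprecision"}[curve.kind]
    lines = [header] + [f"{repr(float(x))}\t{repr(float(y))}" for x, y in curve.points]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
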