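"""Histogram-based gradient-boosted decision trees with GOSS.

A self-contained binary GBDT classifier built from four ingredients:

* **histogram split finding** — continuous features are discretised into at
  most ``k`` quantile bins; per-node gradient statistics are accumulated per
  bin and split thresholds are searched over bin boundaries;
* **histogram subtraction** — a sibling node's histogram is obtained as
  ``parent - child``, so only the smaller child requires a data pass;
* **leaf-wise (best-first) growth with a depth cap** — the splittable leaf
  with the largest gain is always split next, bounded by ``num_leaves`` and
  ``max_depth``;
* **gradient-based one-side sampling (GOSS)** — each boosting round trains on
  the top ``a``-fraction of instances by gradient magnitude plus a random
  ``b``-fraction of the remainder, the latter re-weighted by ``(1-a)/b``.

Split quality is the gradient variance gain

    V(d) = (1/n) * [ (sum_L g_i)^2 / n_l  +  (sum_R g_i)^2 / n_r ]

evaluated from histogram prefix sums; under GOSS the gradient sums amplify
the sampled small-gradient instances by ``(1-a)/b`` while the counts
``n_l, n_r`` stay raw. The loss is binary logistic, with per-instance
negative gradient ``g_i = y_i - p_i``; no second-order statistics are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BinnedMatrix",
    "GradientSet",
    "Histogram",
    "GossPartition",
    "SplitCandidate",
    "TreeNode",
    "GBDTConfig",
    "GBDTModel",
    "GBDTClassifier",
    "bin_features",
    "build_histogram",
    "subtract_histogram",
    "goss_partition",
    "split_variance",
    "goss_split_variance",
    "grow_tree",
    "fit_gbdt",
    "predict_proba_gbdt",
    "dump_tree",
]

# Minimum strict improvement of the split variance over the unsplit node's
# (sum g)^2 / n term required to accept a split; guards against splits driven
# purely by floating-point noise on constant-gradient nodes.
_GAIN_EPS = 1e-12


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GBDTConfig:
    """Hyperparameters of the boosted-tree classifier.

    Defaults follow the grid-searched operating point used for the cascade
    estimators: 400 boosting rounds, depth cap 11, at most 200 leaves.
    """

    n_estimators: int = 400
    learning_rate: float = 0.1
    max_depth: int = 11
    num_leaves: int = 200
    n_bins: int = 255
    min_child_samples: int = 5
    goss_enabled: bool = True
    goss_a: float = 0.2
    goss_b: float = 0.1
    efb_enabled: bool = False
    efb_max_conflict_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.num_leaves < 2:
            raise ValueError("num_leaves must be >= 2")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not (0.0 < self.goss_a <= 1.0 and 0.0 < self.goss_b <= 1.0):
            raise ValueError("goss_a and goss_b must lie in (0, 1]")
        if self.goss_a + self.goss_b > 1.0 + 1e-12:
            raise ValueError("goss_a + goss_b must be <= 1")
        if not (0.0 <= self.efb_max_conflict_rate < 1.0):
            raise ValueError("efb_max_conflict_rate must lie in [0, 1)")


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


@dataclass
class BinnedMatrix:
    """Integer-binned view of a raw feature matrix.

    ``bin_index[i, j]`` is the bin of instance ``i`` on feature ``j``;
    ``bin_edges[j]`` holds the strictly increasing raw-value thresholds for
    feature ``j`` (``len(edges) + 1`` bins). ``offsets`` locate each
    feature's bin block inside the flattened histogram layout used by the
    tree grower.
    """

    bin_index: np.ndarray
    bin_edges: list[np.ndarray]
    n_bins: np.ndarray

    offsets: np.ndarray = field(init=False)
    total_bins: int = field(init=False)
    _codes: Optional[np.ndarray] = field(init=False, default=None, repr=False)

    def __post_init__(self) -> None:
        self.offsets = np.concatenate(([0], np.cumsum(self.n_bins[:-1]))).astype(np.int64)
        self.total_bins = int(self.n_bins.sum())

    @property
    def n_instances(self) -> int:
        return self.bin_index.shape[0]

    @property
    def n_features(self) -> int:
        return self.bin_index.shape[1]

    def codes(self) -> np.ndarray:
        """Bin indices shifted into the flattened per-feature layout (cached)."""
        if self._codes is None:
            self._codes = (self.bin_index + self.offsets[np.newaxis, :]).astype(np.int64)
        return self._codes


def bin_features(raw_matrix: np.ndarray, n_bins: int) -> BinnedMatrix:
    """Discretise each feature column into at most ``n_bins`` quantile bins.

    The mapping raw value -> bin is monotone: a value lands in bin
    ``#(edges <= value)``, so lower bins hold smaller values. Constant
    columns collapse to a single bin. Non-finite entries are rejected with
    a diagnostic naming the offending (row, feature).
    """
    X = np.ascontiguousarray(raw_matrix, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-d feature matrix")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"non-finite feature value at row {r}, feature {c}")

    n, s = X.shape
    edges_list: list[np.ndarray] = []
    bins = np.empty((n, s), dtype=np.int32)
    qs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    for j in range(s):
        col = X[:, j]
        edges = np.unique(np.quantile(col, qs))
        # an edge at (or above) the column max would leave its top bin empty
        edges = edges[edges < col.max()]
        edges_list.append(edges)
        bins[:, j] = np.searchsorted(edges, col, side="right")
    n_bins_per = np.array([len(e) + 1 for e in edges_list], dtype=np.int64)
    return BinnedMatrix(bin_index=bins, bin_edges=edges_list, n_bins=n_bins_per)


def _bin_with_edges(X: np.ndarray, edges_list: Sequence[np.ndarray]) -> np.ndarray:
    """Apply stored bin edges to new data (same monotone convention)."""
    X = np.asarray(X, dtype=np.float64)
    bins = np.empty(X.shape, dtype=np.int32)
    for j, edges in enumerate(edges_list):
        bins[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return bins


# ---------------------------------------------------------------------------
# gradients and histograms
# ---------------------------------------------------------------------------


@dataclass
class GradientSet:
    """Per-instance negative gradients and their GOSS sample weights."""

    gradients: np.ndarray
    sample_weights: np.ndarray

    def __post_init__(self) -> None:
        self.gradients = np.asarray(self.gradients, dtype=np.float64)
        self.sample_weights = np.asarray(self.sample_weights, dtype=np.float64)
        if self.gradients.shape != self.sample_weights.shape:
            raise ValueError("gradients and sample_weights must align")
        if np.any(self.sample_weights <= 0):
            raise ValueError("all sample_weights must be > 0")

    @classmethod
    def unit(cls, gradients: np.ndarray) -> "GradientSet":
        g = np.asarray(gradients, dtype=np.float64)
        return cls(g, np.ones_like(g))


@dataclass
class Histogram:
    """Per-bin statistics of one feature over one node.

    ``grad_sum`` and ``sq_grad_sum`` are weighted (GOSS amplification
    applies); ``count`` is the raw number of instances per bin — the split
    variance uses raw counts on either side even under GOSS.
    """

    feature_id: int
    grad_sum: np.ndarray
    sq_grad_sum: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.grad_sum)
        if not (len(self.sq_grad_sum) == len(self.count) == k):
            raise ValueError("histogram arrays must share one length")


def build_histogram(
    binned: BinnedMatrix,
    grads: GradientSet,
    node_instances: np.ndarray,
    feature_id: int,
) -> Histogram:
    """Accumulate one feature's per-bin statistics over a node in one pass.

    An empty node yields an all-zero histogram (valid, used as the neutral
    element of subtraction).
    """
    idx = np.asarray(node_instances, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= binned.n_instances):
        raise ValueError("node_instances out of range")
    k = int(binned.n_bins[feature_id])
    b = binned.bin_index[idx, feature_id]
    wg = grads.sample_weights[idx] * grads.gradients[idx]
    gs = np.bincount(b, weights=wg, minlength=k)
    sq = np.bincount(b, weights=grads.sample_weights[idx] * grads.gradients[idx] ** 2, minlength=k)
    ct = np.bincount(b, minlength=k).astype(np.float64)
    return Histogram(feature_id=feature_id, grad_sum=gs, sq_grad_sum=sq, count=ct)


def subtract_histogram(parent: Histogram, child: Histogram) -> Histogram:
    """Sibling histogram as parent minus child (the histogram-differencing trick)."""
    if parent.feature_id != child.feature_id:
        raise ValueError("histograms refer to different features")
    if len(parent.grad_sum) != len(child.grad_sum):
        raise ValueError("histograms have different bin counts")
    return Histogram(
        feature_id=parent.feature_id,
        grad_sum=parent.grad_sum - child.grad_sum,
        sq_grad_sum=parent.sq_grad_sum - child.sq_grad_sum,
        count=parent.count - child.count,
    )


# ---------------------------------------------------------------------------
# GOSS
# ---------------------------------------------------------------------------


@dataclass
class GossPartition:
    """One-side sampling of a training round.

    ``top_set_A`` holds the ceil(a*n) instances of largest absolute
    gradient (ties broken toward lower index); ``sampled_set_B`` is a
    uniform without-replacement draw of ceil(b*|A^c|) from the complement.
    Instances in B carry the constant weight ``(1-a)/b`` wherever gradient
    sums are formed.
    """

    top_set_A: np.ndarray
    sampled_set_B: np.ndarray
    a: float
    b: float
    amplification: float


def goss_partition(grads: GradientSet | np.ndarray, a: float, b: float, seed: int) -> GossPartition:
    g = grads.gradients if isinstance(grads, GradientSet) else np.asarray(grads, dtype=np.float64)
    n = g.size
    if not (0.0 < a <= 1.0 and 0.0 < b <= 1.0):
        raise ValueError("a and b must lie in (0, 1]")
    # stable sort on -|g| => ties resolved toward the lower instance index
    order = np.argsort(-np.abs(g), kind="stable")
    n_a = max(1, math.ceil(a * n))
    n_a = min(n_a, n)
    A = order[:n_a]
    complement = order[n_a:]
    if complement.size:
        n_b = max(1, math.ceil(b * complement.size))
        rng = np.random.default_rng(seed)
        B = rng.choice(complement, size=min(n_b, complement.size), replace=False)
    else:
        B = np.empty(0, dtype=np.int64)
    return GossPartition(
        top_set_A=np.sort(A),
        sampled_set_B=np.sort(B),
        a=a,
        b=b,
        amplification=(1.0 - a) / b,
    )


# ---------------------------------------------------------------------------
# split variance (gain)
# ---------------------------------------------------------------------------


def split_variance(histogram: Histogram, threshold_bin: int) -> Optional[float]:
    """Gradient variance gain of splitting one feature at a bin boundary.

    Returns ``(1/n) * [G_l^2/n_l + G_r^2/n_r]`` with instances of bin index
    ``<= threshold_bin`` on the left, or ``None`` when either side is empty
    (no candidate).
    """
    k = len(histogram.grad_sum)
    if not (0 <= threshold_bin < k - 1):
        raise ValueError("threshold_bin must lie in [0, k-1)")
    n_l = float(histogram.count[: threshold_bin + 1].sum())
    n_r = float(histogram.count[threshold_bin + 1 :].sum())
    if n_l == 0 or n_r == 0:
        return None
    g_l = float(histogram.grad_sum[: threshold_bin + 1].sum())
    g_r = float(histogram.grad_sum[threshold_bin + 1 :].sum())
    n = n_l + n_r
    return (g_l * g_l / n_l + g_r * g_r / n_r) / n


def goss_split_variance(
    histA: Histogram,
    histB: Histogram,
    amplification: float,
    threshold_bin: int,
) -> Optional[float]:
    """Estimated variance gain on A u B with B's gradient sums amplified.

    Counts on each side are raw member counts of A u B; only gradient sums
    carry the ``(1-a)/b`` amplification. With A the whole node and B empty
    this reduces exactly to :func:`split_variance`.
    """
    if histA.feature_id != histB.feature_id or len(histA.grad_sum) != len(histB.grad_sum):
        raise ValueError("histograms must describe the same feature and bins")
    k = len(histA.grad_sum)
    if not (0 <= threshold_bin < k - 1):
        raise ValueError("threshold_bin must lie in [0, k-1)")
    sl = slice(None, threshold_bin + 1)
    sr = slice(threshold_bin + 1, None)
    n_l = float(histA.count[sl].sum() + histB.count[sl].sum())
    n_r = float(histA.count[sr].sum() + histB.count[sr].sum())
    if n_l == 0 or n_r == 0:
        return None
    g_l = float(histA.grad_sum[sl].sum() + amplification * histB.grad_sum[sl].sum())
    g_r = float(histA.grad_sum[sr].sum() + amplification * histB.grad_sum[sr].sum())
    n = n_l + n_r
    return (g_l * g_l / n_l + g_r * g_r / n_r) / n


# ---------------------------------------------------------------------------
# tree growing
# ---------------------------------------------------------------------------


@dataclass
class SplitCandidate:
    feature_id: int
    threshold: int  # bin id; instances with bin <= threshold go left
    gain: float  # the split variance V(d)
    n_left: int
    n_right: int


@dataclass
class TreeNode:
    depth: int
    split: Optional[SplitCandidate] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    leaf_value: float = 0.0
    n_instances: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def max_node_depth(self) -> int:
        if self.is_leaf:
            return self.depth
        return max(self.left.max_node_depth(), self.right.max_node_depth())


class _NodeState:
    """Bookkeeping for a frontier leaf during growth."""

    __slots__ = ("node", "instances", "hist_g", "hist_c", "best")

    def __init__(self, node, instances, hist_g, hist_c, best):
        self.node = node
        self.instances = instances
        self.hist_g = hist_g  # flattened weighted gradient sums over all features
        self.hist_c = hist_c  # flattened raw counts over all features
        self.best = best  # (gain_improvement, feature, threshold, V, n_l, n_r) or None


def _node_histograms(binned: BinnedMatrix, wg: np.ndarray, idx: np.ndarray):
    codes = binned.codes()[idx].ravel()
    s = binned.n_features
    hg = np.bincount(codes, weights=np.repeat(wg[idx], s), minlength=binned.total_bins)
    hc = np.bincount(codes, minlength=binned.total_bins).astype(np.float64)
    return hg, hc


def _best_split_flat(binned: BinnedMatrix, hist_g, hist_c, min_child: int):
    """Best (feature, threshold) over the flattened histogram layout.

    Every feature's histogram sums to the node totals, so prefix sums over
    the flattened arrays give every candidate's left-side statistics in one
    vectorised pass; ``argmax`` takes the first maximum, i.e. ties break
    toward the lower feature id, then the lower threshold.
    """
    csg = np.cumsum(hist_g)
    csc = np.cumsum(hist_c)
    offs = binned.offsets
    nb = binned.n_bins
    # cumulative totals just before each feature's block starts
    before_g = np.concatenate(([0.0], csg[offs[1:] - 1])) if len(offs) > 1 else np.array([0.0])
    before_c = np.concatenate(([0.0], csc[offs[1:] - 1])) if len(offs) > 1 else np.array([0.0])
    GL = csg - np.repeat(before_g, nb)
    nL = csc - np.repeat(before_c, nb)
    G = float(hist_g[offs[0] : offs[0] + nb[0]].sum())
    n = float(hist_c[offs[0] : offs[0] + nb[0]].sum())
    GR = G - GL
    nR = n - nL
    last_of_feature = np.zeros(binned.total_bins, dtype=bool)
    last_of_feature[offs + nb - 1] = True
    valid = (~last_of_feature) & (nL >= max(1, min_child)) & (nR >= max(1, min_child))
    if not valid.any():
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        V = (GL * GL / nL + GR * GR / nR) / n
    V = np.where(valid, V, -np.inf)
    pos = int(np.argmax(V))
    v_unsplit = (G * G / n) / n
    improvement = float(V[pos]) - v_unsplit
    if improvement <= _GAIN_EPS:
        return None
    f = int(np.searchsorted(offs, pos, side="right") - 1)
    d = int(pos - offs[f])
    return (improvement, f, d, float(V[pos]), int(nL[pos]), int(nR[pos]))


def grow_tree(
    binned: BinnedMatrix,
    grads: GradientSet,
    config: GBDTConfig,
    seed: int = 0,
    instances: Optional[np.ndarray] = None,
) -> TreeNode:
    """Grow one regression tree leaf-wise (best-first) on binned data.

    The frontier leaf with the largest split-variance gain is split until
    ``num_leaves`` is reached, the depth cap forbids further splits, or no
    leaf improves on its unsplit variance. Leaf values are the learning-rate
    scaled weighted mean gradient of the leaf's instances (predictions are
    additive in these values). ``seed`` is accepted for interface symmetry;
    growth itself is deterministic.
    """
    if instances is None:
        instances = np.arange(binned.n_instances, dtype=np.int64)
    else:
        instances = np.asarray(instances, dtype=np.int64)
    if instances.size < 2:
        raise ValueError("need at least 2 instances to grow a tree")

    wg = grads.sample_weights * grads.gradients
    w = grads.sample_weights
    lr = config.learning_rate

    def finalize(state: _NodeState) -> None:
        idx = state.instances
        state.node.leaf_value = lr * float(wg[idx].sum() / w[idx].sum())

    root = TreeNode(depth=0, n_instances=instances.size)
    hg, hc = _node_histograms(binned, wg, instances)
    frontier: list[_NodeState] = [
        _NodeState(root, instances, hg, hc, _best_split_flat(binned, hg, hc, config.min_child_samples))
    ]
    n_leaves = 1
    while n_leaves < config.num_leaves:
        # pick the splittable frontier leaf with maximal gain improvement
        best_i = -1
        best_gain = -np.inf
        for i, st in enumerate(frontier):
            if st.node.depth >= config.max_depth or st.best is None:
                continue
            if st.best[0] > best_gain:
                best_gain = st.best[0]
                best_i = i
        if best_i < 0:
            break
        st = frontier.pop(best_i)
        _, f, d, V, n_l, n_r = st.best
        st.node.split = SplitCandidate(feature_id=f, threshold=d, gain=V, n_left=n_l, n_right=n_r)
        go_left = binned.bin_index[st.instances, f] <= d
        idx_l = st.instances[go_left]
        idx_r = st.instances[~go_left]
        # build the smaller child directly; derive the sibling by subtraction
        if idx_l.size <= idx_r.size:
            hg_l, hc_l = _node_histograms(binned, wg, idx_l)
            hg_r, hc_r = st.hist_g - hg_l, st.hist_c - hc_l
        else:
            hg_r, hc_r = _node_histograms(binned, wg, idx_r)
            hg_l, hc_l = st.hist_g - hg_r, st.hist_c - hc_r
        for idx_c, hg_c, hc_c in ((idx_l, hg_l, hc_l), (idx_r, hg_r, hc_r)):
            child = TreeNode(depth=st.node.depth + 1, n_instances=idx_c.size)
            best = None
            if child.depth < config.max_depth and idx_c.size >= 2 * config.min_child_samples:
                best = _best_split_flat(binned, hg_c, hc_c, config.min_child_samples)
            frontier.append(_NodeState(child, idx_c, hg_c, hc_c, best))
        st.node.left = frontier[-2].node
        st.node.right = frontier[-1].node
        n_leaves += 1
    for st in frontier:
        finalize(st)
    return root


def _apply_tree(root: TreeNode, bin_index: np.ndarray) -> np.ndarray:
    out = np.empty(bin_index.shape[0], dtype=np.float64)

    def rec(node: TreeNode, idx: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = node.leaf_value
            return
        m = bin_index[idx, node.split.feature_id] <= node.split.threshold
        rec(node.left, idx[m])
        rec(node.right, idx[~m])

    rec(root, np.arange(bin_index.shape[0], dtype=np.int64))
    return out


# ---------------------------------------------------------------------------
# boosting
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class GBDTModel:
    """A fitted boosted-tree binary classifier."""

    trees: list[TreeNode]
    learning_rate: float
    init_score: float
    bin_edges: list[np.ndarray]
    config: GBDTConfig
    n_features_in: int
    efb_bundles: Optional[list] = None  # FeatureBundle list when EFB was applied


def fit_gbdt(X: np.ndarray, y: np.ndarray, config: GBDTConfig) -> GBDTModel:
    """Fit the boosted-tree classifier with logistic loss.

    Per round: compute negative gradients ``g_i = y_i - p_i``, optionally
    draw a GOSS partition (fresh seeded draw each round), grow one leaf-wise
    tree on the sampled instances, and add its learning-rate-scaled leaf
    values to the raw scores. Fully deterministic given ``config.seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes are inconsistent")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"y must contain both classes 0 and 1; got classes {classes.tolist()}")
    y = y.astype(np.float64)

    bundles = None
    X_fit = X
    if config.efb_enabled:
        from lgbmdf.efb import efb_bundle

        bundles, X_fit = efb_bundle(X, config.efb_max_conflict_rate)

    binned = bin_features(X_fit, config.n_bins)
    p = float(y.mean())
    init_score = math.log(p / (1.0 - p))
    scores = np.full(y.shape[0], init_score, dtype=np.float64)
    n = y.shape[0]
    trees: list[TreeNode] = []
    use_goss = config.goss_enabled and (config.goss_a + config.goss_b) < 1.0
    for round_idx in range(config.n_estimators):
        g = y - _sigmoid(scores)
        if use_goss:
            part = goss_partition(g, config.goss_a, config.goss_b, seed=_round_seed(config.seed, round_idx))
            weights = np.ones(n, dtype=np.float64)
            weights[part.sampled_set_B] = part.amplification
            idx = np.concatenate([part.top_set_A, part.sampled_set_B])
            idx.sort()
        else:
            weights = np.ones(n, dtype=np.float64)
            idx = np.arange(n, dtype=np.int64)
        tree = grow_tree(binned, GradientSet(g, weights), config, instances=idx)
        scores += _apply_tree(tree, binned.bin_index)
        trees.append(tree)
    return GBDTModel(
        trees=trees,
        learning_rate=config.learning_rate,
        init_score=init_score,
        bin_edges=binned.bin_edges,
        config=config,
        n_features_in=X.shape[1],
        efb_bundles=bundles,
    )


def _round_seed(seed: int, round_idx: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(round_idx,)).generate_state(1)[0] % (2**31))


def predict_proba_gbdt(model: GBDTModel, X: np.ndarray) -> np.ndarray:
    """Class-probability matrix ``(1-p1, p1)``, rows summing to 1."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features_in:
        raise ValueError(
            f"feature-count mismatch: model expects {model.n_features_in} features, got {X.shape[1] if X.ndim == 2 else 'non-2d'}"
        )
    if model.efb_bundles is not None:
        from lgbmdf.efb import efb_transform

        X = efb_transform(X, model.efb_bundles)
    bins = _bin_with_edges(X, model.bin_edges)
    scores = np.full(X.shape[0], model.init_score, dtype=np.float64)
    for tree in model.trees:
        scores += _apply_tree(tree, bins)
    p1 = _sigmoid(scores)
    return np.column_stack([1.0 - p1, p1])


def dump_tree(root: TreeNode) -> str:
    """Plain-text indented rendering of one tree for inspection."""
    lines: list[str] = []

    def rec(node: TreeNode, indent: int) -> None:
        pad = "  " * indent
        if node.is_leaf:
            lines.append(f"{pad}leaf value={node.leaf_value:.6g} n={node.n_instances}")
        else:
            sp = node.split
            lines.append(
                f"{pad}split feature={sp.feature_id} bin<={sp.threshold} gain={sp.gain:.6g} n={node.n_instances}"
            )
            rec(node.left, indent + 1)
            rec(node.right, indent + 1)

    rec(root, 0)
    return "\n".join(lines)


class GBDTClassifier:
    """Thin scikit-learn-style wrapper around :func:`fit_gbdt`."""

    def __init__(self, **params) -> None:
        self.params = dict(params)
        self.model_: Optional[GBDTModel] = None

    def get_params(self) -> dict:
        return dict(self.params)

    def set_params(self, **params) -> "GBDTClassifier":
        self.params.update(params)
        return self

    def fit(self, X, y) -> "GBDTClassifier":
        self.model_ = fit_gbdt(np.asarray(X), np.asarray(y), GBDTConfig(**self.params))
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        return predict_proba_gbdt(self.model_, np.asarray(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)
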