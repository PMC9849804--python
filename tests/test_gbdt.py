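"""Unit and property tests of the histogram GBDT core."""

import numpy as np
import pytest

from lgbmdf.gbdt import (
    GBDTConfig,
    GradientSet,
    bin_features,
    build_histogram,
    dump_tree,
    fit_gbdt,
    goss_partition,
    goss_split_variance,
    grow_tree,
    predict_proba_gbdt,
    split_variance,
    subtract_histogram,
)


def eq1_direct(gradients, bins, threshold):
    """Independent brute-force evaluation of the split-variance formula."""
    g = np.asarray(gradients, dtype=float)
    left = bins <= threshold
    n_l, n_r = left.sum(), (~left).sum()
    if n_l == 0 or n_r == 0:
        return None
    n = n_l + n_r
    return (g[left].sum() ** 2 / n_l + g[~left].sum() ** 2 / n_r) / n


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


class TestBinning:
    def test_two_bin_quantile_split(self):
        bm = bin_features(np.array([[1.0], [2.0], [3.0], [4.0]]), 2)
        assert bm.bin_index.ravel().tolist() == [0, 0, 1, 1]

    @pytest.mark.parametrize("k", [2, 5, 255])
    def test_constant_column_single_bin(self, k):
        bm = bin_features(np.full((3, 1), 5.0), k)
        assert bm.bin_index.ravel().tolist() == [0, 0, 0]
        assert bm.n_bins[0] == 1

    def test_bins_bounded_by_k(self, rng):
        X = rng.uniform(size=(1000, 3))
        bm = bin_features(X, 255)
        assert bm.bin_index.max() < 255

    def test_mapping_is_monotone(self, rng):
        X = rng.normal(size=(200, 1))
        bm = bin_features(X, 16)
        order = np.argsort(X[:, 0])
        assert np.all(np.diff(bm.bin_index[order, 0]) >= 0)

    def test_edges_strictly_increasing(self, rng):
        X = rng.normal(size=(100, 4))
        bm = bin_features(X, 32)
        for edges in bm.bin_edges:
            assert np.all(np.diff(edges) > 0)

    def test_nonfinite_rejected_with_location(self):
        X = np.zeros((3, 2))
        X[1, 1] = np.nan
        with pytest.raises(ValueError, match="row 1, feature 1"):
            bin_features(X, 4)


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------


class TestHistogram:
    def test_hand_summed_statistics(self):
        bm = bin_features(np.array([[1.0], [2.0], [3.0], [4.0]]), 2)
        # node covers the first three instances, binned [0, 0, 1]
        grads = GradientSet.unit([1.0, 2.0, 3.0, 9.0])
        h = build_histogram(bm, grads, np.arange(3), 0)
        assert h.grad_sum.tolist() == [3.0, 3.0]
        assert h.count.tolist() == [2.0, 1.0]

    def test_empty_node_all_zero(self, rng):
        bm = bin_features(rng.normal(size=(10, 1)), 4)
        h = build_histogram(bm, GradientSet.unit(rng.normal(size=10)), np.array([], dtype=int), 0)
        assert not h.grad_sum.any() and not h.count.any()

    def test_conservation_on_random_node(self, rng):
        X = rng.normal(size=(500, 3))
        g = rng.normal(size=500)
        bm = bin_features(X, 16)
        idx = rng.choice(500, size=300, replace=False)
        for f in range(3):
            h = build_histogram(bm, GradientSet.unit(g), idx, f)
            assert h.count.sum() == 300
            assert h.grad_sum.sum() == pytest.approx(g[idx].sum(), abs=1e-9)

    def test_subtraction_conservation(self):
        bm = bin_features(np.array([[0.0], [1.0], [2.0], [3.0], [4.0]]), 2)
        grads = GradientSet.unit(np.ones(5))
        parent = build_histogram(bm, grads, np.arange(5), 0)
        left = build_histogram(bm, grads, np.arange(2), 0)
        sib = subtract_histogram(parent, left)
        assert sib.count.sum() == 3
        zero = subtract_histogram(parent, parent)
        assert not zero.count.any() and not zero.grad_sum.any()

    def test_subtraction_equals_direct_build(self, rng):
        X = rng.normal(size=(200, 2))
        g = rng.normal(size=200)
        bm = bin_features(X, 32)
        for _ in range(20):
            idx = rng.permutation(200)
            cut = rng.integers(1, 199)
            left_idx, right_idx = idx[:cut], idx[cut:]
            for f in range(2):
                parent = build_histogram(bm, GradientSet.unit(g), idx, f)
                left = build_histogram(bm, GradientSet.unit(g), left_idx, f)
                direct = build_histogram(bm, GradientSet.unit(g), right_idx, f)
                sib = subtract_histogram(parent, left)
                np.testing.assert_array_equal(sib.count, direct.count)
                np.testing.assert_allclose(sib.grad_sum, direct.grad_sum, atol=1e-9)

    def test_mismatched_features_rejected(self, rng):
        bm = bin_features(rng.normal(size=(10, 2)), 4)
        grads = GradientSet.unit(rng.normal(size=10))
        h0 = build_histogram(bm, grads, np.arange(10), 0)
        h1 = build_histogram(bm, grads, np.arange(10), 1)
        with pytest.raises(ValueError):
            subtract_histogram(h0, h1)


# ---------------------------------------------------------------------------
# GOSS
# ---------------------------------------------------------------------------


class TestGoss:
    def test_amplification_constant(self):
        part = goss_partition(GradientSet.unit(np.arange(10.0)), a=0.2, b=0.2, seed=0)
        assert part.amplification == pytest.approx((1 - 0.2) / 0.2)
        assert part.amplification == pytest.approx(4.0)

    def test_top_set_by_magnitude(self):
        part = goss_partition(GradientSet.unit([5.0, 4.0, 3.0, 2.0, 1.0]), a=0.4, b=0.5, seed=0)
        assert set(part.top_set_A) == {0, 1}

    def test_sizes_and_disjointness(self):
        g = np.random.default_rng(3).normal(size=1000)
        part = goss_partition(GradientSet.unit(g), a=0.2, b=0.1, seed=42)
        assert len(part.top_set_A) == 200
        assert len(part.sampled_set_B) == 80
        assert not set(part.top_set_A) & set(part.sampled_set_B)

    def test_ties_break_toward_lower_index(self):
        part = goss_partition(GradientSet.unit([1.0, 1.0, 1.0, 1.0]), a=0.5, b=0.5, seed=0)
        assert set(part.top_set_A) == {0, 1}

    def test_b_never_empty_when_complement_exists(self):
        part = goss_partition(GradientSet.unit(np.arange(5.0)), a=0.2, b=0.01, seed=0)
        assert len(part.sampled_set_B) == 1

    def test_seed_determinism(self):
        g = np.random.default_rng(0).normal(size=100)
        p1 = goss_partition(GradientSet.unit(g), 0.2, 0.1, seed=7)
        p2 = goss_partition(GradientSet.unit(g), 0.2, 0.1, seed=7)
        np.testing.assert_array_equal(p1.sampled_set_B, p2.sampled_set_B)


# ---------------------------------------------------------------------------
# split variance
# ---------------------------------------------------------------------------


class TestSplitVariance:
    def test_hand_evaluated_two_instance_node(self):
        bm = bin_features(np.array([[0.0], [1.0]]), 2)
        h = build_histogram(bm, GradientSet.unit([2.0, -2.0]), np.arange(2), 0)
        assert split_variance(h, 0) == pytest.approx(4.0)

    def test_zero_gradients_give_zero(self):
        bm = bin_features(np.array([[0.0], [1.0]]), 2)
        h = build_histogram(bm, GradientSet.unit([0.0, 0.0]), np.arange(2), 0)
        assert split_variance(h, 0) == 0.0

    def test_one_sided_split_is_no_candidate(self):
        bm = bin_features(np.array([[0.0], [0.0], [1.0]]), 2)
        grads = GradientSet.unit([1.0, 1.0, 1.0])
        h = build_histogram(bm, grads, np.array([0, 1]), 0)  # bin 1 empty
        assert split_variance(h, 0) is None

    def test_matches_brute_force_all_thresholds(self, rng):
        X = rng.normal(size=(60, 1))
        g = rng.normal(size=60)
        bm = bin_features(X, 8)
        h = build_histogram(bm, GradientSet.unit(g), np.arange(60), 0)
        bins = bm.bin_index[:, 0]
        for d in range(int(bm.n_bins[0]) - 1):
            expected = eq1_direct(g, bins, d)
            got = split_variance(h, d)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-9)

    def test_goss_degenerates_to_plain_variance(self, rng):
        X = rng.normal(size=(40, 1))
        g = rng.normal(size=40)
        bm = bin_features(X, 8)
        grads = GradientSet.unit(g)
        hA = build_histogram(bm, grads, np.arange(40), 0)
        hB = build_histogram(bm, grads, np.array([], dtype=int), 0)
        for d in range(int(bm.n_bins[0]) - 1):
            v1 = split_variance(hA, d)
            v2 = goss_split_variance(hA, hB, amplification=4.0, threshold_bin=d)
            if v1 is None:
                assert v2 is None
            else:
                assert abs(v1 - v2) <= 1e-12

    def test_hand_evaluated_goss_estimate(self):
        # A = {g=3} in the low bin, B = {g=1} in the high bin, amplification 1
        bm = bin_features(np.array([[0.0], [1.0]]), 2)
        hA = build_histogram(bm, GradientSet.unit([3.0, 0.0]), np.array([0]), 0)
        hB = build_histogram(bm, GradientSet.unit([0.0, 1.0]), np.array([1]), 0)
        v = goss_split_variance(hA, hB, amplification=1.0, threshold_bin=0)
        assert v == pytest.approx((9.0 / 1 + 1.0 / 1) / 2)

    def test_goss_estimate_matches_direct_sum(self, rng):
        g = rng.normal(size=50)
        X = rng.normal(size=(50, 1))
        bm = bin_features(X, 6)
        part_A = rng.choice(50, size=10, replace=False)
        rest = np.setdiff1d(np.arange(50), part_A)
        part_B = rng.choice(rest, size=8, replace=False)
        amp = (1 - 0.2) / 0.16
        grads = GradientSet.unit(g)
        hA = build_histogram(bm, grads, part_A, 0)
        hB = build_histogram(bm, grads, part_B, 0)
        bins = bm.bin_index[:, 0]
        for d in range(int(bm.n_bins[0]) - 1):
            Al = part_A[bins[part_A] <= d]
            Ar = part_A[bins[part_A] > d]
            Bl = part_B[bins[part_B] <= d]
            Br = part_B[bins[part_B] > d]
            n_l = len(Al) + len(Bl)
            n_r = len(Ar) + len(Br)
            got = goss_split_variance(hA, hB, amp, d)
            if n_l == 0 or n_r == 0:
                assert got is None
                continue
            n = n_l + n_r
            expected = (
                (g[Al].sum() + amp * g[Bl].sum()) ** 2 / n_l
                + (g[Ar].sum() + amp * g[Br].sum()) ** 2 / n_r
            ) / n
            assert got == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# tree growth
# ---------------------------------------------------------------------------


def _stump_config(**kw):
    params = dict(n_estimators=1, num_leaves=2, min_child_samples=1, goss_enabled=False)
    params.update(kw)
    return GBDTConfig(**params)


class TestGrowTree:
    def test_two_leaves_pick_global_best(self, rng):
        X = rng.normal(size=(30, 3))
        g = rng.normal(size=30)
        bm = bin_features(X, 8)
        tree = grow_tree(bm, GradientSet.unit(g), _stump_config())
        assert len(tree.leaves()) == 2
        best = -np.inf
        for f in range(3):
            bins = bm.bin_index[:, f]
            for d in range(int(bm.n_bins[f]) - 1):
                v = eq1_direct(g, bins, d)
                if v is not None:
                    best = max(best, v)
        assert tree.split.gain == pytest.approx(best, abs=1e-9)

    def test_max_depth_one_gives_stump(self, rng):
        X = rng.normal(size=(50, 2))
        g = rng.normal(size=50)
        bm = bin_features(X, 8)
        tree = grow_tree(bm, GradientSet.unit(g), _stump_config(num_leaves=200, max_depth=1))
        assert tree.max_node_depth() <= 1
        assert len(tree.leaves()) <= 2

    def test_sign_separating_feature_chosen_first(self, rng):
        n = 40
        g = np.concatenate([np.ones(20), -np.ones(20)])
        X = np.column_stack([np.concatenate([np.zeros(20), np.ones(20)]), rng.normal(size=n)])
        bm = bin_features(X, 8)
        tree = grow_tree(bm, GradientSet.unit(g), _stump_config())
        assert tree.split.feature_id == 0

    def test_unsplittable_root_single_leaf(self):
        bm = bin_features(np.zeros((5, 1)), 4)  # constant feature: no candidate
        tree = grow_tree(bm, GradientSet.unit(np.ones(5)), _stump_config())
        assert tree.is_leaf

    def test_structural_caps_and_counts(self, rng):
        X = rng.normal(size=(300, 5))
        g = rng.normal(size=300)
        bm = bin_features(X, 32)
        cfg = GBDTConfig(n_estimators=1, num_leaves=8, max_depth=3, min_child_samples=1, goss_enabled=False)
        tree = grow_tree(bm, GradientSet.unit(g), cfg)
        assert len(tree.leaves()) <= 8
        assert tree.max_node_depth() <= 3

        def check_counts(node):
            if node.is_leaf:
                return
            assert node.split.n_left + node.split.n_right == node.n_instances
            check_counts(node.left)
            check_counts(node.right)

        check_counts(tree)


# ---------------------------------------------------------------------------
# boosting
# ---------------------------------------------------------------------------


class TestFitPredict:
    def test_separable_data_perfect_training_auc(self, rng):
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] > 0).astype(int)
        model = fit_gbdt(X, y, GBDTConfig(n_estimators=50, seed=0))
        p = predict_proba_gbdt(model, X)[:, 1]
        pos = p[y == 1].min()
        neg = p[y == 0].max()
        assert pos > neg  # training AUC = 1

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="both classes"):
            fit_gbdt(X, np.zeros(10, dtype=int), GBDTConfig(n_estimators=2))

    def test_same_seed_bitwise_identical(self, rng):
        X = rng.normal(size=(80, 3))
        y = (rng.uniform(size=80) < 0.5).astype(int)
        cfg = GBDTConfig(n_estimators=10, seed=21)
        p1 = predict_proba_gbdt(fit_gbdt(X, y, cfg), X)
        p2 = predict_proba_gbdt(fit_gbdt(X, y, cfg), X)
        np.testing.assert_array_equal(p1, p2)

    def test_zero_trees_equal_base_rate(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([0, 1] * 10)
        model = fit_gbdt(X, y, GBDTConfig(n_estimators=1, seed=0))
        model.trees = []
        p = predict_proba_gbdt(model, X)[:, 1]
        np.testing.assert_allclose(p, 0.5)

    def test_rows_sum_to_one(self, rng):
        X = rng.normal(size=(50, 3))
        y = (rng.uniform(size=50) < 0.4).astype(int)
        model = fit_gbdt(X, y, GBDTConfig(n_estimators=5, seed=3))
        probs = predict_proba_gbdt(model, rng.normal(size=(30, 3)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_feature_count_mismatch_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([0, 1] * 15)
        model = fit_gbdt(X, y, GBDTConfig(n_estimators=2, seed=0))
        with pytest.raises(ValueError, match="feature-count mismatch"):
            predict_proba_gbdt(model, rng.normal(size=(5, 4)))

    def test_prediction_matches_manual_traversal(self):
        X = np.array([[0.0, 10.0], [1.0, 20.0], [2.0, 30.0]])
        y = np.array([0, 0, 1])
        cfg = GBDTConfig(n_estimators=2, num_leaves=3, min_child_samples=1, goss_enabled=False, seed=0)
        model = fit_gbdt(X, y, cfg)
        from lgbmdf.gbdt import _bin_with_edges, _sigmoid

        bins = _bin_with_edges(X, model.bin_edges)
        scores = np.full(3, model.init_score)
        for tree in model.trees:
            for i in range(3):
                node = tree
                while not node.is_leaf:
                    if bins[i, node.split.feature_id] <= node.split.threshold:
                        node = node.left
                    else:
                        node = node.right
                scores[i] += node.leaf_value
        np.testing.assert_allclose(predict_proba_gbdt(model, X)[:, 1], _sigmoid(scores), atol=1e-12)

    def test_dump_tree_plain_text(self, rng):
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] > 0).astype(int)
        model = fit_gbdt(X, y, GBDTConfig(n_estimators=1, seed=0))
        text = dump_tree(model.trees[0])
        assert "split feature=" in text or "leaf value=" in text
        assert "leaf value=" in text


class TestReferenceLibrary:
    def test_generalisation_comparable_to_reference_gbdt(self, rng):
        """Held-out ranking quality tracks an independent GBDT implementation.

        No byte-match is attempted (gain and sampling details differ); the
        check is that both land in the same quality band on shared data.
        """
        import lightgbm as lgb

        from lgbmdf.metrics import auc, roc_curve

        X = rng.normal(size=(400, 8))
        logits = X[:, 0] * X[:, 1] + 0.5 * X[:, 2] + 0.3 * rng.normal(size=400)
        y = (logits > 0).astype(int)
        Xtr, Xte, ytr, yte = X[:300], X[300:], y[:300], y[300:]
        mine = fit_gbdt(Xtr, ytr, GBDTConfig(n_estimators=60, seed=0))
        auc_mine = auc(roc_curve(yte, predict_proba_gbdt(mine, Xte)[:, 1]))
        ref = lgb.LGBMClassifier(n_estimators=60, random_state=0, verbose=-1).fit(Xtr, ytr)
        auc_ref = auc(roc_curve(yte, ref.predict_proba(Xte)[:, 1]))
        assert auc_mine > 0.8
        assert abs(auc_mine - auc_ref) < 0.07


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_estimators": 0},
            {"max_depth": 0},
            {"num_leaves": 1},
            {"goss_a": 0.0},
            {"goss_a": 0.7, "goss_b": 0.6},
            {"efb_max_conflict_rate": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            GBDTConfig(**kw)
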