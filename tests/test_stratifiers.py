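"""Cut points, logical combinations, CART trees, impurities."""

import numpy as np
import pandas as pd
import pytest

from tphen import (
    CutpointModel,
    TreeConfig,
    cross_entropy_impurity,
    fit_bivariate,
    fit_cutpoint,
    fit_tree,
    gini_impurity,
)
from tphen.stratifiers import (
    IMPURITY,
    NoAdmissibleCutError,
    scan_cutpoints,
)


def brute_force_cut(values, labels, min_per_class):
    """Independent oracle: enumerate every midpoint x direction."""
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    ok = np.isfinite(v)
    v, y = v[ok], y[ok]
    u = np.unique(v)
    n = len(v)
    best = None
    for thr, gap in zip((u[:-1] + u[1:]) / 2.0, np.diff(u)):
        n_le = int((v <= thr).sum())
        if n_le < min_per_class or n - n_le < min_per_class:
            continue
        for direction in ("greater", "less_equal"):
            pred = v > thr if direction == "greater" else v <= thr
            acc = float((pred == y).mean())
            key = (acc, gap, -thr, direction == "greater")
            if best is None or key > best[0]:
                best = (key, (acc, thr, direction, gap))
    return None if best is None else best[1]


class TestImpurities:
    @pytest.mark.parametrize(
        "p,expected",
        [((1.0, 0.0), 0.0), ((0.5, 0.5), 0.5), ((0.875, 0.125), 0.21875)],
    )
    def test_gini_values(self, p, expected):
        assert gini_impurity(p) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "p,expected",
        [((1.0, 0.0), 0.0), ((0.5, 0.5), np.log(2)), ((0.25, 0.75), 0.5623351)],
    )
    def test_cross_entropy_values(self, p, expected):
        assert cross_entropy_impurity(p) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("name", ["gini", "cross_entropy"])
    def test_pure_below_mixed(self, name):
        imp = IMPURITY[name]
        assert imp((1.0, 0.0)) < imp((0.7, 0.3)) < imp((0.5, 0.5))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0.5, 0.4))


class TestFitCutpoint:
    def test_separable_example(self):
        m = fit_cutpoint(np.array([1.0, 2, 8, 9]), np.array([0, 0, 1, 1], bool), min_per_class=1)
        assert 2 < m.threshold < 8
        assert m.direction == "greater"
        assert m.train_accuracy == 1.0

    def test_constant_feature_has_no_admissible_cut(self):
        with pytest.raises(NoAdmissibleCutError):
            fit_cutpoint(np.ones(8), np.array([0, 1] * 4, bool), min_per_class=1)

    def test_label_swap_flips_direction_same_accuracy(self):
        v = np.array([1.0, 2, 8, 9])
        y = np.array([0, 0, 1, 1], bool)
        m1 = fit_cutpoint(v, y, min_per_class=1)
        m2 = fit_cutpoint(v, ~y, min_per_class=1)
        assert m1.train_accuracy == m2.train_accuracy == 1.0
        assert {m1.direction, m2.direction} == {"greater", "less_equal"}

    def test_matches_brute_force_on_200_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 31))
            v = np.round(rng.normal(size=n), int(rng.integers(0, 3)))
            y = rng.random(n) < 0.4
            m = int(rng.integers(1, 4))
            mine = scan_cutpoints(v, y, m)
            oracle = brute_force_cut(v, y, m)
            assert (mine is None) == (oracle is None)
            if mine is not None:
                assert mine[0] == pytest.approx(oracle[0], abs=1e-12)
                assert mine[1] == pytest.approx(oracle[1], abs=1e-12)
                assert mine[2] == oracle[2]

    def test_logrank_objective_prefers_survival_split(self, rng):
        n = 30
        v = np.concatenate([rng.normal(0, 0.3, 15), rng.normal(4, 0.3, 15)])
        y = v > 2
        times = np.where(v > 2, rng.exponential(40, n), rng.exponential(5, n))
        events = np.ones(n, bool)
        m = fit_cutpoint(v, y, objective="logrank_p", min_per_class=3,
                         times=times, events=events)
        assert 1 < m.threshold < 3.5
        assert m.direction == "greater"  # better-surviving arm is the responder arm
        assert m.train_logrank_p < 0.01

    def test_min_per_class_constraint_respected(self):
        v = np.array([1.0, 5, 6, 7, 8, 9])
        y = np.array([1, 0, 0, 0, 0, 0], bool)
        m = fit_cutpoint(v, y, min_per_class=2)
        pred = m.decide(v)
        assert min((pred == 1).sum(), (pred == 0).sum()) >= 2


class TestBivariate:
    def test_planted_and_rule_recovered(self, rng):
        a = rng.uniform(0, 10, 60)
        b = rng.uniform(0, 6, 60)
        y = (a > 5) & (b > 3)
        m = fit_bivariate(a, b, y, min_per_class=1)
        assert m.op == "AND"
        assert m.train_accuracy == 1.0

    def test_xor_needs_xor(self, rng):
        a = rng.uniform(0, 10, 80)
        b = rng.uniform(0, 10, 80)
        y = (a > 5) ^ (b > 5)
        only_and = fit_bivariate(a, b, y, ops_allowed=("AND",), min_per_class=1)
        with_xor = fit_bivariate(a, b, y, min_per_class=1)
        assert only_and.train_accuracy < 1.0
        assert with_xor.op == "XOR" and with_xor.train_accuracy == 1.0

    def test_full_op_search_never_below_and_only(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            a, b = r.normal(size=(2, 40))
            y = r.random(40) < 0.4
            full = fit_bivariate(a, b, y, min_per_class=2)
            and_only = fit_bivariate(a, b, y, ops_allowed=("AND",), min_per_class=2)
            assert full.train_accuracy >= and_only.train_accuracy - 1e-12


class TestTree:
    def _best_depth1(self, X, y, impurity):
        """Oracle: exhaustive single split minimising weighted impurity."""
        imp = IMPURITY[impurity]
        n = len(y)
        best = None
        for name in X.columns:
            v = X[name].to_numpy(float)
            u = np.unique(v)
            for thr in (u[:-1] + u[1:]) / 2.0:
                le = v <= thr
                nl = le.sum()
                if nl == 0 or nl == n:
                    continue

                def node_imp(yy):
                    p = yy.mean()
                    return imp((1 - p, p))

                w = (nl * node_imp(y[le]) + (n - nl) * node_imp(y[~le])) / n
                if best is None or w < best[0] - 1e-12:
                    best = (w, name, thr)
        return best

    @pytest.mark.parametrize("impurity", ["gini", "cross_entropy"])
    def test_depth1_equals_best_univariate_split(self, rng, impurity):
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(20, 5)), columns=list("abcde"))
            y = r.random(20) < 0.4
            if y.all() or not y.any():
                continue
            tree = fit_tree(X, y, TreeConfig(depth=1, s_min=2, l_min=1, impurity=impurity))
            oracle = self._best_depth1(X, y, impurity)
            if tree.root.is_leaf:
                continue  # no impurity-decreasing split existed
            w_tree = (oracle[0] if tree.root.feature == oracle[1] else None)
            # the chosen split must achieve the oracle's minimal weighted impurity
            imp = IMPURITY[impurity]
            v = X[tree.root.feature].to_numpy(float)
            le = v <= tree.root.threshold
            n = len(y)

            def node_imp(yy):
                p = yy.mean()
                return imp((1 - p, p))

            w = (le.sum() * node_imp(y[le]) + (~le).sum() * node_imp(y[~le])) / n
            assert w == pytest.approx(oracle[0], abs=1e-12)

    def test_planted_two_feature_structure_recovered(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = 80
            f1 = r.uniform(0, 10, n)
            f2 = r.uniform(0, 10, n)
            y = (f1 > 5.2) & (f2 > 3.0)
            X = pd.DataFrame({"ratio_a": f1, "ratio_b": f2,
                              "noise": r.normal(size=n)})
            tree = fit_tree(X, y, TreeConfig(depth=2, s_min=5, l_min=5))
            feats = {tree.root.feature}
            for child in (tree.root.left, tree.root.right):
                if child is not None and not child.is_leaf:
                    feats.add(child.feature)
            if feats <= {"ratio_a", "ratio_b"} and len(feats) == 2:
                hits += 1
        assert hits >= 48  # >= 95% node-feature agreement

    def test_leaf_probabilities_are_counts(self):
        # one responder shares a duplicated value with a non-responder, so the
        # left side of the best split holds 6 of 7 non-responders
        X = pd.DataFrame({"f": [0.0, 1, 2, 3, 4, 5, 3, 7, 8, 9, 10, 11, 12, 13]})
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1], dtype=bool)
        tree = fit_tree(X, y, TreeConfig(depth=1, s_min=2, l_min=1))
        leaf = tree.root.left
        assert leaf.n == 7
        assert leaf.p_mk[0] == pytest.approx(6 / 7)
        assert leaf.confidence == pytest.approx(6 / 7, abs=1e-12)

    def test_single_class_input_gives_single_leaf(self):
        X = pd.DataFrame({"f": np.arange(10.0)})
        tree = fit_tree(X, np.ones(10, bool), TreeConfig(depth=3, s_min=2, l_min=1))
        assert tree.root.is_leaf
        assert tree.root.output is True

    def test_training_accuracy_nondecreasing_in_depth(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 6)), columns=list("abcdef"))
        y = (X.a + X.b * X.c) > 0
        accs = [
            fit_tree(X, y, TreeConfig(depth=d, s_min=2, l_min=1)).train_accuracy
            for d in (1, 2, 3)
        ]
        assert accs[0] <= accs[1] + 1e-12 and accs[1] <= accs[2] + 1e-12

    def test_manual_traversal_matches_predict(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = (X.a > 0) & (X.b < 0.5)
        tree = fit_tree(X, y, TreeConfig(depth=2, s_min=4, l_min=2))
        rows = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        preds = tree.predict(rows)
        for i, (_, row) in enumerate(rows.iterrows()):
            node = tree.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            assert preds[i] == float(node.output)


class TestPredictContract:
    def test_published_cut_example(self):
        model = CutpointModel(feature="ratio:CD8:iti/CD8:stroma", direction="greater",
                              threshold=5.2)
        rows = pd.DataFrame({"ratio:CD8:iti/CD8:stroma": [5.5, 5.0]})
        assert model.predict(rows).tolist() == [1.0, 0.0]

    def test_missing_feature_value_gives_missing_prediction(self):
        model = CutpointModel(feature="f", direction="greater", threshold=0.0)
        out = model.predict(pd.DataFrame({"f": [np.nan, 1.0]}))
        assert np.isnan(out[0]) and out[1] == 1.0

    def test_unknown_feature_name_rejected(self):
        model = CutpointModel(feature="missing", direction="greater", threshold=0.0)
        with pytest.raises(KeyError):
            model.predict(pd.DataFrame({"f": [1.0]}))
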