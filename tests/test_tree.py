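"""Regression-tree growth, minbucket enforcement, pruning, and routing."""

import numpy as np
import pandas as pd
import pytest

from mpramars import DesignMatrix, best_split, cv_prune, grow
from mpramars.tree import RedundancyTree

from _oracles import exhaustive_best_split


def make_design(X: pd.DataFrame, y: np.ndarray) -> DesignMatrix:
    return DesignMatrix(X, pd.Series(y, index=X.index, name="activity"),
                        list(X.columns), [])


class TestBestSplit:
    def test_constant_response_has_no_split(self):
        rng = np.random.default_rng(0)
        X = rng.random((100, 3))
        y = np.ones(100)
        assert best_split(X, y, np.arange(100), 10) is None

    def test_too_few_rows_is_illegal(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 2))
        y = rng.random(30)
        assert best_split(X, y, np.arange(30), 16) is None

    def test_step_function_threshold_found(self):
        rng = np.random.default_rng(2)
        X = rng.random((1000, 3))
        y = (X[:, 0] > 0.5).astype(float)
        j, threshold, gain = best_split(X, y, np.arange(1000), 50)
        assert j == 0
        assert abs(threshold - 0.5) < 0.01
        assert gain > 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 200))
        p = int(rng.integers(2, 10))
        X = rng.random((n, p)).round(2)  # rounding forces ties in values
        y = rng.normal(size=n) + 2.0 * (X[:, 0] > 0.5)
        minbucket = int(rng.integers(2, max(3, n // 6)))
        got = best_split(X, y, np.arange(n), minbucket)
        expected = exhaustive_best_split(X, y, minbucket)
        if expected is None:
            assert got is None
        else:
            gain_e, j_e, thr_e = expected
            j, thr, gain = got
            assert gain == pytest.approx(gain_e, rel=1e-9)
            assert (j, thr) == (j_e, pytest.approx(thr_e))

    def test_minbucket_respected_on_both_sides(self):
        rng = np.random.default_rng(3)
        X = rng.random((60, 1))
        y = X[:, 0] * 3.0
        j, thr, _ = best_split(X, y, np.arange(60), 25)
        left = (X[:, 0] < thr).sum()
        assert 25 <= left <= 35


class TestGrow:
    def test_minbucket_exceeding_n_gives_single_root(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.random((50, 2)), columns=["a", "b"])
        tree = grow(make_design(X, rng.random(50)), minbucket=100)
        assert tree.root.is_leaf
        assert tree.n_leaves == 1

    def test_constant_response_gives_single_root(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.random((200, 2)), columns=["a", "b"])
        tree = grow(make_design(X, np.zeros(200)), minbucket=10)
        assert tree.root.is_leaf

    def test_two_cluster_signal_recovered(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.random((600, 4)), columns=list("abcd"))
        y = np.where(X["c"] > 0.6, 2.0, -2.0) + rng.normal(0, 0.2, 600)
        tree = grow(make_design(X, y), minbucket=60)
        assert tree.root.split.column == "c"
        assert abs(tree.root.split.threshold - 0.6) < 0.05

    def test_every_leaf_meets_minbucket(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.random((500, 5)), columns=list("abcde"))
        y = X["a"] * 4 + X["b"] * 2 + rng.normal(0, 0.1, 500)
        tree = grow(make_design(X, y), minbucket=40, cp=0.001)
        assert tree.n_leaves > 1
        assert all(leaf.n >= 40 for leaf in tree.leaves())

    def test_leaf_proportions_sum_to_one(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.random((400, 3)), columns=list("abc"))
        y = np.where(X["a"] > 0.5, 1.0, 0.0) + rng.normal(0, 0.1, 400)
        tree = grow(make_design(X, y), minbucket=50)
        assert sum(leaf.n for leaf in tree.leaves()) == 400

    def test_empty_design_rejected(self):
        X = pd.DataFrame({"a": []})
        with pytest.raises(ValueError):
            grow(make_design(X, np.array([])), minbucket=1)

    def test_json_round_trip(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.random((300, 2)), columns=["a", "b"])
        y = np.where(X["a"] > 0.5, 1.0, 0.0)
        tree = grow(make_design(X, y), minbucket=30)
        back = RedundancyTree.from_dict(tree.to_dict())
        assert back.n_leaves == tree.n_leaves
        np.testing.assert_array_equal(back.assign(X), tree.assign(X))


class TestCvPrune:
    def test_single_node_unchanged(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.random((50, 2)), columns=["a", "b"])
        dm = make_design(X, rng.random(50))
        tree = grow(dm, minbucket=100)
        assert cv_prune(tree, dm, 10, seed=0) is tree

    def test_pure_noise_is_usually_pruned_to_root(self):
        pruned_to_root = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.random((400, 4)), columns=list("abcd"))
            dm = make_design(X, rng.normal(size=400))
            tree = grow(dm, minbucket=20, cp=0.005)
            pruned = cv_prune(tree, dm, 10, seed=seed)
            pruned_to_root += int(pruned.root.is_leaf)
        assert pruned_to_root >= 18

    def test_strong_signal_split_retained(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.random((600, 3)), columns=list("abc"))
        y = np.where(X["b"] > 0.5, 3.0, -3.0) + rng.normal(0, 0.3, 600)
        dm = make_design(X, y)
        pruned = cv_prune(grow(dm, minbucket=60), dm, 10, seed=1)
        assert not pruned.root.is_leaf
        assert pruned.root.split.column == "b"

    def test_pruning_never_decreases_training_sse(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.random((500, 4)), columns=list("abcd"))
        y = X["a"] * 2 + rng.normal(0, 0.5, 500)
        dm = make_design(X, y)
        full = grow(dm, minbucket=30, cp=0.002)
        pruned = cv_prune(full, dm, 10, seed=2)
        assert pruned.root.subtree_sse() >= full.root.subtree_sse() - 1e-9
        assert pruned.n_leaves <= full.n_leaves

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.random((300, 3)), columns=list("abc"))
        y = np.where(X["a"] > 0.4, 1.0, 0.0) + rng.normal(0, 0.4, 300)
        dm = make_design(X, y)
        tree = grow(dm, minbucket=30, cp=0.002)
        p1 = cv_prune(tree, dm, 10, seed=5)
        p2 = cv_prune(tree, dm, 10, seed=5)
        assert p1.to_dict() == p2.to_dict()


class TestAssign:
    def build(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.random((200, 2)), columns=["a", "b"])
        y = np.where(X["a"] > 0.5, 1.0, 0.0)
        dm = make_design(X, y)
        return grow(dm, minbucket=20), X

    def test_single_node_assigns_cluster_zero(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.random((30, 2)), columns=["a", "b"])
        tree = grow(make_design(X, rng.random(30)), minbucket=100)
        assert tree.assign_row({"a": 0.2, "b": 0.9}) == 0

    def test_value_at_threshold_goes_right(self):
        tree, _ = self.build()
        thr = tree.root.split.threshold
        right_cluster = tree.root.right.cluster_id if tree.root.right.is_leaf else None
        got = tree.assign_row({"a": thr, "b": 0.0})
        if right_cluster is not None:
            assert got == right_cluster

    def test_routing_reproduces_leaf_counts(self):
        tree, X = self.build()
        assigned = tree.assign(X)
        for leaf in tree.leaves():
            assert (assigned == leaf.cluster_id).sum() == leaf.n

    def test_missing_column_raises(self):
        tree, _ = self.build()
        with pytest.raises(KeyError, match="a"):
            tree.assign_row({"b": 0.1})

    def test_report_text_and_dot_mention_split(self):
        tree, _ = self.build()
        assert "a <" in tree.report_text()
        assert "digraph" in tree.to_dot()
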