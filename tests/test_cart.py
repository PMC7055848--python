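"""Recursive partitioning against an independent brute-force oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import catcart as cc
from catcart.cart import (
    TreeParams,
    _prune_sequence,
    predict_batch,
    tree_length_stats,
)

# ---------------------------------------------------------------------------
# independent oracle: naive exhaustive split search and greedy recursion
# ---------------------------------------------------------------------------


def oracle_impurity(y, criterion):
    y = list(y)
    n = len(y)
    if criterion == "gini":
        return 1.0 - sum((y.count(c) / n) ** 2 for c in set(y))
    mean = sum(y) / n
    return sum((v - mean) ** 2 for v in y)


def oracle_risk(y, criterion):
    return len(y) * oracle_impurity(y, criterion) if criterion == "gini" else oracle_impurity(y, criterion)


def oracle_best_split(df, y, criterion, min_leaf=1):
    """Naive enumeration of every admissible split, same tie-breaks."""
    y = list(y)
    parent = oracle_risk(y, criterion)
    best = None  # (decrease, col_index, sort_key, descriptor)
    for ci, col in enumerate(df.columns):
        x = df[col].tolist()
        if pd.api.types.is_numeric_dtype(df[col]):
            for thr in sorted(
                set(
                    (a + b) / 2
                    for a, b in zip(sorted(set(x))[:-1], sorted(set(x))[1:])
                )
            ):
                left = [yy for xx, yy in zip(x, y) if xx <= thr]
                right = [yy for xx, yy in zip(x, y) if xx > thr]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                dec = parent - oracle_risk(left, criterion) - oracle_risk(right, criterion)
                cand = ("ordinal-threshold", thr, None)
                if dec > 1e-12 and (
                    best is None
                    or dec > best[0] + 1e-9 * max(1.0, abs(best[0]))
                ):
                    best = (dec, ci, cand)
        else:
            levels = sorted(set(map(str, x)))
            present = levels
            subsets = []
            for r in range(len(present)):
                for comb in combinations(present[1:], r):
                    s = (present[0],) + comb
                    if 0 < len(s) < len(present):
                        subsets.append(tuple(sorted(s, key=levels.index)))
            subsets = sorted(set(subsets), key=lambda s: tuple(levels.index(v) for v in s))
            for subset in subsets:
                left = [yy for xx, yy in zip(x, y) if str(xx) in subset]
                right = [yy for xx, yy in zip(x, y) if str(xx) not in subset]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                dec = parent - oracle_risk(left, criterion) - oracle_risk(right, criterion)
                cand = ("categorical-subset", None, subset)
                if dec > 1e-12 and (
                    best is None
                    or dec > best[0] + 1e-9 * max(1.0, abs(best[0]))
                ):
                    best = (dec, ci, cand)
    return best


def oracle_grow(df, y, criterion, params):
    """Independent greedy recursion mirroring the documented stopping rules."""
    y = np.asarray(y)
    root_risk = oracle_risk(list(y), criterion)
    threshold = params.cp * root_risk

    def build(idx):
        yy = y[idx]
        node = {"n": len(idx)}
        if criterion == "gini":
            labels = sorted(map(str, set(yy)))
            counts = {c: int((yy.astype(str) == c).sum()) for c in labels}
            node["prediction"] = max(labels, key=lambda c: (counts[c], ))
            # majority with lexicographic tie-break: pick first max count
            best_count = max(counts.values())
            node["prediction"] = [c for c in labels if counts[c] == best_count][0]
        else:
            node["prediction"] = float(np.mean(yy.astype(float)))
        if (
            len(idx) < params.min_node_size
            or oracle_risk(list(yy), criterion) <= 1e-12
        ):
            return node
        found = oracle_best_split(df.iloc[idx], yy, criterion, params.min_leaf_size)
        if found is None or found[0] < threshold - 1e-12:
            return node
        dec, ci, (kind, thr, subset) = found
        col = df.columns[ci]
        xs = df[col].iloc[idx]
        if kind == "ordinal-threshold":
            go_left = (xs.astype(float) <= thr).to_numpy()
        else:
            go_left = xs.astype(str).isin(subset).to_numpy()
        node["split"] = (col, kind, thr, subset)
        node["left"] = build(idx[go_left])
        node["right"] = build(idx[~go_left])
        return node

    return build(np.arange(len(y)))


def trees_equal(impl, oracle):
    if "split" not in oracle:
        assert impl.is_leaf, "implementation split where oracle stops"
        if isinstance(impl.prediction, str):
            assert impl.prediction == oracle["prediction"]
        else:
            assert np.isclose(impl.prediction, oracle["prediction"])
        return
    assert not impl.is_leaf, "implementation stops where oracle splits"
    col, kind, thr, subset = oracle["split"]
    assert impl.split.predictor == col
    assert impl.split.kind == kind
    if kind == "ordinal-threshold":
        assert np.isclose(impl.split.threshold, thr)
    else:
        assert tuple(sorted(impl.split.left_levels)) == tuple(sorted(subset))
    trees_equal(impl.left, oracle["left"])
    trees_equal(impl.right, oracle["right"])


def random_dataset(rng, criterion):
    n = int(rng.integers(8, 31))
    n_pred = int(rng.integers(1, 4))
    cols = {}
    for j in range(n_pred):
        if rng.random() < 0.6:
            cols[f"x{j}"] = rng.integers(0, 4, n).astype(float)
        else:
            levels = [f"L{k}" for k in range(int(rng.integers(2, 5)))]
            cols[f"x{j}"] = rng.choice(levels, n)
    df = pd.DataFrame(cols)
    if criterion == "gini":
        y = rng.choice(["a", "b", "c"], n)
    else:
        y = rng.normal(0, 1, n).round(2)
    return df, y


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


class TestImpurity:
    def test_pure_node_is_zero(self):
        assert cc.node_impurity(["a"] * 6, "gini") == 0.0
        assert cc.node_impurity([2.0] * 6, "sse") == 0.0

    def test_even_binary_split_is_half(self):
        assert np.isclose(cc.node_impurity(["a", "a", "b", "b"], "gini"), 0.5)

    def test_hand_computed_three_class_gini(self):
        assert np.isclose(
            cc.node_impurity(["a", "a", "b", "c"], "gini"), 0.625
        )

    def test_sse_matches_direct_arithmetic(self):
        y = [1.0, 2.0, 6.0]
        mean = 3.0
        assert np.isclose(
            cc.node_impurity(y, "sse"), sum((v - mean) ** 2 for v in y)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cc.node_impurity([], "gini")


class TestBestSplit:
    def test_perfect_separator_found_at_midpoint(self):
        df = pd.DataFrame({"x0": [1.0, 1.0, 2.0, 5.0, 5.0, 6.0]})
        y = ["a", "a", "a", "b", "b", "b"]
        s = cc.best_split(df, np.array(y), "gini")
        assert s.predictor == "x0" and np.isclose(s.threshold, 3.5)

    def test_constant_outcome_gives_none(self):
        df = pd.DataFrame({"x0": [1.0, 2.0, 3.0]})
        assert cc.best_split(df, np.array(["a", "a", "a"]), "gini") is None

    @pytest.mark.parametrize("criterion", ["gini", "sse"])
    def test_agrees_with_exhaustive_oracle_on_random_data(self, criterion):
        rng = np.random.default_rng(2024 if criterion == "gini" else 2025)
        for _ in range(50):
            df, y = random_dataset(rng, criterion)
            params = TreeParams(criterion=criterion, min_node_size=2)
            impl = cc.best_split(df, np.asarray(y), criterion, params)
            orac = oracle_best_split(df, y, criterion)
            if orac is None:
                assert impl is None
                continue
            dec, ci, (kind, thr, subset) = orac
            assert impl is not None
            assert impl.predictor == df.columns[ci]
            assert np.isclose(impl.decrease, dec)
            if kind == "ordinal-threshold":
                assert np.isclose(impl.threshold, thr)
            else:
                assert tuple(sorted(impl.left_levels)) == tuple(sorted(subset))


class TestGrowTree:
    def test_separable_data_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(2, 3, 30)])
        y = np.array(["a"] * 30 + ["b"] * 30)
        tree = cc.grow_tree(pd.DataFrame({"x0": x}), y, TreeParams(min_node_size=5))
        preds = predict_batch(tree, pd.DataFrame({"x0": x}))
        assert (preds == y).all()

    @pytest.mark.parametrize("criterion", ["gini", "sse"])
    def test_identical_to_independent_greedy_oracle(self, criterion):
        rng = np.random.default_rng(77 if criterion == "gini" else 78)
        params = TreeParams(criterion=criterion, min_node_size=5, cp=0.01)
        for _ in range(25):
            df, y = random_dataset(rng, criterion)
            impl = cc.grow_tree(df, np.asarray(y), params)
            orac = oracle_grow(df, y, criterion, params)
            trees_equal(impl, orac)

    def test_splits_never_increase_weighted_impurity_and_counts_partition(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "x0": rng.integers(0, 4, 300).astype(float),
                "x1": rng.integers(0, 4, 300).astype(float),
                "x2": rng.choice(["u", "v", "w"], 300),
            }
        )
        y = np.where(df.x0 + df.x1 + rng.normal(0, 1, 300) > 3, "hi", "lo")
        tree = cc.grow_tree(df, y, TreeParams())

        def audit(node):
            if node.is_leaf:
                return
            assert node.left.n + node.right.n == node.n
            w_parent = node.n * node.impurity
            w_children = (
                node.left.n * node.left.impurity + node.right.n * node.right.impurity
            )
            assert w_children <= w_parent + 1e-9
            assert node.split.decrease > 0
            audit(node.left)
            audit(node.right)

        audit(tree)

    def test_realized_decreases_respect_cp_threshold(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"x0": rng.normal(0, 1, 200)})
        y = np.where(df.x0 + rng.normal(0, 0.5, 200) > 0, "a", "b")
        params = TreeParams(cp=0.02)
        tree = cc.grow_tree(df, y, params)
        root_risk = tree.n * tree.impurity
        for node in _all_internal(tree):
            assert node.split.decrease >= params.cp * root_risk - 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cc.grow_tree(pd.DataFrame({"x0": []}), np.array([]))

    def test_root_split_agrees_with_sklearn_on_tie_free_data(self):
        """Independent library cross-check: on continuous features (almost
        surely tie-free decreases) the greedy root split must coincide."""
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(123)
        for _ in range(10):
            df = pd.DataFrame(
                {f"x{j}": rng.normal(0, 1, 80) for j in range(3)}
            )
            y = np.where(df.x1 + 0.5 * df.x0 + rng.normal(0, 0.7, 80) > 0, "a", "b")
            tree = cc.grow_tree(df, y, TreeParams(min_node_size=2, cp=0.0))
            sk = DecisionTreeClassifier(criterion="gini", random_state=0).fit(df, y)
            assert tree.split.predictor == f"x{sk.tree_.feature[0]}"
            assert np.isclose(tree.split.threshold, sk.tree_.threshold[0], atol=1e-7)


def _all_internal(tree):
    if tree.is_leaf:
        return []
    return [tree] + _all_internal(tree.left) + _all_internal(tree.right)


class TestPruning:
    def _noisy_data(self, n=300, seed=1):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "x0": rng.normal(0, 1, n),
                "x1": rng.normal(0, 1, n),
            }
        )
        y = np.where(df.x0 + rng.normal(0, 1.2, n) > 0, "a", "b")
        return df, y

    def test_infinite_cp_collapses_to_stump(self):
        df, y = self._noisy_data()
        tree = cc.grow_tree(df, y, TreeParams(cp=0.0, min_node_size=10))
        seq = _prune_sequence(tree, "gini")
        assert seq[-1][1].is_leaf

    def test_zero_alpha_keeps_tree(self):
        df, y = self._noisy_data()
        params = TreeParams(cp=0.0, min_node_size=10)
        tree = cc.grow_tree(df, y, params)
        assert len(_prune_sequence(tree, "gini")[0][1].leaves()) == len(tree.leaves())

    def test_pruned_tree_is_no_worse_than_unpruned_under_cv(self):
        df, y = self._noisy_data(seed=3)
        params = TreeParams(cp=0.0, min_node_size=10, seed=3)
        tree = cc.grow_tree(df, y, params)
        pruned, table = cc.cost_complexity_prune(tree, df, y, params)
        cv = table["cv_risk"].to_numpy()
        full_cv = cv[0]  # beta = 0 keeps the full tree in every fold
        chosen_cv = cv.min()
        se = np.sqrt(full_cv)  # rough binomial scale for the count
        assert chosen_cv <= full_cv + se
        assert len(pruned.leaves()) <= len(tree.leaves())

    def test_pruned_tree_is_nested_and_deterministic(self):
        df, y = self._noisy_data(seed=8)
        params = TreeParams(cp=0.0, min_node_size=10, seed=8)
        tree = cc.grow_tree(df, y, params)
        p1, _ = cc.cost_complexity_prune(tree, df, y, params)
        p2, _ = cc.cost_complexity_prune(tree, df, y, params)
        assert p1.to_json() == p2.to_json()


class TestPathsAndLengths:
    def _tree(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "item_1": rng.integers(0, 4, 200).astype(float),
                "item_2": rng.integers(0, 4, 200).astype(float),
                "age": rng.normal(60, 10, 200),
            }
        )
        y = np.where(df.item_1 + df.item_2 > 3, "hi", "lo")
        return df, cc.grow_tree(df, y, TreeParams(min_node_size=10))

    def test_stump_queries_nothing(self):
        df = pd.DataFrame({"x0": [1.0, 2.0]})
        tree = cc.grow_tree(df, np.array(["a", "a"]), TreeParams(min_node_size=1))
        pred, path = cc.predict_with_path(tree, {"x0": 1.0})
        assert path == set()
        stats = tree_length_stats(tree, df, n_items=5)
        assert stats["pct_decrease"] == 100.0

    def test_path_is_subset_of_tree_predictors(self):
        df, tree = self._tree()
        used = tree.predictors_used()
        for _, row in df.head(40).iterrows():
            _, path = cc.predict_with_path(tree, row)
            assert path <= used
            assert len(path) <= tree.depth() - 1

    def test_missing_value_on_path_rejected(self):
        df, tree = self._tree()
        rec = {"item_1": np.nan, "item_2": 1.0, "age": 50.0}
        with pytest.raises(ValueError):
            cc.predict_with_path(tree, rec)

    def test_length_stats_match_per_record_walks(self):
        df, tree = self._tree()
        stats = tree_length_stats(
            tree, df, n_items=2, item_predictors={"item_1", "item_2"}
        )
        walked = []
        for _, row in df.iterrows():
            _, path = cc.predict_with_path(tree, row)
            walked.append(len(path & {"item_1", "item_2"}))
        assert stats["mean_items"] == np.mean(walked)
        assert stats["min_items"] == min(walked)
        assert stats["max_items"] == max(walked)
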