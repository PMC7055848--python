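"""Classification and regression trees by greedy recursive partitioning.

Trees are grown by exhaustive split search: every ordinal/numeric predictor
is scanned over the midpoints between consecutive distinct observed values,
every categorical predictor (up to 8 levels) over all binary level subsets;
the split with the largest weighted impurity decrease wins, ties broken by
lowest predictor index and then lowest threshold / lexicographically first
level subset, so identical data always grows the identical tree.  Node
impurity is Gini (1 - sum p_c^2) for classification, the sum of squared
deviations from the node mean for regression.  Splitting stops at pure
nodes, nodes below the minimum size, or when no split improves the scaled
risk by the complexity parameter; grown trees can then be pruned by
cost-complexity (weakest-link) pruning with the penalty chosen by k-fold
cross-validation.

Predicting a record routes it root to leaf, and the set of *distinct*
predictors tested along that path is the set of questionnaire items the
tree would actually administer to that respondent — the quantity behind
the questionnaire-length reduction statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import json
import numpy as np
import pandas as pd

from .splitting import kfold_indices, stratified_kfold_indices

__all__ = [
    "TreeParams",
    "SplitSpec",
    "TreeNode",
    "node_impurity",
    "best_split",
    "grow_tree",
    "cost_complexity_prune",
    "predict_with_path",
    "tree_length_stats",
]

_EPS = 1e-12
MAX_CATEGORICAL_LEVELS = 8


@dataclass(frozen=True)
class TreeParams:
    criterion: str = "gini"  # "gini" | "sse"
    min_node_size: int = 20  # smallest node that may still be split
    min_leaf_size: int = 1
    cp: float = 0.01  # complexity parameter, scaled by the root risk
    max_depth: int | None = None
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion not in ("gini", "sse"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.min_node_size < 1 or self.min_leaf_size < 1:
            raise ValueError("node sizes must be >= 1")
        if self.cp < 0:
            raise ValueError("cp must be nonnegative")


@dataclass(frozen=True)
class SplitSpec:
    predictor: str
    predictor_index: int
    kind: str  # "ordinal-threshold" | "categorical-subset"
    threshold: float | None = None
    left_levels: tuple[str, ...] | None = None
    decrease: float = 0.0  # absolute risk decrease achieved on the node

    def goes_left(self, value) -> bool:
        if self.kind == "ordinal-threshold":
            return float(value) <= self.threshold
        return str(value) in self.left_levels


@dataclass
class TreeNode:
    """Internal node (split + children) or leaf (prediction only)."""

    n: int
    impurity: float
    prediction: object  # majority label or node mean
    class_counts: dict[str, int] | None = None  # classification only
    sse: float | None = None  # regression only
    split: SplitSpec | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + max(self.left.depth(), self.right.depth())

    def predictors_used(self) -> set[str]:
        if self.is_leaf:
            return set()
        return (
            {self.split.predictor}
            | self.left.predictors_used()
            | self.right.predictors_used()
        )

    def copy(self) -> "TreeNode":
        return TreeNode(
            n=self.n,
            impurity=self.impurity,
            prediction=self.prediction,
            class_counts=dict(self.class_counts) if self.class_counts else None,
            sse=self.sse,
            split=self.split,
            left=self.left.copy() if self.left else None,
            right=self.right.copy() if self.right else None,
        )

    def to_dict(self) -> dict:
        out: dict = {
            "n": self.n,
            "impurity": self.impurity,
            "prediction": self.prediction,
        }
        if self.class_counts is not None:
            out["class_counts"] = self.class_counts
        if self.sse is not None:
            out["sse"] = self.sse
        if not self.is_leaf:
            s = self.split
            out["split"] = {
                "predictor": s.predictor,
                "kind": s.kind,
                "threshold": s.threshold,
                "left_levels": list(s.left_levels) if s.left_levels else None,
                "decrease": s.decrease,
            }
            out["left"] = self.left.to_dict()
            out["right"] = self.right.to_dict()
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            return f"{pad}leaf n={self.n} -> {self.prediction}\n"
        s = self.split
        test = (
            f"{s.predictor} <= {s.threshold:g}"
            if s.kind == "ordinal-threshold"
            else f"{s.predictor} in {{{', '.join(s.left_levels)}}}"
        )
        return (
            f"{pad}node n={self.n} split [{test}] decrease={s.decrease:.4g}\n"
            + self.left.render(indent + 1)
            + self.right.render(indent + 1)
        )


# ---------------------------------------------------------------------------
# impurity and split search
# ---------------------------------------------------------------------------


def node_impurity(outcomes: Iterable, criterion: str) -> float:
    """Gini impurity of labels, or the sum of squared deviations."""
    if criterion == "gini":
        y = np.asarray(list(outcomes) if not isinstance(outcomes, np.ndarray) else outcomes)
        if y.size == 0:
            raise ValueError("empty outcome list")
        _, counts = np.unique(y, return_counts=True)
        p = counts / y.size
        return float(1.0 - (p**2).sum())
    if criterion == "sse":
        y = np.asarray(outcomes, dtype=float)
        if y.size == 0:
            raise ValueError("empty outcome list")
        return float(((y - y.mean()) ** 2).sum())
    raise ValueError(f"unknown criterion {criterion!r}")


def _node_risk(y_codes: np.ndarray, n_classes: int, criterion: str) -> float:
    """Risk on the splitting scale: n * gini for classification, SSE else."""
    if criterion == "gini":
        counts = np.bincount(y_codes, minlength=n_classes).astype(float)
        n = counts.sum()
        return float(n - (counts**2).sum() / n)
    y = y_codes.astype(float)
    return float(((y - y.mean()) ** 2).sum())


class _Matrix:
    """Encoded training design: numeric columns + integer-coded categoricals."""

    def __init__(self, records: pd.DataFrame):
        self.columns = list(records.columns)
        self.kinds: list[str] = []
        self.values: list[np.ndarray] = []
        self.levels: list[list[str] | None] = []
        for col in self.columns:
            s = records[col]
            if pd.api.types.is_numeric_dtype(s):
                self.kinds.append("ordinal-threshold")
                self.values.append(s.to_numpy(dtype=float))
                self.levels.append(None)
            else:
                lv = sorted(map(str, s.dropna().unique()))
                if len(lv) > MAX_CATEGORICAL_LEVELS:
                    raise ValueError(
                        f"categorical predictor {col!r} has more than "
                        f"{MAX_CATEGORICAL_LEVELS} levels"
                    )
                self.kinds.append("categorical-subset")
                codes = np.array([lv.index(str(v)) for v in s], dtype=int)
                self.values.append(codes)
                self.levels.append(lv)


def _best_ordinal_split(
    x: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    criterion: str,
    parent_risk: float,
    min_leaf: int,
) -> tuple[float, float] | None:
    """Best (threshold, decrease) for one ordinal predictor, else None."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    boundary = np.flatnonzero(xs[:-1] != xs[1:])  # split after position i
    if boundary.size == 0:
        return None
    n_left = boundary + 1
    ok = (n_left >= min_leaf) & (n - n_left >= min_leaf)
    boundary, n_left = boundary[ok], n_left[ok]
    if boundary.size == 0:
        return None
    if criterion == "gini":
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        left_counts = cum[boundary]
        right_counts = cum[-1] - left_counts
        n_right = n - n_left
        risk_l = n_left - (left_counts**2).sum(axis=1) / n_left
        risk_r = n_right - (right_counts**2).sum(axis=1) / n_right
    else:
        yf = ys.astype(float)
        cs, cs2 = np.cumsum(yf), np.cumsum(yf**2)
        sl, sl2 = cs[boundary], cs2[boundary]
        n_right = n - n_left
        sr, sr2 = cs[-1] - sl, cs2[-1] - sl2
        risk_l = sl2 - sl**2 / n_left
        risk_r = sr2 - sr**2 / n_right
    decrease = parent_risk - risk_l - risk_r
    best = int(np.argmax(decrease))  # lowest threshold wins exact ties
    # prefer the lowest threshold among near-equal maxima
    near = np.flatnonzero(decrease >= decrease[best] - 1e-9 * max(1.0, abs(decrease[best])))
    best = int(near[0])
    thr = 0.5 * (xs[boundary[best]] + xs[boundary[best] + 1])
    return float(thr), float(decrease[best])


def _best_categorical_split(
    codes: np.ndarray,
    levels: list[str],
    y: np.ndarray,
    n_classes: int,
    criterion: str,
    parent_risk: float,
    min_leaf: int,
) -> tuple[tuple[int, ...], float] | None:
    present = sorted(set(codes.tolist()))
    if len(present) < 2:
        return None
    n = len(codes)
    if criterion == "gini":
        agg = np.zeros((len(levels), n_classes))
        np.add.at(agg, (codes, y), 1.0)
    else:
        yf = y.astype(float)
        agg = np.zeros((len(levels), 3))
        np.add.at(agg[:, 0], codes, 1.0)
        np.add.at(agg[:, 1], codes, yf)
        np.add.at(agg[:, 2], codes, yf**2)
    best_subset, best_dec = None, -np.inf
    rest = [c for c in present[1:]]
    # enumerate subsets containing the first present level (each bipartition once),
    # in lexicographic order of the level-index tuple for deterministic ties
    subsets = []
    for r in range(len(rest) + 1):
        for comb in combinations(rest, r):
            subset = (present[0],) + comb
            if len(subset) < len(present):
                subsets.append(subset)
    subsets.sort()
    for subset in subsets:
        sel = np.zeros(len(levels), dtype=bool)
        sel[list(subset)] = True
        if criterion == "gini":
            lc = agg[sel].sum(axis=0)
            rc = agg[~sel].sum(axis=0)
            nl, nr = lc.sum(), rc.sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            risk_l = nl - (lc**2).sum() / nl
            risk_r = nr - (rc**2).sum() / nr
        else:
            l = agg[sel].sum(axis=0)
            r_ = agg[~sel].sum(axis=0)
            nl, nr = l[0], r_[0]
            if nl < min_leaf or nr < min_leaf:
                continue
            risk_l = l[2] - l[1] ** 2 / nl
            risk_r = r_[2] - r_[1] ** 2 / nr
        dec = parent_risk - risk_l - risk_r
        if best_subset is None or dec > best_dec + 1e-9 * max(1.0, abs(best_dec)):
            best_subset, best_dec = subset, dec
    if best_subset is None:
        return None
    return best_subset, float(best_dec)


def best_split(
    records: pd.DataFrame,
    outcomes: np.ndarray,
    criterion: str,
    params: TreeParams | None = None,
) -> SplitSpec | None:
    """Exhaustive best split of one node; None when nothing admissible."""
    params = params or TreeParams(criterion=criterion)
    matrix = _Matrix(records)
    classes = sorted(map(str, np.unique(outcomes))) if criterion == "gini" else []
    y = (
        np.array([classes.index(str(v)) for v in outcomes], dtype=int)
        if criterion == "gini"
        else np.asarray(outcomes, dtype=float)
    )
    return _best_split_encoded(matrix, y, len(classes), criterion, params, classes)


def _best_split_encoded(
    matrix: _Matrix,
    y: np.ndarray,
    n_classes: int,
    criterion: str,
    params: TreeParams,
    classes: list[str],
    row_idx: np.ndarray | None = None,
) -> SplitSpec | None:
    if row_idx is None:
        row_idx = np.arange(len(y))
    yy = y[row_idx]
    parent_risk = _node_risk(yy, n_classes, criterion)
    if parent_risk <= _EPS:
        return None
    best: SplitSpec | None = None
    for j, col in enumerate(matrix.columns):
        x = matrix.values[j][row_idx]
        if matrix.kinds[j] == "ordinal-threshold":
            found = _best_ordinal_split(
                x, yy, n_classes, criterion, parent_risk, params.min_leaf_size
            )
            if found is None:
                continue
            thr, dec = found
            cand = SplitSpec(col, j, "ordinal-threshold", threshold=thr, decrease=dec)
        else:
            found = _best_categorical_split(
                x.astype(int),
                matrix.levels[j],
                yy,
                n_classes,
                criterion,
                parent_risk,
                params.min_leaf_size,
            )
            if found is None:
                continue
            subset, dec = found
            cand = SplitSpec(
                col,
                j,
                "categorical-subset",
                left_levels=tuple(matrix.levels[j][c] for c in subset),
                decrease=dec,
            )
        if cand.decrease <= _EPS:
            continue
        if best is None or cand.decrease > best.decrease + 1e-9 * max(
            1.0, abs(best.decrease)
        ):
            best = cand
    return best


# ---------------------------------------------------------------------------
# growing
# ---------------------------------------------------------------------------


def _make_leaf_fields(
    yy: np.ndarray, n_classes: int, criterion: str, classes: list[str]
) -> dict:
    if criterion == "gini":
        counts = np.bincount(yy, minlength=n_classes)
        # majority class; exact ties go to the lexicographically first label
        pred = classes[int(np.argmax(counts))]
        return {
            "impurity": node_impurity(yy, "gini") if yy.size else 0.0,
            "prediction": pred,
            "class_counts": {c: int(k) for c, k in zip(classes, counts)},
        }
    yf = yy.astype(float)
    return {
        "impurity": node_impurity(yf, "sse"),
        "prediction": float(yf.mean()),
        "sse": float(((yf - yf.mean()) ** 2).sum()),
    }


def grow_tree(
    records: pd.DataFrame,
    outcomes,
    params: TreeParams | None = None,
) -> TreeNode:
    """Grow a full greedy tree under the stopping rules in ``params``."""
    params = params or TreeParams()
    outcomes = np.asarray(outcomes)
    if len(records) == 0 or len(records) != len(outcomes):
        raise ValueError("records and outcomes must be non-empty and aligned")
    criterion = params.criterion
    matrix = _Matrix(records)
    if criterion == "gini":
        classes = sorted(map(str, np.unique(outcomes)))
        y = np.array([classes.index(str(v)) for v in outcomes], dtype=int)
    else:
        classes = []
        y = np.asarray(outcomes, dtype=float)
    n_classes = len(classes)
    root_idx = np.arange(len(y))
    root_risk = _node_risk(y[root_idx], n_classes, criterion)
    threshold = params.cp * root_risk

    def build(row_idx: np.ndarray, depth: int) -> TreeNode:
        yy = y[row_idx]
        node = TreeNode(n=len(row_idx), **_make_leaf_fields(yy, n_classes, criterion, classes))
        if (
            len(row_idx) < params.min_node_size
            or (params.max_depth is not None and depth >= params.max_depth)
            or _node_risk(yy, n_classes, criterion) <= _EPS
        ):
            return node
        split = _best_split_encoded(
            matrix, y, n_classes, criterion, params, classes, row_idx
        )
        if split is None or split.decrease < threshold - _EPS:
            return node
        x = matrix.values[split.predictor_index][row_idx]
        if split.kind == "ordinal-threshold":
            go_left = x <= split.threshold
        else:
            subset = {matrix.levels[split.predictor_index].index(lv)
                      for lv in split.left_levels}
            go_left = np.isin(x.astype(int), list(subset))
        node.split = split
        node.left = build(row_idx[go_left], depth + 1)
        node.right = build(row_idx[~go_left], depth + 1)
        return node

    return build(root_idx, 0)


# ---------------------------------------------------------------------------
# cost-complexity pruning
# ---------------------------------------------------------------------------


def _leaf_risk(node: TreeNode, criterion: str) -> float:
    """Pruning risk: misclassification count at the node, or its SSE."""
    if criterion == "gini":
        counts = node.class_counts or {}
        total = sum(counts.values())
        return float(total - max(counts.values())) if counts else 0.0
    return float(node.sse or 0.0)


def _subtree_risk(node: TreeNode, criterion: str) -> float:
    if node.is_leaf:
        return _leaf_risk(node, criterion)
    return _subtree_risk(node.left, criterion) + _subtree_risk(node.right, criterion)


def _prune_sequence(tree: TreeNode, criterion: str) -> list[tuple[float, TreeNode]]:
    """Weakest-link sequence [(alpha_0=0, T_0), (alpha_1, T_1), ...] of
    nested subtrees ending in the root stump."""
    seq: list[tuple[float, TreeNode]] = [(0.0, tree.copy())]
    current = tree.copy()
    while not current.is_leaf:
        # find the minimal link strength g(t) over internal nodes
        links: list[tuple[float, TreeNode]] = []

        def visit(node: TreeNode) -> None:
            if node.is_leaf:
                return
            r_node = _leaf_risk(node, criterion)
            r_sub = _subtree_risk(node, criterion)
            n_leaves = len(node.leaves())
            g = (r_node - r_sub) / max(n_leaves - 1, 1)
            links.append((g, node))
            visit(node.left)
            visit(node.right)

        visit(current)
        g_min = min(g for g, _ in links)
        for g, node in links:
            if g <= g_min + _EPS:
                node.split = None
                node.left = None
                node.right = None
        seq.append((max(g_min, 0.0), current.copy()))
    return seq


def _subtree_for_alpha(
    seq: list[tuple[float, TreeNode]], alpha: float
) -> TreeNode:
    chosen = seq[0][1]
    for a, t in seq:
        if a <= alpha + _EPS:
            chosen = t
    return chosen


def predict_batch(tree: TreeNode, records: pd.DataFrame) -> np.ndarray:
    """Vectorized routing of every record to its leaf prediction."""
    n = len(records)
    out = np.empty(n, dtype=object)
    cols = {c: records[c].to_numpy() for c in records.columns}

    def route(node: TreeNode, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        if node.is_leaf:
            out[idx] = node.prediction
            return
        s = node.split
        vals = cols[s.predictor][idx]
        if s.kind == "ordinal-threshold":
            go_left = vals.astype(float) <= s.threshold
        else:
            go_left = np.isin(vals.astype(str), list(s.left_levels))
        route(node.left, idx[go_left])
        route(node.right, idx[~go_left])

    route(tree, np.arange(n))
    return out


def _prediction_error(
    tree: TreeNode, records: pd.DataFrame, outcomes: np.ndarray, criterion: str
) -> float:
    preds = predict_batch(tree, records)
    if criterion == "gini":
        return float((preds.astype(str) != outcomes.astype(str)).sum())
    return float(((preds.astype(float) - outcomes.astype(float)) ** 2).sum())


def cost_complexity_prune(
    tree: TreeNode,
    records: pd.DataFrame,
    outcomes,
    params: TreeParams | None = None,
) -> tuple[TreeNode, pd.DataFrame]:
    """Weakest-link pruning with the penalty picked by k-fold CV.

    The candidate penalties are the geometric means of consecutive alphas
    in the full tree's pruning sequence.  Folds are stratified by class for
    classification.  The subtree whose penalty minimises the cross-
    validated misclassification count (or SSE) is returned, ties resolved
    toward the smaller tree.
    """
    params = params or TreeParams()
    outcomes = np.asarray(outcomes)
    criterion = params.criterion
    seq = _prune_sequence(tree, criterion)
    alphas = [a for a, _ in seq]
    if len(alphas) == 1:
        table = pd.DataFrame(
            {"alpha": alphas, "n_leaves": [len(seq[0][1].leaves())],
             "train_risk": [_subtree_risk(seq[0][1], criterion)],
             "cv_risk": [np.nan]}
        )
        return seq[0][1].copy(), table

    # candidate penalties: geometric means between consecutive alphas
    betas = [0.0]
    for a0, a1 in zip(alphas[:-1], alphas[1:]):
        betas.append(float(np.sqrt(max(a0, _EPS) * max(a1, _EPS))))
    betas[-1] = alphas[-1] * 1.0000001  # ensure the stump is reachable

    n = len(outcomes)
    k = min(params.cv_folds, n)
    if criterion == "gini":
        folds = stratified_kfold_indices(outcomes.astype(str), k, params.seed)
    else:
        folds = kfold_indices(n, k, params.seed)

    cv_risk = np.zeros(len(betas))
    for fold in range(k):
        train = folds != fold
        test = ~train
        if not test.any() or not train.any():
            continue
        fold_tree = grow_tree(records[train], outcomes[train], params)
        fold_seq = _prune_sequence(fold_tree, criterion)
        for i, beta in enumerate(betas):
            sub = _subtree_for_alpha(fold_seq, beta)
            cv_risk[i] += _prediction_error(
                sub, records[test], outcomes[test], criterion
            )

    # ties toward the larger penalty (the smaller tree)
    tied = np.flatnonzero(cv_risk <= cv_risk.min() + _EPS)
    best_i = int(tied[-1])
    pruned = _subtree_for_alpha(seq, betas[best_i]).copy()
    table = pd.DataFrame(
        {
            "alpha": alphas,
            "beta": betas,
            "n_leaves": [len(t.leaves()) for _, t in seq],
            "train_risk": [_subtree_risk(t, criterion) for _, t in seq],
            "cv_risk": cv_risk,
        }
    )
    return pruned, table


# ---------------------------------------------------------------------------
# prediction and path accounting
# ---------------------------------------------------------------------------


def predict_with_path(tree: TreeNode, record) -> tuple[object, set[str]]:
    """Route a record to its leaf; also report distinct predictors queried."""
    node = tree
    queried: set[str] = set()
    while not node.is_leaf:
        value = record[node.split.predictor]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(
                f"missing value for predictor {node.split.predictor!r} on the path"
            )
        queried.add(node.split.predictor)
        node = node.left if node.split.goes_left(value) else node.right
    return node.prediction, queried


def tree_length_stats(
    tree: TreeNode,
    records: pd.DataFrame,
    n_items: int,
    item_predictors: set[str] | None = None,
) -> dict[str, float]:
    """Distinct questionnaire items queried per routed record.

    Demographic predictors are excluded from the count when
    ``item_predictors`` is given: only actual questionnaire items shorten
    or lengthen the administered questionnaire.
    """
    n = len(records)
    counts = np.zeros(n, dtype=float)
    cols = {c: records[c].to_numpy() for c in records.columns}

    def route(node: TreeNode, idx: np.ndarray, path: set[str]) -> None:
        if idx.size == 0:
            return
        if node.is_leaf:
            queried = path if item_predictors is None else path & item_predictors
            counts[idx] = len(queried)
            return
        s = node.split
        vals = cols[s.predictor][idx]
        if s.kind == "ordinal-threshold":
            go_left = vals.astype(float) <= s.threshold
        else:
            go_left = np.isin(vals.astype(str), list(s.left_levels))
        route(node.left, idx[go_left], path | {s.predictor})
        route(node.right, idx[~go_left], path | {s.predictor})

    route(tree, np.arange(n), set())
    arr = counts
    mean = float(arr.mean())
    return {
        "min_items": float(arr.min()),
        "mean_items": mean,
        "max_items": float(arr.max()),
        "pct_decrease": 100.0 * (1.0 - mean / n_items),
    }
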