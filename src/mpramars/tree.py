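"""CART-style regression tree with a hard minimum leaf size and CV pruning.

Splitting follows the classical variance-reduction (ANOVA) criterion: the
chosen split maximises the decrease in within-node sum of squared errors,
subject to both children holding at least ``ceil(minbucket)`` rows.  A split
is only kept while its gain is at least ``cp`` times the root SSE, and the
grown tree is trimmed back by cost-complexity pruning with the subtree chosen
by seeded k-fold cross-validation.  Rows with feature value < threshold go
left; values equal to the threshold go right.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix


@dataclass(frozen=True)
class SplitRule:
    column: str
    threshold: float


@dataclass
class TreeNode:
    n: int
    mean: float
    sse: float
    split: SplitRule | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    cluster_id: int | None = None  # set on leaves after growth

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def subtree_sse(self) -> float:
        return sum(leaf.sse for leaf in self.leaves())


@dataclass
class RedundancyTree:
    root: TreeNode
    minbucket: int
    cp: float
    columns: list[str]
    n: int

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def assign_row(self, row) -> int:
        node = self.root
        while not node.is_leaf:
            try:
                value = row[node.split.column]
            except (KeyError, IndexError):
                raise KeyError(f"row is missing split column {node.split.column!r}") from None
            node = node.left if value < node.split.threshold else node.right
        return node.cluster_id

    def assign(self, X: pd.DataFrame) -> np.ndarray:
        """Vectorised descent of every row of a feature frame."""
        out = np.empty(len(X), dtype=int)
        idx = np.arange(len(X))

        def descend(node: TreeNode, rows: np.ndarray) -> None:
            if node.is_leaf:
                out[rows] = node.cluster_id
                return
            if node.split.column not in X.columns:
                raise KeyError(f"rows are missing split column {node.split.column!r}")
            col = X[node.split.column].to_numpy(dtype=float)[rows]
            go_left = col < node.split.threshold
            descend(node.left, rows[go_left])
            descend(node.right, rows[~go_left])

        descend(self.root, idx)
        return out

    def predict_mean(self, X: pd.DataFrame) -> np.ndarray:
        means = {leaf.cluster_id: leaf.mean for leaf in self.leaves()}
        return np.array([means[c] for c in self.assign(X)])

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        def node_dict(node: TreeNode) -> dict:
            d = {"n": node.n, "mean": node.mean, "sse": node.sse}
            if node.is_leaf:
                d["cluster_id"] = node.cluster_id
            else:
                d["column"] = node.split.column
                d["threshold"] = node.split.threshold
                d["left"] = node_dict(node.left)
                d["right"] = node_dict(node.right)
            return d

        return {
            "root": node_dict(self.root),
            "minbucket": self.minbucket,
            "cp": self.cp,
            "columns": self.columns,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RedundancyTree":
        def build(d: dict) -> TreeNode:
            if "column" in d:
                return TreeNode(
                    d["n"], d["mean"], d["sse"],
                    split=SplitRule(d["column"], d["threshold"]),
                    left=build(d["left"]), right=build(d["right"]),
                )
            return TreeNode(d["n"], d["mean"], d["sse"], cluster_id=d["cluster_id"])

        return cls(build(payload["root"]), payload["minbucket"], payload["cp"],
                   list(payload["columns"]), payload["n"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def report_text(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: int) -> None:
            pad = "  " * indent
            pct = 100.0 * node.n / self.n
            if node.is_leaf:
                lines.append(
                    f"{pad}leaf {node.cluster_id}: mean={node.mean:.3f} "
                    f"n={node.n} ({pct:.1f}%)"
                )
            else:
                lines.append(
                    f"{pad}{node.split.column} < {node.split.threshold:.4g} "
                    f"[mean={node.mean:.3f} n={node.n} ({pct:.1f}%)]"
                )
                walk(node.left, indent + 1)
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)

    def to_dot(self) -> str:
        lines = ["digraph tree {", "  node [shape=box];"]
        counter = [0]

        def walk(node: TreeNode) -> int:
            me = counter[0]
            counter[0] += 1
            pct = 100.0 * node.n / self.n
            if node.is_leaf:
                lines.append(
                    f'  n{me} [label="cluster {node.cluster_id}\\n'
                    f'mean {node.mean:.3f}\\n{pct:.1f}%"];'
                )
            else:
                lines.append(
                    f'  n{me} [label="{node.split.column} < {node.split.threshold:.4g}"];'
                )
                l, r = walk(node.left), walk(node.right)
                lines.append(f"  n{me} -> n{l} [label=yes];")
                lines.append(f"  n{me} -> n{r} [label=no];")
            return me

        walk(self.root)
        lines.append("}")
        return "\n".join(lines)


def _node_sse(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if y.size else 0.0


def best_split(
    X: np.ndarray, y: np.ndarray, rows: np.ndarray, minbucket: int
) -> tuple[int, float, float] | None:
    """Best (column index, threshold, SSE gain) under the leaf-size constraint.

    Candidate thresholds are midpoints between consecutive distinct values;
    ties in gain are broken towards the lowest column index, then the lowest
    threshold.  Returns None when no legal split has positive gain.
    """
    n = rows.size
    if n < 2 * minbucket:
        return None
    ysub = y[rows]
    total = ysub.sum()
    base = total**2 / n
    best: tuple[float, int, float] | None = None
    for j in range(X.shape[1]):
        x = X[rows, j]
        order = np.argsort(x, kind="mergesort")
        xs = x[order]
        cum = np.cumsum(ysub[order])
        n_left = np.arange(1, n)
        ok = (np.diff(xs) > 0) & (n_left >= minbucket) & (n - n_left >= minbucket)
        if not ok.any():
            continue
        s_left = cum[:-1][ok]
        nl = n_left[ok]
        gain = s_left**2 / nl + (total - s_left) ** 2 / (n - nl) - base
        k = int(np.argmax(gain))
        g = float(gain[k])
        if g <= 1e-12:
            continue
        pos = np.flatnonzero(ok)[k]
        threshold = float((xs[pos] + xs[pos + 1]) / 2.0)
        if best is None or g > best[0] + 1e-12:
            best = (g, j, threshold)
    if best is None:
        return None
    return best[1], best[2], best[0]


def grow(design: DesignMatrix, minbucket: float, cp: float = 0.01) -> RedundancyTree:
    """Grow the tree by recursive best splits.

    ``minbucket`` is enforced as ``ceil(minbucket)``; with ``ceil(minbucket)
    >= n`` the tree is the bare root (no clustering).  A split must reduce the
    SSE by at least ``cp`` times the root SSE to be kept.
    """
    if design.n == 0:
        raise ValueError("cannot grow a tree on an empty design matrix")
    mb = int(math.ceil(minbucket))
    if mb < 1:
        raise ValueError("minbucket must be positive")
    columns = list(design.X.columns)
    X = design.X.to_numpy(dtype=float)
    y = design.y.to_numpy(dtype=float)
    root_sse = _node_sse(y)
    min_gain = cp * root_sse

    def build(rows: np.ndarray) -> TreeNode:
        ysub = y[rows]
        node = TreeNode(rows.size, float(ysub.mean()), _node_sse(ysub))
        found = best_split(X, y, rows, mb)
        if found is None:
            return node
        j, threshold, gain = found
        if gain < min_gain:
            return node
        go_left = X[rows, j] < threshold
        node.split = SplitRule(columns[j], threshold)
        node.left = build(rows[go_left])
        node.right = build(rows[~go_left])
        return node

    root = build(np.arange(design.n))
    tree = RedundancyTree(root, mb, cp, columns, design.n)
    _relabel_leaves(tree)
    return tree


def _relabel_leaves(tree: RedundancyTree) -> None:
    for i, leaf in enumerate(tree.leaves()):
        leaf.cluster_id = i


def _clone(node: TreeNode) -> TreeNode:
    if node.is_leaf:
        return TreeNode(node.n, node.mean, node.sse, cluster_id=node.cluster_id)
    return TreeNode(node.n, node.mean, node.sse, split=node.split,
                    left=_clone(node.left), right=_clone(node.right))


def _weakest_link_alphas(root: TreeNode) -> list[float]:
    """Increasing complexity-parameter sequence of the nested subtree family."""
    work = _clone(root)
    alphas: list[float] = []
    while not work.is_leaf:
        best_g, targets = math.inf, []

        def scan(node: TreeNode) -> None:
            nonlocal best_g, targets
            if node.is_leaf:
                return
            g = (node.sse - node.subtree_sse()) / (len(node.leaves()) - 1)
            if g < best_g - 1e-12:
                best_g, targets = g, [node]
            elif g <= best_g + 1e-12:
                targets.append(node)
            scan(node.left)
            scan(node.right)

        scan(work)
        for node in targets:
            node.split, node.left, node.right = None, None, None
        alphas.append(max(best_g, 0.0))
    return alphas


def _prune_at(root: TreeNode, alpha: float) -> TreeNode:
    """Collapse every weakest link with g <= alpha (cost-complexity pruning)."""
    work = _clone(root)
    changed = True
    while changed:
        changed = False

        def scan(node: TreeNode) -> None:
            nonlocal changed
            if node.is_leaf:
                return
            g = (node.sse - node.subtree_sse()) / (len(node.leaves()) - 1)
            if g <= alpha + 1e-12:
                node.split, node.left, node.right = None, None, None
                changed = True
                return
            scan(node.left)
            scan(node.right)

        scan(work)
    return work


def cv_prune(
    tree: RedundancyTree, design: DesignMatrix, n_folds: int = 10, seed: int = 0
) -> RedundancyTree:
    """Select the cost-complexity subtree minimising seeded k-fold CV error.

    Candidate complexity values are geometric means of consecutive weakest-
    link alphas (rpart's convention); per fold a tree is regrown on the
    training part with the same minbucket and cp, pruned at each candidate,
    and scored on the held-out rows.  Ties prefer the smaller tree.
    """
    if tree.root.is_leaf:
        return tree
    alphas = _weakest_link_alphas(tree.root)
    grid = sorted(set(alphas))
    candidates = [0.0]
    for a, b in zip(grid, grid[1:]):
        candidates.append(math.sqrt(max(a, 1e-300) * b))
    candidates.append(grid[-1] * 2.0 + 1e-12)

    n = design.n
    n_folds = max(2, min(n_folds, n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % n_folds

    X = design.X
    y = design.y.to_numpy(dtype=float)
    errors = np.zeros(len(candidates))
    for fold in range(n_folds):
        test = fold_of == fold
        train_design = design.subset(design.X.index[~test])
        fold_tree = grow(train_design, tree.minbucket, tree.cp)
        X_test = X.loc[test]
        y_test = y[test]
        for i, alpha in enumerate(candidates):
            pruned_root = _prune_at(fold_tree.root, alpha)
            pruned = RedundancyTree(pruned_root, tree.minbucket, tree.cp,
                                    tree.columns, train_design.n)
            _relabel_leaves(pruned)
            pred = pruned.predict_mean(X_test)
            errors[i] += float(((y_test - pred) ** 2).sum())

    # minimum CV error; on ties keep the largest alpha (smallest subtree)
    best_err = errors.min()
    best_alpha = max(a for a, e in zip(candidates, errors) if e <= best_err + 1e-9)
    pruned_root = _prune_at(tree.root, best_alpha)
    out = RedundancyTree(pruned_root, tree.minbucket, tree.cp, tree.columns, tree.n)
    _relabel_leaves(out)
    return out
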