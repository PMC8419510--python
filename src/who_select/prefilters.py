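"""Filter-style feature reduction: tree-ensemble Gini importance and
chi-square dependency ranking.

The importance formulas operate on a minimal explicit tree representation
(``TreeNode``/``DecisionTree``) so externally supplied trees can be scored;
``grow_forest`` provides a built-in ensemble (bootstrapped CART trees grown
by scikit-learn, converted to the minimal representation) for end-to-end
use.  Chi-square scores are computed from bin-by-class contingency tables
with equal-frequency binning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "TreeNode",
    "DecisionTree",
    "ImportanceVector",
    "ChiSquareScore",
    "node_importance",
    "tree_feature_importance",
    "forest_feature_importance",
    "grow_forest",
    "chi_square_score",
    "chi_square_feature_scores",
    "prefilter",
]


@dataclass
class TreeNode:
    """A node holding its weighted sample count and Gini contamination.

    Internal nodes carry a ``split_feature`` and both children; leaves
    carry neither.
    """

    weighted_samples: float
    impurity: float
    split_feature: Optional[int] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    def __post_init__(self) -> None:
        if self.weighted_samples < 0:
            raise ValueError("weighted_samples must be nonnegative")
        if self.impurity < 0:
            raise ValueError("impurity must be nonnegative")
        has_children = self.left is not None and self.right is not None
        has_split = self.split_feature is not None
        if has_children != has_split or (self.left is None) != (self.right is None):
            raise ValueError(
                "a node must have both children and a split_feature, or neither"
            )

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None


@dataclass
class DecisionTree:
    root: TreeNode
    n_features: int

    def __post_init__(self) -> None:
        for node in self.internal_nodes():
            if not 0 <= node.split_feature < self.n_features:
                raise ValueError(
                    f"split_feature {node.split_feature} out of range "
                    f"for n_features={self.n_features}"
                )

    def internal_nodes(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                yield node
                stack.append(node.left)
                stack.append(node.right)


@dataclass
class ImportanceVector:
    raw: Optional[np.ndarray] = None
    normalized: Optional[np.ndarray] = None
    forest_averaged: Optional[np.ndarray] = None
    n_trees: int = 1


@dataclass(frozen=True)
class ChiSquareScore:
    statistic: float
    observed: np.ndarray
    expected: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.observed.size)


def node_importance(node: TreeNode) -> float:
    """Impurity decrease attributed to one split:
    w*C - w_left*C_left - w_right*C_right."""
    if node.is_leaf:
        raise ValueError("node_importance is defined only for internal nodes")
    return (
        node.weighted_samples * node.impurity
        - node.left.weighted_samples * node.left.impurity
        - node.right.weighted_samples * node.right.impurity
    )


def tree_feature_importance(tree: DecisionTree) -> ImportanceVector:
    """Per-feature importance of one tree.

    raw[i] = (sum of node importances over nodes splitting on i) divided by
    the sum over all internal nodes; normalized[i] = raw[i] / sum(raw).
    """
    internal = list(tree.internal_nodes())
    if not internal:
        raise ValueError("tree has no internal nodes")
    raw = np.zeros(tree.n_features)
    total = 0.0
    for node in internal:
        imp = node_importance(node)
        raw[node.split_feature] += imp
        total += imp
    if total != 0:
        raw = raw / total
    raw_sum = raw.sum()
    normalized = raw / raw_sum if raw_sum != 0 else raw.copy()
    return ImportanceVector(raw=raw, normalized=normalized, n_trees=1)


def forest_feature_importance(trees: Sequence[DecisionTree]) -> ImportanceVector:
    """Average of per-tree normalized importances over the ensemble."""
    trees = list(trees)
    if not trees:
        raise ValueError("forest_feature_importance requires at least one tree")
    n_features = trees[0].n_features
    if any(t.n_features != n_features for t in trees):
        raise ValueError("all trees must share the same n_features")
    acc = np.zeros(n_features)
    for t in trees:
        acc += tree_feature_importance(t).normalized
    return ImportanceVector(forest_averaged=acc / len(trees), n_trees=len(trees))


def _convert_sklearn_tree(clf: DecisionTreeClassifier, n_features: int) -> DecisionTree:
    t = clf.tree_

    def build(idx: int) -> TreeNode:
        left, right = t.children_left[idx], t.children_right[idx]
        if left == -1:
            return TreeNode(
                weighted_samples=float(t.weighted_n_node_samples[idx]),
                impurity=float(t.impurity[idx]),
            )
        return TreeNode(
            weighted_samples=float(t.weighted_n_node_samples[idx]),
            impurity=float(t.impurity[idx]),
            split_feature=int(t.feature[idx]),
            left=build(left),
            right=build(right),
        )

    return DecisionTree(root=build(0), n_features=n_features)


def grow_forest(
    matrix: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 50,
    max_depth: int = 5,
    seed: int = 0,
) -> List[DecisionTree]:
    """Grow a bootstrapped ensemble of Gini CART trees and return them in
    the minimal representation used by the importance formulas."""
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    trees: List[DecisionTree] = []
    attempts = 0
    while len(trees) < n_trees:
        attempts += 1
        if attempts > 10 * n_trees:
            raise RuntimeError("could not grow enough non-trivial trees")
        idx = rng.integers(n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue  # pure bootstrap: no split possible
        clf = DecisionTreeClassifier(
            criterion="gini",
            max_depth=max_depth,
            random_state=int(rng.integers(2**31 - 1)),
        )
        clf.fit(X[idx], y[idx])
        if clf.tree_.node_count < 3:
            continue
        trees.append(_convert_sklearn_tree(clf, X.shape[1]))
    return trees


def chi_square_score(
    observed: Sequence[float], expected: Sequence[float]
) -> ChiSquareScore:
    """Pearson chi-square statistic sum((Y - E)^2 / E) over cells."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal length")
    if obs.size == 0:
        raise ValueError("empty observed/expected vectors")
    if np.any(exp <= 0):
        raise ValueError("expected values must be strictly positive")
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    return ChiSquareScore(statistic=statistic, observed=obs, expected=exp)


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Discretize into at most ``bins`` equal-frequency bins; duplicated
    quantile edges are merged.  Returns integer bin codes."""
    quantiles = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(quantiles)
    return np.searchsorted(edges, x, side="left")


def chi_square_feature_scores(
    matrix: np.ndarray,
    labels: np.ndarray,
    bins: int = 5,
) -> np.ndarray:
    """Chi-square dependency score of each feature with the class label.

    Each feature is discretized into equal-frequency bins; observed counts
    are the bin-by-class contingency table and expected counts come from
    the margins.  Constant features score 0 (with a warning).
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("at least two classes required")
    class_idx = np.searchsorted(classes, y)
    n = X.shape[0]
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        codes = _equal_frequency_bins(X[:, j], bins)
        n_bins = codes.max() + 1
        if n_bins < 2:
            warnings.warn(f"feature {j} is constant; chi-square score set to 0")
            scores[j] = 0.0
            continue
        table = np.zeros((n_bins, classes.size))
        np.add.at(table, (codes, class_idx), 1.0)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row * col / n
        mask = expected.ravel() > 0
        scores[j] = chi_square_score(
            table.ravel()[mask], expected.ravel()[mask]
        ).statistic
    return scores


def prefilter(
    matrix: np.ndarray,
    labels: np.ndarray,
    method: str,
    keep: int,
    bins: int = 5,
    n_trees: int = 50,
    max_depth: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Indices (sorted ascending) of the ``keep`` top-ranked features.

    ``method`` is ``"gini"`` (built-in forest importance) or ``"chi2"``.
    Ranking ties are broken toward the lower feature index.
    """
    X = np.asarray(matrix, dtype=float)
    n_features = X.shape[1]
    if not 1 <= keep <= n_features:
        raise ValueError(f"keep must be in [1, {n_features}], got {keep}")
    if method == "gini":
        trees = grow_forest(X, labels, n_trees=n_trees, max_depth=max_depth, seed=seed)
        scores = forest_feature_importance(trees).forest_averaged
    elif method == "chi2":
        scores = chi_square_feature_scores(X, labels, bins=bins)
    else:
        raise ValueError(f"unknown prefilter method {method!r}")
    # stable sort on -score: ties resolve to the lower index
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:keep])
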