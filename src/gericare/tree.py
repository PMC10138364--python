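"""A small CART learner with Gini impurity and pre-pruning.

The decision-support model is a depth-limited binary tree grown greedily:
at each node the split (feature, threshold) with the largest decrease in
Gini impurity

    Gini = 1 - sum_j p_j**2

is taken, where p_j is the proportion of training records of class j at the
node.  Pre-pruning stops growth at a maximum depth and a minimum number of
samples per leaf (the defaults used downstream are depth 3 and 6 samples).
The same learner backs both the care-plan recommender (over one-hot-encoded
categorical variables) and the posture classifier (over numeric geometric
features).

Determinism: features are scanned in index order and thresholds in
increasing order; the first split achieving the best decrease wins, so a
fit depends only on the data and its order.  Ties between classes at a leaf
are broken toward the lowest class index, which callers exploit by ordering
classes most-severe-first.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = ["gini", "DecisionTree", "TreeNode"]


def gini(proportions: Sequence[float]) -> float:
    """Gini impurity of a class-proportion vector (must sum to 1)."""
    p = np.asarray(proportions, dtype=float)
    if p.size == 0 or (p < 0).any() or (p > 1).any():
        raise ValueError("proportions must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()}, expected 1")
    return float(1.0 - np.sum(p**2))


def _gini_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p**2))


@dataclasses.dataclass
class TreeNode:
    """Internal node (feature/threshold set) or leaf (class distribution)."""

    n_samples: int
    counts: list[int]
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"n_samples": self.n_samples, "counts": list(map(int, self.counts))}
        if not self.is_leaf:
            d.update(
                feature=int(self.feature),
                threshold=float(self.threshold),
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(n_samples=d["n_samples"], counts=list(d["counts"]))
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


class DecisionTree:
    """Gini CART over a numeric feature matrix.

    Parameters
    ----------
    max_depth : maximum number of split levels on any root-to-leaf path.
    min_samples_leaf : minimum training records in every leaf.
    classes : ordered class labels; index order breaks leaf ties, so put the
        most severe class first when severity matters.
    feature_names : optional, for explanation traces.
    """

    def __init__(
        self,
        max_depth: int = 3,
        min_samples_leaf: int = 6,
        classes: Optional[Sequence[str]] = None,
        feature_names: Optional[Sequence[str]] = None,
        seed: int = 0,
    ):
        self.max_depth = int(max_depth)
        self.min_samples_leaf = int(min_samples_leaf)
        self.classes = list(classes) if classes is not None else None
        self.feature_names = list(feature_names) if feature_names is not None else None
        self.seed = int(seed)  # kept for API symmetry; the fit is deterministic
        self.root: Optional[TreeNode] = None

    # -- fitting ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "DecisionTree":
        X = np.asarray(X, dtype=float)
        y = list(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        if self.classes is None:
            self.classes = sorted(set(y))
        unknown = set(y) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside declared classes: {sorted(unknown)}")
        y_idx = np.array([self.classes.index(v) for v in y], dtype=int)
        if self.feature_names is None:
            self.feature_names = [f"x{j}" for j in range(X.shape[1])]
        self.root = self._grow(X, y_idx, depth=0)
        return self

    def _grow(self, X: np.ndarray, y: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(y, minlength=len(self.classes))
        node = TreeNode(n_samples=len(y), counts=counts.tolist())
        if (
            depth >= self.max_depth
            or len(y) < 2 * self.min_samples_leaf
            or _gini_counts(counts) == 0.0
        ):
            return node
        split = self._best_split(X, y, counts)
        if split is None:
            return node
        j, thr = split
        mask = X[:, j] <= thr
        node.feature = j
        node.threshold = thr
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    def _best_split(
        self, X: np.ndarray, y: np.ndarray, counts: np.ndarray
    ) -> Optional[tuple[int, float]]:
        n, d = X.shape
        parent = _gini_counts(counts)
        best: Optional[tuple[int, float]] = None
        best_dec = 1e-12  # require a strictly positive decrease
        k = len(self.classes)
        for j in range(d):
            col = X[:, j]
            order = np.argsort(col, kind="stable")
            col_s, y_s = col[order], y[order]
            left = np.zeros(k)
            right = counts.astype(float).copy()
            i = 0
            while i < n - 1:
                # advance over a block of equal feature values
                v = col_s[i]
                while i < n and col_s[i] == v:
                    left[y_s[i]] += 1
                    right[y_s[i]] -= 1
                    i += 1
                if i >= n:
                    break
                nl = int(left.sum())
                nr = n - nl
                if nl < self.min_samples_leaf or nr < self.min_samples_leaf:
                    continue
                dec = parent - (nl * _gini_counts(left) + nr * _gini_counts(right)) / n
                if dec > best_dec + 1e-12:
                    best_dec = dec
                    best = (j, float((v + col_s[i]) / 2.0))
        return best

    # -- prediction -------------------------------------------------------

    def _leaf(self, x: np.ndarray) -> tuple[TreeNode, list[str]]:
        if self.root is None:
            raise RuntimeError("tree is not fitted")
        node = self.root
        path: list[str] = []
        while not node.is_leaf:
            name = self.feature_names[node.feature]
            if x[node.feature] <= node.threshold:
                path.append(f"{name} <= {node.threshold:g}")
                node = node.left
            else:
                path.append(f"{name} > {node.threshold:g}")
                node = node.right
        return node, path

    def predict_one(self, x: np.ndarray) -> str:
        leaf, _ = self._leaf(np.asarray(x, dtype=float))
        return self.classes[int(np.argmax(leaf.counts))]

    def predict(self, X: np.ndarray) -> list[str]:
        X = np.asarray(X, dtype=float)
        return [self.predict_one(row) for row in X]

    def predict_proba_one(self, x: np.ndarray) -> np.ndarray:
        leaf, _ = self._leaf(np.asarray(x, dtype=float))
        c = np.asarray(leaf.counts, dtype=float)
        return c / c.sum()

    def decision_path(self, x: np.ndarray) -> list[str]:
        """Root-to-leaf explanation trace for one sample."""
        _, path = self._leaf(np.asarray(x, dtype=float))
        return path

    # -- structure checks & persistence -----------------------------------

    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root) if self.root else 0

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        if self.root:
            walk(self.root)
        return out

    def to_dict(self) -> dict:
        if self.root is None:
            raise RuntimeError("tree is not fitted")
        return {
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "classes": self.classes,
            "feature_names": self.feature_names,
            "seed": self.seed,
            "root": self.root.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        tree = cls(
            max_depth=d["max_depth"],
            min_samples_leaf=d["min_samples_leaf"],
            classes=d["classes"],
            feature_names=d["feature_names"],
            seed=d.get("seed", 0),
        )
        tree.root = TreeNode.from_dict(d["root"])
        return tree

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "DecisionTree":
        return cls.from_dict(json.loads(Path(path).read_text()))
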