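"""Exact path-dependent SHAP values for decision-tree ensembles.

Implements the polynomial-time TreeSHAP recursion (Lundberg-style path
algorithm) over a minimal array representation of binary trees, with
adapters for scikit-learn decision trees and histogram gradient-boosting
ensembles. Attributions explain the raw (margin) output; the per-row sum of
attributions plus the expected value reproduces the model output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np


@dataclass
class Tree:
    children_left: np.ndarray  # -1 at leaves
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    missing_go_left: np.ndarray  # bool per node
    value: np.ndarray  # leaf payoff (internal entries unused)
    cover: np.ndarray  # weighted sample count per node

    def is_leaf(self, j: int) -> bool:
        return self.children_left[j] < 0

    def hot_child(self, j: int, x: np.ndarray) -> int:
        xv = x[self.feature[j]]
        if np.isnan(xv):
            go_left = bool(self.missing_go_left[j])
        else:
            go_left = xv <= self.threshold[j]
        return int(self.children_left[j] if go_left else self.children_right[j])

    def expected_value(self) -> float:
        def rec(j):
            if self.is_leaf(j):
                return float(self.value[j])
            l, r = self.children_left[j], self.children_right[j]
            return (
                self.cover[l] * rec(l) + self.cover[r] * rec(r)
            ) / self.cover[j]

        return rec(0)

    def predict_one(self, x: np.ndarray) -> float:
        j = 0
        while not self.is_leaf(j):
            j = self.hot_child(j, x)
        return float(self.value[j])


class _PathElement:
    __slots__ = ("d", "z", "o", "w")

    def __init__(self, d=-1, z=1.0, o=1.0, w=0.0):
        self.d, self.z, self.o, self.w = d, z, o, w

    def copy(self):
        return _PathElement(self.d, self.z, self.o, self.w)


def _extend(path, depth, pz, po, pi):
    path[depth].d = pi
    path[depth].z = pz
    path[depth].o = po
    path[depth].w = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        path[i + 1].w += po * path[i].w * (i + 1.0) / (depth + 1.0)
        path[i].w = pz * path[i].w * (depth - i) / (depth + 1.0)


def _unwind(path, depth, idx):
    o = path[idx].o
    z = path[idx].z
    nxt = path[depth].w
    for i in range(depth - 1, -1, -1):
        if o != 0:
            tmp = path[i].w
            path[i].w = nxt * (depth + 1.0) / ((i + 1.0) * o)
            nxt = tmp - path[i].w * z * (depth - i) / (depth + 1.0)
        else:
            path[i].w = path[i].w * (depth + 1.0) / (z * (depth - i))
    for i in range(idx, depth):
        path[i].d = path[i + 1].d
        path[i].z = path[i + 1].z
        path[i].o = path[i + 1].o


def _unwound_sum(path, depth, idx):
    o = path[idx].o
    z = path[idx].z
    nxt = path[depth].w
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if o != 0:
            tmp = nxt * (depth + 1.0) / ((i + 1.0) * o)
            total += tmp
            nxt = path[i].w - tmp * z * (depth - i) / (depth + 1.0)
        elif z != 0:
            total += (path[i].w / z) / ((depth - i) / (depth + 1.0))
    return total


def _recurse(tree: Tree, x, phi, j, parent_path, depth, pz, po, pi):
    path = [p.copy() for p in parent_path] + [_PathElement()]
    _extend(path, depth, pz, po, pi)
    if tree.is_leaf(j):
        leaf = tree.value[j]
        for i in range(1, depth + 1):
            w = _unwound_sum(path, depth, i)
            el = path[i]
            phi[el.d] += w * (el.o - el.z) * leaf
        return
    hot = tree.hot_child(j, x)
    l, r = int(tree.children_left[j]), int(tree.children_right[j])
    cold = r if hot == l else l
    w = tree.cover[j]
    hot_zf = tree.cover[hot] / w
    cold_zf = tree.cover[cold] / w
    iz = io = 1.0
    split = int(tree.feature[j])
    path_index = 0
    while path_index <= depth:
        if path[path_index].d == split:
            break
        path_index += 1
    if path_index != depth + 1:
        iz = path[path_index].z
        io = path[path_index].o
        _unwind(path, depth, path_index)
        depth -= 1
        path = path[:-1]
    _recurse(tree, x, phi, hot, path, depth + 1, hot_zf * iz, io, split)
    _recurse(tree, x, phi, cold, path, depth + 1, cold_zf * iz, 0.0, split)


def tree_shap_values(tree: Tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """SHAP values of one tree for one sample."""
    phi = np.zeros(n_features)
    _recurse(tree, np.asarray(x, dtype=float), phi, 0, [], 0, 1.0, 1.0, -1)
    return phi


class TreeEnsemble:
    """Additive ensemble of :class:`Tree` plus a constant offset."""

    def __init__(self, trees: list[Tree], base_offset: float = 0.0):
        self.trees = trees
        self.base_offset = float(base_offset)

    @property
    def expected_value(self) -> float:
        return self.base_offset + sum(t.expected_value() for t in self.trees)

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(len(X), self.base_offset)
        for t in self.trees:
            out += np.array([t.predict_one(x) for x in X])
        return out

    def shap_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, m = X.shape
        phi = np.zeros((n, m))
        for t in self.trees:
            for i in range(n):
                phi[i] += tree_shap_values(t, X[i], m)
        return phi

    @classmethod
    def from_sklearn_tree(cls, estimator) -> "TreeEnsemble":
        t = estimator.tree_
        value = t.value[:, 0, 0] if t.value.ndim == 3 else t.value[:, 0]
        missing_left = getattr(t, "missing_go_to_left", None)
        if missing_left is None:
            missing_left = np.ones(t.node_count, dtype=bool)
        return cls(
            [
                Tree(
                    children_left=t.children_left.copy(),
                    children_right=t.children_right.copy(),
                    feature=t.feature.copy(),
                    threshold=t.threshold.copy(),
                    missing_go_left=np.asarray(missing_left, dtype=bool),
                    value=np.asarray(value, dtype=float),
                    cover=t.weighted_n_node_samples.copy(),
                )
            ]
        )

    @classmethod
    def from_hist_gradient_boosting(cls, model) -> "TreeEnsemble":
        """Adapter for fitted HistGradientBoosting models (binary
        classification or regression); explains the raw decision value."""
        trees = []
        for stage in model._predictors:
            nodes = stage[0].nodes
            trees.append(
                Tree(
                    children_left=np.where(nodes["is_leaf"], -1, nodes["left"].astype(int)),
                    children_right=np.where(nodes["is_leaf"], -1, nodes["right"].astype(int)),
                    feature=nodes["feature_idx"].astype(int),
                    threshold=nodes["num_threshold"].astype(float),
                    missing_go_left=nodes["missing_go_to_left"].astype(bool),
                    value=nodes["value"].astype(float),
                    cover=nodes["count"].astype(float),
                )
            )
        base = float(np.ravel(model._baseline_prediction)[0])
        return cls(trees, base_offset=base)


# ---------------------------------------------------------------------------
# brute-force oracle (tests only; exponential in tree features)
# ---------------------------------------------------------------------------

def expvalue(tree: Tree, x: np.ndarray, subset: frozenset) -> float:
    """Path-dependent conditional expectation with features in ``subset``
    fixed to x and the rest marginalised by node cover."""

    def rec(j):
        if tree.is_leaf(j):
            return float(tree.value[j])
        if tree.feature[j] in subset:
            return rec(tree.hot_child(j, x))
        l, r = int(tree.children_left[j]), int(tree.children_right[j])
        return (tree.cover[l] * rec(l) + tree.cover[r] * rec(r)) / tree.cover[j]

    return rec(0)


def brute_force_shap(tree: Tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact Shapley values by subset enumeration over the features used in
    the tree (others get zero attribution)."""
    used = sorted(
        {int(f) for f, leaf in zip(tree.feature, tree.children_left < 0) if not leaf}
    )
    m = len(used)
    phi = np.zeros(n_features)
    for i in used:
        others = [f for f in used if f != i]
        for k in range(m):
            for S in combinations(others, k):
                Sset = frozenset(S)
                weight = factorial(k) * factorial(m - k - 1) / factorial(m)
                phi[i] += weight * (
                    expvalue(tree, x, Sset | {i}) - expvalue(tree, x, Sset)
                )
    return phi
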