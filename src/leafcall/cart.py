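"""CART regression tree on 0/1 labels.

Greedy recursive binary splitting with the squared-error (variance
reduction) criterion: the calling step consumes leaf *means* of the 0/1
known-variant labels, so regression semantics are the natural fit.  Splits
are axis-aligned thresholds at midpoints between consecutive distinct sorted
feature values; at equal impurity the lowest feature index and then the
smallest threshold wins, which together with stable sorting makes training
fully deterministic for a fixed input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .records import FEATURE_NAMES


@dataclass(slots=True)
class Leaf:
    count: int
    mean_qual: float


@dataclass(slots=True)
class Internal:
    feature_name: str
    threshold: float
    left: "TreeNode"  # condition "value > threshold" false
    right: "TreeNode"  # condition true

    @property
    def feature_index(self) -> int:
        return FEATURE_NAMES.index(self.feature_name)


TreeNode = Union[Leaf, Internal]


@dataclass(slots=True)
class TrainConfig:
    """Stopping rules and determinism knobs for tree training.

    The defaults target whole-genome candidate counts (leaves of hundreds to
    thousands of candidates); small simulated datasets need proportionally
    smaller ``min_leaf``/``min_split`` or the tree degenerates to its root.
    """

    max_depth: int = 14
    min_leaf: int = 200
    min_split: int = 400
    #: a split must decrease the total SSE by at least this fraction of the
    #: training-set size (sklearn's min_impurity_decrease convention); on 0/1
    #: labels, whose variance is at most 0.25, the 0.01 default demands that
    #: each split explain >= 4% of the worst-case label variance, which stops
    #: the transductive tree from chasing individual mislabelled candidates
    min_impurity_decrease: float = 0.01
    seed: int = 0
    subsample_cap: Optional[int] = None  # reservoir-subsample training set above this


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (weighted child SSE, feature, threshold) over all candidate splits.

    Returns None when no admissible split strictly reduces the node SSE.
    """
    n = len(y)
    total = float(y.sum())
    total2 = float((y * y).sum())
    parent_sse = total2 - total * total / n
    best = None  # (wsse, feature, threshold)
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y[order]
        cs = np.cumsum(ys)
        cs2 = np.cumsum(ys * ys)
        cut = np.nonzero(xs[:-1] < xs[1:])[0]  # split between i and i+1
        cut = cut[(cut + 1 >= min_leaf) & (n - cut - 1 >= min_leaf)]
        if cut.size == 0:
            continue
        nl = cut + 1.0
        nr = n - nl
        sl = cs[cut]
        sl2 = cs2[cut]
        wsse = (sl2 - sl * sl / nl) + ((total2 - sl2) - (total - sl) ** 2 / nr)
        j = int(np.argmin(wsse))  # first minimum -> smallest threshold
        lo, hi = xs[cut[j]], xs[cut[j] + 1]
        thr = (lo + hi) / 2.0
        if not (lo <= thr < hi):  # midpoint rounded onto hi: fall back to lo
            thr = lo
        if best is None or wsse[j] < best[0]:
            best = (float(wsse[j]), f, float(thr))
    if best is None or best[0] >= parent_sse - 1e-12:
        return None
    return parent_sse, best


def train_tree(X, y, config: TrainConfig = None, feature_names: Sequence[str] = FEATURE_NAMES) -> TreeNode:
    """Train a CART regression tree on a feature matrix and 0/1 labels.

    Parameters
    ----------
    X : (n, n_features) array; columns follow ``feature_names`` (by default
        the 12 caller features in :data:`FEATURE_NAMES` order)
    y : length-n array of 0/1 labels
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, n_features) with matching y")
    if len(y) == 0:
        raise ValueError("cannot train a tree on an empty sample set")
    if config.subsample_cap is not None and len(y) > config.subsample_cap:
        rng = np.random.default_rng(config.seed)
        keep = np.sort(rng.choice(len(y), size=config.subsample_cap, replace=False))
        X, y = X[keep], y[keep]
    n_total = len(y)

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        ysub = y[idx]
        n = len(idx)
        mean = float(ysub.mean())
        if (
            depth >= config.max_depth
            or n < config.min_split
            or n < 2 * config.min_leaf
            or np.all(ysub == ysub[0])
        ):
            return Leaf(count=n, mean_qual=mean)
        found = _best_split(X[idx], ysub, config.min_leaf)
        if found is None:
            return Leaf(count=n, mean_qual=mean)
        parent_sse, (wsse, f, thr) = found
        if parent_sse - wsse < config.min_impurity_decrease * n_total:
            return Leaf(count=n, mean_qual=mean)
        mask = X[idx, f] > thr
        return Internal(
            feature_name=feature_names[f],
            threshold=thr,
            left=grow(idx[~mask], depth + 1),
            right=grow(idx[mask], depth + 1),
        )

    return grow(np.arange(len(y)), 0)


def predict_leaf(tree: TreeNode, fv, feature_names: Sequence[str] = FEATURE_NAMES) -> Leaf:
    """Route one feature vector to its leaf (boundary goes left: > is strict)."""
    index = {name: i for i, name in enumerate(feature_names)}
    node = tree
    while isinstance(node, Internal):
        try:
            i = index[node.feature_name]
        except KeyError:
            raise ValueError(f"tree refers to unknown feature {node.feature_name!r}") from None
        node = node.right if fv[i] > node.threshold else node.left
    return node


def predict_many(tree: TreeNode, X, feature_names: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
    """Leaf mean quals for each row of X."""
    X = np.asarray(X, dtype=np.float64)
    return np.array([predict_leaf(tree, row, feature_names).mean_qual for row in X])


def assign_leaf_quals(candidates, tree: TreeNode) -> None:
    """Replace each candidate's label with its leaf's mean label (in place)."""
    for cand in candidates:
        cand.leaf_qual = predict_leaf(tree, cand.features).mean_qual


def iter_leaves(tree: TreeNode):
    if isinstance(tree, Leaf):
        yield tree
    else:
        yield from iter_leaves(tree.left)
        yield from iter_leaves(tree.right)


def tree_depth(tree: TreeNode) -> int:
    if isinstance(tree, Leaf):
        return 0
    return 1 + max(tree_depth(tree.left), tree_depth(tree.right))
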