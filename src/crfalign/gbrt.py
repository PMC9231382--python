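"""Gradient-boosted regression trees, self-contained and deterministic.

Each boosting stage is a :class:`StageEnsemble` of exactly six depth-5
regression trees fitted to squared-error residuals with unit inner shrinkage
(the only learning rate in the model is the stage weight ``mu``).  Split
search is exact: every midpoint of consecutive distinct sorted feature values
is scored by variance reduction, with ties broken by the lowest feature
index, then the lowest threshold, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

TREES_PER_STAGE = 6
DEFAULT_MAX_DEPTH = 5
DEFAULT_MIN_LEAF = 20


@dataclass
class TreeNode:
    """Internal node (feature, threshold, children) or leaf (value)."""

    feature: int = -1
    threshold: float = 0.0
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    value: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"value": self.value}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "value" in d:
            return cls(value=float(d["value"]))
        return cls(
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class RegressionTree:
    """A binary regression tree of maximum depth 5."""

    root: TreeNode
    n_features: int
    max_depth: int = DEFAULT_MAX_DEPTH

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        out = np.empty(X.shape[0])
        self._predict_into(self.root, X, np.arange(X.shape[0]), out)
        return out

    def _predict_into(self, node: TreeNode, X: np.ndarray,
                      idx: np.ndarray, out: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = node.value
            return
        go_left = X[idx, node.feature] <= node.threshold
        self._predict_into(node.left, X, idx[go_left], out)
        self._predict_into(node.right, X, idx[~go_left], out)

    def predict_one(self, x: Sequence[float]) -> float:
        return float(self.predict(np.asarray(x)[None, :])[0])

    def depth(self) -> int:
        def _d(n: TreeNode) -> int:
            return 0 if n.is_leaf else 1 + max(_d(n.left), _d(n.right))
        return _d(self.root)

    def to_dict(self) -> dict:
        return {"n_features": self.n_features, "max_depth": self.max_depth,
                "root": self.root.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        return cls(root=TreeNode.from_dict(d["root"]),
                   n_features=int(d["n_features"]),
                   max_depth=int(d["max_depth"]))


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int
                ) -> Optional[Tuple[int, float]]:
    """Exact exhaustive split search maximising squared-error reduction.

    Candidate thresholds are midpoints of consecutive distinct sorted values;
    both children must keep at least ``min_leaf`` rows.  Ties go to the
    lowest feature index, then the lowest threshold.  Zero-gain splits are
    allowed (an XOR-type target needs them to become separable deeper down);
    returns None only when no admissible split exists.
    """
    n = len(y)
    best: Optional[Tuple[int, float]] = None
    best_gain = -np.inf
    total = y.sum()
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y[order]
        csum = np.cumsum(ys)
        left_n = np.arange(1, n)
        # SSE reduction = n_l*n_r/n * (mean_l - mean_r)^2 (constant terms drop)
        with np.errstate(invalid="ignore"):
            mean_l = csum[:-1] / left_n
            mean_r = (total - csum[:-1]) / (n - left_n)
            gain = left_n * (n - left_n) / n * (mean_l - mean_r) ** 2
        valid = (
            (xs[1:] > xs[:-1])
            & (left_n >= min_leaf)
            & ((n - left_n) >= min_leaf)
        )
        gain = np.where(valid, gain, -np.inf)
        if not valid.any():
            continue
        k = int(np.argmax(gain))
        # among equal gains prefer the lowest threshold within this feature
        ties = np.flatnonzero(gain >= gain[k] - 1e-15)
        k = int(ties[0])
        if gain[k] > best_gain:
            best_gain = float(gain[k])
            best = (f, float(0.5 * (xs[k] + xs[k + 1])))
    return best


def _grow(X: np.ndarray, y: np.ndarray, depth: int, max_depth: int,
          min_leaf: int) -> TreeNode:
    node = TreeNode(value=float(y.mean()))
    if depth >= max_depth or len(y) < 2 * min_leaf or np.ptp(y) <= 1e-15:
        return node
    split = _best_split(X, y, min_leaf)
    if split is None:
        return node
    f, thr = split
    mask = X[:, f] <= thr
    node.feature, node.threshold = f, thr
    node.left = _grow(X[mask], y[mask], depth + 1, max_depth, min_leaf)
    node.right = _grow(X[~mask], y[~mask], depth + 1, max_depth, min_leaf)
    return node


def fit_tree(X: np.ndarray, y: np.ndarray, max_depth: int = DEFAULT_MAX_DEPTH,
             min_leaf: int = DEFAULT_MIN_LEAF) -> RegressionTree:
    """Fit one regression tree by greedy exact variance-reduction splits.

    Leaf values are the mean target of their rows.  Constant targets yield a
    single leaf; an empty input is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(y) == 0:
        raise ValueError("fit_tree needs a non-empty 2-D X matching y")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("fit_tree requires finite inputs")
    root = _grow(X, y, 0, max_depth, max(min_leaf, 1))
    return RegressionTree(root=root, n_features=X.shape[1], max_depth=max_depth)


@dataclass
class StageEnsemble:
    """One boosting stage for one alignment state: exactly six trees.

    The stage prediction is the sum of the six tree outputs; the trees were
    fitted sequentially to residuals (unit inner shrinkage).
    """

    state: str
    trees: List[RegressionTree]

    def __post_init__(self) -> None:
        if len(self.trees) != TREES_PER_STAGE:
            raise ValueError(
                f"stage for state {self.state!r} must hold exactly "
                f"{TREES_PER_STAGE} trees, got {len(self.trees)}"
            )

    @property
    def n_features(self) -> int:
        return self.trees[0].n_features

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros(X.shape[0])
        for t in self.trees:
            out += t.predict(X)
        return out

    def to_dict(self) -> dict:
        return {"state": self.state, "trees": [t.to_dict() for t in self.trees]}

    @classmethod
    def from_dict(cls, d: dict) -> "StageEnsemble":
        return cls(state=d["state"],
                   trees=[RegressionTree.from_dict(t) for t in d["trees"]])


def fit_stage(samples: Dict[str, Tuple[np.ndarray, np.ndarray]],
              max_depth: int = DEFAULT_MAX_DEPTH,
              min_leaf: int = DEFAULT_MIN_LEAF) -> Dict[str, StageEnsemble]:
    """Fit one boosting stage: an independent six-tree ensemble per state.

    ``samples`` maps each alignment state to ``(X, y)``; each ensemble runs
    six rounds of residual fitting.  A state with zero samples is an error.
    """
    empty = [s for s, (X, _) in samples.items() if len(X) == 0]
    if empty:
        raise ValueError(f"no training samples for state(s) {empty}")
    out: Dict[str, StageEnsemble] = {}
    for state, (X, y) in samples.items():
        X = np.asarray(X, dtype=float)
        resid = np.asarray(y, dtype=float).copy()
        trees: List[RegressionTree] = []
        for _ in range(TREES_PER_STAGE):
            t = fit_tree(X, resid, max_depth=max_depth, min_leaf=min_leaf)
            resid -= t.predict(X)
            trees.append(t)
        out[state] = StageEnsemble(state=state, trees=trees)
    return out


def predict_stages(stages: Sequence[Tuple[float, Dict[str, StageEnsemble]]],
                   state: str, X: np.ndarray) -> np.ndarray:
    """Weighted sum ``sum_k mu_k * T_k(x)`` for one state's edges.

    An empty stage list gives 0 (the pure base model).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.zeros(X.shape[0])
    for mu, ensembles in stages:
        ens = ensembles[state]
        if ens.n_features != X.shape[1]:
            raise ValueError("feature schema mismatch in stage prediction")
        out += mu * ens.predict(X)
    return out
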