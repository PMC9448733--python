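"""Single CART-style regression trees grown under a stopping configuration.

Split selection minimises the total within-child sum of squared deviations
(equivalently maximises the between-child variance reduction), with
candidate thresholds at midpoints of adjacent distinct sorted values of each
candidate feature and ties in the reduction broken by (feature index,
threshold) lexicographic order.  A split must strictly reduce the SSE and
respect the minimum leaf size; a node with no such split becomes terminal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .data import ConfigurationError, Dataset, DatasetSummary
from .stopping import StoppingConfig

__all__ = [
    "SplitCandidate",
    "RegressionTree",
    "best_split",
    "grow_tree",
    "predict_tree",
    "tree_size_stats",
]


@dataclass(frozen=True)
class SplitCandidate:
    """A candidate axis-aligned split and the SSE reduction it achieves."""

    feature_index: int
    threshold: float
    sse_reduction: float
    left_n: int
    right_n: int


@dataclass(frozen=True)
class RegressionTree:
    """Binary regression tree in flat-array form (breadth-first node order).

    ``feature[i] == -1`` marks a leaf; ``value`` holds the in-node outcome
    mean for every node (internal nodes included), ``n`` the in-node sample
    size.  Routing: feature value <= threshold goes left, else right.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    n: np.ndarray

    @property
    def n_nodes(self) -> int:
        return int(self.feature.shape[0])

    @property
    def terminal_count(self) -> int:
        return int(np.sum(self.feature < 0))

    def depth_of(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        for i in range(self.n_nodes):
            if self.feature[i] >= 0:
                d[self.left[i]] = d[i] + 1
                d[self.right[i]] = d[i] + 1
        return d

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=np.float64)))
        return _kernel.predict_arrays(
            self.feature, self.threshold, self.left, self.right, self.value, X
        )

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
            "n": self.n.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        return cls(
            np.asarray(d["feature"], dtype=np.int64),
            np.asarray(d["threshold"], dtype=np.float64),
            np.asarray(d["left"], dtype=np.int64),
            np.asarray(d["right"], dtype=np.int64),
            np.asarray(d["value"], dtype=np.float64),
            np.asarray(d["n"], dtype=np.int64),
        )


def _sample_arrays(sample) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sample, Dataset):
        return sample.features, sample.outcome
    X, y = sample
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=np.float64)))
    y = np.asarray(y, dtype=np.float64).ravel()
    return X, y


def best_split(
    sample,
    candidate_features,
    config: StoppingConfig,
) -> SplitCandidate | None:
    """Best leaf-size-respecting split of a node sample, or None.

    ``sample`` is a Dataset or an ``(X, y)`` pair holding the node's rows.
    """
    X, y = _sample_arrays(sample)
    m = y.shape[0]
    if m < 2:
        return None
    feats = np.sort(np.asarray(candidate_features, dtype=np.int64))
    if feats.size == 0:
        raise ConfigurationError("candidate_features must be nonempty")
    min_leaf = config.min_leaf_size if config.min_leaf_size is not None else 1
    idx = np.arange(m)
    f, thr, score, k = _kernel.best_split_arrays(X, y, idx, 0, m, feats, min_leaf)
    if f < 0:
        return None
    s = float(np.sum(y))
    parent_score = s * s / m
    gain = float(score) - parent_score
    if gain <= 1e-10 * (1.0 + parent_score):
        return None
    return SplitCandidate(int(f), float(thr), gain, int(k), int(m - k))


def grow_tree(
    sample,
    summary: DatasetSummary,
    config: StoppingConfig,
    mtry: int,
    maxnodes: int,
    rng: np.random.Generator,
) -> RegressionTree:
    """Grow one tree breadth-first on ``sample`` under the stopping rules.

    The dispersion rules compare each node's in-sample statistic against
    ``theta`` times the corresponding statistic in ``summary`` (computed on
    the full training outcome).  ``mtry`` features are drawn uniformly
    without replacement at each node via ``rng``; the same rng state yields
    an identical tree.
    """
    X, y = _sample_arrays(sample)
    p = X.shape[1]
    if not 1 <= mtry <= p:
        raise ConfigurationError(f"mtry must lie in 1..{p}, got {mtry}")
    if maxnodes < 1:
        raise ConfigurationError("maxnodes must be >= 1")
    theta_var = -1.0 if config.theta_variance is None else float(config.theta_variance)
    theta_rng = -1.0 if config.theta_range is None else float(config.theta_range)
    theta_icr = -1.0 if config.theta_icr is None else float(config.theta_icr)
    tot_icr = summary.icr_for(config.icr_centile) if config.theta_icr is not None else 0.0
    min_parent = config.min_parent_size if config.min_parent_size is not None else 0
    min_leaf = config.min_leaf_size if config.min_leaf_size is not None else 1
    seed = int(rng.integers(1 << 31)) if mtry < p else 0
    arrays = _kernel.grow_arrays(
        np.ascontiguousarray(X),
        y,
        theta_var,
        summary.total_variance,
        theta_rng,
        summary.total_range,
        theta_icr,
        tot_icr,
        float(config.icr_centile),
        float(100.0 - config.icr_centile),
        min_parent,
        min_leaf,
        mtry,
        maxnodes,
        seed,
    )
    return RegressionTree(*arrays)


def predict_tree(tree: RegressionTree, feature_row: np.ndarray) -> float:
    """Prediction for a single feature row."""
    row = np.asarray(feature_row, dtype=np.float64).ravel()
    return float(tree.predict(row[None, :])[0])


def tree_size_stats(tree: RegressionTree) -> dict:
    """Terminal count, depth and smallest leaf size of a tree."""
    leaves = tree.feature < 0
    return {
        "terminal_count": tree.terminal_count,
        "depth": int(tree.depth_of().max()),
        "min_leaf_n": int(tree.n[leaves].min()),
    }
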