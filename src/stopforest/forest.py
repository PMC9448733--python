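"""Bootstrap-aggregated forests of stopping-rule-limited regression trees.

Each tree is grown on a uniform with-replacement bootstrap sample of size n
drawn from its own RNG stream seeded by ``(seed, tree_index)``, so fits are
reproducible and independent of tree-growth order.  The dataset-level
dispersion summary used by the stopping rules is computed once on the full
(un-bootstrapped) training outcome.  Prediction is the unweighted mean of
the per-tree predictions.  Observation weights play no role in fitting;
they only weight prediction error at evaluation time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .data import (
    DEFAULT_CENTILES,
    ConfigurationError,
    DataError,
    Dataset,
    DatasetSummary,
    summarise,
)
from .stopping import StoppingConfig
from .tree import RegressionTree, grow_tree

__all__ = ["ForestParams", "Forest", "fit", "predict", "serialize", "deserialize"]

_FORMAT_VERSION = 1


def _default_stopping() -> StoppingConfig:
    # parent-node size 5: the classical regression-forest default
    return StoppingConfig(min_parent_size=5)


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.

    ``mtry=None`` resolves at fit time to about half the number of features
    (at least 1).  Defaults ntree=1000 and maxnodes=1000 are the reference
    settings used throughout the benchmark evaluations.
    """

    ntree: int = 1000
    mtry: int | None = None
    maxnodes: int = 1000
    stopping: StoppingConfig = field(default_factory=_default_stopping)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ConfigurationError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ConfigurationError("mtry must be >= 1")
        if self.maxnodes < 1:
            raise ConfigurationError("maxnodes must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is None:
            return max(1, round(p / 2))
        if self.mtry > p:
            raise ConfigurationError(f"mtry={self.mtry} exceeds the {p} available features")
        return self.mtry


@dataclass(frozen=True)
class Forest:
    """A fitted forest: the trees plus everything needed to predict."""

    trees: tuple[RegressionTree, ...]
    params: ForestParams
    summary: DatasetSummary
    feature_names: tuple[str, ...]

    @property
    def p(self) -> int:
        return len(self.feature_names)


def fit(train: Dataset, params: ForestParams) -> Forest:
    """Fit a forest of ``params.ntree`` trees to a training dataset."""
    mtry = params.resolve_mtry(train.p)
    centiles = tuple(dict.fromkeys(DEFAULT_CENTILES + params.stopping.centiles_needed()))
    summary = summarise(train.outcome, centiles)
    X, y, n = train.features, train.outcome, train.n
    trees = []
    for t in range(params.ntree):
        rng = np.random.default_rng([params.seed, t])
        inbag = rng.integers(0, n, size=n)
        trees.append(
            grow_tree(
                (X[inbag], y[inbag]),
                summary,
                params.stopping,
                mtry,
                params.maxnodes,
                rng,
            )
        )
    resolved = replace(params, mtry=mtry)
    return Forest(tuple(trees), resolved, summary, train.feature_names)


def predict(forest: Forest, features: np.ndarray) -> np.ndarray:
    """Per-row unweighted mean of the tree predictions."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        X = np.atleast_2d(X)
    if X.shape[0] == 0:
        return np.empty(0)
    if X.shape[1] != forest.p:
        raise ConfigurationError(
            f"feature matrix has {X.shape[1]} columns, forest was trained on {forest.p}"
        )
    X = np.ascontiguousarray(X)
    acc = np.zeros(X.shape[0])
    for tree in forest.trees:
        acc += tree.predict(X)
    return acc / len(forest.trees)


def serialize(forest: Forest, path: str | Path) -> None:
    """Write a forest to a JSON file; round-trips predictions bit-exactly."""
    stopping = forest.params.stopping
    doc = {
        "format_version": _FORMAT_VERSION,
        "params": {
            "ntree": forest.params.ntree,
            "mtry": forest.params.mtry,
            "maxnodes": forest.params.maxnodes,
            "seed": forest.params.seed,
            "stopping": {
                "theta_variance": stopping.theta_variance,
                "theta_range": stopping.theta_range,
                "theta_icr": stopping.theta_icr,
                "icr_centile": stopping.icr_centile,
                "min_parent_size": stopping.min_parent_size,
                "min_leaf_size": stopping.min_leaf_size,
            },
        },
        "summary": {
            "total_variance": forest.summary.total_variance,
            "total_range": forest.summary.total_range,
            "icr": {str(k): v for k, v in forest.summary.icr.items()},
            "n": forest.summary.n,
        },
        "feature_names": list(forest.feature_names),
        "trees": [t.to_dict() for t in forest.trees],
    }
    Path(path).write_text(json.dumps(doc))


def deserialize(path: str | Path) -> Forest:
    """Read a forest written by :func:`serialize`."""
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise DataError(f"cannot read forest file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format_version") != _FORMAT_VERSION:
        raise DataError(
            f"forest file {path} has format version {doc.get('format_version')!r}; "
            f"this build reads version {_FORMAT_VERSION}"
        )
    try:
        s = doc["params"]["stopping"]
        params = ForestParams(
            ntree=doc["params"]["ntree"],
            mtry=doc["params"]["mtry"],
            maxnodes=doc["params"]["maxnodes"],
            seed=doc["params"]["seed"],
            stopping=StoppingConfig(
                theta_variance=s["theta_variance"],
                theta_range=s["theta_range"],
                theta_icr=s["theta_icr"],
                icr_centile=s["icr_centile"],
                min_parent_size=s["min_parent_size"],
                min_leaf_size=s["min_leaf_size"],
            ),
        )
        summary = DatasetSummary(
            total_variance=doc["summary"]["total_variance"],
            total_range=doc["summary"]["total_range"],
            icr={float(k): v for k, v in doc["summary"]["icr"].items()},
            n=doc["summary"]["n"],
        )
        trees = tuple(RegressionTree.from_dict(t) for t in doc["trees"])
    except (KeyError, TypeError) as exc:
        raise DataError(f"forest file {path} is corrupt: {exc}") from exc
    return Forest(trees, params, summary, tuple(doc["feature_names"]))
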