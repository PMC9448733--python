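"""Weighted MSPE, tenfold-CV evaluation, threshold sweeps and excess tables.

The mean square prediction error is weighted by the observation weights of
the evaluated rows, ``MSPE = sum(w_i (y_i - yhat_i)^2) / sum(w_i)``.
Cross-validated error is *pooled*: weighted squared errors and weights are
accumulated over all folds and divided once at the end, which is invariant
to fold-size imbalance (it is not the mean of per-fold MSEs).

A threshold sweep (:func:`tune`) evaluates one stopping rule over a grid of
thresholds, each grid point with only that rule enabled, and reports the
full MSPE curve together with its minimum (minMSPE); ties in the minimum
break toward the smaller threshold.  :func:`relative_excess` turns a
rule-by-dataset MSPE matrix into the percentage excess of each rule over the
best rule per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ConfigurationError, DataError, Dataset, kfold_indices, train_test_split
from .forest import Forest, ForestParams, fit, predict
from .stopping import RULE_KINDS, StoppingConfig

__all__ = [
    "DEFAULT_GRIDS",
    "EvalResult",
    "SweepResult",
    "mspe",
    "holdout_mspe",
    "cv_mspe",
    "tune",
    "relative_excess",
]

#: default tuning grids per rule kind: node sizes for the parent/leaf rules,
#: proportions of the total dispersion statistic for the others.  The leaf
#: grid brackets the common regression default of 5.
DEFAULT_GRIDS: Mapping[str, tuple[float, ...]] = {
    "parent": (2, 5, 10, 25, 50, 100),
    "leaf": (1, 2, 5, 10, 25, 50),
    "variance": (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5),
    "range": (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5),
    "icr": (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5),
}


def derive_seed(seed: int, index: int) -> int:
    """Deterministic sub-seed for (sweep grid point | CV fold) streams."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (1 << 31))


@dataclass(frozen=True)
class EvalResult:
    """An MSPE measurement, with per-fold pieces when cross-validated."""

    mspe: float
    params: ForestParams
    per_fold_sse: tuple[float, ...] | None = None
    per_fold_weight: tuple[float, ...] | None = None
    rule_kind: str | None = None
    threshold: float | None = None


@dataclass(frozen=True)
class SweepResult:
    """MSPE curve of one stopping rule over a threshold grid."""

    rule_kind: str
    grid: tuple[float, ...]
    mspes: tuple[float, ...]
    results: tuple[EvalResult, ...]

    @property
    def min_mspe(self) -> float:
        return float(min(self.mspes))

    @property
    def best_threshold(self) -> float:
        # grid is ascending, argmin keeps the first -> smaller threshold on ties
        return self.grid[int(np.argmin(self.mspes))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.grid, "mspe": self.mspes})


def mspe(y_true, y_pred, weights=None) -> float:
    """Weighted mean square prediction error (weights default to 1)."""
    y = np.asarray(y_true, dtype=np.float64).ravel()
    yhat = np.asarray(y_pred, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise DataError(f"length mismatch: {y.shape[0]} true vs {yhat.shape[0]} predicted")
    if y.size < 1:
        raise DataError("mspe needs at least one observation")
    if weights is None:
        return float(np.mean((y - yhat) ** 2))
    w = np.asarray(weights, dtype=np.float64).ravel()
    if w.shape != y.shape:
        raise DataError("weights length mismatch")
    if np.any(w <= 0):
        raise DataError("weights must be strictly positive")
    return float(np.sum(w * (y - yhat) ** 2) / np.sum(w))


def holdout_mspe(train: Dataset, test: Dataset, params: ForestParams) -> EvalResult:
    """Fit on ``train``, score on ``test`` using the test observations' weights."""
    train, test = train_test_split(train, test)
    forest = fit(train, params)
    yhat = predict(forest, test.features)
    return EvalResult(mspe=mspe(test.outcome, yhat, test.weights), params=forest.params)


def cv_mspe(dataset: Dataset, params: ForestParams, k: int = 10, cv_seed: int = 0) -> EvalResult:
    """Pooled k-fold cross-validated weighted MSPE.

    Fold assignment is a seeded uniform partition (weights ignored); each
    fold's forest uses a seed derived from ``(params.seed, fold)``.
    """
    folds = kfold_indices(dataset.n, k, cv_seed)
    all_idx = np.arange(dataset.n)
    sses, wts = [], []
    for fi, fold in enumerate(folds):
        mask = np.ones(dataset.n, dtype=bool)
        mask[fold] = False
        fold_params = replace(params, seed=derive_seed(params.seed, fi))
        forest = fit(dataset.subset(all_idx[mask]), fold_params)
        yhat = predict(forest, dataset.features[fold])
        err = dataset.outcome[fold] - yhat
        w = dataset.weights[fold]
        sses.append(float(np.sum(w * err**2)))
        wts.append(float(np.sum(w)))
    return EvalResult(
        mspe=float(sum(sses) / sum(wts)),
        params=params,
        per_fold_sse=tuple(sses),
        per_fold_weight=tuple(wts),
    )


def tune(
    dataset: Dataset,
    rule_kind: str,
    grid: Sequence[float] | None = None,
    base_params: ForestParams | None = None,
    *,
    k: int = 10,
    cv_seed: int = 0,
    icr_centile: float = 25.0,
    test: Dataset | None = None,
) -> SweepResult:
    """Sweep one stopping rule's threshold and report the MSPE curve.

    Each grid point enables only the swept criterion and evaluates either
    pooled k-fold CV on ``dataset`` or, when ``test`` is given, the holdout
    error of a forest trained on ``dataset``.  Forest seeds are derived per
    grid point from ``base_params.seed`` so sweeps are reproducible.
    """
    if rule_kind not in RULE_KINDS:
        raise ConfigurationError(f"unknown rule kind {rule_kind!r}; expected one of {RULE_KINDS}")
    if base_params is None:
        base_params = ForestParams()
    if grid is None:
        grid = DEFAULT_GRIDS[rule_kind]
    grid = tuple(sorted(float(g) for g in grid))
    if not grid:
        raise ConfigurationError("threshold grid must be nonempty")
    results = []
    for gi, value in enumerate(grid):
        stopping = StoppingConfig.single_rule(rule_kind, value, icr_centile)
        params_g = replace(
            base_params, stopping=stopping, seed=derive_seed(base_params.seed, gi)
        )
        if test is not None:
            res = holdout_mspe(dataset, test, params_g)
        else:
            res = cv_mspe(dataset, params_g, k=k, cv_seed=cv_seed)
        results.append(replace(res, rule_kind=rule_kind, threshold=value))
    return SweepResult(
        rule_kind=rule_kind,
        grid=grid,
        mspes=tuple(r.mspe for r in results),
        results=tuple(results),
    )


def relative_excess(mspe_table: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Percentage excess of each rule's MSPE over the per-dataset minimum.

    For each dataset (column), returns ``100 * (value / column minimum - 1)``;
    the row attaining the column minimum maps to 0.
    """
    values = np.asarray(
        mspe_table.to_numpy() if isinstance(mspe_table, pd.DataFrame) else mspe_table,
        dtype=np.float64,
    )
    if values.ndim != 2:
        raise DataError("mspe table must be two-dimensional (rules x datasets)")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise DataError("mspe table entries must be positive and finite")
    excess = 100.0 * (values / values.min(axis=0, keepdims=True) - 1.0)
    if isinstance(mspe_table, pd.DataFrame):
        return pd.DataFrame(excess, index=mspe_table.index, columns=mspe_table.columns)
    return excess
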