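"""Model/Results front end for stopping-rule-limited regression forests.

Mirrors the fit pattern of the mainstream statistical-modelling packages:
build a model object from data, call :meth:`StoppedForestRegression.fit` to
obtain a results object carrying the fitted forest, fitted values,
residuals, tree-size diagnostics and a ``summary()`` table.

    >>> model = StoppedForestRegression.from_dataframe(df, outcome="y")
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import forest as _forest
from .data import Dataset, load_csv
from .evaluation import EvalResult, holdout_mspe, mspe
from .forest import Forest, ForestParams
from .stopping import explain
from .tree import tree_size_stats

__all__ = ["StoppedForestRegression", "StoppedForestResults"]


class StoppedForestRegression:
    """A regression random forest whose tree growth is limited by stopping rules.

    Parameters
    ----------
    dataset
        Training data (features, outcome, optional observation weights).
    params
        Forest hyperparameters; defaults to ntree=1000, maxnodes=1000,
        mtry ~ p/2 and the classical minimum-parent-size-5 stopping rule.
    """

    def __init__(self, dataset: Dataset, params: ForestParams | None = None):
        self.dataset = dataset
        self.params = params if params is not None else ForestParams()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        weights: str | None = None,
        params: ForestParams | None = None,
    ) -> "StoppedForestRegression":
        w = df[weights].to_numpy() if weights is not None else None
        drop = [outcome] + ([weights] if weights is not None else [])
        feats = df.drop(columns=drop)
        ds = Dataset(
            feats.to_numpy(dtype=float),
            df[outcome].to_numpy(dtype=float),
            w,
            tuple(feats.columns.astype(str)),
            outcome,
        )
        return cls(ds, params)

    @classmethod
    def from_csv(
        cls,
        path,
        outcome: str,
        weights: str | None = None,
        params: ForestParams | None = None,
    ) -> "StoppedForestRegression":
        return cls(load_csv(path, outcome, weights), params)

    def fit(self, **param_overrides) -> "StoppedForestResults":
        params = replace(self.params, **param_overrides) if param_overrides else self.params
        return StoppedForestResults(self, _forest.fit(self.dataset, params))


class StoppedForestResults:
    """Results of a fitted stopping-rule forest."""

    def __init__(self, model: StoppedForestRegression, forest: Forest):
        self.model = model
        self.forest = forest
        self.params = forest.params
        self.fittedvalues = _forest.predict(forest, model.dataset.features)
        self.resid = model.dataset.outcome - self.fittedvalues

    @property
    def training_mspe(self) -> float:
        """Weighted mean square error on the training rows (resubstitution)."""
        ds = self.model.dataset
        return mspe(ds.outcome, self.fittedvalues, ds.weights)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, Dataset):
            X = X.features
        elif isinstance(X, pd.DataFrame):
            X = X[list(self.forest.feature_names)].to_numpy(dtype=float)
        return _forest.predict(self.forest, np.asarray(X, dtype=float))

    def evaluate(self, test: Dataset) -> float:
        """Weighted MSPE on a held-out dataset, using the test rows' weights."""
        return mspe(test.outcome, self.predict(test), test.weights)

    def tree_sizes(self) -> pd.DataFrame:
        """Per-tree terminal count, depth and smallest leaf size."""
        return pd.DataFrame([tree_size_stats(t) for t in self.forest.trees])

    def save(self, path) -> None:
        _forest.serialize(self.forest, path)

    def summary(self) -> str:
        ds = self.model.dataset
        sizes = self.tree_sizes()
        s = self.forest.summary
        lines = [
            "Stopping-rule regression forest",
            "=" * 47,
            f"outcome: {ds.outcome_name:<24s} n obs: {ds.n}",
            f"features: {ds.p:<23d} ntree: {self.params.ntree}",
            f"mtry: {self.params.mtry:<27d} maxnodes: {self.params.maxnodes}",
            f"seed: {self.params.seed}",
            "-" * 47,
            "stopping rules:",
            *("  " + ln for ln in explain(self.params.stopping).splitlines()),
            "-" * 47,
            f"total outcome variance: {s.total_variance:.6g}",
            f"total outcome range:    {s.total_range:.6g}",
            f"mean terminal nodes/tree: {sizes['terminal_count'].mean():.1f}",
            f"mean tree depth:          {sizes['depth'].mean():.1f}",
            f"training MSPE (weighted): {self.training_mspe:.6g}",
        ]
        return "\n".join(lines)

    def holdout(self, test: Dataset) -> EvalResult:
        """Refit-free alias kept for symmetry with evaluation.holdout_mspe."""
        return EvalResult(mspe=self.evaluate(test), params=self.params)
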