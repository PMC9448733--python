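"""Tabular regression datasets and the dataset-level dispersion summaries.

The dispersion-based stopping rules compare a node's outcome spread against
the spread of the outcome in the *total* training set, so the summary
statistics (variance, range, intercentile ranges) are computed once per
dataset and carried alongside it.

Conventions fixed here and used everywhere else in the package:

* variance uses the population divisor ``n`` (the rules compare a ratio of
  variances, so the divisor cancels as long as both sides use the same one);
* percentiles use linear interpolation between order statistics (the common
  "type 7" convention, numpy's default), centralised in :func:`percentile`
  so the whole package can be switched at one place;
* rows containing any missing value are dropped at load time with a logged
  count;
* every column is treated as numeric — categorical source columns must be
  numerically coded by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernel

__all__ = [
    "ConfigurationError",
    "DataError",
    "Dataset",
    "DatasetSummary",
    "load_csv",
    "write_csv",
    "summarise",
    "percentile",
    "population_variance",
    "train_test_split",
    "kfold_indices",
]

logger = logging.getLogger(__name__)

DEFAULT_CENTILES = (10.0, 25.0)


class ConfigurationError(ValueError):
    """Raised when user-supplied configuration is inconsistent."""


class DataError(ValueError):
    """Raised when the data itself violates an invariant."""


@dataclass(frozen=True)
class Dataset:
    """A numeric regression dataset: features, outcome, observation weights.

    Weights default to 1 and are used *only* to weight prediction error;
    they take no part in bootstrap sampling or split search.
    """

    features: np.ndarray
    outcome: np.ndarray
    weights: np.ndarray = None  # type: ignore[assignment]
    feature_names: tuple[str, ...] = ()
    outcome_name: str = "y"

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=np.float64)
        if X.ndim != 2:
            raise DataError("features must be a 2-D matrix")
        y = np.asarray(self.outcome, dtype=np.float64).ravel()
        n, p = X.shape
        if n < 1 or p < 1:
            raise DataError("dataset needs at least one row and one feature")
        if y.shape[0] != n:
            raise DataError("outcome length does not match feature rows")
        w = self.weights
        w = np.ones(n) if w is None else np.asarray(w, dtype=np.float64).ravel()
        if w.shape[0] != n:
            raise DataError("weights length does not match feature rows")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y)) and np.all(np.isfinite(w))):
            raise DataError("dataset contains non-finite values")
        if np.any(w <= 0):
            raise DataError("observation weights must be strictly positive")
        names = tuple(self.feature_names) or tuple(f"x{j}" for j in range(p))
        if len(names) != p:
            raise DataError("feature_names length does not match feature columns")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "feature_names", names)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def subset(self, indices: np.ndarray) -> "Dataset":
        """Row-subset (used for CV folds and bootstrap complements)."""
        idx = np.asarray(indices, dtype=np.intp)
        return Dataset(
            self.features[idx],
            self.outcome[idx],
            self.weights[idx],
            self.feature_names,
            self.outcome_name,
        )

    def to_dataframe(self, include_weights: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df[self.outcome_name] = self.outcome
        if include_weights:
            df["_weight"] = self.weights
        return df


@dataclass(frozen=True)
class DatasetSummary:
    """Dispersion statistics of the full training outcome.

    ``icr`` maps a centile X in (0, 50) to the intercentile range
    ``percentile(100 - X) - percentile(X)``.
    """

    total_variance: float
    total_range: float
    icr: Mapping[float, float]
    n: int

    def icr_for(self, centile: float) -> float:
        key = float(centile)
        if key not in self.icr:
            raise ConfigurationError(
                f"summary holds no {key:g}% intercentile range; recompute the "
                f"summary with this centile included"
            )
        return self.icr[key]


def percentile(values: np.ndarray, q: float) -> float:
    """Type-7 (linear interpolation) percentile — the package-wide convention.

    Shares its compiled implementation with the tree-growth kernel, so node
    statistics and dataset-level summaries of the same vector agree bitwise
    (which makes the theta = 1 halting limit exact rather than approximate).
    """
    y = np.sort(np.asarray(values, dtype=np.float64).ravel())
    return float(_kernel.sorted_percentile(y, float(q)))


def population_variance(values: np.ndarray) -> float:
    """Population (divide-by-n) variance via the tree-growth kernel routine."""
    return float(_kernel.population_variance(np.asarray(values, dtype=np.float64).ravel()))


def summarise(outcome: np.ndarray, centiles: Iterable[float] = DEFAULT_CENTILES) -> DatasetSummary:
    """Dispersion summary of an outcome vector: population variance, range, ICRs."""
    y = np.asarray(outcome, dtype=np.float64).ravel()
    if y.size < 1:
        raise DataError("cannot summarise an empty outcome vector")
    ys = np.sort(y)
    icr = {}
    for x in centiles:
        x = float(x)
        if not 0.0 < x < 50.0:
            raise ConfigurationError(f"intercentile centile must lie in (0, 50), got {x}")
        icr[x] = float(
            _kernel.sorted_percentile(ys, 100.0 - x) - _kernel.sorted_percentile(ys, x)
        )
    return DatasetSummary(
        total_variance=population_variance(y),
        total_range=float(ys[-1] - ys[0]),
        icr=icr,
        n=int(y.size),
    )


def load_csv(
    path: str | Path,
    outcome_column: str,
    weight_column: str | None = None,
) -> Dataset:
    """Load a headered CSV into a :class:`Dataset`.

    Every column is coerced to numeric; cells that are empty or non-numeric
    count as missing and the whole row is dropped (count logged). Remaining
    columns other than the outcome (and optional weight) become features.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    raw = pd.read_csv(path)
    if outcome_column not in raw.columns:
        raise ConfigurationError(
            f"outcome column {outcome_column!r} not found in {path.name} "
            f"(columns: {list(raw.columns)})"
        )
    if weight_column is not None and weight_column not in raw.columns:
        raise ConfigurationError(f"weight column {weight_column!r} not found in {path.name}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    complete = numeric.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("load_csv(%s): dropped %d row(s) with missing values", path.name, n_dropped)
    numeric = numeric.loc[complete]
    if numeric.empty:
        raise DataError(f"{path.name}: no complete rows remain after dropping missing values")
    y = numeric[outcome_column].to_numpy(dtype=np.float64)
    w = None
    drop_cols = [outcome_column]
    if weight_column is not None:
        w = numeric[weight_column].to_numpy(dtype=np.float64)
        if np.any(w <= 0):
            raise DataError(f"{path.name}: weight column {weight_column!r} has non-positive entries")
        drop_cols.append(weight_column)
    feats = numeric.drop(columns=drop_cols)
    if feats.shape[1] < 1:
        raise DataError(f"{path.name}: no feature columns remain")
    return Dataset(
        feats.to_numpy(dtype=np.float64),
        y,
        w,
        tuple(feats.columns.astype(str)),
        outcome_column,
    )


def write_csv(dataset: Dataset, path: str | Path, weight_column: str | None = None) -> None:
    """Write a Dataset back to the CSV dialect :func:`load_csv` reads."""
    df = dataset.to_dataframe()
    if weight_column is not None:
        df[weight_column] = dataset.weights
    df.to_csv(path, index=False)


def train_test_split(train: Dataset, test: Dataset) -> tuple[Dataset, Dataset]:
    """Validate that two datasets share a schema and return them unchanged."""
    if train.feature_names != test.feature_names:
        raise ConfigurationError(
            "train/test feature columns differ: "
            f"{train.feature_names} vs {test.feature_names}"
        )
    if train.outcome_name != test.outcome_name:
        raise ConfigurationError(
            f"train/test outcome columns differ: {train.outcome_name!r} vs {test.outcome_name!r}"
        )
    return train, test


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded k-fold partition of ``range(n)``; fold sizes differ by at most 1."""
    if not 2 <= k <= n:
        raise ConfigurationError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]
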