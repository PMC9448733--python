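"""Synthetic regression datasets with known structure.

These generators stand in for real benchmark data in the test suite: a
one-feature step function whose true tree structure is known exactly, the
standard Friedman #1 nonlinear benchmark with known noiseless values, and a
suite of tiny random datasets for exhaustive-search oracle sweeps.  The
oracle-suite outcomes are small integers so that candidate-split scores are
exact in floating point and ties resolve identically in any faithful
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ConfigurationError, Dataset

__all__ = ["SyntheticSpec", "gen_piecewise", "gen_friedman1", "gen_oracle_suite"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic dataset; the same spec regenerates it exactly."""

    generator: str
    n: int
    noise_sd: float = 0.0
    seed: int = 0

    def generate(self) -> Dataset:
        if self.generator == "piecewise":
            return gen_piecewise(self.n, (0.3, 0.6), (0.0, 5.0, 10.0), self.noise_sd, self.seed)
        if self.generator == "friedman1":
            return gen_friedman1(self.n, self.noise_sd, self.seed)
        raise ConfigurationError(f"unknown generator {self.generator!r}")


def gen_piecewise(
    n: int,
    cuts,
    leaf_means,
    noise_sd: float,
    seed: int,
) -> Dataset:
    """Step function of a single uniform feature plus Gaussian noise.

    ``outcome = leaf_means[j] + eps`` where j indexes the interval of [0, 1]
    delimited by the sorted ``cuts``.  With ``noise_sd = 0`` a tree carrying
    the true cut structure achieves zero error.
    """
    cuts = np.asarray(cuts, dtype=np.float64).ravel()
    means = np.asarray(leaf_means, dtype=np.float64).ravel()
    if np.any(np.diff(cuts) <= 0):
        raise ConfigurationError("cuts must be strictly increasing")
    if means.size != cuts.size + 1:
        raise ConfigurationError("need one leaf mean per interval (len(cuts) + 1)")
    if n < 1 or noise_sd < 0:
        raise ConfigurationError("need n >= 1 and noise_sd >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=n)
    y = means[np.searchsorted(cuts, x, side="right")]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return Dataset(x[:, None], y, feature_names=("x0",), outcome_name="y")


def gen_friedman1(n: int, noise_sd: float, seed: int) -> Dataset:
    """Friedman #1 benchmark: 10 uniform features, 5 of them inert.

    ``y = 10 sin(pi x1 x2) + 20 (x3 - 0.5)^2 + 10 x4 + 5 x5 + eps``.
    """
    if n < 1 or noise_sd < 0:
        raise ConfigurationError("need n >= 1 and noise_sd >= 0")
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, 10))
    y = (
        10.0 * np.sin(np.pi * X[:, 0] * X[:, 1])
        + 20.0 * (X[:, 2] - 0.5) ** 2
        + 10.0 * X[:, 3]
        + 5.0 * X[:, 4]
    )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return Dataset(X, y, feature_names=tuple(f"x{j}" for j in range(10)), outcome_name="y")


def gen_oracle_suite(
    max_n: int = 30,
    max_p: int = 4,
    count: int = 50,
    seed: int = 0,
) -> list[Dataset]:
    """Tiny random datasets for exhaustive-search tree-equivalence sweeps.

    Columns mix continuous uniforms with few-valued "categorical as numeric"
    codes; outcomes are small integers (guaranteeing tied outcome values),
    and one dataset carries duplicated rows to exercise tie-breaking.
    """
    if max_n > 30 or max_p > 4:
        raise ConfigurationError("oracle suite is restricted to n <= 30, p <= 4")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(count):
        n = int(rng.integers(5, max_n + 1))
        p = int(rng.integers(1, max_p + 1))
        X = np.empty((n, p))
        for j in range(p):
            if rng.random() < 0.4:
                X[:, j] = rng.integers(0, 3, size=n).astype(np.float64)
            else:
                X[:, j] = rng.uniform(size=n)
        y = rng.integers(0, 11, size=n).astype(np.float64)
        if i == 1 and n >= 6:  # force duplicate rows in one dataset
            X[n // 2 :] = X[: n - n // 2]
            y[n // 2 :] = y[: n - n // 2]
        out.append(Dataset(X, y))
    return out
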