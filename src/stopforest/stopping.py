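"""Tree-expansion stopping rules.

Five criteria can halt the growth of a regression tree below a node:

(a) node outcome variance no greater than a proportion ``theta_variance`` of
    the variance of the outcome in the total training set;
(b) the same with the range (max - min);
(c) the same with the [X%, 100-X%] intercentile range (X = 10 or 25 by
    convention, any X in (0, 50) accepted);
(d) node size below a minimum parent-node size;
(e) a minimum terminal (leaf) node size.

Rules (a)-(d) are pre-split halts: a node that triggers any enabled one
becomes a leaf.  Rule (e) instead constrains candidate splits — a split is
invalid if either child would fall below the minimum — and a node with no
valid split becomes a leaf.  Growth halts when *any* enabled rule triggers.

All dispersion comparisons are non-strict (``node stat <= theta * total
stat``), so ``theta = 0`` halts only exactly-constant nodes and ``theta = 1``
makes the comparison trigger whenever the node statistic does not exceed the
total.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import ConfigurationError, DatasetSummary, percentile, population_variance

__all__ = [
    "RULE_KINDS",
    "StoppingConfig",
    "StopDecision",
    "node_dispersion_halt",
    "split_respects_leaf_size",
    "explain",
]

#: canonical rule names used by sweeps and the CLI
RULE_KINDS = ("variance", "range", "icr", "parent", "leaf")


@dataclass(frozen=True)
class StoppingConfig:
    """Which stopping criteria are enabled and their thresholds.

    ``None`` disables a criterion; at least one must be enabled.
    """

    theta_variance: float | None = None
    theta_range: float | None = None
    theta_icr: float | None = None
    icr_centile: float = 25.0
    min_parent_size: int | None = None
    min_leaf_size: int | None = None

    def __post_init__(self) -> None:
        enabled = [
            self.theta_variance,
            self.theta_range,
            self.theta_icr,
            self.min_parent_size,
            self.min_leaf_size,
        ]
        if all(v is None for v in enabled):
            raise ConfigurationError("at least one stopping criterion must be enabled")
        for name in ("theta_variance", "theta_range", "theta_icr"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.icr_centile < 50.0:
            raise ConfigurationError(f"icr_centile must lie in (0, 50), got {self.icr_centile}")
        if self.min_parent_size is not None and self.min_parent_size < 2:
            raise ConfigurationError("min_parent_size must be >= 2")
        if self.min_leaf_size is not None and self.min_leaf_size < 1:
            raise ConfigurationError("min_leaf_size must be >= 1")

    @classmethod
    def single_rule(cls, kind: str, value: float, icr_centile: float = 25.0) -> "StoppingConfig":
        """Config with only one criterion enabled — what threshold sweeps use."""
        if kind == "variance":
            return cls(theta_variance=float(value))
        if kind == "range":
            return cls(theta_range=float(value))
        if kind == "icr":
            return cls(theta_icr=float(value), icr_centile=icr_centile)
        if kind == "parent":
            return cls(min_parent_size=int(value))
        if kind == "leaf":
            return cls(min_leaf_size=int(value))
        raise ConfigurationError(f"unknown rule kind {kind!r}; expected one of {RULE_KINDS}")

    def centiles_needed(self) -> tuple[float, ...]:
        return (self.icr_centile,) if self.theta_icr is not None else ()


@dataclass(frozen=True)
class StopDecision:
    """Outcome of the pre-split halting check at one node."""

    halt: bool
    triggered: frozenset[str]

    def __post_init__(self) -> None:
        if self.halt != bool(self.triggered):
            raise ValueError("halt must hold exactly when some rule triggered")


def node_dispersion_halt(
    node_outcome: np.ndarray,
    summary: DatasetSummary,
    config: StoppingConfig,
) -> StopDecision:
    """Pre-split halting decision for a node (criteria a-d).

    A degenerate total statistic of 0 is well defined: the rule reduces to
    "node statistic <= 0", so a constant training outcome halts at the root.
    """
    y = np.asarray(node_outcome, dtype=np.float64).ravel()
    if y.size < 1:
        raise ValueError("node outcome must be nonempty")
    triggered = set()
    if config.theta_variance is not None:
        if population_variance(y) <= config.theta_variance * summary.total_variance:
            triggered.add("variance")
    if config.theta_range is not None:
        if float(np.max(y) - np.min(y)) <= config.theta_range * summary.total_range:
            triggered.add("range")
    if config.theta_icr is not None:
        x = config.icr_centile
        node_icr = percentile(y, 100.0 - x) - percentile(y, x)
        if node_icr <= config.theta_icr * summary.icr_for(x):
            triggered.add("icr")
    if config.min_parent_size is not None and y.size < config.min_parent_size:
        triggered.add("parent_size")
    return StopDecision(halt=bool(triggered), triggered=frozenset(triggered))


def split_respects_leaf_size(left_n: int, right_n: int, config: StoppingConfig) -> bool:
    """True iff a candidate split obeys the minimum leaf size (criterion e)."""
    if left_n < 1 or right_n < 1:
        raise ValueError("both children must be nonempty")
    if config.min_leaf_size is None:
        return True
    return min(left_n, right_n) >= config.min_leaf_size


def explain(config: StoppingConfig) -> str:
    """Stable human-readable description of the enabled criteria."""
    lines = []
    if config.theta_variance is not None:
        lines.append(
            f"halt when node variance <= {config.theta_variance:g} x total variance"
        )
    if config.theta_range is not None:
        lines.append(f"halt when node range <= {config.theta_range:g} x total range")
    if config.theta_icr is not None:
        x = config.icr_centile
        lines.append(
            f"halt when node {x:g}-{100 - x:g}% intercentile range <= "
            f"{config.theta_icr:g} x total {x:g}-{100 - x:g}% intercentile range"
        )
    if config.min_parent_size is not None:
        lines.append(f"parent node size >= {config.min_parent_size} required to split")
    if config.min_leaf_size is not None:
        lines.append(f"every leaf must keep >= {config.min_leaf_size} observation(s)")
    return "\n".join(lines)
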