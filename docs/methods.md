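# Methods

## Model

`stopforest` fits regression random forests: an ensemble of `ntree` CART-style
binary regression trees, each grown on an independent uniform bootstrap sample
of size *n* drawn with replacement from the training data, with `mtry`
candidate features drawn uniformly without replacement at every node.  The
forest prediction for a row is the unweighted mean of the tree predictions;
each tree predicts the mean outcome of the leaf the row routes to (routing
convention: feature value ≤ threshold goes left, including exact equality).

Split search is standard CART for regression: among candidate thresholds at
midpoints of adjacent distinct sorted values of each candidate feature, choose
the split minimising the total within-child sum of squared deviations
(equivalently maximising the between-child SSE reduction).  Ties in the
reduction break lexicographically by (feature index, threshold).  A split must
strictly reduce the SSE; a node with no admissible strictly-improving split
becomes terminal.  The split search is unweighted, as is bootstrap sampling —
observation weights enter only the error metric (below).

## Stopping rules

What distinguishes the model is how tree expansion is halted.  Five criteria
are available, and growth below a node stops as soon as *any* enabled one
triggers:

| rule | trigger |
|---|---|
| variance | node outcome variance ≤ θ_var × variance of the outcome in the total training set |
| range | node outcome range ≤ θ_range × total range |
| intercentile range | node [X, 100−X]% intercentile range ≤ θ_icr × the total-set value (X = 10 or 25 conventionally; any X ∈ (0, 50)) |
| parent size | node holds fewer than `min_parent_size` observations |
| leaf size | a candidate split is invalid if either child would hold fewer than `min_leaf_size` observations |

The first four are pre-split halts; the leaf-size rule instead constrains the
candidate set, and a node with no valid candidate becomes terminal.  Parent-
and leaf-size limits are *not* equivalent: leaves of size ≥ *n* force every
split parent to size ≥ 2*n*, but a parent-size limit of 2*n* still admits
splits as unbalanced as 1/(2*n*−1).  The test suite constructs such an
instance explicitly.

Dispersion comparisons are non-strict (≤), so θ = 0 halts only
exactly-constant nodes and θ = 1 forces a halt whenever the node statistic
does not exceed the total-set statistic.  Node statistics are computed on the
in-bag observations in the node; the "total" statistics are computed once per
fit on the full, un-bootstrapped training outcome.  One consequence worth
knowing: a bootstrap sample's variance or intercentile range can *exceed* the
full-sample value, so θ_var = 1 or θ_icr = 1 does not mathematically guarantee
root-only trees inside a forest — θ_range = 1 does, because an in-bag range
can never exceed the total range.  The closed-form root-only identities in the
tests use the range rule at the forest level for exactly this reason.

`maxnodes` caps the number of terminal nodes per tree.  Expansion is
breadth-first (FIFO), and a node is made a leaf if splitting it would push the
prospective terminal count above the cap; breadth-first order makes the cap's
effect deterministic and reproducible.

## Evaluation protocol

The error metric is the weighted mean square prediction error,
MSPE = Σ wᵢ(yᵢ − ŷᵢ)² / Σ wᵢ, with weights taken from the *evaluated* rows
(all 1 when the data carry no weights).  Cross-validated MSPE uses a seeded
uniform k-fold partition (fold sizes differ by at most one) and is *pooled*:
weighted squared errors and weights accumulate over all folds and are divided
once, which is invariant to fold-size imbalance, unlike the mean of per-fold
MSEs.

Each stopping rule is tuned by sweeping its threshold over a grid, with only
the swept criterion enabled, at ntree = 1000 and maxnodes = 1000, and
reporting the curve and its minimum (minMSPE; ties toward the smaller
threshold).  Default grids: parent sizes {2, 5, 10, 25, 50, 100}, leaf sizes
{1, 2, 5, 10, 25, 50} (bracketing the common regression default of 5), and
proportions {0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5} for the three
dispersion rules.  `relative_excess` converts a rule × dataset minMSPE matrix
into the percentage excess of each rule over the per-dataset best,
100·(value/column minimum − 1).

## Numerical choices

* **Percentiles** are type 7 (linear interpolation between order statistics,
  the most common default).  The dataset-level summaries use the same
  compiled routine as the per-node statistics, so a node identical to the
  summarised vector compares exactly equal at θ = 1 — the limit cases are
  exact, not approximate.
* **Variance** uses the population divisor *n*; the rules compare a ratio of
  variances, so the divisor cancels as long as both sides use the same one.
* **Split-score ties.** The comparison score S²_L/n_L + S²_R/n_R of two
  mathematically equal candidates can differ by a rounding error when the
  terms decompose differently.  A candidate must therefore beat the incumbent
  by a relative tolerance of 1e-10 to replace it, so equal-score candidates
  tie robustly and the lexicographic break applies; the same tolerance guards
  the strictly-positive-reduction requirement.  Genuinely distinct scores on
  the kinds of few-valued outcomes where exact ties arise differ by many
  orders of magnitude more than this.
* **Thresholds** at midpoints are nudged down to the lower neighbour when the
  midpoint rounds up to the upper value (adjacent floats), so routing by
  ``x ≤ threshold`` reproduces the enumerated partition exactly.
* **Seeding.**  Tree *t* of a forest draws its bootstrap and feature
  subsamples from a stream seeded by `(seed, t)` (numpy `SeedSequence`), so
  results do not depend on growth order.  CV folds and sweep grid points
  derive per-unit forest seeds the same way.  Same seed ⇒ bit-identical
  forest.
* **Degenerate inputs.**  A constant-outcome node is terminal (no split can
  reduce its SSE); a constant training outcome makes every dispersion rule's
  total statistic 0, reducing the trigger to "node statistic ≤ 0", so the
  root halts immediately.

## Synthetic data

Three generators make every stage testable without external data:

* `gen_piecewise` — a step function of one uniform feature plus Gaussian
  noise; with zero noise the true tree structure is known and exactly
  recoverable, and a root-only fit's error equals the outcome's population
  variance.
* `gen_friedman1` — the standard nonlinear benchmark
  y = 10 sin(π x₁x₂) + 20(x₃ − 0.5)² + 10x₄ + 5x₅ + ε with ten uniform
  features, five of them inert; noiseless values are known in closed form.
* `gen_oracle_suite` — tiny datasets (n ≤ 30, p ≤ 4) mixing continuous and
  few-valued numeric columns with *integer* outcomes, for node-for-node
  equivalence sweeps against an exhaustive-search CART oracle that scores
  candidates in exact rational arithmetic.  Integer outcomes make candidate
  sums exact in floating point, so score ties are real and the tie-break
  logic is genuinely exercised.

These fixtures share none of the marginal structure of real survey or
benchmark data (no skewed outcomes, no correlated features, no survey
weights), so passing tests demonstrate algorithmic correctness and protocol
behaviour, not field performance.

## Scale of the shipped checks

The test suite and the acceptance script run the full tuning protocol
(ntree = 1000, maxnodes = 1000, mtry = 7, tenfold CV, default grids) on the
Boston Housing data (506 tracts, outcome: per-capita crime rate, 13
features), loaded at run time from the R `MASS` package; a full leaf-size
sweep takes about 90 s on one CPU.  Synthetic demonstrations use n = 120–300
and ntree = 25–100, sizes at which forest behaviour (variance reduction,
tuning curves) is already stable.  The loaders for the other classic
benchmark tables (MIT Servo rise-time, Tasmanian Abalone, Los Angeles Ozone,
NHANES glycohemoglobin) expect user-supplied CSVs, since those tables are not
redistributable with the package; the Servo reproduction checks run — and
currently fail — until such a file is supplied at `data/servo.csv`.

## Known limitations

* Categorical features must be numerically coded by the caller; splits treat
  all columns as ordered numeric.  (Dedicated categorical coding was
  deliberately left out.)
* No out-of-bag error machinery; evaluation is by held-out test set or CV.
* Observation weights support a single weight column; no survey-design
  (strata/PSU) handling.
* Classification losses (Gini, cross-entropy) are out of scope.
* Missing values are handled by dropping incomplete rows at load time, with a
  logged count; there is no imputation or surrogate-split support.
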