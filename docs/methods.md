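# Methods

This note records the models implemented, the defaults and why, the design
choices made where the approach was genuinely open, and what the synthetic
study conditions do and do not establish about real telemonitoring data.

## Models

### Learning vector quantization

Prototypes are trained online: one pass per epoch over a seeded shuffle of
the rows; the winner (nearest prototype, ties to the lowest index) moves
toward the sample by its learning rate. Four modes:

- `lvq1_supervised` — labelled prototypes, attraction on label match and
  repulsion on mismatch, one global rate decaying linearly,
  η(t) = η₀(1 − t/T) over total presentations. The printed source of the
  update rule lists the same label condition on both branches, which is
  internally inconsistent; the accompanying prose (repel when classes
  differ, non-winners frozen) is what is implemented.
- `olvq1_supervised` — per-prototype rates η_j ← min(η_j/(s·η_j + 1), η_max)
  with s = +1 on match and −1 on mismatch.
- `unsupervised_vq` (default) — the OLVQ1 machinery with s ≡ +1: pure
  attraction with per-prototype harmonically decaying rates. This is online
  vector quantization and is how the pipeline clusters unlabelled feature
  data. With one prototype and s ≡ +1 the update is a stochastic
  approximation of the mean, so the prototype converges to the data mean.
- `unsupervised_vq_global` — attraction-only with the global decaying LVQ1
  rate; provided so the method comparison has an unsupervised LVQ1
  counterpart to the unsupervised OLVQ1 mode.

Defaults: J = 9 (the cluster count used for the telemonitoring data),
η₀ = η_max = 0.3, 100 epochs. All overridable.

**Initialization.** Prototypes are seeded samples of data rows. Plain
uniform sampling of J distinct rows leaves a substantial chance (≈ 78% for
J = K = 3 equal blobs) that some well-separated cluster starts without a
prototype, and attraction-only updates with decaying rates cannot recover
from that, so the default is distance-weighted sampling (each next row is
drawn with probability proportional to its squared distance from the
prototypes chosen so far) plus `n_init = 4` restarts keeping the codebook
with the lowest final mean quantization error. `init="sample"` restores
uniform row sampling. Everything is driven by a single seed; identical
(data, config) runs are bit-identical.

### ANFIS

First-order Takagi–Sugeno system; product t-norm; normalized firing
strengths; linear consequents; weighted-sum output. Four membership
families with the usual parameterizations: triangular (a ≤ b ≤ c),
trapezoidal (a ≤ b ≤ c ≤ d), generalized bell (width a > 0, slope b > 0,
center c), Gaussian (center, σ > 0).

**Grid initialization.** Per input, `mfs_per_input` (default 3) centers
are evenly spaced over [min, max] of the training rows with widths chosen
so adjacent functions cross near degree 0.5 (Gaussian σ = Δ/(2√(2 ln 2)),
bell a = Δ/2 with slope 2, triangular feet at the neighbouring centers,
trapezoidal shoulders at ±Δ/4 and feet at ±3Δ/4). The outermost
triangular/trapezoidal functions are shoulder-clamped to 1 beyond the data
range so the training hull is always covered; queries outside the support
of every rule raise a degenerate-coverage error rather than silently
extrapolating from nothing. Grid rule bases enumerate all mᵖ antecedent
combinations and are refused beyond `max_grid_inputs = 6` inputs (3¹⁶ ≈
4.3×10⁷ rules for the full feature set is infeasible); the scatter
alternative places one rule per seeded vector-quantization cluster of the
inputs (default `scatter_rules = 9`), with per-rule widths from
within-cluster spread.

**Numerics of the forward pass.** Firing strengths are products of up to p
membership degrees; for tail queries in high dimension these underflow
double precision. Normalized strengths are therefore computed in log space
(per-row shift by the log-maximum before exponentiation), which is exact up
to floating rounding because layer 3 only needs relative magnitudes.

**Hybrid training.** Per epoch: (1) ridge least squares for all consequents
with premises frozen — the design row for sample i concatenates
w̄_r(x_i)·[x_i, 1] over rules; solved by LAPACK least squares on the
ridge-augmented system (default λ = 10⁻⁸, minimum-norm with a warning when
unridged and rank-deficient); (2) one batch gradient step on the
sum-of-squared-errors with respect to membership parameters, analytic for
Gaussian and bell, subgradient (zero at kinks and on shoulder plateaus) for
the piecewise-linear families, with step halving (up to 12 halvings from
`premise_step = 10⁻³`) whenever the step would increase the SSE, and
sort-and-clip constraint repair afterwards (σ and bell width floored at
10⁻⁶ of the feature range). A final least-squares solve leaves consequents
optimal for the final premises. The per-epoch training-RMSE log is
non-increasing by construction. The default is 200 epochs, the training
length used for the telemonitoring models this package re-implements;
the tests and the acceptance script use 8–20 epochs, which is
already well past the point of diminishing returns at their problem sizes
(a few hundred to two thousand rows, 3–9 rules) — deliberately small,
reproducible study conditions, not a statement about real-data needs.

### Combined model and evaluation

`fit_combined` clusters the training rows (unsupervised OLVQ1 by default),
then trains one ANFIS per cluster and routes queries to the nearest
prototype's expert. Two guards keep the per-cluster least-squares solves
well posed:

- clusters with fewer than `min_cluster_size` rows (default
  max(30, 3 × rule count)) are merged into the cluster of the nearest
  prototype before any expert is trained;
- each expert's partition granularity is reduced until it has at least ten
  rows per consequent coefficient (the usual one-in-ten sizing rule),
  bottoming out at a single rule, i.e. a local linear model. Without this,
  grid rules that fire on (almost) no training rows receive arbitrary
  consequents and produce unbounded extrapolation for held-out rows near
  cluster boundaries — the failure mode is catastrophic (order-of-magnitude
  RMSE inflation), which is why granularity adapts to the data rather than
  being fixed.

Cross-validation is whole-pipeline: the seeded shuffle-then-chunk splitter
produces k folds (sizes differing by at most one), and clustering plus all
experts are refit on every training split, so no information from held-out
rows reaches any training stage. A per-cluster reading of the protocol —
evaluating each expert within its own cluster — would leak the cluster
assignment of test rows into training and is the likely source of
near-perfect published figures; it is not the default anywhere in this
package. `compare_methods` reuses identical folds across method
specifications so comparisons are paired. R² follows the coefficient of
determination about the mean of the actuals and may be negative; it is
reported, not clipped.

Targets are fit independently (one combined model per target), and each
expert's seed is derived from the configured seed plus its cluster index,
so whole reports are reproducible byte for byte.

## Synthetic study conditions

`SyntheticSpec` draws K isotropic Gaussian feature blobs (rejection-sampled
centers at pairwise distance ≥ `center_separation`) and gives each cluster
its own input→output map plus additive Gaussian output noise. Defaults: K =
3 clusters, d = 2 inputs, 650 rows per cluster (the scale of the clusters
a nine-way segmentation of the 5875 real recordings produces, 264–995 rows
with mean ≈ 653), separation 12 with within-cluster sd 1
(separability ratio 12), per-cluster nonlinear Sugeno-type generators (grid
membership functions over the cluster's ±3 sd box, seeded random
consequents, cluster offsets 20 apart), noise sd 0.5. The generator returns
the true labels, generator parameters, and noiseless outputs, so tests can
compare against the Bayes-optimal RMSE (= noise sd) rather than against
tuned expectations. `generator="linear"` substitutes pure linear
per-cluster maps.

`make_telemonitoring_like` draws 16 features as independent truncated
Gaussians matched to the published per-feature min/max/mean/sd of the UCI
telemonitoring table, with two pseudo-UPDRS targets from a hidden
nine-regime map. It exists so the command-line workflow can be exercised
end to end without a download.

What these conditions do not emulate: the strong collinearity of
jitter/shimmer variants in real voice data (features are independent within
clusters; a covariance hook exists), subject-level repeated-measure
structure, non-Gaussian feature tails, and any genuine physiology of
dysphonia. Consequently, green tests here establish the algorithmic claims
(correct updates, oracle-equivalent solves, recovery under the assumed
mixture structure, the qualitative advantage of clustering when regimes
differ) — not clinical performance on real recordings.

The recovery tests deliberately sample inputs covering the generator's
exact box (corners included), so grid initialization on the sample starts
from the generating premises and noiseless training RMSE measures the
solver, not initialization luck.

## Known limitations

- Scatter partitioning ties every input's membership function to the same
  rule index (axis-aligned cluster rules); no subtractive clustering.
- Premise training of piecewise-linear families uses subgradients; their
  parameters move little in practice and may sit at kinks.
- The evaluation splitter ignores subject identity; for real repeated-
  measure data a grouped split would be more conservative.
- The published real-data comparison is not reproduced quantitatively —
  target scaling, evaluation scope, and the rule-generation strategy for 16
  inputs are unstated in the source description; `scripts/replicate_comparison.py`
  provides a transparent, leakage-free attempt for users who download the
  data.
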