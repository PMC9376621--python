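# Methods

This note documents the model implemented by `dsanfis`, the numerical and
design choices that were genuinely open, what the synthetic generators do
and do not emulate, and the package's known limitations.

## Model

### Affinity graph

Rows of the normalized feature table are graph nodes; edge weights are
Gaussian affinities `a_ij = exp(−d²_ij/σ²)` with `d²_ij` the squared
Euclidean distance over all predictors and zero diagonal (no self-loops).
Binary-encoded categoricals (e.g. Gender) enter the distance as ordinary
0/1 coordinates; with a small bandwidth this effectively stratifies
clusters by the categorical value, which is a property of the single-kernel
design, not a bug.

**Bandwidth.** "The variance of the pairwise distances" admits two
readings; the default (`bandwidth="auto"`) uses the population variance of
the unsquared upper-triangle Euclidean distances, with
`"auto_sqdist_var"` (variance of the squared distances) and any explicit
positive number as alternatives. The automatic rule is adaptive but can be
small when the data lack a between-cluster distance component (a single
homogeneous cloud) — σ² then undersizes the kernel and peeling fragments
the cloud. For the 7-predictor cohort-like demonstrations we therefore fix
σ² = 2.0, about twice the mean squared pairwise distance of the normalized
rows, which yields rule bases of a size (≈ 15–20 rules on 373 subjects)
comparable to what compact interpretable systems target. Identical points
under an automatic rule (zero distance variance) raise an error advising an
explicit bandwidth.

### Dominant sets and replicator dynamics

The combinatorial definition (internal weights `W_S(i) > 0`, every
nonempty subset weight positive, external extension weights non-positive)
is implemented verbatim with subset-memoized recursion — exponential in
|S|, so it serves verification, diagnostics and the brute-force enumeration
oracle only. One boundary decision: the external condition is checked as
`W_{S∪{i}}(i) ≤ tol` (tol = 1e−12). Treating exact zeros as non-extending
is required for the unweighted intuition to hold (on a path graph the two
edges are the dominant sets; on an edgeless graph each singleton is); a
strict `< 0` test leaves such tied configurations with no dominant sets at
all.

The production path maximizes `f(z) = zᵀAz` on the simplex by replicator
dynamics. Choices:

* **Start**: the barycenter `z = 1/M` — deterministic, unbiased, and makes
  the entire clustering reproducible without a seed.
* **Stopping**: objective increment `< 1e−8` or 1000 iterations (both
  exposed). The iterate is renormalized to the simplex each step to cancel
  accumulated rounding.
* **Support threshold**: `z_i > 1e−5`. The mathematical support is
  `z_i > 0`, which floating point cannot test; 1e−5 is far below the `1/|S|`
  scale of equilibrium weights for any cluster the pipeline produces.
* **Degeneracy**: if `zᵀAz = 0` (e.g. an edgeless subgraph) the dynamics
  stop flagged; extraction then falls back to a flagged singleton at the
  maximum-degree node and peeling terminates.

**Peeling** removes each extracted support from the graph (the affinity
submatrix is reused; the kernel is not recomputed) and repeats until fewer
than `min_remaining = 2` nodes remain or extraction degenerates; leftovers
form the residual clutter group. The cluster count is an outcome. The
Motzkin–Straus identity (max f = 1 − 1/ω on 0/1 adjacency, ω the clique
number) and exhaustive subset enumeration on ≤ 6-node random graphs are the
correctness oracles in the test suite.

### Rule induction

Cluster → rule: antecedent center = mean of the cluster's projection on
each attribute; width = **population** standard deviation (denominator
|S|), floored at `sigma_floor = 0.01` in normalized units because singleton
or constant projections give σ = 0 and an ill-defined membership. The
consequent is the cluster's majority class, ties broken toward the globally
more frequent training class (deterministic, maximizes prior accuracy).
The residual group becomes a rule by default (`include_residual=True`) —
it carries real subjects, just diverse ones; a flag excludes it.

### Inference and hybrid training

Memberships use the standard Gaussian form `exp(−(x−c)²/(2σ²))`
(`mf_convention="half"`); the no-½ variant `exp(−((x−c)/σ)²)` is available
as `"plain"` (the two coincide after rescaling σ by √2). Firing strengths
are product T-norms, normalized to sum to one; total underflow (an input
far from every rule) falls back to uniform weights, flagged. The output is
a convex combination of consequents; classification thresholds at 0.5 with
ties to positive, confidence `max(z, 1−z)`.

Each training epoch runs (i) an exact least-squares solve of the
consequents at fixed premises — minimum-norm via `lstsq`, which handles the
rank deficiency of identically firing duplicate rules, with a tiny-ridge
(1e−10) fallback — then (ii) one batch gradient step on centers and widths
at fixed consequents, with analytic gradients of the **mean** squared
output error (normalizing by batch size makes the learning rate independent
of the fold size). Widths are re-floored after every step; non-finite
gradients (possible when an extreme parameter excursion underflows all
firing strengths) reject the step rather than poisoning the parameters.
Defaults: 50 epochs, learning rate 0.01 — deliberately conservative; the
cohort-scale demonstrations use 100 epochs at 0.3, which on 300+-row folds
is still a small step relative to the curvature observed. Consequents are
unclamped reals after training and read as per-rule confidence levels. The
rule count and feature set are structural and never change during training.

## Preprocessing

Order matters: means for imputation are fitted on the **raw** scale, then
min-max normalization maps each attribute to [0, 1] by its fitted range.
Transform never clamps, so held-out rows may fall outside [0, 1] — that is
intentional (clamping would hide distribution shift from the kernel).
Constant columns normalize to 0.0 instead of erroring, which keeps small
CV folds alive. Correlation screening reports pairs with |r| above a
threshold (default 0.95); dropping is a user decision — for the cohort-like
table the eTIV/ASF pair is the motivating case and eTIV is dropped in the
examples. In cross-validation all statistics are fitted inside each
training fold by default (`fit_scope="train_fold"`); `"global"` reproduces
a single whole-table fit.

## Evaluation harness

Stratified k-fold splitting deals each class's shuffled indices round-robin
with a rotating offset, so per-fold class counts are within one of exact
proportionality *and* fold sizes are within one of each other (373 rows at
k = 10 gives folds of 37 or 38). Repeats reseed deterministically from
`base_seed + run`. Two spreads are reported deliberately: the SD of fold
accuracies within a run (large — fold composition varies) and the SD of the
run means (small). Pooled confusion counts across all repeats give the
aggregate precision/recall/specificity/accuracy. scikit-learn's splitter
and `confusion_matrix` appear only as cross-checks in the tests.

## Synthetic generators

`make_blobs` draws isotropic Gaussian clusters plus uniform clutter on
[0, 1]ⁿ, clipped to the cube — the geometry for which dominant-set peeling
has a sharp expected answer. Exact membership recovery (ARI = 1) is the
expected regime when blob spread is small against both the separation and
the automatic kernel scale (the packaged fixture uses spread 0.02 with
centre separations ≥ 0.45, i.e. > 20 spreads); at wider spreads the method
correctly refuses to swallow low-cohesion tail points, splitting them off
as mini-clusters, and ARI falls below 1 — a property of the model, not a
failure of the implementation.

`make_oasis_like` matches published marginal summaries of a 373-session
dementia cohort (means/SDs/ranges for Age, EDUC, SES, MMSE, eTIV, nWBV,
ASF), injects missing values into SES (19/373) and MMSE (2/373), builds
eTIV as a noisy reciprocal of ASF (|r| ≈ 0.99) to exercise the correlation
screen, and assigns the binary diagnosis by a logistic model in
standardized (−MMSE, −nWBV) with the intercept bisected so expected
prevalence matches 167/373. It emulates *marginals, missingness and one
collinear pair only*: the joint correlation structure, longitudinal visit
dependence, and the real label-generating process are not modeled. Passing
CV results on this table therefore demonstrate pipeline correctness,
determinism and a recoverable signal — they do not certify performance on
the real cohort, whose headline accuracies are not reproducible without the
original data. On this synthetic table the pipeline reaches roughly 65–73%
CV accuracy (seed-dependent) against a ≈ 55% majority baseline and ≈ 79%
for an L2 logistic reference, with the supervised ANFIS stage consistently
above the untrained cluster-rules ablation.

## Problem sizes used in the checks

The acceptance script runs the cohort arithmetic (instant), blob recovery
at 75 points, and the repeated CV at M = 373, k = 10 with 3 repetitions for
each of the tuned and ablation configurations — about half a minute in
total. The test suite's exhaustive oracles are capped where the
combinatorics demand it: subset enumeration at ≤ 6 nodes (100 random
graphs), Motzkin–Straus at ≤ 8 nodes with 30 restarts, memoization-free
weight recursion at 5-node sets.

## Known limitations

* The combinatorial weight recursion is exponential and unusable beyond
  ~12 nodes; it is verification-only by design.
* Peeling granularity is bandwidth-sensitive; there is no automatic
  bandwidth selection beyond the two variance rules.
* Binary classification only; the consequent coding assumes 0/1 labels.
* No out-of-sample cluster assignment: new subjects are classified by the
  fuzzy rules, not attached to clusters.
* First-order TSK consequents are deliberately not implemented — constant
  consequents keep each rule readable as a class vote with confidence.
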