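# Methods

## The cohort and its reconstruction

The study population behind this package is a five-year hospital cohort of
2518 admissions for acute phosphide poisoning (1330 aluminum phosphide,
1188 zinc phosphide; 1836 recovered, 682 died). Its published record
consists of two-way contingency tables: each of five predictors (age
group, sex, cholinesterase level, silver-nitrate test, mode of poisoning)
crossed once with the outcome and once with the poison type, plus the
poison × outcome joint. Patient-level data were never released, so the
package reconstructs a cohort with exactly the published low-order
structure and makes every downstream claim at that level.

**Raking.** For each predictor X, the three-way X × poison × outcome table
is completed by iterative proportional fitting from the independence seed
P(X)·P(poison, outcome), cycling over all three two-way margins until the
largest absolute margin error is below `tol` (default 1e-10, capped at
10 000 cycles; non-convergence raises with the residual error). The cycle
includes the poison × outcome margin because the table must collapse to
the published joint exactly, not only to the two predictor margins. The
IPF fixed point is the maximum-entropy (minimum-discrimination) completion
consistent with the printed margins.

**Integer reconciliation.** With binary poison and outcome, fixing all
three margins leaves one free integer per predictor level — the
(AlP, died) cell. Each raked value is floored into its feasibility
interval and the remaining mass up to the global AlP-died total (622) is
assigned by largest fractional remainder, making every margin exact. The
reconciliation is only defined (and only attempted) when the margins are
genuine integer counts.

**Combining predictors.** Predictors are drawn conditionally independently
given (poison type, outcome). This is again the maximum-entropy choice:
the published tables carry no information on predictor–predictor
association beyond what the two conditioning variables induce. Exact mode
lays out each (poison, outcome) cell with exact per-predictor level counts
(independently shuffled within the cell) and then applies one seeded
permutation to the whole cohort, so crosstabs are bit-exact and splits are
safe. Sampled mode draws cells from the poison × outcome joint and levels
from the raked conditionals.

**Ages.** Only the range 1–60 and group counts are published. Group labels
overlap in print; groups are taken half-open — `<10` → [1, 9],
`10–20` → [10, 19], …, `40–50` → [40, 49] — except `>50` → [51, 60], and
ages are uniform integers within the record's group. Reproducing the
published mean/median age is deliberately not a goal. Whether the original
model used age in years or the grouped variable is not documented; both
encodings are available (`age_encoding` in `encode_features`), with years
as the default.

**Clinical flags.** Blood pressure, pulse and echocardiography are
abnormal in 100% of deaths and 0% of survivors in the published tables;
they are generated to satisfy that identity and excluded from the feature
matrix (they would be outcome leaks). Residence and occupation are
optional cosmetic fields drawn from the published univariate proportions
(88.5% rural, 52.6% students) and never enter the features.

**What the generator does not emulate.** Any predictor–predictor
dependence beyond the conditioning structure, dose, time to admission,
treatment, temporal trends, and missingness (no missing values are ever
emitted). Consequently, classifier performance on the synthetic cohort
measures what the published margins support — not the performance
attainable on the real patient-level data, which is why pipeline
validation uses a planted-signal cohort (below) rather than a target
accuracy on the reconstruction.

## Feature encoding

Fixed column order: age, sex (male = 1), poison type (AlP = 1),
silver-nitrate (positive = 1), cholinesterase (abnormal = 1), mode
(suicidal = 1); label 1 = died. `scaling` ∈ {minmax, zscore, none}
applies to the age column; a zero-variance age column maps to zeros.

## The relevance vector machine

Binary classification with a Bernoulli-logistic likelihood over a kernel
design matrix Φ (one Gram block per kernel spec, optional leading bias
column; multiple simultaneous kernel blocks are supported, though the
default pipeline uses Bayesian optimization to *select* a single family).
Weights carry independent N(0, αⱼ⁻¹) priors. Fitting alternates:

- **Inner (Laplace/IRLS):** Newton iterations with backtracking on the
  penalized negative log-likelihood to the MAP weights; Hessian
  H = ΦᵀBΦ + diag(α) + jitter·I with B = diag(p(1−p)) clipped below at
  1e-12; posterior covariance Σ = H⁻¹ via Cholesky. Convergence at
  max |gradient| < 1e-5 or 50 iterations.
- **Outer (type-II updates):** γⱼ = 1 − αⱼΣⱼⱼ (clipped at 1e-12),
  αⱼ ← γⱼ/μⱼ²; columns with αⱼ > `prune_threshold` (default 1e12) are
  removed. Stops when max |Δ log α| < 1e-6 or after `max_outer_iter`
  rounds, followed by a final IRLS pass at the last precisions.

Defaults: `alpha_init` 1.0, `jitter` 1e-8, `max_outer_iter` 20. The outer
budget is a deliberate truncation: relevance-vector sparsity sharpens
monotonically with more evidence-maximization rounds (on the 200-point
blob benchmark, ~80% of columns survive at 20 rounds, ~10% at 200, ~5% at
500, at ~0.2 s either way), but inside a cross-validated BO loop on
thousands of records the marginal rounds cost far more than they change
the decision boundary. Runs that care about maximal sparsity should raise
`max_outer_iter`; the sparsity test in the suite does exactly that.

`max_basis` (default 600) caps the kernel basis with a seeded stratified
subsample so a fit on the 2518-record cohort stays O(600³); the full basis
is available by setting it to None. Degenerate outcomes are handled
explicitly: single-class labels raise; a model with every column pruned
predicts 0.5 everywhere. Prediction is p = σ(Φ_active μ) at the fixed 0.5
threshold (the posterior mode, matching the single published confusion
matrix; no threshold tuning, no predictive-variance moderation).

With the outer loop disabled (`max_outer_iter=0`) the fit is an
L2-penalized kernel-logistic regression at fixed α, which is how the MAP
step is validated against a dense grid-search oracle.

**Fitness.** The BO objective is the stratified k-fold cross-validated
misclassification rate (default 5 folds; the large planted-signal runs use
3 as a desk-scale choice), computed on the training partition only — the
held-out test split never influences kernel selection.

## Kernels

gaussian exp(−γ‖u−v‖₂²), laplacian exp(−γ‖u−v‖₁), polynomial
(γ⟨u,v⟩+c)ᵈ with d ∈ [1,5], sigmoid tanh(γ⟨u,v⟩+c). The γ-multiplies-
distance parameterization is the common convention; since γ is searched on
a log scale the convention is absorbed by the search. The sigmoid kernel
is indefinite; nothing in the fit assumes positive-definite Gram matrices
(the Newton Hessian is positive definite regardless).

## Bayesian optimization

Search space: kernel family (categorical over the four families), γ
log-uniform on [1e-3, 1e3], coef0 uniform on [−5, 5], degree integer
{1…5}; coef0/degree are carried for every configuration but only act for
the families that use them. Encoded coordinates: one-hot family block plus
continuous/integer dimensions rescaled to [0, 1] (log10 first for γ).

Surrogate: zero-mean GP on standardized objectives with covariance
amp² · Matérn-5/2(per-dimension length-scales over the non-categorical
block) · exp(−θ · [families differ]) plus a noise term (floor 1e-6).
Hyperparameters maximize the log marginal likelihood (L-BFGS-B, bounded
log-parameters, one fixed + two random restarts, seeded). A degenerate
history (all configurations identical) falls back to the prior with a
warning.

Acquisition: expected improvement for minimization, EI = (y*−μ)Φ(z) +
σφ(z), with EI = max(y*−μ, 0) at σ = 0; maximized over 2048 seeded random
candidates (robust in the mixed space, deterministic under the seed, ties
to the first maximizer). The loop evaluates `n_init` = 8 random
configurations then alternates surrogate fit / proposal / evaluation until
`max_iter` = 40 total evaluations or an observed objective reaches
`target_fitness`. A configuration whose evaluation raises is recorded as
failed with objective worst-so-far + 0.1 and never aborts the run. The
best-so-far trace is non-increasing by construction. Although the generic
acquisition formalism is often written as argmax over a utility, the
implementation minimizes classification error throughout (y* = min yₙ).

## Experiment pipeline

Cohort → chi-square battery → encoding → stratified split → BO → refit →
test evaluation → JSON report. The 80:20 split uses per-class
largest-remainder rounding (2518 records → 504 test: 367 recovered + 137
died) and a seeded permutation; whether the original split was stratified
is undocumented, and stratification is the defensible default for a 27%
event rate. One master seed fans out through `numpy.random.SeedSequence`
children to the generator, the planted-signal noise, the split, RVM basis
subsampling and BO, so reports are byte-identical across runs with the
same config. The report echoes the config, the full BO history and trace,
the test confusion matrix and metrics (undefined 0/0 metrics as null), the
chi-square battery, and library versions; `report_schema.json` documents
its shape and `validate_report` enforces the required keys and ranges.

## Descriptive statistics

Pearson chi-square without continuity correction — the uncorrected form is
what reproduces the published 2×2 statistics (e.g. poison × outcome
552.94, silver-nitrate × poison 2151.52); two printed values (5.26, 1.29)
are truncations of 5.2653 and 1.2963, so reproduction is asserted within
0.01. ROC AUC is the rank-based Mann–Whitney statistic with average ranks
(ties count half). Spearman is the Pearson correlation of mid-ranks.
Published per-variable Spearman coefficients and the cholinesterase
regression require raw per-record values that were never printed; the
Spearman operation is provided as plumbing only.

## Validation strategy and limitations

Because the real cohort's patient-level data (and hence its reported ~97%
test accuracy) are unobtainable, pipeline correctness is established by
construction-level checks instead: generator crosstab exactness; EI
against a 10⁶-draw Monte-Carlo integral; BO recovery of a known quadratic
minimum (median error over 10 seeds); RVM reduction to a grid-search
logistic oracle; and an end-to-end run on a cohort with a planted rule
(died iff silver-nitrate positive and cholinesterase abnormal, 5% label
flips) where test accuracy ≥ 0.9 demonstrates structure recovery — the
noise ceiling is 0.95. On the maximum-entropy reconstruction itself the
pipeline reaches roughly 0.84 accuracy / 0.87 AUC, a measure of what the
published margins alone support rather than of the method.

Problem sizes used by the shipped validation runs: the planted-signal run
uses the full 2518 records, 3-fold CV fitness, 40 BO evaluations and
max_basis 600; the quadratic benchmark uses 30 evaluations × 10 seeds;
oracle checks run at n ≤ 50. These are the package's desk-scale defaults
and are configurable.
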