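# Methods

## Model and pipeline

The package treats a multi-compartment aging study as six independent
"blocks" — compartment x omic abundance matrices (samples x features,
log-scale relative abundance) — joined to one subject metadata table (age,
sex, race, BMI, clinical covariates) by sample ID. The analysis proceeds:
QC → per-feature cross-sectional age association → per-block
cross-validated elastic-net age clock → aging scores and composites →
clinical-correlate screen → signature validation.

### Quality control

Features measured below the limit of detection in strictly more than 70%
of samples are removed (`preprocess.filter_lod`; values below LOD but
retained keep their reported values, following affinity-proteomics
convention — a config switch can set them to missing instead). Assays with
a standardized negative-control deviation strictly above the ensemble mean
+ 4 SD are removed (`qc_exclude_assays`; population SD, ddof = 0 — note
that with fewer than ~17 assays the maximum standardized deviation is
below 4, so the rule can only bite in wide panels). Synthetic cohorts
carry no plate controls, so this step is an identity with a logged notice.
A per-block standardized PCA provides sample-outlier and variance
overviews; blocks that share a feature panel can be stacked into one PCA
for compartment-separation views.

### Per-feature age association

OLS of each feature on age plus covariates (sex, race, BMI by default),
two-sided t-test on the age coefficient, BH step-up across the features of
a block. Features sharing the complete design are fit in one vectorised
solve; features with censored entries are fit per-feature on complete
cases (skipped below parameters + 1 observations). Constant covariates
(e.g. a single-level race stratum in a small cohort) are dropped with a
warning. "Age-associated" defaults to BH q < 0.05; raw p is available via
a config switch since discovery-cohort practice varies.

### Elastic-net clock

For each (α, λ) grid point, `n_runs` repetitions of a fresh k-fold
partition; per fold, features are standardized by training-fold statistics
only and missing entries imputed to the training mean (fold-honest
imputation); the coordinate-descent elastic net (scikit-learn, glmnet
parameterisation) fits the training folds and predicts the held-out fold,
so each subject is predicted exactly once per run. OOB mean/SD aggregate
over runs; `QF = Pearson corr(age, OOB mean)`.

Nulls: within each run, `n_perm` whole-cohort permutations of the response
are pushed through the identical partition and fitting procedure. The
model p-value is the +1/+1-corrected rank of the observed QF among the
`n_runs·n_perm` null QFs. Per feature, two statistics are tracked — the
selection frequency (fraction of run x fold fits with a nonzero
coefficient) and the mean coefficient over fits where selected — each with
an empirical p-value counting null models whose per-model statistic
reaches the observed one (ties counted, hence conservative; the observed
statistic aggregates all runs while each null model spans one run's folds,
which makes the frequency p additionally conservative).

Numerical choices:

- λ path: per α, 20 (default) log-spaced points descending 3 decades from
  the data-driven λ_max (smallest λ with an all-zero lasso solution;
  α floored at 10⁻³ for the ridge end). Coordinate descent is warm-started
  along the descending path and reuses a per-fold Gram matrix. Pure ridge
  (α = 0) is solved in closed form.
- Model selection: argmax of QF with ties broken toward larger λ, then
  larger α (the sparser model). Ties are taken within a 10⁻⁴ QF window:
  exact float ties never occur, and without the window a flat QF-vs-λ
  profile resolves to the densest end of the path, where the frequency
  statistic saturates at 1 for signal and null models alike.
- Sex enters every clock as an ordinary penalized feature (plain elastic
  net has no forced-in covariates; the risk is that sex can be shrunk
  away, which is acceptable for a covariate of small effect).
- Full-scale schedule: 500 runs of fivefold CV with 125 permutations per
  run. Tests and drivers use reduced schedules (stated per experiment);
  the structure is identical and seeded per run
  (`default_rng([seed, 9173, run])`), so partitions are reproducible and
  independently reconstructible.
- Degenerate inputs: constant response and k > n are errors; zero-variance
  features are dropped with a warning and reported with frequency 0.

### Aging scores

Raw score = residual of OOB mean prediction on the cohort OLS line of
prediction vs age. Residualizing (rather than predicted − chronological
age) absorbs calibration bias and regression-to-the-mean compression; the
scores sum to zero by construction. Scores are z-scored per block over
non-missing subjects (zero-variance columns are an error), flagged
accelerated/decelerated at |z| > 1.5, and averaged within compartments
across the available omics (z-scores rather than raw years, so omics with
different prediction-error scales contribute equally; a compartment score
is missing only when both omics are). Score concordance uses Pearson
correlation on pairwise-complete subjects (≥ 3 required; Spearman by
flag). The z-transform is applied to the residual scores; whether to
standardize before or after residualization is immaterial for flags since
residualization is linear.

### Clinical correlates

Subjects scored in at least 4 of the 6 blocks enter the screen. Each
(composite score, covariate) cell: Spearman rho and two-sided p on
pairwise-complete data (≥ 5 pairs), no multiplicity correction, relaxed
p < 0.10 reporting threshold with star tiers (·/*/**/*** at
0.10/0.05/0.01/0.001). Covariates flagged for adjustment (stature-dependent
walk metrics, adjusted for height) use a partial Spearman: rank-transform
both variables (average ranks), residualize each on the ranked adjusters
by OLS — symmetric in the two variables — and test the Pearson correlation
of residuals with a t-approximation at df = n − 2 − (#adjusters).

### Signature validation

The selected signature (features passing the frequency-p filter, ordered
by selection frequency; if a reduced permutation schedule leaves the
filter empty, the top-25 features by frequency) is refit without
regularization by leave-one-out OLS — "GLM" read as Gaussian/identity
since age is continuous — and summarized by corr(age, LOOCV predictions).
By default the refit uses signature features only (a flag adds
covariates). Rank-deficient designs fall back to a 10⁻⁸ ridge with a log
notice. Cross-platform transfer is emulated by a case-normalized exact-ID
intersection of the signature with a target catalog.

## The synthetic cohort generator

`synthetic.simulate_cohort` draws, per block b, feature j, subject i:

    x_bij = β0_bj + β_bj·(age_i + loading_b·δ_i) + γsex_bj·sex_i
            + γbmi_bj·BMI_i + ε_bij

- δ_i ~ N(0, σ_δ), σ_δ = 5 years, independent of age — the minimal latent
  structure consistent with residual-based aging scores. One shared factor
  with per-block `loading` lets both one-factor and decoupled regimes be
  simulated.
- Ages are drawn uniform-within-bin from the demographic bins
  23/20/18/28/12 over 22–34/35–49/50–64/65–79/80–92 (n = 101); sex ~
  Bernoulli(0.55), race ~ Bernoulli(0.82), BMI ~ N(25.6, 3) truncated to
  [18, 30] — a healthy-cohort profile.
- A fraction `frac_age_assoc` of features get nonzero slopes
  |β| ~ |N(0.03, 0.015)| log-units/year (floored at 0.0075), 70% positive
  ("over-represented"); the defaults per block follow observed
  cross-sectional detection rates (≈ a third of plasma proteins, ≈ a tenth
  of urine proteins age-associated). Residual noise ε ~ N(0, 0.5).
- Per-feature censoring at the `lod_quantile` (default 5%) marginal
  quantile; censored values are stored as missing plus a boolean mask
  (imputation policy belongs to the consumer).
- Blocks cover different subject subsets (`frac_subjects`, e.g. 50% for
  muscle proteomics), so missing-data handling in composites and the
  ≥ 4-block filter is exercised.
- Clinical covariates = baseline(age, sex) + loading·δ + noise, with signs
  matching aging physiology: hemoglobin-like and strength-like negative,
  alkaline-phosphatase-like positive, height uncoupled (adjustment
  covariate), walk-speed mildly negative.

What the generator does **not** emulate: assay chemistry and count noise,
realistic feature–feature correlation networks (features are conditionally
independent given age, δ, sex, BMI), longitudinal visits beyond
independent redraws of the same truth, batch/plate structure, and
non-linear age trajectories. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under the stated
generative model — not that any particular biological finding transfers to
real cohorts.

## Validation experiments (`omicage.evaluation`)

Problem sizes were chosen so each experiment finishes in minutes on one
CPU while keeping the estimand identifiable:

- **OLS degeneracy**: α = 0, λ = 10⁻¹⁰, n = 60 > p = 10; OOB must match
  independent k-fold `LinearRegression` predictions to < 10⁻⁶.
- **Null calibration**: 20 replicates, n = 80, p = 300 pure noise,
  response permuted before entry; 20 runs x 25 permutations; the fraction
  of model p ≤ 0.05 must not exceed 0.10 (empirical p-values are valid but
  conservative).
- **Planted signal**: one feature = age + N(0, 2) among 49 noise features,
  n = 100; QF > 0.95 and selection frequency > 0.9 at the selected model.
- **FDR control**: 20 pure-null blocks (n = 100, p = 2000); mean realized
  false-discovery proportion at q < 0.05 within Monte-Carlo margin
  (2·√(0.05·0.95/20) ≈ 0.10) of 0.05.
- **Parameter recovery**: the six default blocks at full default
  dimensions, loading 1, σ_δ = 5; clocks at α ∈ {0.1, 0.5}, 5-point λ
  path, 20 runs. The overall composite z-score must correlate > 0.8 with
  the true δ and all cross-block score correlations must clear the n ≈ 50
  null 95th percentile. Shrinking the blocks further would starve the
  small metabolomic blocks of signal features and make δ unidentifiable
  per compartment — the block dimensions are part of the experimental
  conditions, not a tuning knob.
- **Flag tail**: 10⁵ standard-normal scores; flag rate within ±0.01 of
  2·(1 − Φ(1.5)) = 0.1336.
- **Fixtures**: 6-point score residualization and 4-point LOOCV match
  closed forms to 10⁻¹².
- **Determinism**: the smoke pipeline (n = 60, three blocks) run twice
  with one seed produces byte-identical outputs (SHA-256 per file).

## Known limitations

- The frequency-based feature p-value is uninformative when the selected λ
  is small enough that null models select most features in most folds (the
  statistic saturates at 1 on both sides and ties are counted
  conservatively); the coefficient-based p-value discriminates in that
  regime and both are always reported.
- Empirical p-value resolution is 1/(n_runs·n_perm + 1); reduced schedules
  bound how small a reported p can be.
- The clock penalizes sex like any feature rather than forcing it in.
- Partial Spearman p-values rely on a t-approximation after rank
  residualization; exact permutation p-values are not implemented.
- The generator's conditional independence of features given the latent
  structure understates the effective multiplicity correlation of real
  panels; FDR calibration on real data may differ.
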