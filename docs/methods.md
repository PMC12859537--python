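# Methods

## The problem

A clinical risk model fitted by maximum likelihood on a development sample
of size n with p candidate predictors is usually overfitted: its
predictions for new patients are too extreme. On external validation data
this shows up as a calibration slope (CS) below 1, where CS is the slope
from refitting a logistic model of the outcome on the candidate model's
linear predictor. Penalized likelihood (ridge, lasso) shrinks
coefficients toward zero and improves calibration *on average*, but the
penalty strength λ selected by standard k-fold cross-validation is highly
variable and biased upward, because the cross-validation training sets
have size n·(k−1)/k — smaller than the data the final model is fit on. The
package implements a modified tuning procedure that removes this size
mismatch, the closely related bootstrap tuning, the comparator shrinkage
methods, and the Monte-Carlo machinery to quantify how often each method
yields a well-calibrated model.

## Models (`shrinktune.models`)

Logistic regression throughout: logit P(y=1|x) = β₀ + βᵀx.

* **MLE** — Newton–Raphson with step-halving; gradient tolerance 1e-8.
  Non-convergence or a standardized slope exceeding 40 (a separated or
  quasi-separated configuration) flags the fit (`converged=False`); flagged
  replicates are excluded from simulation summaries with a count, never
  silently.
* **Penalized likelihood** — maximizes (1/n)·l(β) − λ·s(β), with
  s(β)=Σβⱼ² (ridge) or Σ|βⱼ| (lasso) over the slopes only; the intercept
  is never penalized. Covariates are standardized internally (mean 0, SD
  with denominator n) and coefficients back-transformed, so λ is
  comparable across sample sizes and datasets — the convention of the
  widely used penalized-GLM software in this field. Ridge is solved by
  warm-started Newton iterations along the descending λ path; lasso by
  IRLS with coordinate-descent soft-thresholding (exact zeros), active-set
  sweeps, and a KKT convergence check. Final model fits converge to
  gradient norm 1e-8; the many path fits inside cross-validation and
  resampling loops use 1e-7, which changes the cv deviance curves by
  ~1e-8 (far below Monte-Carlo noise) and never the selected λ. The
  kernels are numba-compiled: a tuning run fits the entire path thousands
  of times, which is the computational bottleneck of the whole study.
* **λ grids** — descending, log-equispaced, length 100 by default,
  spanning λmax down to λmax·1e-4. For lasso, λmax = maxⱼ |xⱼᵀ(y−ȳ)|/n on
  standardized covariates is the smallest λ with an all-zero fit. Ridge
  has no finite all-zero λ; its anchor is the lasso λmax × 1000
  (configurable constant `RIDGE_ANCHOR`).
* **Firth** — maximizes l(β) + ½·log det I(β) by modified-score Newton
  iterations (hat-diagonal score adjustment, step-halving on the penalized
  likelihood, score tolerance 1e-6, cap 100 iterations). Estimates stay
  finite under separation. Because the Firth penalty biases average
  predictions toward 0.5, the intercept is afterwards re-estimated alone
  by ML with the slope part of the linear predictor as a fixed offset;
  the intercept score equation then forces the mean predicted probability
  to equal the observed event fraction.
* **Bootstrap uniform shrinkage** — the classical heuristic: refit MLE on
  each of n_boot = 200 bootstrap resamples, compute each refit's
  calibration slope on the original data, average these slopes into a
  single shrinkage factor, multiply all MLE slopes by it, and re-estimate
  the intercept (offset ML again, preserving the event fraction).
  Resamples where the MLE fails are skipped and counted; more than 50%
  failures aborts. The number of resamples is this package's choice; 200
  puts the Monte-Carlo error of the factor well below the sampling noise
  it estimates.

## Tuning (`shrinktune.tuning`)

All three selectors minimize the cross-validated (or out-of-sample)
binomial deviance, −2·Σ[y·log p̂ + (1−y)·log(1−p̂)], accumulated over
held-out observations and divided by n. Held-out linear predictors are
clipped to |η| ≤ 23.03 (probabilities within ~1e-10 of the boundary) so
deviances are always finite.

* **standard_tune** — k-fold CV (default k=10, uniform random fold
  assignment, not stratified; folds re-drawn up to 10 times if a
  cv-training set is single-class); λ = argmin of the curve. With
  `repeats>1` the median of per-repeat minimizers is used. Leave-one-out
  (k=n) is supported.
* **modified_tune** — B times (default 100): draw a bootstrap
  pseudo-dataset of size n_pseudo = round(n·k/(k−1)) — so each cv-training
  set has the original size n — and run the standard k-fold machinery on
  it; average the B deviance curves pointwise and take the argmin.
  The final model is then fit on the *original* data at the selected λ.
* **bootstrap_tune** — B times: fit the path on a bootstrap resample of
  size n and score every λ's deviance on the original data; average and
  take the argmin.

Design choices where the procedure is genuinely open:

* One common λ grid, computed from the original development dataset, is
  used across folds, resamples and B iterations: pointwise averaging of
  curves requires a shared abscissa.
* Argmin ties break toward the **larger** λ (more shrinkage — the
  conservative direction); on a descending grid that is the first index.
* Bootstrap duplicates can land in both the cv-training and cv-test folds
  of a pseudo-dataset. This mild leakage is inherent to the procedure as
  defined and is left uncorrected.
* Tuning is deterministic given (dataset, seed, parameters).

## Validation (`shrinktune.validation`)

Per-model, on an independent validation draw: calibration slope,
calibration-in-the-large (intercept of the refit with the linear
predictor as a fixed offset), C-statistic (rank-based, ties ½), Brier
score, and RMSPE = √mean((π_true − p̂)²) against the generator's true
probabilities. Across replicates: RMSD(log-CS) = √mean((log CS_i − log
target)²) with target 1, and p_well_cal = proportion of replicates with
CS in [0.9, 1.1] (inclusive). Paired head-to-head comparisons against a
reference method use |log CS| (distance from 1 on the log scale,
consistent with RMSD), larger C, and smaller RMSPE; ties are no win.

A constant linear predictor (possible when lasso shrinks every slope to
zero) has an undefined CS: it is reported missing, counts as *not*
well-calibrated in p_well_cal, and is excluded from RMSD(log-CS), with
`n_degenerate` reported — excluding silently would bias the summaries
invisibly.

## Data generator (`shrinktune.datagen`)

Covariates are multivariate normal, mean 0, unit variances, block
correlation matrix: r_true = 0.1 within the true-predictor block,
r_noise = 0.05 within the noise block, r_cross = 0 between blocks (the
cross-block value is this package's choice; only the within-block values
are standard in this literature). The outcome is Bernoulli with
π = expit(β₀ + k·(base_coefs)ᵀx); the main scenario uses base_coefs =
(0.5, 0.3, 0.3, 0.25, 0.25, 0, …, 0) with 5 true and 7 noise predictors,
β₀ = 0 (prevalence 0.5) and k = 0.93 (true C-statistic 0.7).

`calibrate_dgm` solves (β₀, k) for arbitrary prevalence/C targets on one
large common-random-numbers sample (default 500,000 rows): prevalence is
monotone increasing in β₀ and the C-statistic monotone increasing in k, so
the two one-dimensional root-finds (Brent) alternate until both targets
are met within 0.005. Failure to bracket reports the achievable range.

What the generator does *not* emulate: real covariate distributions
(skewness, binary/categorical mixtures, missingness), model
misspecification (the fitted model family always contains the truth), and
outcome dependence beyond the logistic-linear form. Passing tests
therefore demonstrate the estimators' behaviour under a correctly
specified, moderately correlated Gaussian design — the standard benchmark
in this literature — not performance on any particular clinical dataset.

## Simulation machinery (`shrinktune.experiment`)

`run_scenario` draws, per replicate, one development set and one
independent validation set (default nval = 50,000; all methods in a
replicate share both), fits every requested method, validates, and
aggregates. Per-replicate failures are logged as flagged rows, never
fatal. Seeds: each replicate derives its streams from
`SeedSequence([master_seed, replicate])`, with one child stream per
method in a fixed canonical order — results are bit-reproducible and
independent of the requested method subset and of the joblib worker
count. CSV output uses 10-significant-digit formatting so identical runs
produce byte-identical files.

`find_recommended_n` bisects on n (rounded to steps of 10) for the
smallest size at which the median validation CS of MLE reaches a target
(default 0.9, the usual expected-shrinkage criterion), with common
random numbers across candidate sizes. Inside the search the validation
draws use 10,000 rows rather than 50,000: validation size only adds noise
to each replicate's CS, not bias, and the median over ≥300 replicates
absorbs it; the saved time goes into replication.

`folds_sensitivity` re-runs standard tuning at several fold counts
(5, 10, 20, …, n) on shared replicates for paired comparisons of the
selected λ and resulting CS.

## Problem sizes for the bundled checks

The reference study runs nsim = 1000 replicates with B = 100. The bundled
test suite and the acceptance script reproduce its headline quantities at
desk scale, as their own protocol choices: nsim = 500 for MLE-only
quantities, nsim = 200 with B = 50 for the modified/bootstrap-tuning
quantities (the B = 50 behaviour is documented to be nearly identical to
B = 100), λ grids of length 40 (log-spacing factor ≈ 1.27 per step — far
finer than the CS differences being measured), nval = 50,000, and
nsim = 300 per candidate inside the recommended-n search. Monte-Carlo
standard errors at these sizes are 2–4 percentage points for the
proportion-type quantities.

## Known limitations

* Penalized fits use one fixed λ grid per dataset; no pathwise
  early-stopping rules or one-standard-error selection.
* No elastic net, adaptive lasso, 0.632(+) bootstrap variants, or
  time-to-event outcomes.
* The recommended-n search assumes the median CS is monotone in n, which
  holds for MLE under this generator but is not checked adaptively.
* Metrics assume a binary outcome and a dataset containing both classes;
  decision-analytic measures (net benefit) and calibration plots are out
  of scope.
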