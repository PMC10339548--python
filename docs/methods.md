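# Methods

This note documents the statistical models, algorithmic choices, defaults
and limitations of `nomostack`.

## Cohort handling

A cohort is a patient-by-feature matrix with an optional ordinal risk label
(1 = low, 2 = intermediate, 3 = high). Quality control is complete-case:
any row with a missing or non-numeric feature cell is excluded at read time
and counted in the log; no imputation is offered.

**Truncation.** A few assays are unreliable past machine limits; the
default configuration caps PSA at 1000 ng/mL and floors ALT, IL-6 and
IL-1β at 5, 1.5 and 5 respectively. Rules live in config
(`CapRule`, serializable to YAML), never in code, and truncation is
idempotent.

**Normalization.** Min-max scaling to [0, 1] per feature. The fitted
min/max are stored so the transform is invertible and re-applicable to new
data, where out-of-range values are clipped into [0, 1]. Constant features
map to 0 with a warning rather than being dropped, so downstream selection
can discard them on its own evidence. By default the scaler is fitted on
the *full* cohort before splitting — this reproduces the original
workflow's ordering and leaks test-set ranges into training;
`PipelineConfig(fit_scaler_on_train=True)` gives the leak-free variant.
The same ordering applies to feature selection (run pre-split by default).

**Risk labeling.** When labels are not supplied, a helper applies the
standard guideline thresholds: low requires PSA < 10 ng/mL, grade group 1
and stage ≤ T2a; any of PSA > 20, grade group ≥ 4 or stage ≥ T2c makes
high; otherwise intermediate. Guideline editions differ at the margins, so
supplying labels directly always takes precedence.

**Splitting.** The 4:1 train/test split is stratified by risk group by
default. Each stratum's test count is its size × fraction rounded half-up
(clamped to [1, n−1]); the total is the sum over strata. This makes the
group proportions deviate from the target fraction by less than one
patient per stratum and reproduces the published 12/10/18 test allocation
from groups of 59/48/90 at fraction 0.2 for every seed. Plain random
splitting is available by flag.

## Synthetic cohorts

Only per-group marginal means and SDs (and the 47:38:72 group prevalences)
of the motivating training cohort are published, so the generator draws
group membership from the prevalence mixture and each feature
independently from a per-group marginal:

* **Truncated normal** for approximately symmetric features (ages, cell
  percentages, hemoglobin), truncated at physiological floors (0, or 18
  years for age) and caps (100 for percentages). With the published
  moments the truncation mass is negligible, so sample moments match the
  profile (verified at n = 5000 per group: mean within 3·sd/√n, sd within
  10%).
* **Moment-matched lognormal** for right-skewed biomarkers (PSA, alkaline
  phosphatase, LDH, interleukins, ALT, Th/Ts): σ² = ln(1 + sd²/mean²),
  μ = ln(mean) − σ²/2. The choice is forced by the data: a normal with
  sd 312.92 around mean 199.62 would put ~26% of high-risk PSA values
  below zero.

Generator-level floors/caps are only the hard physical ones (PSA ≤ 1000,
IL-6 ≥ 1.5 — both assay limits that shape the published moments); the
clinical truncation floors for ALT and IL-1β are applied by the
preprocessing stage, as they would be on real data.

The builtin profile carries 17 features: the nine retained by L1 selection
in the source cohort (Age, alkaline phosphatase, B cells, IL-1β, IL-2R,
LDH, neutrophil percentage, PSA, Th/Ts) plus eight weakly separated decoys
(lymphocyte %, lymphocyte count, hemoglobin, ALT, T/Ts/NK cell %, IL-6),
so that feature selection is exercised against realistic competition.

**Joint structure.** The published tables give marginals only. An optional
Gaussian copula accepts a user-supplied correlation matrix (validated
symmetric PSD with unit diagonal); none is invented by default. Passing
tests on these cohorts therefore demonstrates correctness of the machinery
and qualitative behavior under the published group separations — not
performance on the real joint distribution, where feature correlations
(e.g. PSA with stage-driven labels) could change both selection and
discrimination substantially. Test-set metric values from the real study
are for the same reason not reproduction targets.

## L1 feature selection

The ordinal outcome is coded 1/2/3 and fitted with squared-error Lasso
(the loss implied by a mean-squared-error cross-validation curve):
(1/2n)‖y − b₀ − Xb‖² + λ‖b‖₁, solved by coordinate descent
(scikit-learn's `lasso_path`, tolerance 1e−12) on a 100-point log-spaced
grid spanning four decades below λ_max = max|X'ᶜyᶜ|/n. Cross-validation is
stratified 5-fold; fold MSE curves give the mean and its standard error
per λ. `lambda_min` minimizes the CV mean; `lambda_1se` is the largest λ
whose CV mean is within one SE of that minimum and is the default
selection rule (the sparser, flatter-optimum choice); `min` is available
by flag. Coefficients below 1e−10 count as zero. The path is
oracle-checked: KKT residuals below 1e−6 at every grid point, and on an
orthonormal design (X'X = nI) the path equals the soft-threshold closed
form sign(b)·max(|b| − λ, 0).

## Base learners and meta-features

Default models and settings (seeded, otherwise library defaults):
Platt-calibrated RBF SVM (`CalibratedClassifierCV(SVC)`), decision tree,
random forest (200 trees), XGBoost (100 trees, depth 3), AdaBoost (100
stumps). Hyperparameters are not tuned. Training is stratified 10-fold;
every training patient receives exactly one out-of-fold (OOF) probability
vector per model (partition-checked), and each model is also refit on the
full training set for test-time prediction.

**Scalarization.** The stacking covariate per model is the expected
ordinal rank Σ k·p_k ∈ [1, 3] (default), which preserves ordinality and
yields one nomogram axis per model; P(high) is available by flag. Stacking
uses OOF meta-features by default to limit optimism;
`stack_in_sample=True` uses refit in-sample predictions instead.

**Importances.** Tree-family models use their native impurity/gain
attribution. Models without one (the SVM) use permutation importance
scored by OOF log-loss: for each fold model, each held-out column is
permuted (10 repeats) and the log-loss increase recorded. Each raw
measurement is floored at zero before accumulation — under a fully null
model every feature then collects the same half-normal noise mean, giving
a near-uniform profile instead of normalization-amplified noise — and the
totals are normalized to the simplex. Simplex columns are required by the
conservation law of the feature mapping.

## Proportional-odds regression

Cumulative-logit parameterization P(Y ≤ k|x) = σ(θ_k − xβ), so β > 0 means
higher risk and exp(β) is an odds ratio (matching the convention of
published univariate/multivariate tables). The log-likelihood
Σ log[σ(θ_y − η) − σ(θ_{y−1} − η)] is maximized by L-BFGS from a zero
start with analytic gradients, thresholds kept ordered via a log-gap
reparameterization, followed by a damped Newton polish in (β, θ) space
(finite-difference Hessian of the analytic gradient) until the gradient
inf-norm is below 1e−6. The gradient itself is finite-difference-checked
in the suite. Covariance is the inverse observed information (central
differences of the analytic gradient); odds ratios, 95% intervals and
p-values are Wald. No multiple-testing correction is applied in the
univariate screen. With two outcome levels the model reduces exactly to
binary logistic regression (matched to scikit-learn at 1e−6); the K = 3
fit is cross-checked against statsmodels' `OrderedModel`.

**Separation.** A fit whose effect span |β_j|·range(x_j) exceeds 30 (an
odds ratio of e³⁰ across the observed range) is reported as a
non-convergence error naming the covariate. The guard applies only to
pure-ML fits: with a positive `ridge` the penalized objective has a finite
optimum even under separation.

**Ridge.** `fit_olr(..., ridge=r)` adds r‖β‖² to the negative
log-likelihood. The pipeline uses r = 1e−3 for the stacking fits and the
mapped-feature refit. This is not regularization for performance: the
mapped feature matrix CF = MV·FIᵀ has rank at most N (the number of kept
models) while carrying M > N columns, so the unpenalized MLE is a flat
affine set; the ridge selects its minimum-norm member and keeps the Wald
covariance finite. Odds ratios from ridge fits are reported as-is and
should be read as descriptive.

**VIF.** Variance inflation factors use the textbook 1/(1 − R²) with OLS
of each covariate on the rest; exact collinearity reports +∞ rather than
raising. The stacking meta-features are intentionally collinear (all five
models approximate the same outcome), so the pipeline reports their VIFs
and warns above 10 before selection.

## Nomograms and the feature mapping

For covariate i with range [lo_i, hi_i], points_i(x) = 100·β_i·(x − r_i)/Δ
with anchor r_i = lo_i for β_i > 0 and hi_i otherwise, and
Δ = max_k |β_k|·(hi_k − lo_k). Every axis is ≥ 0 and zero at its
protective extreme; exactly one axis attains 100 points. Total points map
affinely to the linear predictor, η = η_min + T·Δ/100, and onward to class
probabilities through the fitted thresholds; the round trip is exact to
1e−9. Ranges default to the observed training min/max. The bundle
serializes to delimited text (per-axis point tables at 101 grid values, a
total-points → probability table) and round-trips bit-exactly
(`float_precision="round_trip"` on read).

The feature mapping CF_i = Σ_j FI_ij·MV_j is applied per patient with the
importance columns restricted to the models kept by independent-predictor
selection. Because each FI column sums to one, Σ_i CF_i = Σ_j MV_j exactly
(verified to 1e−12 on 1000 random simplex instances). The clinic-feature
nomogram is produced by *refitting* the ordinal model on the CF matrix
(the mapping defines axis values, not coefficients); the analytic
alternative β_clinic = FI·β_ML is provided as a helper for comparison.

**Predictive score and cutoffs.** The score is the linear predictor η
(total points are co-reported; published cutoff magnitudes are consistent
with the η scale, not a 0–100+ point scale). Classification is score ≤ c1
→ low, ≤ c2 → intermediate, else high (boundary closed on the lower
class). When cutoffs are not supplied they are derived by maximizing
macro-averaged per-class recall over all candidate pairs (midpoints
between consecutive distinct scores, quantile-thinned above 512; the
search is an O(m) sweep over a prefix-max decomposition). Ties prefer the
smaller c1 then c2, and the achieved macro recall is returned alongside so
chance-level fits are visible. Note that η — and hence the numeric cutoff
values — depends on the covariate scale of the refit; scores from
different runs are comparable only through their induced classifications.

## Evaluation

* **AUC** is the Mann-Whitney statistic with midrank tie handling, checked
  exhaustively against all-pairs counting. The 3-class summary is macro
  one-vs-rest by default; `ordinal_score` dichotomizes low vs
  intermediate-or-high on the expected-rank score — the same
  dichotomization used for decision curves and the DeLong comparisons.
* **DeLong** uses the structural-components estimator with covariance;
  identical score vectors return z = 0, p = 1 by convention. Null
  p-values are KS-uniform in the suite and the variance is within 15% of a
  2000-replicate bootstrap.
* **Calibration** bins patients into equal-count groups by predicted
  probability (default 10) and applies the standard bootstrap-optimism
  correction: per resample, refit, take the difference between the
  resample curve and the same model's curve on the original data
  (interpolated at the apparent curve's abscissae), and subtract the
  average from the apparent curve. Degenerate resamples (single outcome
  class, failed refits) are skipped and counted.
* **Decision curves** report NB(t) = TP/n − FP/n·t/(1 − t) on a 0.01–0.80
  grid against treat-all and treat-none, with the event defined as
  intermediate-or-high risk. Closed forms (treat-all zero crossing at the
  prevalence; perfect predictor at NB ≡ prevalence) are tested.
* **Bootstrap CIs** are percentile 2.5/97.5 with class-stratified
  resampling, B = 1000 by default (200 in the pipeline's panel for speed);
  more than 5% failing resamples is an error rather than a silent skip.

## Problem sizes and determinism

Simulation-backed checks use sizes at which their statistical tolerances
are meaningful rather than the largest feasible ones: parameter recovery
at n = 5000 × 100 replicates; null calibrations at 200–500 replicates;
the end-to-end synthetic workflow at n = 1000 (and n = 250–500 in the
faster pipeline tests). Every stochastic routine takes an explicit seed,
sub-seeds are derived by `SeedSequence`, and a pipeline rerun with the
same config is byte-identical.

## Known limitations

* The synthetic cohorts have independent features within groups unless a
  correlation is supplied; conclusions about real-data performance are
  out of reach by design (the source cohort is not deposited).
* The mapped-feature refit is identified only through the ridge; its
  coefficients (and hence cutoff magnitudes) are scale-dependent.
* Ordinal stacking on near-separable meta-features yields very large odds
  ratios; they are reported with the ridge caveat rather than suppressed.
* The EAU-style labeling helper uses one edition's thresholds; users with
  their own assignments should pass labels directly.
* No partial proportional odds, multinomial fallback, or Firth correction;
  no imputation; no survival endpoints.
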