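# nomostack

Stacked-ensemble ordinal nomograms for tripartite clinical risk
stratification.

## The problem

Prostate-cancer treatment choice hinges on a three-level (low /
intermediate / high) risk stratification that is usually assigned from PSA,
biopsy grade and clinical stage. Peripheral-blood immune profiles
(lymphocyte subsets measured by flow cytometry, serum interleukins) carry
additional signal, but turning a panel of 40+ laboratory features into a
bedside tool requires both the predictive power of machine-learning
classifiers and the interpretability of a classical nomogram.

`nomostack` implements a workflow that gets both. Five tabular classifiers
(SVM, decision tree, random forest, gradient boosting, AdaBoost) are
trained with stratified 10-fold cross-validation; each model's 3-class
probability vector is collapsed to a scalar meta-feature
MV<sub>j</sub> = Σ<sub>k</sub> k·p<sub>k</sub> ∈ [1, 3]. A
proportional-odds ordinal logistic regression (OLR)

P(Y ≤ k | x) = σ(θ<sub>k</sub> − xβ),  θ₁ < θ₂,

stacks the meta-features of the models that survive Wald
independent-predictor selection (p < 0.05) into an "ML nomogram". A
feature-mapping step then converts the model axes back into clinic-feature
axes: with FI<sub>i,j</sub> the normalized importance of clinic feature *i*
in model *j* (each importance column on the simplex),

CF<sub>i</sub> = Σ<sub>j</sub> FI<sub>i,j</sub> · MV<sub>j</sub>,

which conserves the total signal (Σ<sub>i</sub> CF<sub>i</sub> =
Σ<sub>j</sub> MV<sub>j</sub>). Refitting the OLR on the CF matrix yields a
nomogram whose axes are clinic features — interpretable like a
conventional nomogram, but carrying the ensemble's discrimination. Point
scales follow the standard convention: the widest-effect axis spans 100
points, total points are an affine bijection of the linear predictor η,
and two cutoffs on η induce the tripartite classification.

Around this core the package provides the full study pipeline: cohort
quality control (complete-case filtering, assay-limit truncation, min-max
normalization), L1 feature selection with 5-fold cross-validated penalty
choice (one-standard-error rule), a stratified 4:1 train/test split, and an
evaluation panel (macro one-vs-rest sensitivity/specificity/F1/AUC with
stratified bootstrap CIs, the DeLong test, optimism-corrected calibration
curves, decision-curve analysis). Because the motivating cohort is not
publicly deposited, a first-class synthetic-cohort generator reproduces the
published per-risk-group feature means/SDs (group prevalences 47:38:72) so
every stage is testable offline.

## Worked example

```bash
# a 197-patient synthetic cohort with the published group statistics
nomostack simulate --n 197 --seed 1 --out cohort.csv

# the full pipeline on a larger simulated cohort
nomostack run --seed 1 --n 500 --out-dir run1
```

prints

```
                 sensitivity  specificity     f1  auc_macro_ovr  auc_low_vs_rest
clinic_ml_train        0.823        0.927  0.815          0.938            0.925
clinic_ml_test         0.807        0.919  0.797          0.934            0.919
clinic_test            0.789        0.915  0.788          0.922            0.917
cutoffs: c1=8.729, c2=13.839; artifacts in run1
```

Rows are the mapped clinic-ML nomogram on the training and held-out test
split, and the conventional clinic nomogram (OLR directly on the selected
features) on the test split. `auc_low_vs_rest` is the discrimination of
low-risk from intermediate-or-high-risk patients — the dichotomization
that drives active-surveillance decisions; `cutoffs` are the two
score thresholds, derived by maximizing macro recall on the training
scores, that split patients into the three risk groups. The run directory
contains every intermediate as delimited text: the Lasso CV curve, the
stacking regression tables, per-model out-of-fold probabilities and
importances, the three nomogram lookup bundles (`axes.csv`,
`prob_table.csv`, ...), per-patient predictive scores, a decision-curve
table, and a `manifest.json` sufficient to reproduce the run bit-for-bit.

The same workflow is available as a library:

```python
from nomostack import builtin_profile, generate
from nomostack.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(config=PipelineConfig(seed=1), n_simulate=500)
print(result.metric_panel)
print(result.clinic_ml_nomogram.prob_table(11))
```

To run on real data, pass a CSV (`patient_id` column, one feature per
column, ordinal `risk` column coded 1/2/3) via `nomostack run --cohort
your_cohort.csv ...`.

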