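"""End-to-end orchestration: preprocess -> select -> train -> stack -> nomograms -> evaluate.

Mirrors the study workflow: quality control and truncation, min-max
normalization, L1 feature selection with 5-fold CV, a stratified 4:1
train/test split, stratified 10-fold training of the five base classifiers,
proportional-odds stacking of their scalarized predictions with
independent-predictor selection, the feature-mapping conversion to a
clinic-feature nomogram, tripartite cutoffs on the predictive score, and a
metric panel on the held-out test set.  Every intermediate artifact is
written as delimited text so a run is diffable and reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    DEFAULT_CAP_RULES,
    CohortTable,
    apply_truncation,
    drop_feature,
    min_max_normalize,
    split_train_test,
)
from .exceptions import ValidationError
from .lasso import fit_lasso_path, select_features
from .learners import train_base_models
from .metrics import confusion_metrics, decision_curve, multiclass_auc
from .nomogram import (
    RiskCutoffs,
    build_nomogram,
    classify,
    derive_cutoffs,
    fma_convert,
)
from .ordinal import fit_olr, multivariate_select, univariate_screen, wald_table
from .simulate import builtin_profile, generate


@dataclass
class PipelineConfig:
    """Defaults reproduce the study's stated settings (4:1 split, 5-fold Lasso
    CV, 10-fold base-model CV, alpha 0.05, score cutoffs 2.24/6.00)."""

    seed: int = 0
    test_fraction: float = 0.2
    fit_scaler_on_train: bool = False  # False = normalize before splitting
    drop_features: tuple[str, ...] = ()
    lasso_folds: int = 5
    lasso_rule: str = "one_se"
    base_folds: int = 10
    importance: str = "native"
    scalarization: str = "expected_rank"
    stack_in_sample: bool = False  # False = stack on out-of-fold predictions
    alpha: float = 0.05
    ridge: float = 1e-3  # Tikhonov term for rank-deficient/near-separated refits
    cutoffs: tuple[float, float] | None = None  # None = derive from training scores
    derive_cutoffs: bool = True
    n_boot: int = 200

    def __post_init__(self) -> None:
        if self.cutoffs is not None and not self.cutoffs[0] < self.cutoffs[1]:
            raise ValidationError("cutoffs require c1 < c2")
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "cutoffs" in doc and doc["cutoffs"] is not None:
            doc["cutoffs"] = tuple(doc["cutoffs"])
        if "drop_features" in doc:
            doc["drop_features"] = tuple(doc["drop_features"])
        return cls(**doc)


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    selected_features: list[str]
    train: CohortTable
    test: CohortTable
    ensemble: object
    kept_models: list[str]
    ml_fit: object
    ml_nomogram: object
    clinic_ml_fit: object
    clinic_ml_nomogram: object
    clinic_fit: object
    clinic_nomogram: object
    cutoffs: RiskCutoffs
    cutoff_macro_recall: float
    scores_train: np.ndarray
    scores_test: np.ndarray
    metric_panel: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def preprocess(
    cohort: CohortTable,
    cap_rules=DEFAULT_CAP_RULES,
    drop: tuple[str, ...] = (),
) -> CohortTable:
    """Truncation at assay caps/floors plus configured feature drops."""
    rules = [r for r in cap_rules if r.feature_name in cohort.feature_names]
    table = apply_truncation(cohort, rules)
    for name in drop:
        if name in table.feature_names:
            table = drop_feature(table, name)
    return table


def run_pipeline(
    cohort: CohortTable | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    n_simulate: int = 500,
) -> PipelineResult:
    """Execute the full workflow; simulates a builtin-profile cohort if none given."""
    config = config or PipelineConfig()
    rng_seed = config.seed
    if cohort is None:
        cohort = generate(builtin_profile(n=n_simulate, seed=rng_seed))
    tables: dict[str, pd.DataFrame] = {}

    # ---- preprocessing ---------------------------------------------------------
    cohort = preprocess(cohort, drop=config.drop_features)
    if config.fit_scaler_on_train:
        train_raw, test_raw = split_train_test(
            cohort, config.test_fraction, seed=rng_seed, stratified=True
        )
        train_norm, stats = min_max_normalize(train_raw)
        test_norm, _ = min_max_normalize(test_raw, stats)
        lasso_input = train_norm
    else:
        normalized, stats = min_max_normalize(cohort)
        lasso_input = normalized

    # ---- L1 feature selection (pre-split, as in the source workflow) -----------
    lasso = fit_lasso_path(lasso_input, folds=config.lasso_folds, seed=rng_seed)
    selected = select_features(lasso, rule=config.lasso_rule)
    if not selected:
        raise ValidationError("feature selection returned an empty panel")
    tables["lasso_cv"] = pd.DataFrame(
        {
            "lambda": lasso.lambda_grid,
            "cv_mse": lasso.cv_mean,
            "cv_se": lasso.cv_se,
            "n_nonzero": lasso.n_nonzero_path,
        }
    )

    if config.fit_scaler_on_train:
        train = train_norm.subset_features(selected)
        test = test_norm.subset_features(selected)
    else:
        sel_table = normalized.subset_features(selected)
        train, test = split_train_test(
            sel_table, config.test_fraction, seed=rng_seed, stratified=True
        )

    # ---- base learners ----------------------------------------------------------
    ensemble = train_base_models(
        train,
        folds=config.base_folds,
        seed=rng_seed,
        importance=config.importance,
        scalarization=config.scalarization,
    )
    meta_train = (
        ensemble.transform(train.features)
        if config.stack_in_sample
        else ensemble.meta_features
    )
    meta_test = ensemble.transform(test.features)

    # ---- stacking: screen, select independent predictors, ML nomogram ----------
    meta_cohort = CohortTable(meta_train, train.risk.copy())
    tables["stack_univariate"] = univariate_screen(meta_cohort, ridge=config.ridge)
    ml_fit, kept_models = multivariate_select(
        meta_cohort, alpha=config.alpha, ridge=config.ridge
    )
    tables["stack_multivariate"] = wald_table(ml_fit)
    ml_ranges = np.column_stack(
        [meta_train[kept_models].min(axis=0), meta_train[kept_models].max(axis=0)]
    )
    ml_nomogram = build_nomogram(ml_fit, ranges=ml_ranges)

    # ---- feature mapping -> clinic-ML nomogram ---------------------------------
    fma_train = fma_convert(ensemble, kept_models)
    # CF has at most as many independent directions as kept models, so the
    # refit needs the minimum-norm (ridge) solution
    clinic_ml_fit = fit_olr(fma_train.CF, train.risk.to_numpy(), ridge=config.ridge)
    clinic_ml_nomogram = build_nomogram(clinic_ml_fit, X=fma_train.CF)
    fma_test = fma_convert(FI=fma_train.FI, MV=meta_test[kept_models])

    scores_train = clinic_ml_fit.linear_predictor(fma_train.CF)
    scores_test = clinic_ml_fit.linear_predictor(fma_test.CF)

    # ---- conventional clinic nomogram (comparison arm) -------------------------
    tables["clinic_univariate"] = univariate_screen(train, ridge=config.ridge)
    try:
        clinic_fit, kept_clinic = multivariate_select(
            train, alpha=config.alpha, ridge=config.ridge
        )
    except ValidationError:
        warnings.warn("no clinic feature passed selection; using the full model", stacklevel=2)
        clinic_fit = fit_olr(train.features, train.risk.to_numpy(), ridge=config.ridge)
        kept_clinic = train.feature_names
    tables["clinic_multivariate"] = wald_table(clinic_fit)
    clinic_nomogram = build_nomogram(clinic_fit, X=train.features[kept_clinic])

    # ---- cutoffs and classification ---------------------------------------------
    if config.cutoffs is not None and not config.derive_cutoffs:
        cutoffs = RiskCutoffs(*config.cutoffs)
        macro = np.nan
    else:
        cutoffs, macro = derive_cutoffs(scores_train, train.risk.to_numpy())
    yhat_test = classify(scores_test, cutoffs)
    yhat_train = classify(scores_train, cutoffs)

    # ---- evaluation --------------------------------------------------------------
    probs_test = clinic_ml_fit.predict_proba(fma_test.CF)
    probs_train = clinic_ml_fit.predict_proba(fma_train.CF)
    clinic_probs_test = clinic_fit.predict_proba(test.features[kept_clinic])
    rows = []
    for label, yy, yh, pp in (
        ("clinic_ml_train", train.risk.to_numpy(), yhat_train, probs_train),
        ("clinic_ml_test", test.risk.to_numpy(), yhat_test, probs_test),
    ):
        cm = confusion_metrics(yy, yh)
        cm["auc_macro_ovr"] = multiclass_auc(yy, pp, "macro_ovr")
        cm["auc_low_vs_rest"] = multiclass_auc(yy, pp, "ordinal_score")
        rows.append(pd.Series(cm, name=label))
    cm = confusion_metrics(
        test.risk.to_numpy(), clinic_fit.predict_class(test.features[kept_clinic])
    )
    cm["auc_macro_ovr"] = multiclass_auc(test.risk.to_numpy(), clinic_probs_test, "macro_ovr")
    cm["auc_low_vs_rest"] = multiclass_auc(test.risk.to_numpy(), clinic_probs_test, "ordinal_score")
    rows.append(pd.Series(cm, name="clinic_test"))
    panel = pd.DataFrame(rows)

    dca = decision_curve(test.risk.to_numpy(), 1.0 - probs_test[:, 0])
    tables["dca_test"] = dca.to_frame()

    result = PipelineResult(
        config=config,
        selected_features=selected,
        train=train,
        test=test,
        ensemble=ensemble,
        kept_models=kept_models,
        ml_fit=ml_fit,
        ml_nomogram=ml_nomogram,
        clinic_ml_fit=clinic_ml_fit,
        clinic_ml_nomogram=clinic_ml_nomogram,
        clinic_fit=clinic_fit,
        clinic_nomogram=clinic_nomogram,
        cutoffs=cutoffs,
        cutoff_macro_recall=macro,
        scores_train=scores_train,
        scores_test=scores_test,
        metric_panel=panel,
        tables=tables,
    )
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = "%.17g"
    result.train.to_csv(out_dir / "train.csv")
    result.test.to_csv(out_dir / "test.csv")
    result.metric_panel.to_csv(out_dir / "metric_panel.csv", float_format=fmt)
    for name, tab in result.tables.items():
        tab.to_csv(out_dir / f"{name}.csv", index=False, float_format=fmt)
    result.ensemble.meta_features.to_csv(out_dir / "meta_features_train.csv", float_format=fmt)
    result.ensemble.importances.to_csv(out_dir / "feature_importances.csv", float_format=fmt)
    result.clinic_ml_nomogram.save(out_dir / "clinic_ml_nomogram")
    result.ml_nomogram.save(out_dir / "ml_nomogram")
    result.clinic_nomogram.save(out_dir / "clinic_nomogram")
    pd.DataFrame(
        {
            "patient_id": list(result.train.patient_ids) + list(result.test.patient_ids),
            "split": ["train"] * result.train.n + ["test"] * result.test.n,
            "score": np.concatenate([result.scores_train, result.scores_test]),
            "risk": np.concatenate(
                [result.train.risk.to_numpy(), result.test.risk.to_numpy()]
            ),
        }
    ).to_csv(out_dir / "predictive_scores.csv", index=False, float_format=fmt)
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(result.config),
        "selected_features": result.selected_features,
        "kept_models": result.kept_models,
        "cutoffs": [result.cutoffs.c1, result.cutoffs.c2],
        "cutoff_macro_recall": result.cutoff_macro_recall,
        "n_train": result.train.n,
        "n_test": result.test.n,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
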