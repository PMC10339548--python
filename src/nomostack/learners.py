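"""Base classifier ensemble: cross-validated probabilities and importances.

Five tabular classifiers (SVM, decision tree, random forest, gradient
boosting, AdaBoost) are trained with stratified 10-fold cross-validation.
Each model contributes

* an out-of-fold class-probability matrix (every training patient predicted
  by a model that never saw it),
* a scalar "meta-feature" per patient — by default the expected ordinal rank
  sum_k k * p_k in [1, 3] — used as a stacking covariate, and
* a normalized feature-importance vector (a simplex over the clinic
  features) used by the feature-mapping conversion of the nomogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .cohort import RISK_LEVELS, CohortTable
from .exceptions import StratificationError, ValidationError

DEFAULT_MODEL_NAMES = ("SVM", "DecisionTree", "RandomForest", "XGBoost", "AdaBoost")


def default_model_specs(seed: int = 0) -> dict[str, object]:
    """Library-default configurations of the five base classifiers."""
    return {
        # Platt-scaled SVM (the probability-capable variant)
        "SVM": CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed), ensemble=False),
        "DecisionTree": DecisionTreeClassifier(random_state=seed),
        "RandomForest": RandomForestClassifier(n_estimators=200, random_state=seed),
        "XGBoost": XGBClassifier(
            n_estimators=100,
            max_depth=3,
            learning_rate=0.3,
            eval_metric="mlogloss",
            random_state=seed,
            verbosity=0,
        ),
        "AdaBoost": AdaBoostClassifier(n_estimators=100, random_state=seed),
    }


def scalarize(probs: np.ndarray, method: str = "expected_rank") -> np.ndarray:
    """Collapse a patient x 3 class-probability matrix to one scalar per patient.

    ``expected_rank`` returns sum_k k * p_k with k in {1, 2, 3} (so the value
    lives in [1, 3] and preserves ordinality); ``prob_high`` returns p_3.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2:
        raise ValidationError("expected a 2-D probability matrix")
    if np.any(probs < -1e-12) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValidationError("rows must be probability vectors summing to 1")
    if method == "expected_rank":
        ranks = np.arange(1, probs.shape[1] + 1, dtype=float)
        return probs @ ranks
    if method == "prob_high":
        return probs[:, -1]
    raise ValidationError(f"unknown scalarization {method!r}")


@dataclass
class EnsemblePredictions:
    """Everything stacking and the feature-mapping step need from the ensemble."""

    model_names: list[str]
    feature_names: list[str]
    index: pd.Index
    y: np.ndarray
    oof_probs: dict[str, np.ndarray]  # per model: n x 3, out-of-fold
    refit_models: dict[str, object]  # fit on the full training set
    meta_features: pd.DataFrame  # n x N, scalarized OOF probabilities
    importances: pd.DataFrame  # M x N, each column on the simplex
    scalarization: str = "expected_rank"
    fold_models: dict[str, list] = field(default_factory=dict, repr=False)

    def transform(self, X: pd.DataFrame, in_sample: bool = True) -> pd.DataFrame:
        """Meta-features for new data from the refit models."""
        cols = {}
        for name in self.model_names:
            probs = _predict_proba_3(self.refit_models[name], X.to_numpy(dtype=float))
            cols[name] = scalarize(probs, self.scalarization)
        return pd.DataFrame(cols, index=X.index)


def _predict_proba_3(model, X: np.ndarray) -> np.ndarray:
    """Probability matrix aligned to the three ordinal classes."""
    raw = model.predict_proba(X)
    classes = list(getattr(model, "classes_", range(raw.shape[1])))
    out = np.zeros((len(X), len(RISK_LEVELS)))
    for j, c in enumerate(classes):
        out[:, int(c)] = raw[:, j]  # classes are 0-based internal codes
    return out


def _native_importance(model) -> np.ndarray | None:
    imp = getattr(model, "feature_importances_", None)
    if imp is None:
        return None
    return np.asarray(imp, dtype=float)


def permutation_importance_oof(
    fold_models: list[tuple[object, np.ndarray]],
    X: np.ndarray,
    y0: np.ndarray,
    seed: int,
    repeats: int = 10,
) -> np.ndarray:
    """Permutation importance scored by out-of-fold log-loss increase.

    For every cross-validation fold, each feature column of the held-out
    block is permuted in turn and the rise in log-loss of that fold's model
    is recorded.  Each raw measurement is floored at zero before
    accumulation (an uninformative feature then collects the same
    half-normal noise mean as every other, so a fully null model yields a
    near-uniform profile instead of amplified noise), and the totals are
    normalized to the simplex.
    """
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    deltas = np.zeros(p)
    labels = np.arange(len(RISK_LEVELS))
    for model, va in fold_models:
        Xva, yva = X[va], y0[va]
        base = log_loss(yva, _predict_proba_3(model, Xva), labels=labels)
        for j in range(p):
            for _ in range(repeats):
                Xp = Xva.copy()
                Xp[:, j] = Xp[rng.permutation(len(Xva)), j]
                d = log_loss(yva, _predict_proba_3(model, Xp), labels=labels) - base
                deltas[j] += max(d, 0.0)
    total = deltas.sum()
    if total <= 0:
        return np.full(p, 1.0 / p)
    return deltas / total


def feature_importance(
    model,
    train: CohortTable,
    method: str = "native",
    seed: int = 0,
    repeats: int = 10,
) -> np.ndarray:
    """Normalized (simplex) importance of each clinic feature in one model.

    ``native`` uses the model's own attribution (tree impurity/gain) when it
    exists, falling back to permutation with a warning; ``permutation``
    shuffles one feature at a time and scores the log-loss increase on the
    supplied data.
    """
    X = train.features.to_numpy(dtype=float)
    if method == "native":
        imp = _native_importance(model)
        if imp is not None:
            imp = np.clip(imp, 0.0, None)
            return imp / imp.sum() if imp.sum() > 0 else np.full(len(imp), 1.0 / len(imp))
        warnings.warn(
            f"{type(model).__name__} has no native importances; using permutation",
            stacklevel=2,
        )
    elif method != "permutation":
        raise ValidationError(f"unknown importance method {method!r}")
    if train.risk is None:
        raise ValidationError("permutation importance requires labels")
    y0 = train.risk.to_numpy() - 1
    whole = [(model, np.arange(len(X)))]
    return permutation_importance_oof(whole, X, y0, seed=seed, repeats=repeats)


def train_base_models(
    train: CohortTable,
    specs: dict[str, object] | None = None,
    folds: int = 10,
    seed: int = 0,
    importance: str = "native",
    scalarization: str = "expected_rank",
) -> EnsemblePredictions:
    """Stratified k-fold training of the base ensemble on a labeled cohort."""
    if train.risk is None:
        raise ValidationError("training requires risk labels")
    specs = specs if specs is not None else default_model_specs(seed)
    y = train.risk.to_numpy()
    counts = pd.Series(y).value_counts()
    if counts.min() < folds:
        raise StratificationError(
            f"smallest class has {counts.min()} members < {folds} folds; reduce folds"
        )
    X = train.features.to_numpy(dtype=float)
    y0 = y - 1  # 0-based internal codes (xgboost requires 0..K-1)
    n = len(y)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y0))

    oof_probs: dict[str, np.ndarray] = {}
    refit_models: dict[str, object] = {}
    fold_models: dict[str, list] = {}
    importances: dict[str, np.ndarray] = {}
    for name, proto in specs.items():
        oof = np.full((n, len(RISK_LEVELS)), np.nan)
        fms = []
        for tr, va in splits:
            m = clone(proto)
            m.fit(X[tr], y0[tr])
            oof[va] = _predict_proba_3(m, X[va])
            fms.append((m, va))
        assert not np.isnan(oof).any(), "out-of-fold coverage gap"
        refit = clone(proto)
        refit.fit(X, y0)
        oof_probs[name] = oof
        refit_models[name] = refit
        fold_models[name] = fms

        if importance == "native" and _native_importance(refit) is not None:
            imp = np.clip(_native_importance(refit), 0.0, None)
            importances[name] = (
                imp / imp.sum() if imp.sum() > 0 else np.full(X.shape[1], 1.0 / X.shape[1])
            )
        else:
            importances[name] = permutation_importance_oof(fms, X, y0, seed=seed)

    meta = pd.DataFrame(
        {name: scalarize(oof_probs[name], scalarization) for name in specs},
        index=train.features.index,
    )
    imp_df = pd.DataFrame(importances, index=train.feature_names)
    return EnsemblePredictions(
        model_names=list(specs),
        feature_names=train.feature_names,
        index=train.features.index,
        y=y,
        oof_probs=oof_probs,
        refit_models=refit_models,
        meta_features=meta,
        importances=imp_df,
        scalarization=scalarization,
        fold_models=fold_models,
    )
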