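"""Evaluation panel: macro metrics, AUC, DeLong, calibration and decision curves.

AUC is computed from the Mann-Whitney statistic with midrank tie handling;
the DeLong test compares two correlated AUCs through their structural
components; calibration curves are bias-corrected by bootstrap optimism;
decision-curve analysis reports net benefit NB(t) = TP/n - FP/n * t/(1-t)
against treat-all and treat-none policies.  Confidence intervals are
percentile bootstrap with class-stratified resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .exceptions import ValidationError


# --------------------------------------------------------------------------- AUC
def auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = P(pos > neg) + 0.5 P(tie), via midranks (tie-corrected)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def multiclass_auc(
    y: np.ndarray, prob: np.ndarray, scheme: str = "macro_ovr"
) -> float:
    """Single-number AUC for the 3-class ordinal task.

    ``macro_ovr`` averages the three one-vs-rest AUCs of each class
    probability (classes absent from ``y`` are skipped with a warning);
    ``ordinal_score`` dichotomizes low vs {intermediate, high} and scores the
    expected-rank scalarization — the same dichotomization used for the
    decision curves.
    """
    y = np.asarray(y)
    prob = np.asarray(prob, dtype=float)
    if np.any(np.abs(prob.sum(axis=1) - 1.0) > 1e-6):
        raise ValidationError("probability rows must sum to 1")
    if scheme == "ordinal_score":
        score = prob @ np.arange(1, prob.shape[1] + 1)
        return auc_mann_whitney(score[y >= 2], score[y == 1])
    if scheme != "macro_ovr":
        raise ValidationError(f"unknown AUC scheme {scheme!r}")
    aucs = []
    for k in range(prob.shape[1]):
        cls = k + 1
        mask = y == cls
        if mask.sum() == 0 or mask.sum() == len(y):
            warnings.warn(f"class {cls} absent; skipped in macro AUC", stacklevel=2)
            continue
        aucs.append(auc_mann_whitney(prob[mask, k], prob[~mask, k]))
    return float(np.mean(aucs))


# ----------------------------------------------------------------- confusion panel
def confusion_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    """Macro one-vs-rest sensitivity, specificity and F1 over the classes in y."""
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if len(y) != len(yhat):
        raise ValidationError("y and yhat must have the same length")
    sens, spec, f1 = [], [], []
    for cls in np.unique(y):
        tp = np.sum((y == cls) & (yhat == cls))
        fn = np.sum((y == cls) & (yhat != cls))
        fp = np.sum((y != cls) & (yhat == cls))
        tn = np.sum((y != cls) & (yhat != cls))
        sens.append(tp / (tp + fn))
        spec.append(tn / (tn + fp) if (tn + fp) else np.nan)
        f1.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    return {
        "sensitivity": float(np.mean(sens)),
        "specificity": float(np.nanmean(spec)),
        "f1": float(np.mean(f1)),
    }


# ------------------------------------------------------------------------- DeLong
def _structural_components(y01: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    pos = score[y01 == 1]
    neg = score[y01 == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per negative
    return v10, v01, float(auc)


def delong_test(
    y_binary: np.ndarray, score_a: np.ndarray, score_b: np.ndarray
) -> tuple[float, float, float, float]:
    """DeLong comparison of two correlated AUCs on the same patients.

    Returns (auc_a, auc_b, z, p) with a two-sided normal p-value.  Identical
    score vectors give z = 0, p = 1 by convention.
    """
    y01 = np.asarray(y_binary).astype(int)
    if set(np.unique(y01)) != {0, 1}:
        raise ValidationError("y_binary must contain both classes coded 0/1")
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if len(a) != len(y01) or len(b) != len(y01):
        raise ValidationError("scores must be paired with the labels")
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        raise ValidationError("all scores tied; AUC variance is degenerate")

    v10a, v01a, auc_a = _structural_components(y01, a)
    v10b, v01b, auc_b = _structural_components(y01, b)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var <= 0 or np.allclose(a, b):
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def delong_variance(y_binary: np.ndarray, score_a: np.ndarray, score_b: np.ndarray) -> float:
    """Variance of AUC_a - AUC_b from the structural components."""
    y01 = np.asarray(y_binary).astype(int)
    v10a, v01a, _ = _structural_components(y01, np.asarray(score_a, dtype=float))
    v10b, v01b, _ = _structural_components(y01, np.asarray(score_b, dtype=float))
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    S = s10 / m + s01 / n
    return float(S[0, 0] + S[1, 1] - 2 * S[0, 1])


# -------------------------------------------------------------------- calibration
def calibration_curve(
    fit_predict: Callable[[pd.DataFrame, np.ndarray], Callable[[pd.DataFrame], np.ndarray]],
    X: pd.DataFrame,
    event: np.ndarray,
    bins: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Apparent and bootstrap-optimism-corrected calibration curve.

    ``fit_predict(X, event)`` must return a closure mapping a feature frame
    to event probabilities (the refittable model).  The apparent curve bins
    patients into equal-count groups by predicted probability and plots the
    observed event fraction; the bias-corrected curve subtracts the average
    optimism over ``n_boot`` bootstrap refits (train on a resample, compare
    the resample curve with the same model's curve on the original data).
    """
    event = np.asarray(event).astype(int)
    n = len(event)
    if bins > n // 2:
        raise ValidationError(f"bins={bins} exceeds n/2={n // 2}")
    rng = np.random.default_rng(seed)

    predict = fit_predict(X, event)
    p_hat = np.asarray(predict(X), dtype=float)
    centers, observed = _binned_curve(p_hat, event, bins)

    optimism = np.zeros(len(centers))
    n_ok = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(event[idx])) < 2:
            continue
        try:
            predict_b = fit_predict(X.iloc[idx], event[idx])
        except Exception:  # refit may legitimately fail on a degenerate resample
            continue
        p_boot = np.asarray(predict_b(X.iloc[idx]), dtype=float)
        c_b, o_b = _binned_curve(p_boot, event[idx], bins)
        p_orig = np.asarray(predict_b(X), dtype=float)
        c_o, o_o = _binned_curve(p_orig, event, bins)
        boot_at = np.interp(centers, c_b, o_b)
        orig_at = np.interp(centers, c_o, o_o)
        optimism += boot_at - orig_at
        n_ok += 1
    if n_ok:
        optimism /= n_ok
    return pd.DataFrame(
        {
            "predicted": centers,
            "observed_apparent": observed,
            "observed_corrected": observed - optimism,
            "n_boot_effective": n_ok,
        }
    )


def _binned_curve(p: np.ndarray, event: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(p, kind="mergesort")
    splits = np.array_split(order, bins)
    centers = np.array([p[s].mean() for s in splits if len(s)])
    observed = np.array([event[s].mean() for s in splits if len(s)])
    return centers, observed


# ---------------------------------------------------------------- decision curves
@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.net_benefit_model,
                "nb_all": self.net_benefit_all,
                "nb_none": self.net_benefit_none,
            }
        )


def decision_curve(
    y: np.ndarray,
    p_event: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> DecisionCurve:
    """Net benefit across threshold probabilities, dichotomized low vs rest.

    ``y`` may be ordinal labels in {1,2,3} (event = intermediate-or-high) or
    a binary 0/1 event indicator.
    """
    y = np.asarray(y)
    event = (y >= 2).astype(int) if set(np.unique(y)) - {0, 1} else y.astype(int)
    p_event = np.asarray(p_event, dtype=float)
    if np.any((p_event < 0) | (p_event > 1)):
        raise ValidationError("event probabilities must lie in [0, 1]")
    if thresholds is None:
        thresholds = np.arange(0.01, 0.801, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds >= 1) or np.any(thresholds <= 0):
        raise ValidationError("thresholds must lie strictly inside (0, 1)")
    n = len(event)
    prev = event.mean()
    odds = thresholds / (1.0 - thresholds)
    nb_model = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        called = p_event >= t
        tp = np.sum(called & (event == 1))
        fp = np.sum(called & (event == 0))
        nb_model[i] = tp / n - fp / n * odds[i]
    nb_all = prev - (1.0 - prev) * odds
    return DecisionCurve(thresholds, nb_model, nb_all, np.zeros_like(thresholds))


# -------------------------------------------------------------------- bootstrap CI
def bootstrap_ci(
    metric: Callable[..., float],
    arrays: Sequence[np.ndarray],
    n_boot: int = 1000,
    seed: int = 0,
    stratify: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Percentile 95% bootstrap interval with optional class-stratified resampling.

    ``metric(*arrays[idx])`` is evaluated on resampled row indices; more than
    5% failing resamples is an error.  ``n_boot=1`` degenerates to the point
    estimate with a warning.
    """
    arrays = [np.asarray(a) for a in arrays]
    n = len(arrays[0])
    rng = np.random.default_rng(seed)
    point = float(metric(*arrays))
    if n_boot < 2:
        warnings.warn("n_boot < 2 yields a degenerate interval", stacklevel=2)
        return point, point, point
    if stratify is not None:
        stratify = np.asarray(stratify)
        groups = [np.where(stratify == g)[0] for g in np.unique(stratify)]
    vals, failures = [], 0
    for _ in range(n_boot):
        if stratify is None:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.concatenate([g[rng.integers(0, len(g), size=len(g))] for g in groups])
        try:
            vals.append(float(metric(*[a[idx] for a in arrays])))
        except Exception:
            failures += 1
    if failures > 0.05 * n_boot:
        raise ValidationError(f"metric failed on {failures}/{n_boot} resamples")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return point, float(lo), float(hi)
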