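"""L1-penalized feature selection on the numerically coded ordinal outcome.

The ordinal risk label is coded 1/2/3 and regressed on all (normalized)
features under the squared-error Lasso

    (1 / 2n) * ||y - b0 - X b||^2 + lambda * ||b||_1,

solved by coordinate descent over a log-spaced lambda grid spanning four
decades below lambda_max (the smallest penalty with an all-zero solution).
Stratified k-fold cross-validation picks the penalty; the default rule is
the one-standard-error rule (largest lambda whose CV error is within one SE
of the minimum), with the plain CV minimum available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort import CohortTable
from .exceptions import ValidationError

_ZERO_TOL = 1e-10  # coefficients smaller than this count as exactly zero


@dataclass
class LassoResult:
    """Solution path plus cross-validated penalty choice."""

    feature_names: list[str]
    lambda_grid: np.ndarray  # decreasing
    coef_path: np.ndarray  # p x L
    intercept_path: np.ndarray  # L
    cv_mean: np.ndarray  # L
    cv_se: np.ndarray  # L
    lambda_min: float
    lambda_1se: float

    def coef_at(self, lam: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.lambda_grid - lam)))
        return self.coef_path[:, idx]

    @property
    def n_nonzero_path(self) -> np.ndarray:
        return (np.abs(self.coef_path) > _ZERO_TOL).sum(axis=0)


def _centered(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    xm = X.mean(axis=0)
    ym = y.mean()
    return X - xm, y - ym, xm, ym


def _path(Xc: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    _, coefs, _ = lasso_path(Xc, yc, alphas=lambdas, tol=1e-12, max_iter=100_000)
    return coefs


def fit_lasso_path(
    table: CohortTable,
    folds: int = 5,
    seed: int = 0,
    grid_size: int = 100,
    n_decades: float = 4.0,
) -> LassoResult:
    """Fit the full regularization path with stratified k-fold CV MSE."""
    if table.risk is None:
        raise ValidationError("Lasso selection requires risk labels")
    if table.n <= folds:
        raise ValidationError(f"need more rows ({table.n}) than folds ({folds})")
    X = table.features.to_numpy(dtype=float)
    y = table.risk.to_numpy(dtype=float)
    n = len(y)

    Xc, yc, xm, ym = _centered(X, y)
    lam_max = float(np.max(np.abs(Xc.T @ yc)) / n)
    if lam_max <= 0:  # constant outcome or all-constant features
        lam_max = 1e-3
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max) - n_decades, grid_size)

    coefs = _path(Xc, yc, lambdas)
    intercepts = ym - xm @ coefs

    labels = table.risk.to_numpy()
    if len(np.unique(labels)) > 1:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:  # constant outcome: stratification is vacuous
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_mse = np.empty((folds, grid_size))
    for k, (tr, va) in enumerate(cv.split(X, labels)):
        Xtr_c, ytr_c, xm_k, ym_k = _centered(X[tr], y[tr])
        coefs_k = _path(Xtr_c, ytr_c, lambdas)
        pred = (X[va] - xm_k) @ coefs_k + ym_k  # n_va x L
        fold_mse[k] = ((pred - y[va][:, None]) ** 2).mean(axis=0)
    cv_mean = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(folds)

    i_min = int(np.argmin(cv_mean))
    lambda_min = float(lambdas[i_min])
    within = cv_mean <= cv_mean[i_min] + cv_se[i_min]
    lambda_1se = float(lambdas[np.argmax(within)])  # grid is decreasing: first hit is largest

    return LassoResult(
        feature_names=table.feature_names,
        lambda_grid=lambdas,
        coef_path=coefs,
        intercept_path=intercepts,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_min=lambda_min,
        lambda_1se=lambda_1se,
    )


def select_features(result: LassoResult, rule: str = "one_se") -> list[str]:
    """Features with nonzero coefficients at the chosen penalty, in input order."""
    if rule not in ("one_se", "min"):
        raise ValidationError(f"unknown selection rule {rule!r}")
    lam = result.lambda_1se if rule == "one_se" else result.lambda_min
    coef = result.coef_at(lam)
    selected = [n for n, c in zip(result.feature_names, coef) if abs(c) > _ZERO_TOL]
    if not selected:
        warnings.warn("Lasso selected no features at the chosen penalty", stacklevel=2)
    return selected


def kkt_max_violation(table: CohortTable, result: LassoResult) -> float:
    """Worst KKT residual of the L1 problem over the whole grid (oracle check).

    At a solution, (1/n) Xc' (yc - Xc b) must equal lambda * sign(b_j) for
    active coordinates and lie in [-lambda, lambda] for inactive ones.
    """
    X = table.features.to_numpy(dtype=float)
    y = table.risk.to_numpy(dtype=float)
    Xc, yc, _, _ = _centered(X, y)
    n = len(y)
    worst = 0.0
    for i, lam in enumerate(result.lambda_grid):
        b = result.coef_path[:, i]
        g = Xc.T @ (yc - Xc @ b) / n
        active = np.abs(b) > _ZERO_TOL
        if active.any():
            worst = max(worst, float(np.max(np.abs(g[active] - lam * np.sign(b[active])))))
        if (~active).any():
            worst = max(worst, float(np.max(np.abs(g[~active])) - lam))
    return worst
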