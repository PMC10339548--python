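"""Proportional-odds (cumulative-logit) ordinal logistic regression.

The model for an ordinal outcome Y in {1, ..., K} with covariates x is

    P(Y <= k | x) = sigmoid(theta_k - x @ beta),   theta_1 < ... < theta_{K-1},

so positive coefficients mean higher risk and exp(beta_j) is the common
odds ratio across every cumulative split.  The log-likelihood is maximized
by quasi-Newton (L-BFGS) from a zero start with analytic gradients, the
thresholds kept ordered through a log-gap reparameterization; standard
errors come from the inverse observed information.  Univariate screening,
multivariate independent-predictor selection by Wald p-value, and variance
inflation factors complete the regression workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .cohort import CohortTable
from .exceptions import ConvergenceError, ValidationError

_GRAD_TOL = 1e-6
_MAX_ITER = 500
# An effect span |beta_j| * range(x_j) beyond this (log-odds across the observed
# covariate range, i.e. an odds ratio of e^30) signals separation.
_EFFECT_DIVERGENCE = 30.0


@dataclass
class OLRFit:
    """Fitted proportional-odds model with Wald covariance."""

    beta: np.ndarray  # p
    theta: np.ndarray  # K-1, strictly increasing
    cov: np.ndarray  # (p + K - 1) square, parameter order (beta..., theta...)
    loglik: float
    covariate_names: list[str]
    n: int
    n_classes: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def linear_predictor(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta

    def predict_proba(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Class probabilities, rows summing to 1."""
        eta = self.linear_predictor(X)
        cum = expit(self.theta[None, :] - eta[:, None])  # P(Y <= k)
        cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
        return np.diff(cum, axis=1)

    def predict_class(self, X: np.ndarray | pd.DataFrame, classes=None) -> np.ndarray:
        classes = np.arange(1, self.n_classes + 1) if classes is None else np.asarray(classes)
        return classes[self.predict_proba(X).argmax(axis=1)]


def _encode_y(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("outcome must have at least 2 observed levels")
    lookup = {c: i for i, c in enumerate(classes)}
    return np.array([lookup[v] for v in y]), classes


def olr_loglik_grad(
    beta: np.ndarray, theta: np.ndarray, X: np.ndarray, y_idx: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood with analytic gradients w.r.t. beta and theta.

    Exposed (rather than private) so the finite-difference oracle in the
    test-suite can probe arbitrary parameter points.
    """
    K = len(theta) + 1
    eta = X @ beta
    theta_ext = np.concatenate(([-np.inf], theta, [np.inf]))
    z_up = theta_ext[y_idx + 1] - eta
    z_lo = theta_ext[y_idx] - eta
    F_up = expit(z_up)
    F_lo = expit(z_lo)
    pmf = np.clip(F_up - F_lo, 1e-300, None)
    ll = float(np.log(pmf).sum())

    f_up = F_up * (1.0 - F_up)
    f_lo = F_lo * (1.0 - F_lo)
    # d ll / d eta_i = -(f_up - f_lo)/pmf ; eta = X beta
    d_eta = -(f_up - f_lo) / pmf
    g_beta = X.T @ d_eta

    g_theta = np.zeros(K - 1)
    for k in range(1, K):
        up_mask = y_idx + 1 == k  # theta_k is the upper bound for class k
        lo_mask = y_idx == k  # and the lower bound for class k+1
        g_theta[k - 1] = (f_up[up_mask] / pmf[up_mask]).sum() - (
            f_lo[lo_mask] / pmf[lo_mask]
        ).sum()
    return ll, g_beta, g_theta


def _unpack(params: np.ndarray, p: int, K: int) -> tuple[np.ndarray, np.ndarray]:
    beta = params[:p]
    a = params[p:]
    theta = np.empty(K - 1)
    theta[0] = a[0]
    if K > 2:
        theta[1:] = a[0] + np.cumsum(np.exp(a[1:]))
    return beta, theta


def fit_olr(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    names: list[str] | None = None,
    ridge: float = 0.0,
) -> OLRFit:
    """Maximum-likelihood proportional-odds fit.

    ``ridge`` adds a Tikhonov penalty ridge * ||beta||^2 to the negative
    log-likelihood.  It is 0 by default (pure ML); a small positive value
    selects the minimum-norm solution when the design is rank-deficient —
    the importance-mapped feature matrix is one such design, since it has
    at most as many independent directions as there are ensemble models.

    Raises :class:`ConvergenceError` on separation (diverging coefficients),
    naming the offending covariate.
    """
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    n, p = X.shape
    if names is None:
        names = [f"x{j+1}" for j in range(p)]
    if np.ptp(X, axis=0).min() == 0:
        const = names[int(np.argmin(np.ptp(X, axis=0)))]
        raise ValidationError(f"constant covariate {const!r}; the thresholds absorb intercepts")
    y_idx, classes = _encode_y(y)
    K = len(classes)

    def objective(params: np.ndarray) -> tuple[float, np.ndarray]:
        beta, theta = _unpack(params, p, K)
        ll, g_beta, g_theta = olr_loglik_grad(beta, theta, X, y_idx)
        # chain rule onto (theta_1, log-gaps)
        g_a = np.empty(K - 1)
        g_a[0] = g_theta.sum()
        for m in range(1, K - 1):
            g_a[m] = g_theta[m:].sum() * np.exp(params[p + m])
        pen = ridge * float(beta @ beta)
        g_pen = 2.0 * ridge * beta
        return -(ll - pen), -np.concatenate([g_beta - g_pen, g_a])

    x0 = np.zeros(p + K - 1)  # zero start: beta = 0, theta = (0, 1, 2, ...)
    res = optimize.minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": _MAX_ITER, "ftol": 1e-14, "gtol": 1e-10},
    )
    beta, theta = _unpack(res.x, p, K)
    beta, theta = _newton_polish(beta, theta, X, y_idx, ridge)
    ll, g_beta, g_theta = olr_loglik_grad(beta, theta, X, y_idx)
    g_beta_pen = g_beta - 2.0 * ridge * beta
    grad_norm = max(np.abs(g_beta_pen).max(initial=0.0), np.abs(g_theta).max(initial=0.0))
    # with ridge > 0 the penalized objective has a finite optimum even under
    # separation, so the divergence guard applies to the pure-ML fit only
    effect_span = np.abs(beta) * np.ptp(X, axis=0)
    if ridge == 0.0 and effect_span.max(initial=0.0) > _EFFECT_DIVERGENCE:
        worst = names[int(np.argmax(effect_span))]
        raise ConvergenceError(
            f"effect of {worst!r} diverged (|beta|*range > {_EFFECT_DIVERGENCE:g}); "
            "likely separation"
        )
    if grad_norm > _GRAD_TOL:
        raise ConvergenceError(
            f"gradient inf-norm {grad_norm:.2e} above {_GRAD_TOL:g} after optimization"
        )

    cov = _wald_covariance(beta, theta, X, y_idx, ridge)
    return OLRFit(
        beta=beta,
        theta=theta,
        cov=cov,
        loglik=ll,
        covariate_names=list(names),
        n=n,
        n_classes=K,
    )


def _newton_polish(
    beta: np.ndarray,
    theta: np.ndarray,
    X: np.ndarray,
    y_idx: np.ndarray,
    ridge: float,
    max_steps: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped Newton refinement in (beta, theta) space to drive the gradient
    inf-norm below the convergence tolerance (the quasi-Newton stage may stop
    a hair short of it)."""
    p = len(beta)

    def neg_obj_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        b, t = x[:p], x[p:]
        ll, gb, gt = olr_loglik_grad(b, t, X, y_idx)
        return -(ll - ridge * float(b @ b)), -np.concatenate([gb - 2 * ridge * b, gt])

    x = np.concatenate([beta, theta])
    f, g = neg_obj_grad(x)
    for _ in range(max_steps):
        if np.abs(g).max() <= 0.1 * _GRAD_TOL:
            break
        m = len(x)
        H = np.zeros((m, m))
        for j in range(m):
            h = 1e-5 * (1.0 + abs(x[j]))
            e = np.zeros(m)
            e[j] = h
            H[:, j] = (neg_obj_grad(x + e)[1] - neg_obj_grad(x - e)[1]) / (2 * h)
        H = (H + H.T) / 2.0
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(m), -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -g, rcond=None)[0]
        t_len = 1.0
        for _ in range(30):  # backtracking; keep thresholds strictly ordered
            x_new = x + t_len * step
            if np.all(np.diff(x_new[p:]) > 0):
                f_new, g_new = neg_obj_grad(x_new)
                if f_new <= f + 1e-12:
                    x, f, g = x_new, f_new, g_new
                    break
            t_len /= 2.0
        else:
            break
    return x[:p], x[p:]


def _wald_covariance(
    beta: np.ndarray, theta: np.ndarray, X: np.ndarray, y_idx: np.ndarray,
    ridge: float = 0.0,
) -> np.ndarray:
    """Inverse observed information via central differences of the gradient."""
    p, K = len(beta), len(theta) + 1

    def grad(params: np.ndarray) -> np.ndarray:
        b, t = params[:p], np.sort(params[p:])
        _, gb, gt = olr_loglik_grad(b, t, X, y_idx)
        return np.concatenate([gb - 2.0 * ridge * b, gt])

    x = np.concatenate([beta, theta])
    m = len(x)
    H = np.zeros((m, m))
    for j in range(m):
        h = 1e-5 * (1.0 + abs(x[j]))
        e = np.zeros(m)
        e[j] = h
        H[:, j] = (grad(x + e) - grad(x - e)) / (2 * h)
    H = (H + H.T) / 2.0
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return cov


def wald_table(fit: OLRFit) -> pd.DataFrame:
    """Odds ratios with 95% Wald intervals and two-sided p-values per covariate."""
    from scipy.stats import norm

    se = fit.se[: len(fit.beta)]
    z = np.divide(fit.beta, se, out=np.zeros_like(fit.beta), where=se > 0)
    p = 2 * norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "covariate": fit.covariate_names,
            "odds_ratio": np.exp(fit.beta),
            "ci_low": np.exp(fit.beta - 1.96 * se),
            "ci_high": np.exp(fit.beta + 1.96 * se),
            "p_value": p,
        }
    )


def univariate_screen(
    table: CohortTable, covariates: list[str] | None = None, ridge: float = 0.0
) -> pd.DataFrame:
    """One single-covariate proportional-odds fit per feature (screening table).

    Covariates whose fit fails (e.g. separation) are reported with NaNs and
    the screen continues.
    """
    if table.risk is None:
        raise ValidationError("screening requires risk labels")
    covariates = covariates or table.feature_names
    rows = []
    for name in covariates:
        try:
            fit = fit_olr(
                table.features[[name]], table.risk.to_numpy(), names=[name], ridge=ridge
            )
            rows.append(wald_table(fit).iloc[0])
        except (ConvergenceError, ValidationError) as exc:
            warnings.warn(f"univariate fit failed for {name!r}: {exc}", stacklevel=2)
            rows.append(
                pd.Series(
                    {
                        "covariate": name,
                        "odds_ratio": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p_value": np.nan,
                    }
                )
            )
    return pd.DataFrame(rows).reset_index(drop=True)


def vif(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    R^2_j is from OLS of covariate j on the remaining covariates plus an
    intercept; exact collinearity yields +inf rather than an exception.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValidationError("VIF needs at least two covariates")
    out = np.empty(p)
    for j in range(p):
        target = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        tss = ((target - target.mean()) ** 2).sum()
        if tss <= 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - (resid**2).sum() / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def multivariate_select(
    table: CohortTable,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    vif_warn: float = 10.0,
    ridge: float = 0.0,
) -> tuple[OLRFit, list[str]]:
    """Fit the full multivariate model, keep Wald-significant covariates, refit.

    The kept covariates are the "independent predictors"; the returned fit is
    the refit on that subset.  High VIFs are flagged before selection.
    """
    if table.risk is None:
        raise ValidationError("selection requires risk labels")
    covariates = covariates or table.feature_names
    if len(covariates) < 2:
        raise ValidationError("multivariate selection needs at least two covariates")
    X = table.features[covariates]
    v = vif(X)
    if np.any(~np.isfinite(v)) or np.any(v > vif_warn):
        flagged = [c for c, vv in zip(covariates, v) if not np.isfinite(vv) or vv > vif_warn]
        warnings.warn(f"high collinearity (VIF > {vif_warn:g}) for {flagged}", stacklevel=2)
    full = fit_olr(X, table.risk.to_numpy(), names=covariates, ridge=ridge)
    tab = wald_table(full)
    kept = tab.loc[tab["p_value"] < alpha, "covariate"].tolist()
    if not kept:
        raise ValidationError(
            f"no covariate reached Wald p < {alpha:g}; cannot build an empty model"
        )
    if kept == covariates:
        return full, kept
    refit = fit_olr(table.features[kept], table.risk.to_numpy(), names=kept, ridge=ridge)
    return refit, kept
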