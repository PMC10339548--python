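"""Point-scale nomograms and the feature-mapping conversion.

A fitted proportional-odds model becomes a nomogram by mapping each
covariate's contribution to a 0-100 point axis: the covariate with the
widest effect range |beta| * (hi - lo) spans exactly 100 points, every axis
is 0 at its protective extreme, and total points are an affine bijection of
the linear predictor eta, which in turn yields the three class
probabilities.

The feature-mapping step projects a nomogram whose axes are *model
predictions* back onto clinic features: with FI the (feature x model)
matrix of normalized importances and MV the per-patient vector of
scalarized model predictions,

    CF_i = sum_j FI[i, j] * MV[j],

which conserves the total (sum_i CF_i = sum_j MV_j) because every
importance column sums to 1.  Refitting the ordinal model on the CF matrix
yields a nomogram expressed in clinic features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ValidationError
from .learners import EnsemblePredictions
from .ordinal import OLRFit

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


@dataclass(frozen=True)
class RiskCutoffs:
    """Tripartite cutoffs on the predictive score: low <= c1 < intermediate <= c2 < high."""

    c1: float
    c2: float

    def __post_init__(self) -> None:
        if not self.c1 < self.c2:
            raise ValidationError("cutoffs require c1 < c2")


@dataclass
class Nomogram:
    """Point-scale representation of a proportional-odds fit."""

    covariate_names: list[str]
    beta: np.ndarray
    theta: np.ndarray
    ranges: np.ndarray  # p x 2, [lo, hi] per covariate
    delta: float  # widest effect span: max_k |beta_k| * (hi_k - lo_k)
    eta_min: float  # linear predictor when every axis sits at 0 points

    # -- per-axis point geometry -------------------------------------------------
    def axis_points(self, values: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Points earned on each axis (affine in the covariate, >= 0)."""
        V = self._coerce(values)
        lo, hi = self.ranges[:, 0], self.ranges[:, 1]
        anchor = np.where(self.beta > 0, lo, hi)
        return 100.0 * self.beta * (V - anchor) / self.delta

    def total_points(self, values: np.ndarray | pd.DataFrame) -> np.ndarray:
        return self.axis_points(values).sum(axis=1)

    @property
    def max_axis_points(self) -> np.ndarray:
        span = np.abs(self.beta) * (self.ranges[:, 1] - self.ranges[:, 0])
        return 100.0 * span / self.delta

    # -- score map ----------------------------------------------------------------
    def points_to_eta(self, total_points: np.ndarray | float) -> np.ndarray | float:
        return self.eta_min + np.asarray(total_points) * self.delta / 100.0

    def eta_to_points(self, eta: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(eta) - self.eta_min) * 100.0 / self.delta

    def class_probs_from_eta(self, eta: np.ndarray) -> np.ndarray:
        eta = np.atleast_1d(np.asarray(eta, dtype=float))
        cum = expit(self.theta[None, :] - eta[:, None])
        cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
        return np.diff(cum, axis=1)

    def prob_table(self, n_grid: int = 101) -> pd.DataFrame:
        """Total-points -> class-probability lookup on an even grid."""
        T = np.linspace(0.0, float(self.max_axis_points.sum()), n_grid)
        probs = self.class_probs_from_eta(self.points_to_eta(T))
        return pd.DataFrame(
            {
                "total_points": T,
                "p_low": probs[:, 0],
                "p_intermediate": probs[:, 1],
                "p_high": probs[:, 2],
            }
        )

    def score(self, record: np.ndarray | pd.DataFrame | dict) -> tuple[np.ndarray, np.ndarray]:
        """(eta, total_points) for one or more records; values clipped to ranges."""
        V = self._coerce(record)
        lo, hi = self.ranges[:, 0], self.ranges[:, 1]
        if np.any(V < lo - 1e-12) or np.any(V > hi + 1e-12):
            warnings.warn("record values outside axis ranges were clipped", stacklevel=2)
            V = np.clip(V, lo, hi)
        eta = V @ self.beta
        return eta, self.total_points(V)

    def _coerce(self, values) -> np.ndarray:
        if isinstance(values, dict):
            missing = [c for c in self.covariate_names if c not in values]
            if missing:
                raise ValidationError(f"record missing axis values for {missing}")
            values = np.array([[values[c] for c in self.covariate_names]], dtype=float)
        elif isinstance(values, pd.DataFrame):
            missing = [c for c in self.covariate_names if c not in values.columns]
            if missing:
                raise ValidationError(f"record missing axis values for {missing}")
            values = values[self.covariate_names].to_numpy(dtype=float)
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[None, :]
        if values.shape[1] != len(self.covariate_names):
            raise ValidationError("record width does not match nomogram axes")
        return values

    # -- serialization ------------------------------------------------------------
    def save(self, directory: str | Path, n_grid: int = 101) -> None:
        """Delimited-text lookup bundle: model params, axis tables, prob table."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        model = pd.DataFrame(
            {
                "covariate": self.covariate_names,
                "beta": self.beta,
                "lo": self.ranges[:, 0],
                "hi": self.ranges[:, 1],
            }
        )
        model.to_csv(d / "model.csv", index=False, float_format=_FLOAT_FMT)
        pd.DataFrame({"theta": self.theta}).to_csv(
            d / "thresholds.csv", index=False, float_format=_FLOAT_FMT
        )
        rows = []
        for i, name in enumerate(self.covariate_names):
            grid = np.linspace(self.ranges[i, 0], self.ranges[i, 1], n_grid)
            V = np.tile(self.ranges[:, 0], (n_grid, 1))
            V[:, i] = grid
            pts = self.axis_points(V)[:, i]
            rows.append(pd.DataFrame({"covariate": name, "value": grid, "points": pts}))
        pd.concat(rows).to_csv(d / "axes.csv", index=False, float_format=_FLOAT_FMT)
        self.prob_table(n_grid).to_csv(
            d / "prob_table.csv", index=False, float_format=_FLOAT_FMT
        )

    @classmethod
    def load(cls, directory: str | Path) -> "Nomogram":
        d = Path(directory)
        model = pd.read_csv(d / "model.csv", float_precision="round_trip")
        theta = pd.read_csv(
            d / "thresholds.csv", float_precision="round_trip"
        )["theta"].to_numpy()
        return build_nomogram(
            OLRFit(
                beta=model["beta"].to_numpy(),
                theta=theta,
                cov=np.zeros((len(model) + len(theta),) * 2),
                loglik=np.nan,
                covariate_names=model["covariate"].tolist(),
                n=0,
                n_classes=len(theta) + 1,
            ),
            ranges=model[["lo", "hi"]].to_numpy(),
        )


def build_nomogram(fit: OLRFit, ranges: np.ndarray | None = None, X=None) -> Nomogram:
    """Construct the point scale from a fitted model and per-covariate ranges.

    ``ranges`` defaults to the observed min/max of ``X`` (the training data).
    """
    if ranges is None:
        if X is None:
            raise ValidationError("provide ranges or training data X")
        arr = np.asarray(X, dtype=float)
        ranges = np.column_stack([arr.min(axis=0), arr.max(axis=0)])
    ranges = np.asarray(ranges, dtype=float)
    if ranges.shape != (len(fit.beta), 2):
        raise ValidationError("ranges must be a (p, 2) array of [lo, hi]")
    widths = ranges[:, 1] - ranges[:, 0]
    if np.any(widths <= 0):
        bad = [fit.covariate_names[i] for i in np.where(widths <= 0)[0]]
        raise ValidationError(f"zero-width axis range for {bad}")
    spans = np.abs(fit.beta) * widths
    delta = float(spans.max())
    if delta <= 0:
        raise ValidationError("all coefficients are zero; no nomogram axis")
    anchor = np.where(fit.beta > 0, ranges[:, 0], ranges[:, 1])
    eta_min = float(anchor @ fit.beta)
    return Nomogram(
        covariate_names=list(fit.covariate_names),
        beta=fit.beta.copy(),
        theta=fit.theta.copy(),
        ranges=ranges,
        delta=delta,
        eta_min=eta_min,
    )


@dataclass
class FMAResult:
    """Clinic-feature values obtained by importance-weighted back-mapping."""

    CF: pd.DataFrame  # patients x M clinic features
    FI: pd.DataFrame  # M x N (kept models), columns on the simplex
    MV: pd.DataFrame  # patients x N scalarized model predictions


def fma_convert(
    ensemble: EnsemblePredictions | None = None,
    kept_models: list[str] | None = None,
    *,
    FI: pd.DataFrame | None = None,
    MV: pd.DataFrame | None = None,
) -> FMAResult:
    """Project model-prediction axes onto clinic features: CF = MV @ FI^T.

    Either pass a trained ensemble plus the stacking-retained model names, or
    supply the FI (feature x model) and MV (patient x model) blocks directly.
    """
    if ensemble is not None:
        kept = kept_models or ensemble.model_names
        FI = ensemble.importances[kept]
        MV = ensemble.meta_features[kept]
    if FI is None or MV is None:
        raise ValidationError("provide an ensemble or both FI and MV")
    if list(FI.columns) != list(MV.columns):
        raise ValidationError("FI and MV must cover the same models in the same order")
    col_sums = FI.to_numpy().sum(axis=0)
    if np.any(FI.to_numpy() < -1e-12) or np.any(np.abs(col_sums - 1.0) > 1e-6):
        raise ValidationError("each importance column must lie on the simplex")
    CF = pd.DataFrame(
        MV.to_numpy() @ FI.to_numpy().T, index=MV.index, columns=FI.index
    )
    return FMAResult(CF=CF, FI=FI.copy(), MV=MV.copy())


def analytic_clinic_beta(FI: pd.DataFrame, beta_ml: np.ndarray) -> pd.Series:
    """Alternative to refitting: push model coefficients through FI (beta_clinic = FI @ beta)."""
    return pd.Series(FI.to_numpy() @ np.asarray(beta_ml), index=FI.index)


def classify(scores: np.ndarray, cutoffs: RiskCutoffs) -> np.ndarray:
    """Tripartite labels from scores: <= c1 low, (c1, c2] intermediate, > c2 high."""
    scores = np.asarray(scores, dtype=float)
    return np.where(scores <= cutoffs.c1, 1, np.where(scores <= cutoffs.c2, 2, 3))


def derive_cutoffs(
    scores: np.ndarray,
    labels: np.ndarray,
    max_candidates: int = 512,
) -> tuple[RiskCutoffs, float]:
    """Grid-search the cutoff pair maximizing macro-averaged per-class recall.

    Candidates are midpoints between consecutive distinct scores (quantile
    thinned above ``max_candidates``); ties prefer the smaller c1 then the
    smaller c2.  Returns the cutoffs together with the achieved macro recall
    so chance-level performance is visible alongside the thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 3:
        raise ValidationError("cutoff derivation needs all three classes present")
    uniq = np.unique(scores)
    if len(uniq) < 3:
        raise ValidationError("scores are (near-)degenerate; cannot place two cutoffs")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    if len(mids) > max_candidates:
        qs = np.linspace(0, 1, max_candidates)
        mids = np.unique(np.quantile(mids, qs))

    n_k = {k: max((labels == k).sum(), 1) for k in (1, 2, 3)}
    s1 = np.sort(scores[labels == 1])
    s2 = np.sort(scores[labels == 2])
    s3 = np.sort(scores[labels == 3])
    # recall terms as step functions of the candidate thresholds
    r1 = np.searchsorted(s1, mids, side="right") / n_k[1]  # P(score<=c1 | low)
    c2_low = np.searchsorted(s2, mids, side="right") / n_k[2]
    r3 = 1.0 - np.searchsorted(s3, mids, side="right") / n_k[3]  # P(score>c2 | high)

    # macro recall = [r1(c1) - F2(c1)]/3 + [F2(c2) + r3(c2)]/3, separable in c1, c2
    A = r1 - c2_low  # function of c1
    B = c2_low + r3  # function of c2
    best = (-np.inf, np.inf, np.inf)
    m = len(mids)
    # prefix maxima of A allow an O(m) sweep over c2 with the c1 < c2 constraint
    bestA = np.full(m, -np.inf)
    bestA_idx = np.zeros(m, dtype=int)
    run, run_idx = -np.inf, 0
    for i in range(m):
        if A[i] > run:  # strict: keeps the smallest argmax on ties
            run, run_idx = A[i], i
        bestA[i], bestA_idx[i] = run, run_idx
    for j in range(1, m):
        total = (bestA[j - 1] + B[j]) / 3.0
        cand = (total, mids[bestA_idx[j - 1]], mids[j])
        if total > best[0] + 1e-15 or (
            abs(total - best[0]) <= 1e-15 and (cand[1], cand[2]) < (best[1], best[2])
        ):
            best = cand
    acc, c1, c2 = best
    return RiskCutoffs(c1=float(c1), c2=float(c2)), float(acc)
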