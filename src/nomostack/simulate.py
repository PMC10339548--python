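"""Synthetic patient cohorts with per-risk-group marginal statistics.

The real lymphocyte-subset cohort is not publicly deposited, so this module
generates stand-in cohorts that reproduce the published per-group means and
standard deviations of the training set (group prevalences 47:38:72 for
low/intermediate/high).  Each feature is drawn per group from either a
floor-truncated normal or a moment-matched lognormal (for right-skewed
biomarkers whose high-risk SD exceeds the mean, e.g. PSA); an optional
Gaussian copula imposes a user-supplied feature correlation structure —
none is invented by default because only marginal moments are published.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import RISK_HIGH, RISK_INTERMEDIATE, RISK_LOW, CohortTable
from .exceptions import ValidationError

TRUNCATED_NORMAL = "truncated_normal"
LOGNORMAL = "lognormal"


@dataclass(frozen=True)
class FeatureSpec:
    """Marginal distribution of one feature within one risk group."""

    mean: float
    sd: float
    family: str = TRUNCATED_NORMAL
    floor: float = 0.0
    cap: float = np.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be nonnegative")
        if self.floor > self.cap:
            raise ValidationError("floor must not exceed cap")
        if self.family not in (TRUNCATED_NORMAL, LOGNORMAL):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.family == LOGNORMAL and self.mean <= 0:
            raise ValidationError("lognormal requires a strictly positive mean")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function used by the (copula) sampler."""
        if self.sd == 0:
            return np.full_like(u, self.mean, dtype=float)
        if self.family == LOGNORMAL:
            # moment matching: E=mean, Var=sd^2
            sigma2 = np.log1p((self.sd / self.mean) ** 2)
            mu = np.log(self.mean) - sigma2 / 2.0
            x = stats.lognorm(s=np.sqrt(sigma2), scale=np.exp(mu)).ppf(u)
            return np.clip(x, self.floor, self.cap)
        a = (self.floor - self.mean) / self.sd
        b = (self.cap - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd).ppf(u)


@dataclass(frozen=True)
class GroupProfile:
    """All feature marginals for one ordinal risk group."""

    group: int
    features: Mapping[str, FeatureSpec]


@dataclass
class CohortSpec:
    """Full generative spec: size, group mixture, per-group marginals, copula."""

    n: int
    group_weights: tuple[float, float, float]
    profiles: dict[int, GroupProfile]
    correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.group_weights, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValidationError("group weights must be nonnegative and sum to 1")
        names = self.feature_names
        for p in self.profiles.values():
            if list(p.features) != names:
                raise ValidationError("all group profiles must share one feature list")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (len(names), len(names)):
                raise ValidationError("correlation matrix shape must match features")
            if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
                raise ValidationError("correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise ValidationError("correlation matrix must be positive semi-definite")

    @property
    def feature_names(self) -> list[str]:
        first = self.profiles[min(self.profiles)]
        return list(first.features)


# Published training-set group statistics (mean, sd) for low/intermediate/high,
# with the sampling family and hard physiological floors/caps.  The first nine
# features are the panel retained by L1 selection in the source cohort; the
# remaining eight are weakly separated decoys so selection has work to do.
_BUILTIN_ROWS: dict[str, dict] = {
    "Age": dict(stats=[(63.23, 8.18), (65.53, 7.10), (68.57, 7.42)],
                family=TRUNCATED_NORMAL, floor=18.0, unit="years"),
    "Alkaline phosphatase": dict(stats=[(73.62, 29.75), (67.87, 15.89), (229.25, 556.22)],
                                 family=LOGNORMAL, unit="U/L"),
    "B cells": dict(stats=[(12.74, 5.69), (12.55, 6.07), (11.54, 5.20)],
                    family=TRUNCATED_NORMAL, cap=100.0, unit="%"),
    "Interleukin-1b": dict(stats=[(6.55, 4.06), (5.92, 3.05), (8.69, 8.10)],
                           family=LOGNORMAL, unit="pg/mL"),
    "Interleukin-2R": dict(stats=[(427.45, 189.32), (444.39, 149.37), (572.76, 425.87)],
                           family=LOGNORMAL, unit="U/mL"),
    "Lactate dehydrogenase": dict(stats=[(168.89, 37.15), (157.05, 34.14), (200.83, 129.90)],
                                  family=LOGNORMAL, unit="U/L"),
    "Neutrophil percentage": dict(stats=[(65.96, 11.34), (58.69, 10.44), (60.51, 9.04)],
                                  family=TRUNCATED_NORMAL, cap=100.0, unit="%"),
    "PSA": dict(stats=[(7.56, 7.24), (12.67, 9.50), (199.62, 312.92)],
                family=LOGNORMAL, cap=1000.0, unit="ng/mL"),
    "Th/Ts": dict(stats=[(2.17, 0.88), (2.24, 0.79), (2.55, 1.19)],
                  family=LOGNORMAL, unit="ratio"),
    "Lymphocyte percentage": dict(stats=[(23.33, 9.44), (29.32, 9.25), (26.65, 7.77)],
                                  family=TRUNCATED_NORMAL, cap=100.0, unit="%"),
    "Lymphocytes": dict(stats=[(1.52, 0.65), (1.64, 0.57), (1.53, 0.42)],
                        family=TRUNCATED_NORMAL, unit="1e9/L"),
    "Hemoglobin": dict(stats=[(134.13, 16.14), (137.16, 11.84), (128.82, 15.81)],
                       family=TRUNCATED_NORMAL, unit="g/L"),
    "ALT": dict(stats=[(21.72, 13.18), (19.13, 12.07), (18.83, 14.52)],
                family=LOGNORMAL, unit="U/L"),
    "T cells": dict(stats=[(67.57, 8.16), (67.44, 9.43), (67.92, 10.43)],
                    family=TRUNCATED_NORMAL, cap=100.0, unit="%"),
    "Ts cells": dict(stats=[(22.14, 7.31), (20.36, 5.49), (19.94, 6.61)],
                     family=TRUNCATED_NORMAL, cap=100.0, unit="%"),
    "NK cells": dict(stats=[(18.86, 8.17), (19.27, 9.26), (19.76, 10.84)],
                     family=TRUNCATED_NORMAL, cap=100.0, unit="%"),
    "Interleukin-6": dict(stats=[(3.79, 4.86), (4.99, 13.06), (9.87, 14.87)],
                          family=LOGNORMAL, floor=1.5, unit="pg/mL"),
}

#: Training-set group sizes behind the builtin mixture weights.
BUILTIN_GROUP_COUNTS = {RISK_LOW: 47, RISK_INTERMEDIATE: 38, RISK_HIGH: 72}

#: Features retained by L1 selection in the source cohort.
SELECTED_NINE = (
    "Age",
    "Alkaline phosphatase",
    "B cells",
    "Interleukin-1b",
    "Interleukin-2R",
    "Lactate dehydrogenase",
    "Neutrophil percentage",
    "PSA",
    "Th/Ts",
)


def builtin_units() -> dict[str, str]:
    return {name: row["unit"] for name, row in _BUILTIN_ROWS.items()}


def builtin_profile(n: int = 157, seed: int = 0) -> CohortSpec:
    """CohortSpec carrying the published training-set group moments."""
    profiles: dict[int, GroupProfile] = {}
    for k, group in enumerate((RISK_LOW, RISK_INTERMEDIATE, RISK_HIGH)):
        feats = {}
        for name, row in _BUILTIN_ROWS.items():
            mean, sd = row["stats"][k]
            feats[name] = FeatureSpec(
                mean=mean,
                sd=sd,
                family=row["family"],
                floor=row.get("floor", 0.0 if row["family"] == TRUNCATED_NORMAL else 1e-6),
                cap=row.get("cap", np.inf),
            )
        profiles[group] = GroupProfile(group=group, features=feats)
    total = sum(BUILTIN_GROUP_COUNTS.values())
    weights = tuple(BUILTIN_GROUP_COUNTS[g] / total for g in (RISK_LOW, RISK_INTERMEDIATE, RISK_HIGH))
    return CohortSpec(n=n, group_weights=weights, profiles=profiles, seed=seed)


def generate(spec: CohortSpec, n: int | None = None, seed: int | None = None) -> CohortTable:
    """Draw a labeled cohort from ``spec``; deterministic under its seed.

    Group membership is multinomial in ``group_weights``; features are drawn
    from the group's marginals through inverse-CDF sampling of uniforms that
    are either independent (default) or coupled by a Gaussian copula when
    ``spec.correlation`` is given.
    """
    spec = replace(spec, n=spec.n if n is None else n, seed=spec.seed if seed is None else seed)
    if spec.n < 1:
        raise ValidationError("cohort size must be at least 1")
    rng = np.random.default_rng(spec.seed)
    names = spec.feature_names
    groups = rng.choice(
        sorted(spec.profiles), size=spec.n, p=np.asarray(spec.group_weights, dtype=float)
    )
    if spec.correlation is not None:
        C = np.asarray(spec.correlation, dtype=float)
        w, V = np.linalg.eigh(C)
        root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        z = rng.standard_normal((spec.n, len(names))) @ root.T
        u = stats.norm.cdf(z)
    else:
        u = rng.uniform(size=(spec.n, len(names)))
    u = np.clip(u, 1e-12, 1 - 1e-12)

    X = np.empty((spec.n, len(names)))
    for g, profile in spec.profiles.items():
        mask = groups == g
        if not mask.any():
            continue
        for j, name in enumerate(names):
            X[mask, j] = profile.features[name].ppf(u[mask, j])

    ids = [f"P{i+1:05d}" for i in range(spec.n)]
    feats = pd.DataFrame(X, index=ids, columns=names)
    risk = pd.Series(groups.astype(int), index=ids, name="risk")
    return CohortTable(feats, risk, builtin_units() if names == list(_BUILTIN_ROWS) else {})


def profile_from_yaml(path: str | Path) -> CohortSpec:
    """Load a CohortSpec from the package's YAML profile dialect."""
    doc = yaml.safe_load(Path(path).read_text())
    profiles: dict[int, GroupProfile] = {}
    for g_str, feats in doc["profiles"].items():
        g = int(g_str)
        specs = {
            name: FeatureSpec(
                mean=float(f["mean"]),
                sd=float(f["sd"]),
                family=f.get("family", TRUNCATED_NORMAL),
                floor=float(f.get("floor", 0.0)),
                cap=float(f.get("cap", np.inf)),
            )
            for name, f in feats.items()
        }
        profiles[g] = GroupProfile(group=g, features=specs)
    corr = doc.get("correlation")
    return CohortSpec(
        n=int(doc.get("n", 157)),
        group_weights=tuple(float(w) for w in doc["group_weights"]),
        profiles=profiles,
        correlation=None if corr is None else np.asarray(corr, dtype=float),
        seed=int(doc.get("seed", 0)),
    )


def profile_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    doc = {
        "n": spec.n,
        "seed": spec.seed,
        "group_weights": [float(w) for w in spec.group_weights],
        "profiles": {
            str(g): {
                name: {
                    "mean": f.mean,
                    "sd": f.sd,
                    "family": f.family,
                    "floor": None if np.isneginf(f.floor) else float(f.floor),
                    "cap": None if np.isposinf(f.cap) else float(f.cap),
                }
                for name, f in p.features.items()
            }
            for g, p in spec.profiles.items()
        },
    }
    if spec.correlation is not None:
        doc["correlation"] = np.asarray(spec.correlation).tolist()
    # strip null caps so the file round-trips through FeatureSpec defaults
    for feats in doc["profiles"].values():
        for f in feats.values():
            if f["cap"] is None:
                f["cap"] = float("inf")
            if f["floor"] is None:
                f["floor"] = float("-inf")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
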