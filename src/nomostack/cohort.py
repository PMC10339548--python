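"""Cohort ingestion, quality control, truncation, normalization and splitting.

A cohort is a patient-by-feature table of laboratory/clinical measurements
with an optional ordinal risk label per patient (1 = low, 2 = intermediate,
3 = high).  Rows with missing or non-numeric feature values are rejected at
read time; a handful of assay-limited features are truncated at configured
caps/floors; features are min-max normalized to [0, 1]; and the cohort is
split 4:1 into training and test sets, stratified by risk group by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    ConfigurationError,
    EmptyCohortError,
    StratificationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Ordinal risk codes, low < intermediate < high.
RISK_LOW, RISK_INTERMEDIATE, RISK_HIGH = 1, 2, 3
RISK_LEVELS = (RISK_LOW, RISK_INTERMEDIATE, RISK_HIGH)
RISK_NAMES = {RISK_LOW: "low", RISK_INTERMEDIATE: "intermediate", RISK_HIGH: "high"}

#: Clinical T-stage codes in increasing order of local extent.
T_STAGES = ("T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3a", "T3b", "T4")


@dataclass(frozen=True)
class CapRule:
    """Truncation rule for one feature: cap from above or floor from below.

    Assay detection limits make some recorded values unreliable past a
    threshold; those values are replaced by the threshold itself.
    """

    feature_name: str
    kind: str  # "upper_cap" | "lower_floor"
    threshold: float

    def __post_init__(self) -> None:
        if self.kind not in ("upper_cap", "lower_floor"):
            raise ValidationError(f"unknown cap rule kind {self.kind!r}")
        if not np.isfinite(self.threshold):
            raise ValidationError("cap rule threshold must be finite")


#: Default truncation config for the prostate-cancer lymphocyte-subset panel:
#: PSA capped at 1000 ng/mL; ALT, IL-6 and IL-1β floored at their assay
#: detection limits (5, 1.5 and 5).
DEFAULT_CAP_RULES = (
    CapRule("PSA", "upper_cap", 1000.0),
    CapRule("ALT", "lower_floor", 5.0),
    CapRule("Interleukin-6", "lower_floor", 1.5),
    CapRule("Interleukin-1b", "lower_floor", 5.0),
)


@dataclass
class NormalizationStats:
    """Per-feature min/max of the fitting cohort; re-applicable and invertible."""

    min_: pd.Series
    max_: pd.Series

    def __post_init__(self) -> None:
        if not (self.max_ >= self.min_).all():
            raise ValidationError("normalization stats require max >= min per feature")

    @property
    def feature_names(self) -> list[str]:
        return list(self.min_.index)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            name: {"min": float(self.min_[name]), "max": float(self.max_[name])}
            for name in self.feature_names
        }
        Path(path).write_text(yaml.safe_dump({"normalization": payload}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NormalizationStats":
        payload = yaml.safe_load(Path(path).read_text())["normalization"]
        names = list(payload)
        return cls(
            min_=pd.Series({n: payload[n]["min"] for n in names}, dtype=float),
            max_=pd.Series({n: payload[n]["max"] for n in names}, dtype=float),
        )


def cap_rules_to_yaml(rules: Iterable[CapRule], path: str | Path) -> None:
    payload = [
        {"feature": r.feature_name, "kind": r.kind, "threshold": float(r.threshold)}
        for r in rules
    ]
    Path(path).write_text(yaml.safe_dump({"truncation": payload}, sort_keys=False))


def cap_rules_from_yaml(path: str | Path) -> list[CapRule]:
    payload = yaml.safe_load(Path(path).read_text())["truncation"]
    return [CapRule(r["feature"], r["kind"], float(r["threshold"])) for r in payload]


@dataclass
class CohortTable:
    """Patient-by-feature matrix with optional ordinal risk labels.

    ``features`` is indexed by opaque patient ids; ``risk`` (when present) is
    aligned to the same index with values in {1, 2, 3}.  ``units`` carries
    free-text measurement units per feature.
    """

    features: pd.DataFrame
    risk: pd.Series | None = None
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.risk is not None:
            self.risk = self.risk.astype(int)
            if not self.risk.index.equals(self.features.index):
                raise ValidationError("risk labels must align with the feature index")
            bad = set(self.risk.unique()) - set(RISK_LEVELS)
            if bad:
                raise ValidationError(f"risk labels outside {{1,2,3}}: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def patient_ids(self) -> list[str]:
        return [str(i) for i in self.features.index]

    def subset_features(self, names: Sequence[str]) -> "CohortTable":
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise ConfigurationError(f"unknown features: {missing}")
        return CohortTable(
            self.features[list(names)].copy(),
            None if self.risk is None else self.risk.copy(),
            {k: v for k, v in self.units.items() if k in names},
        )

    def to_csv(self, path: str | Path, sep: str = ",", label_col: str = "risk") -> None:
        out = self.features.copy()
        if self.risk is not None:
            out[label_col] = self.risk
        out.to_csv(path, sep=sep, index_label="patient_id")


def read_cohort(
    path: str | Path,
    label_col: str = "risk",
    sep: str = ",",
    id_col: str = "patient_id",
    units: Mapping[str, str] | None = None,
) -> CohortTable:
    """Read a delimited-text cohort, dropping rows with missing feature values.

    The header row is mandatory.  ``label_col`` and ``id_col`` are optional in
    the file; all remaining columns are treated as numeric features.  Rows
    containing any missing/non-numeric feature cell are excluded (mirroring a
    complete-case design) and the exclusion count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cohort file not found: {path}")
    raw = pd.read_csv(path, sep=sep, na_values=["", "NA"], dtype=str)
    if id_col in raw.columns:
        raw = raw.set_index(id_col)
    else:
        raw.index = [f"row{i+1}" for i in range(len(raw))]

    risk_raw = raw.pop(label_col) if label_col in raw.columns else None
    feats = raw.apply(pd.to_numeric, errors="coerce")
    keep = feats.notna().all(axis=1)
    if risk_raw is not None:
        risk_num = pd.to_numeric(risk_raw, errors="coerce")
        keep &= risk_num.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "read_cohort: excluded %d of %d rows with missing/non-numeric values",
            n_dropped,
            len(feats),
        )
    feats = feats.loc[keep].astype(float)
    if feats.empty:
        raise EmptyCohortError(f"no complete rows in {path}")
    if not np.isfinite(feats.to_numpy()).all():
        raise ValidationError("non-finite feature values after parsing")
    risk = risk_num.loc[keep].astype(int) if risk_raw is not None else None
    return CohortTable(feats, risk, dict(units or {}))


def apply_truncation(table: CohortTable, rules: Iterable[CapRule]) -> CohortTable:
    """Clip feature values at the configured caps/floors; returns a new table."""
    feats = table.features.copy()
    for rule in rules:
        if rule.feature_name not in feats.columns:
            raise ConfigurationError(
                f"truncation rule names absent feature {rule.feature_name!r}"
            )
        col = feats[rule.feature_name]
        if rule.kind == "upper_cap":
            feats[rule.feature_name] = col.clip(upper=rule.threshold)
        else:
            feats[rule.feature_name] = col.clip(lower=rule.threshold)
    return replace(table, features=feats)


def drop_feature(table: CohortTable, name: str) -> CohortTable:
    """Remove one feature column (e.g. an assay with too many duplicate values)."""
    if name not in table.features.columns:
        raise ConfigurationError(f"cannot drop absent feature {name!r}")
    units = {k: v for k, v in table.units.items() if k != name}
    return CohortTable(table.features.drop(columns=[name]), table.risk, units)


def min_max_normalize(
    table: CohortTable, stats: NormalizationStats | None = None
) -> tuple[CohortTable, NormalizationStats]:
    """Scale each feature to [0, 1] via x' = (x - min) / (max - min).

    With ``stats`` supplied (transforming held-out data with the fitting
    cohort's ranges) values are clipped into [0, 1].  Constant features map
    to 0 with a warning rather than being dropped.
    """
    feats = table.features
    if stats is None:
        if table.n == 0:
            raise EmptyCohortError("cannot fit normalization on an empty cohort")
        stats = NormalizationStats(feats.min(axis=0), feats.max(axis=0))
        clip = False
    else:
        if list(stats.feature_names) != table.feature_names:
            raise ConfigurationError("normalization stats do not match table features")
        clip = True
    span = stats.max_ - stats.min_
    constant = span <= 0
    if constant.any():
        warnings.warn(
            f"constant features normalized to 0: {list(span.index[constant])}",
            stacklevel=2,
        )
    safe_span = span.where(~constant, 1.0)
    out = (feats - stats.min_) / safe_span
    out.loc[:, constant[constant].index] = 0.0
    if clip:
        out = out.clip(0.0, 1.0)
    return replace(table, features=out), stats


def inverse_normalize(table: CohortTable, stats: NormalizationStats) -> CohortTable:
    """Undo :func:`min_max_normalize` (exact on non-constant features)."""
    span = (stats.max_ - stats.min_).where(stats.max_ > stats.min_, 0.0)
    feats = table.features * span + stats.min_
    return replace(table, features=feats)


def assign_risk_label(psa: float, isup_grade: int, stage: str) -> int:
    """Tripartite risk from PSA (ng/mL), ISUP grade group and clinical T stage.

    Standard guideline thresholds: low risk requires PSA < 10, ISUP 1 and
    stage <= T2a; any of PSA > 20, ISUP >= 4 or stage >= T2c makes high risk;
    everything else is intermediate.
    """
    if not np.isfinite(psa) or psa < 0:
        raise ValidationError(f"PSA out of range: {psa}")
    if isup_grade not in (1, 2, 3, 4, 5):
        raise ValidationError(f"ISUP grade group must be 1-5, got {isup_grade}")
    if stage not in T_STAGES:
        raise ValidationError(f"unknown T stage {stage!r}")
    stage_idx = T_STAGES.index(stage)
    t2a, t2c = T_STAGES.index("T2a"), T_STAGES.index("T2c")
    if psa > 20 or isup_grade >= 4 or stage_idx >= t2c:
        return RISK_HIGH
    if psa < 10 and isup_grade == 1 and stage_idx <= t2a:
        return RISK_LOW
    return RISK_INTERMEDIATE


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_test(
    table: CohortTable,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[CohortTable, CohortTable]:
    """Random disjoint train/test partition, stratified by risk group by default.

    Stratified allocation rounds each stratum's test count to the nearest
    integer (half up), so group proportions deviate from ``test_fraction`` by
    less than 1/stratum size; the total test count is the sum over strata.
    """
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    index = table.features.index

    if stratified:
        if table.risk is None:
            raise ValidationError("stratified split requires risk labels")
        test_ids: list = []
        for level in sorted(table.risk.unique()):
            members = index[table.risk == level]
            n_s = len(members)
            if n_s < 2:
                raise StratificationError(
                    f"stratum {RISK_NAMES.get(level, level)} has {n_s} member(s); "
                    "need at least 2"
                )
            n_test = min(max(_round_half_up(n_s * test_fraction), 1), n_s - 1)
            perm = rng.permutation(n_s)
            test_ids.extend(members[perm[:n_test]])
        test_mask = index.isin(test_ids)
    else:
        n_test = min(max(_round_half_up(table.n * test_fraction), 1), table.n - 1)
        perm = rng.permutation(table.n)
        test_mask = np.zeros(table.n, dtype=bool)
        test_mask[perm[:n_test]] = True

    def _take(mask: np.ndarray) -> CohortTable:
        return CohortTable(
            table.features.loc[mask].copy(),
            None if table.risk is None else table.risk.loc[mask].copy(),
            dict(table.units),
        )

    return _take(~test_mask), _take(test_mask)
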