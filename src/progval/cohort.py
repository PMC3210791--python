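"""Cohort container, schema, delimited-text I/O and small shared utilities.

A *cohort* is one row per patient with a binary 10-year survival outcome
``Y_i`` (1 = alive at 10 years, 0 = dead), an external model's predicted
10-year survival probability ``p_i`` in (0, 1), and categorical covariates
(age group, ER status, tumour size group, grade, ...).  The external model is
treated strictly as a black box: only its output probability enters any
computation here.

Outcome coding: survival = 1, so every odds ratio downstream is the odds of
*surviving* to 10 years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortSchema",
    "Cohort",
    "SubgroupSpec",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "logit",
    "inv_logit",
    "clip_probability",
    "nottingham_prognostic_index",
    "MISSING_LEVEL",
]

#: Level assigned to a missing categorical covariate value.  Missing
#: covariates are kept as an explicit level (subgroup tables subset per
#: covariate independently), only missing outcome/prediction excludes a row.
MISSING_LEVEL = "missing"

#: Predictions are clipped into [CLIP_EPS, 1 - CLIP_EPS] before any logit;
#: actuarial tools round their output and can emit exactly 0 or 1.
CLIP_EPS = 1e-6


class CohortValidationError(ValueError):
    """Raised when a cohort file or record violates the declared schema."""


# ---------------------------------------------------------------------------
# probability-scale helpers
# ---------------------------------------------------------------------------

def clip_probability(p, eps: float = CLIP_EPS):
    """Clip probabilities into [eps, 1 - eps]."""
    return np.clip(p, eps, 1.0 - eps)


def logit(p):
    """log(p / (1 - p)).  Input must lie strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("logit requires probabilities strictly inside (0, 1)")
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    """Inverse of :func:`logit`: 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable logistic
    return float(out) if out.ndim == 0 else out


def nottingham_prognostic_index(grade: int, nodes: float, size_mm: float) -> float:
    """Nottingham Prognostic Index: grade + nodal score + 0.2 x size.

    The 0.2 weight applies to tumour size **in centimetres** (the classical
    Nottingham convention); this function accepts millimetres and converts.

    Parameters
    ----------
    grade : histological (Elston-Ellis) grade, 1-3.
    nodes : nodal category score (classically 1-3).
    size_mm : tumour size in millimetres, >= 0.
    """
    if grade not in (1, 2, 3):
        raise ValueError(f"grade must be 1, 2 or 3, got {grade!r}")
    if size_mm < 0:
        raise ValueError("tumour size must be non-negative")
    return float(grade) + float(nodes) + 0.2 * (float(size_mm) / 10.0)


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

def _canon(label) -> str:
    """Canonical form for category matching: trimmed, lower-case string."""
    return str(label).strip().lower()


@dataclass(frozen=True)
class CohortSchema:
    """Ordered covariate names, their level sets and reference levels.

    ``levels`` maps covariate name -> ordered tuple of level labels.  The
    reference level (the "OR = 1" row of a report) defaults to the first
    level and can be overridden per covariate via ``reference``.
    Category labels are matched case-insensitively after trimming.
    """

    levels: Mapping[str, Sequence[str]]
    reference: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        lv = {str(k): tuple(str(x) for x in v) for k, v in self.levels.items()}
        object.__setattr__(self, "levels", lv)
        ref = dict(self.reference)
        for cov, levels in lv.items():
            if not levels:
                raise CohortValidationError(f"covariate {cov!r} has no levels")
            if len({_canon(l) for l in levels}) != len(levels):
                raise CohortValidationError(f"duplicate levels for {cov!r}")
            r = ref.get(cov, levels[0])
            if _canon(r) not in {_canon(l) for l in levels}:
                raise CohortValidationError(
                    f"reference level {r!r} not among levels of {cov!r}"
                )
            ref[cov] = self.match(cov, r)
        object.__setattr__(self, "reference", ref)

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(self.levels)

    def match(self, covariate: str, label) -> str:
        """Resolve *label* to the declared level spelling, or raise."""
        for lvl in self.levels[covariate]:
            if _canon(lvl) == _canon(label):
                return lvl
        raise CohortValidationError(
            f"unknown level {label!r} for covariate {covariate!r}; "
            f"declared levels: {list(self.levels[covariate])}"
        )

    def with_missing(self) -> "CohortSchema":
        """Schema where every covariate additionally admits 'missing'."""
        lv = {
            c: ls if MISSING_LEVEL in ls else ls + (MISSING_LEVEL,)
            for c, ls in self.levels.items()
        }
        return CohortSchema(levels=lv, reference=dict(self.reference))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "covariates": {
                c: {"levels": list(ls), "reference": self.reference[c]}
                for c, ls in self.levels.items()
            }
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSchema":
        cov = d["covariates"]
        return cls(
            levels={c: tuple(v["levels"]) for c, v in cov.items()},
            reference={c: v.get("reference", v["levels"][0]) for c, v in cov.items()},
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# subgroup specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupSpec:
    """A subgroup of a cohort: one level of one covariate, or everyone.

    ``SubgroupSpec.all()`` selects the whole cohort; agreement tables use it
    for their leading "all patients" row.
    """

    covariate: str
    level: str = "all"

    @classmethod
    def all(cls) -> "SubgroupSpec":
        return cls(covariate="all", level="all")

    @property
    def is_all(self) -> bool:
        return self.covariate == "all"

    def label(self) -> str:
        return "all patients" if self.is_all else f"{self.covariate}={self.level}"


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A validated patient table plus its covariate schema.

    ``data`` holds columns ``outcome`` (0/1 int), ``prediction`` (float in
    (0,1) after clipping) and one string column per schema covariate.
    """

    data: pd.DataFrame
    schema: CohortSchema
    label: str = ""
    n_excluded: int = 0  # rows dropped for missing outcome/prediction

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        validate_cohort(self)

    # -- basic access -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def outcomes(self) -> np.ndarray:
        return self.data["outcome"].to_numpy(dtype=int)

    @property
    def predictions(self) -> np.ndarray:
        return self.data["prediction"].to_numpy(dtype=float)

    @property
    def prediction_logits(self) -> np.ndarray:
        return logit(clip_probability(self.predictions))

    @property
    def n_events(self) -> int:
        """Number of deaths (outcome = 0)."""
        return int((self.outcomes == 0).sum())

    def subset(self, spec: SubgroupSpec) -> "Cohort":
        """The sub-cohort selected by *spec* (may be empty for table rows)."""
        if spec.is_all:
            return self
        if spec.covariate not in self.schema.covariates:
            raise CohortValidationError(
                f"unknown covariate {spec.covariate!r} in subgroup spec"
            )
        level = self.schema.match(spec.covariate, spec.level)
        mask = self.data[spec.covariate] == level
        sub = dataclasses.replace(
            self,
            data=self.data.loc[mask],
            label=f"{self.label}[{spec.label()}]" if self.label else spec.label(),
            n_excluded=0,
        )
        return sub

    def level_counts(self, covariate: str) -> dict[str, int]:
        counts = self.data[covariate].value_counts()
        return {lvl: int(counts.get(lvl, 0)) for lvl in self.schema.levels[covariate]}


def validate_cohort(cohort: Cohort) -> None:
    df = cohort.data
    for col in ("outcome", "prediction"):
        if col not in df.columns:
            raise CohortValidationError(f"cohort is missing column {col!r}")
    if df["outcome"].isna().any() or df["prediction"].isna().any():
        raise CohortValidationError("cohort contains missing outcome or prediction")
    bad = ~df["outcome"].isin([0, 1])
    if bad.any():
        raise CohortValidationError(
            f"outcome must be 0/1; offending row index {int(np.flatnonzero(bad)[0])}"
        )
    p = df["prediction"].to_numpy(dtype=float)
    out = (p < 0.0) | (p > 1.0)
    if out.any():
        i = int(np.flatnonzero(out)[0])
        raise CohortValidationError(
            f"prediction outside [0, 1] at row {i}: {p[i]!r}"
        )
    for cov in cohort.schema.covariates:
        if cov not in df.columns:
            raise CohortValidationError(f"cohort is missing covariate column {cov!r}")
        declared = set(cohort.schema.levels[cov])
        observed = set(df[cov].unique())
        unknown = observed - declared
        if unknown:
            raise CohortValidationError(
                f"unknown level(s) {sorted(unknown)} for covariate {cov!r}"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cohort(path, schema: CohortSchema, label: str = "") -> Cohort:
    """Read a comma-separated cohort table and validate it against *schema*.

    The file must be UTF-8 with a header row containing ``outcome``,
    ``prediction`` and one column per schema covariate.  Rows with a missing
    outcome or prediction are dropped and counted in ``Cohort.n_excluded``
    (patients whose 10-year status is unknown are excluded from analysis).
    Missing covariate values become the explicit level ``"missing"``.
    Category labels are matched case-insensitively after trimming.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in ("outcome", "prediction"):
        if col not in df.columns:
            raise CohortValidationError(
                f"{path}: missing mandatory column {col!r}"
            )
    missing_cols = [c for c in schema.covariates if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"{path}: missing covariate columns {missing_cols}")

    keep = df["outcome"].notna() & (df["outcome"].str.strip() != "")
    keep &= df["prediction"].notna() & (df["prediction"].str.strip() != "")
    n_excluded = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    if df.empty:
        raise CohortValidationError(f"{path}: no analysable rows")

    try:
        outcome = df["outcome"].str.strip().astype(float)
    except ValueError as exc:
        raise CohortValidationError(f"{path}: non-numeric outcome: {exc}") from exc
    if not outcome.isin([0.0, 1.0]).all():
        i = int(np.flatnonzero(~outcome.isin([0.0, 1.0]))[0])
        raise CohortValidationError(f"{path}: outcome not 0/1 at data row {i}")
    try:
        pred = df["prediction"].str.strip().astype(float)
    except ValueError as exc:
        raise CohortValidationError(f"{path}: non-numeric prediction: {exc}") from exc
    out_of_range = (pred < 0.0) | (pred > 1.0)
    if out_of_range.any():
        i = int(np.flatnonzero(out_of_range)[0])
        raise CohortValidationError(
            f"{path}: prediction outside [0, 1] at data row {i}: {pred.iloc[i]}"
        )

    use_schema = schema
    clean = pd.DataFrame(
        {"outcome": outcome.astype(int), "prediction": clip_probability(pred)}
    )
    any_missing = False
    for cov in schema.covariates:
        raw = df[cov]
        blank = raw.isna() | (raw.str.strip() == "")
        if blank.any():
            any_missing = True
        clean[cov] = [
            MISSING_LEVEL if b else schema.match(cov, v)
            for v, b in zip(raw, blank)
        ]
    if any_missing:
        use_schema = schema.with_missing()

    return Cohort(data=clean, schema=use_schema, label=label, n_excluded=n_excluded)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to CSV (UTF-8, header row, full float precision)."""
    df = cohort.data.copy()
    df["prediction"] = df["prediction"].map(lambda v: format(float(v), ".17g"))
    df.to_csv(path, index=False)
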