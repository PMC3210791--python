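"""Added predictive value via logistic models with a fixed-coefficient term.

To ask what a covariate adds to an external prediction ``p_i``, fit

    logit P(Y_i = 1) = alpha + sum_j beta_j X_ij + logit(p_i)

where the last term is an *offset*: its coefficient is constrained to 1, so
the external prediction is taken as given and never re-estimated.  Two modes
mirror two different questions:

* **multivariate** — all covariates the external model already uses, fitted
  together.  A significant coefficient means the association of that
  predictor with the outcome in the validation population differs from the
  population the external model was built on.
* **univariate** — each covariate the external model does *not* use, fitted
  on its own.  A significant coefficient means the predictor adds prognostic
  information beyond the external prediction.

Categorical covariates use reference-level indicator coding; each variable
gets a single factor-level likelihood-ratio p-value (df = number of
non-reference levels) rather than per-level p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._fitting import GLMFit, fit_binomial_glm
from .cohort import Cohort, CohortValidationError

__all__ = [
    "OffsetModelSpec",
    "LevelEstimate",
    "OffsetModelResult",
    "fit_offset_model",
    "factor_p_value",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class OffsetModelSpec:
    """Which covariates enter the offset model, and how.

    ``mode`` is ``"multivariate"`` (all variables together) or
    ``"univariate"`` (one model per variable).  Reference levels come from
    the cohort schema unless overridden here.
    """

    variables: tuple[str, ...]
    mode: Literal["multivariate", "univariate"] = "multivariate"
    reference: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        if self.mode not in ("multivariate", "univariate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variables in spec")


@dataclass
class LevelEstimate:
    """Estimate for one non-reference level of a covariate."""

    variable: str
    level: str
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    estimable: bool = True


@dataclass
class OffsetModelResult:
    """A fitted offset-logistic model.

    ``levels`` lists one estimate per non-reference level of each included
    variable (reference levels have odds ratio fixed at 1 and are not
    listed).  ``factor_p`` maps variable -> likelihood-ratio p-value for
    dropping the whole variable.  ``dropped_levels`` records declared levels
    with no observations (they are excluded from the design, as an empty
    treatment arm would be).
    """

    mode: str
    variables: tuple[str, ...]
    intercept: float
    levels: list[LevelEstimate]
    factor_p: dict[str, float | None]
    loglik: float
    n: int
    converged: bool
    estimable: bool
    fitted: np.ndarray | None = None
    dropped_levels: dict[str, list[str]] = field(default_factory=dict)
    message: str = ""

    def level_estimate(self, variable: str, level: str) -> LevelEstimate:
        for est in self.levels:
            if est.variable == variable and est.level == level:
                return est
        raise KeyError((variable, level))


def _design(
    cohort: Cohort, variables: Sequence[str], reference: Mapping[str, str]
) -> tuple[np.ndarray, list[tuple[str, str]], dict[str, list[str]]]:
    """Intercept + indicator columns for non-reference, observed levels.

    Returns the design matrix, the (variable, level) pair for each indicator
    column, and the declared-but-unobserved levels that were dropped.
    """
    n = cohort.n
    cols = [np.ones(n)]
    names: list[tuple[str, str]] = []
    dropped: dict[str, list[str]] = {}
    for var in variables:
        if var not in cohort.schema.covariates:
            raise CohortValidationError(f"variable {var!r} not in cohort schema")
        ref = reference.get(var, cohort.schema.reference[var])
        ref = cohort.schema.match(var, ref)
        values = cohort.data[var].to_numpy()
        observed = set(values)
        for lvl in cohort.schema.levels[var]:
            if lvl == ref:
                continue
            if lvl not in observed:
                dropped.setdefault(var, []).append(lvl)
                continue
            cols.append((values == lvl).astype(float))
            names.append((var, lvl))
        if ref not in observed and var not in dropped:
            dropped.setdefault(var, [])
    return np.column_stack(cols), names, dropped


def _observed_level_count(cohort: Cohort, var: str) -> int:
    return int(cohort.data[var].nunique())


def _fit_one(
    cohort: Cohort, variables: Sequence[str], reference: Mapping[str, str],
    mode: str, compute_factor_p: bool = True,
) -> OffsetModelResult:
    for var in variables:
        if _observed_level_count(cohort, var) < 2:
            raise CohortValidationError(
                f"variable {var!r} has a single observed level; "
                "it cannot enter an offset model"
            )
    y = cohort.outcomes
    offset = cohort.prediction_logits
    X, names, dropped = _design(cohort, variables, reference)
    fit = fit_binomial_glm(y, X, offset=offset)
    se = np.sqrt(np.maximum(np.diag(fit.cov), 0.0)) if np.all(
        np.isfinite(fit.cov)
    ) else np.full(X.shape[1], np.nan)

    levels = []
    for j, (var, lvl) in enumerate(names, start=1):
        coef = float(fit.params[j]) if np.isfinite(fit.params[j]) else np.nan
        s = float(se[j]) if np.isfinite(se[j]) else np.nan
        ok = fit.ok and np.isfinite(coef) and np.isfinite(s) and abs(coef) < 30
        levels.append(
            LevelEstimate(
                variable=var, level=lvl, coef=coef, se=s,
                odds_ratio=float(np.exp(coef)) if np.isfinite(coef) else np.nan,
                ci_low=float(np.exp(coef - _Z975 * s)) if ok else np.nan,
                ci_high=float(np.exp(coef + _Z975 * s)) if ok else np.nan,
                estimable=ok,
            )
        )

    result = OffsetModelResult(
        mode=mode,
        variables=tuple(variables),
        intercept=float(fit.params[0]) if np.isfinite(fit.params[0]) else np.nan,
        levels=levels,
        factor_p={},
        loglik=fit.llf,
        n=cohort.n,
        converged=fit.converged,
        estimable=fit.ok,
        fitted=fit.fitted if fit.ok else None,
        dropped_levels=dropped,
        message=fit.message,
    )
    if compute_factor_p and fit.ok:
        for var in variables:
            rest = [v for v in variables if v != var]
            reduced = _fit_one(cohort, rest, reference, mode, compute_factor_p=False)
            try:
                result.factor_p[var] = factor_p_value(result, reduced)
            except (ValueError, CohortValidationError):
                result.factor_p[var] = None
    elif compute_factor_p:
        result.factor_p = {var: None for var in variables}
    return result


def fit_offset_model(
    cohort: Cohort, spec: OffsetModelSpec
) -> OffsetModelResult | dict[str, OffsetModelResult]:
    """Fit offset-logistic model(s) per *spec*.

    Multivariate mode returns one :class:`OffsetModelResult`; univariate mode
    returns ``{variable: OffsetModelResult}`` with one single-variable model
    each.  A variable with a single observed level raises a validation error
    naming it; a declared level with no observations is silently dropped from
    the design and recorded in ``dropped_levels``.
    """
    if spec.mode == "multivariate":
        return _fit_one(cohort, spec.variables, spec.reference, spec.mode)
    return {
        var: _fit_one(cohort, [var], spec.reference, spec.mode)
        for var in spec.variables
    }


def fit_offset_null(cohort: Cohort) -> OffsetModelResult:
    """The offset-only model: intercept + logit(p) with coefficient 1.

    This is the "model without predictors" baseline of accuracy tables.
    """
    return _fit_one(cohort, [], {}, "null", compute_factor_p=False)


def factor_p_value(full: OffsetModelResult, reduced: OffsetModelResult) -> float:
    """Likelihood-ratio p-value for the variable(s) dropped in *reduced*.

    *reduced* must be nested in *full*: same offset, a subset of variables.
    df = number of indicator columns removed.  Zero removed columns is a
    degenerate nesting and returns p = 1.
    """
    if not set(reduced.variables) <= set(full.variables):
        raise ValueError("reduced model is not nested in the full model")
    df = len(full.levels) - len(reduced.levels)
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    if df == 0:
        return 1.0
    if not (full.estimable and reduced.estimable):
        raise ValueError("cannot form LR test from non-estimable fits")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return float(stats.chi2.sf(stat, df))
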