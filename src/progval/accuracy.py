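"""Predictive inaccuracy, explained variation, bootstrap SEs and AUC.

Predictive inaccuracy (PI) of a model with fitted survival probabilities
``pi_hat_i`` is the mean absolute difference from the binary outcome:

    PI = (1/n) * sum_i |Y_i - pi_hat_i|            (lower is better)

Explained variation (EV) is the proportional reduction in PI relative to a
reference model — an R^2-like quantity for binary outcomes:

    EV = 100 * (PI_ref - PI_model) / PI_ref        (percent; may be negative)

Here the reference is always the offset-only model (external prediction
alone) and candidate models add one covariate on top of the offset, so EV
measures what the covariate buys beyond the external prediction.  Standard
errors come from a nonparametric bootstrap (patients resampled with
replacement, models refitted per resample; 200 resamples by default).
Evaluation is in-sample (apparent performance), with no optimism correction.

AUC is the Wilcoxon-Mann-Whitney probability that a random survivor scores
higher than a random non-survivor, ties counted 1/2; its confidence interval
uses the DeLong asymptotic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .cohort import Cohort, CohortValidationError
from .offset_models import OffsetModelResult, OffsetModelSpec, fit_offset_model, \
    fit_offset_null

__all__ = [
    "BootstrapConfig",
    "AccuracyResult",
    "predictive_inaccuracy",
    "explained_variation",
    "auc",
    "bootstrap_se",
    "accuracy_table",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: number of resamples B (default 200) and seed."""

    B: int = 200
    seed: int = 0
    stratified: bool = False  # preserve the outcome split in each resample

    def __post_init__(self):
        if self.B < 2:
            raise ValueError("bootstrap needs B >= 2 resamples")


@dataclass
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float


@dataclass
class AccuracyResult:
    """One row of an accuracy table: PI +/- SE, EV +/- SE, AUC [CI]."""

    model_label: str
    pi: float
    pi_se: float | None
    ev: float | None  # percent; None for the reference row
    ev_se: float | None
    auc: AUCResult | None
    n_failed_resamples: int = 0
    reliable: bool = True


# ---------------------------------------------------------------------------
# point metrics
# ---------------------------------------------------------------------------

def predictive_inaccuracy(outcomes, fitted) -> float:
    """Mean absolute difference between outcomes and fitted probabilities."""
    y = np.asarray(outcomes, dtype=float)
    p = np.asarray(fitted, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("fitted probabilities must lie in [0, 1]")
    return float(np.mean(np.abs(y - p)))


def explained_variation(pi_ref: float, pi_model: float) -> float:
    """Percent reduction in predictive inaccuracy relative to a reference.

    Negative values mean the richer model fit *worse* in absolute error.
    """
    if pi_ref <= 0:
        raise ValueError("explained variation undefined: reference PI is 0")
    return 100.0 * (pi_ref - pi_model) / pi_ref


def auc(outcomes, scores, ci: bool = True) -> AUCResult:
    """Rank-based AUC with a DeLong asymptotic 95% confidence interval.

    Equals the pairwise probability that a randomly chosen patient with
    ``Y=1`` scores above a randomly chosen patient with ``Y=0``, ties
    counting 1/2.  Requires both outcome classes.
    """
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("length mismatch between outcomes and scores")
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: only one outcome class present")
    r_all = rankdata(np.concatenate([pos, neg]))
    value = (float(np.sum(r_all[:m])) - m * (m + 1) / 2.0) / (m * n)
    if not ci:
        return AUCResult(auc=value, ci_low=np.nan, ci_high=np.nan, se=np.nan)
    # DeLong structural components via midranks
    v01 = (r_all[:m] - rankdata(pos)) / n          # one per positive
    v10 = 1.0 - (r_all[m:] - rankdata(neg)) / m    # one per negative
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    se = float(np.sqrt(var))
    return AUCResult(
        auc=value,
        ci_low=float(max(0.0, value - _Z975 * se)),
        ci_high=float(min(1.0, value + _Z975 * se)),
        se=se,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _fit_for_table(cohort: Cohort, variables: tuple[str, ...]) -> OffsetModelResult:
    """Offset model used by accuracy rows; no factor p-values needed.

    A variable whose observed levels collapse to one (possible in a bootstrap
    resample, or for a genuinely constant covariate) contributes nothing to
    the design, so the fit reduces to the offset-only model.
    """
    usable = [v for v in variables if cohort.data[v].nunique() > 1]
    if not usable:
        return fit_offset_null(cohort)
    from .offset_models import _fit_one

    return _fit_one(cohort, usable, {}, "univariate", compute_factor_p=False)


def _resample(cohort: Cohort, rng: np.random.Generator, stratified: bool) -> Cohort:
    import dataclasses

    n = cohort.n
    if stratified:
        idx_parts = []
        for val in (0, 1):
            rows = np.flatnonzero(cohort.outcomes == val)
            if len(rows):
                idx_parts.append(rng.choice(rows, size=len(rows), replace=True))
        idx = np.concatenate(idx_parts)
    else:
        idx = rng.integers(0, n, size=n)
    return dataclasses.replace(cohort, data=cohort.data.iloc[idx], n_excluded=0)


def bootstrap_se(
    cohort: Cohort,
    variables: tuple[str, ...] = (),
    statistic: str = "pi",
    cfg: BootstrapConfig = BootstrapConfig(),
) -> tuple[float, int]:
    """Bootstrap SE of PI or EV for an offset model with *variables*.

    Patients are resampled with replacement ``cfg.B`` times; the model (and,
    for EV, the offset-only reference) is refitted on each resample and the
    statistic recomputed.  Returns ``(SE, n_failed)`` where failed resamples
    (non-estimable refits) are dropped.  More than 20% failures raises.
    """
    if statistic not in ("pi", "ev"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(cfg.seed)
    values = []
    n_failed = 0
    for _ in range(cfg.B):
        boot = _resample(cohort, rng, cfg.stratified)
        try:
            fit = _fit_for_table(boot, variables)
            if not fit.estimable:
                raise CohortValidationError("non-estimable resample fit")
            pi_model = predictive_inaccuracy(boot.outcomes, fit.fitted)
            if statistic == "pi":
                values.append(pi_model)
            else:
                null = fit_offset_null(boot)
                if not null.estimable:
                    raise CohortValidationError("non-estimable null refit")
                pi_ref = predictive_inaccuracy(boot.outcomes, null.fitted)
                values.append(explained_variation(pi_ref, pi_model))
        except (CohortValidationError, ValueError):
            n_failed += 1
    if n_failed > 0.2 * cfg.B:
        raise CohortValidationError(
            f"bootstrap unreliable: {n_failed}/{cfg.B} resamples failed"
        )
    return float(np.std(values, ddof=1)), n_failed


# ---------------------------------------------------------------------------
# accuracy table
# ---------------------------------------------------------------------------

def accuracy_table(
    cohort: Cohort,
    new_vars: tuple[str, ...],
    cfg: BootstrapConfig = BootstrapConfig(),
) -> list[AccuracyResult]:
    """PI, EV and AUC for the offset-only model and one-covariate extensions.

    The first row is the offset-only "model without predictors" (its EV is
    reported as missing); each further row adds one variable from *new_vars*
    in a univariate offset model.  EV is computed against the first row.
    All rows are evaluated in-sample; SEs bootstrap the whole refit.
    """
    rows: list[AccuracyResult] = []
    null = fit_offset_null(cohort)
    if not null.estimable:
        raise CohortValidationError("offset-only model is non-estimable")
    pi_ref = predictive_inaccuracy(cohort.outcomes, null.fitted)
    pi_se, nf = bootstrap_se(cohort, (), "pi", cfg)
    rows.append(
        AccuracyResult(
            model_label="model without predictors",
            pi=pi_ref, pi_se=pi_se, ev=None, ev_se=None,
            auc=auc(cohort.outcomes, null.fitted),
            n_failed_resamples=nf,
        )
    )
    for var in new_vars:
        fit = _fit_for_table(cohort, (var,))
        if not fit.estimable:
            rows.append(
                AccuracyResult(
                    model_label=f"model with {var}",
                    pi=np.nan, pi_se=None, ev=None, ev_se=None, auc=None,
                    reliable=False,
                )
            )
            continue
        pi_model = predictive_inaccuracy(cohort.outcomes, fit.fitted)
        pi_se, nf1 = bootstrap_se(cohort, (var,), "pi", cfg)
        ev_se, nf2 = bootstrap_se(cohort, (var,), "ev", cfg)
        rows.append(
            AccuracyResult(
                model_label=f"model with {var}",
                pi=pi_model,
                pi_se=pi_se,
                ev=explained_variation(pi_ref, pi_model),
                ev_se=ev_se,
                auc=auc(cohort.outcomes, fit.fitted),
                n_failed_resamples=nf1 + nf2,
            )
        )
    return rows
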