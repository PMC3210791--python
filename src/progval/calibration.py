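"""Calibration of external survival predictions against observed outcomes.

The agreement test is logistic recalibration: with ``Y_i`` the observed
binary 10-year survival and ``p_i`` the external model's predicted survival
probability, fit

    logit P(Y_i = 1) = alpha + beta * logit(p_i)

and test the joint null ``H0: (alpha, beta) = (0, 1)`` — a well-calibrated
model.  The joint test is well suited to small cohorts and subgroups where
grouping patients into near-constant-risk sets would leave tiny cells.

The default joint statistic is a 2-df likelihood-ratio test against the
fully constrained model ``logit P(Y_i = 1) = logit(p_i)`` (an offset-only
model with no free parameter); a Wald version is available.  Subgroup
p-values in agreement tables apply the same joint test within each subgroup;
a 1-df calibration-in-the-large test (alpha free, beta fixed at 1) is also
offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from ._fitting import GLMFit, bernoulli_loglik, fit_binomial_glm
from .cohort import Cohort, SubgroupSpec, clip_probability

__all__ = [
    "CalibrationFit",
    "AgreementRow",
    "CalibrationBin",
    "fit_calibration",
    "agreement_table",
    "bin_predictions",
]


@dataclass
class CalibrationFit:
    """Recalibration intercept/slope and the joint calibration test."""

    alpha: float
    beta: float
    vcov: np.ndarray  # 2x2 covariance of (alpha_hat, beta_hat)
    joint_stat: float
    p_value: float | None
    df: int
    n: int
    events: int  # deaths (outcome = 0)
    test: str = "lr"
    estimable: bool = True
    converged: bool = True
    message: str = ""


@dataclass
class AgreementRow:
    """One row of a predicted-versus-observed agreement table.

    Percentages are stored unrounded; reports round to one decimal.
    ``difference`` is mean predicted minus observed survival, in percentage
    points: positive means the external model was over-optimistic.
    """

    subgroup: SubgroupSpec
    n: int
    mean_predicted: float | None  # percent
    observed: float | None  # percent
    difference: float | None  # percentage points
    p_value: float | None
    estimable: bool = True


@dataclass
class CalibrationBin:
    """One prediction interval of a binned calibration curve."""

    lower: float
    upper: float
    count: int
    mean_predicted: float | None
    observed_fraction: float | None


def _joint_test_lr(fit: GLMFit, y: np.ndarray, lp: np.ndarray) -> tuple[float, float]:
    """2-df LR statistic vs the fixed model logit = logit(p) (offset only)."""
    from .cohort import inv_logit

    ll0 = bernoulli_loglik(y, inv_logit(lp))
    stat = max(0.0, 2.0 * (fit.llf - ll0))
    return stat, float(stats.chi2.sf(stat, 2))


def _joint_test_wald(fit: GLMFit) -> tuple[float, float]:
    d = fit.params - np.array([0.0, 1.0])
    stat = float(d @ np.linalg.solve(fit.cov, d))
    stat = max(0.0, stat)
    return stat, float(stats.chi2.sf(stat, 2))


def fit_calibration(cohort: Cohort, test: str = "lr") -> CalibrationFit:
    """Fit the logistic recalibration model and test (alpha, beta) = (0, 1).

    Parameters
    ----------
    cohort : cohort with outcomes and clipped predictions.
    test : ``"lr"`` (default, 2-df likelihood ratio) or ``"wald"``.

    A subgroup with a single outcome value, or one in which the fit separates,
    yields a non-estimable result (``estimable=False``) with a missing p-value
    rather than a fabricated one.
    """
    if test not in ("lr", "wald"):
        raise ValueError(f"unknown test {test!r}")
    y = cohort.outcomes
    lp = cohort.prediction_logits
    n = cohort.n
    events = cohort.n_events
    if n < 2 or len(np.unique(y)) < 2:
        return CalibrationFit(
            alpha=np.nan, beta=np.nan, vcov=np.full((2, 2), np.nan),
            joint_stat=np.nan, p_value=None, df=2, n=n, events=events,
            test=test, estimable=False, converged=False,
            message="single outcome value or n < 2",
        )
    X = np.column_stack([np.ones(n), lp])
    fit = fit_binomial_glm(y, X)
    if not fit.ok:
        return CalibrationFit(
            alpha=float(fit.params[0]) if np.isfinite(fit.params[0]) else np.nan,
            beta=float(fit.params[1]) if np.isfinite(fit.params[1]) else np.nan,
            vcov=fit.cov, joint_stat=np.nan, p_value=None, df=2, n=n,
            events=events, test=test, estimable=False,
            converged=fit.converged, message=fit.message or "separation",
        )
    if test == "lr":
        stat, p = _joint_test_lr(fit, y, lp)
    else:
        stat, p = _joint_test_wald(fit)
    return CalibrationFit(
        alpha=float(fit.params[0]),
        beta=float(fit.params[1]),
        vcov=fit.cov,
        joint_stat=stat,
        p_value=p,
        df=2,
        n=n,
        events=events,
        test=test,
    )


def calibration_in_the_large(cohort: Cohort) -> CalibrationFit:
    """1-df test of alpha = 0 with the slope fixed at 1.

    Fits ``logit P(Y=1) = alpha + logit(p)`` (prediction as offset) and
    likelihood-ratio-tests alpha against the offset-only model.
    """
    from .cohort import inv_logit

    y = cohort.outcomes
    lp = cohort.prediction_logits
    n = cohort.n
    events = cohort.n_events
    if n < 1 or len(np.unique(y)) < 2:
        return CalibrationFit(
            alpha=np.nan, beta=1.0, vcov=np.full((2, 2), np.nan),
            joint_stat=np.nan, p_value=None, df=1, n=n, events=events,
            test="citl", estimable=False, converged=False,
            message="single outcome value",
        )
    X = np.ones((n, 1))
    fit = fit_binomial_glm(y, X, offset=lp)
    if not fit.ok:
        return CalibrationFit(
            alpha=np.nan, beta=1.0, vcov=np.full((2, 2), np.nan),
            joint_stat=np.nan, p_value=None, df=1, n=n, events=events,
            test="citl", estimable=False, converged=fit.converged,
            message=fit.message or "separation",
        )
    ll0 = bernoulli_loglik(y, inv_logit(lp))
    stat = max(0.0, 2.0 * (fit.llf - ll0))
    vcov = np.zeros((2, 2))
    vcov[0, 0] = fit.cov[0, 0]
    return CalibrationFit(
        alpha=float(fit.params[0]), beta=1.0, vcov=vcov,
        joint_stat=stat, p_value=float(stats.chi2.sf(stat, 1)),
        df=1, n=n, events=events, test="citl",
    )


def agreement_table(
    cohort: Cohort,
    specs: Sequence[SubgroupSpec] | None = None,
    subgroup_test: str = "joint",
) -> list[AgreementRow]:
    """Predicted-versus-observed survival, overall and per subgroup.

    *specs* defaults to the "all patients" row followed by every level of
    every schema covariate.  ``subgroup_test`` selects the p-value in each
    row: ``"joint"`` (2-df recalibration test, default) or ``"citl"``
    (1-df calibration-in-the-large).  Empty subgroups yield a row with
    ``n=0`` and missing statistics.
    """
    if specs is None:
        specs = [SubgroupSpec.all()] + [
            SubgroupSpec(cov, lvl)
            for cov in cohort.schema.covariates
            for lvl in cohort.schema.levels[cov]
        ]
    else:
        specs = list(specs)
        if not any(s.is_all for s in specs):
            specs = [SubgroupSpec.all()] + specs
        specs.sort(key=lambda s: not s.is_all)  # "all" first, stable otherwise
    if subgroup_test not in ("joint", "citl"):
        raise ValueError(f"unknown subgroup test {subgroup_test!r}")

    rows: list[AgreementRow] = []
    for spec in specs:
        sub = cohort.subset(spec)
        if sub.n == 0:
            rows.append(
                AgreementRow(
                    subgroup=spec, n=0, mean_predicted=None, observed=None,
                    difference=None, p_value=None, estimable=False,
                )
            )
            continue
        mean_pred = 100.0 * float(np.mean(sub.predictions))
        observed = 100.0 * float(np.mean(sub.outcomes))
        if subgroup_test == "joint":
            calfit = fit_calibration(sub)
        else:
            calfit = calibration_in_the_large(sub)
        rows.append(
            AgreementRow(
                subgroup=spec,
                n=sub.n,
                mean_predicted=mean_pred,
                observed=observed,
                difference=mean_pred - observed,
                p_value=calfit.p_value,
                estimable=calfit.estimable,
            )
        )
    return rows


def bin_predictions(
    cohort: Cohort, width: float = 0.05, keep_empty: bool = False
) -> list[CalibrationBin]:
    """Bin predictions into intervals of *width* and average outcomes per bin.

    Intervals are ``[k*width, (k+1)*width)`` with the final interval closed
    at 1.  Plot data omits empty bins by default; ``keep_empty=True`` retains
    them with ``count=0`` so the bins always tile [0, 1].
    """
    if not (0.0 < width <= 1.0):
        raise ValueError("bin width must lie in (0, 1]")
    p = cohort.predictions
    y = cohort.outcomes
    nbins = int(np.ceil(round(1.0 / width, 12)))
    idx = np.minimum((p / width).astype(int), nbins - 1)
    bins: list[CalibrationBin] = []
    for k in range(nbins):
        mask = idx == k
        count = int(mask.sum())
        if count == 0:
            if keep_empty:
                bins.append(
                    CalibrationBin(
                        lower=k * width, upper=min((k + 1) * width, 1.0),
                        count=0, mean_predicted=None, observed_fraction=None,
                    )
                )
            continue
        bins.append(
            CalibrationBin(
                lower=k * width,
                upper=min((k + 1) * width, 1.0),
                count=count,
                mean_predicted=float(np.mean(p[mask])),
                observed_fraction=float(np.mean(y[mask])),
            )
        )
    return bins
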