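"""Internal wrapper around statsmodels binomial GLM fits.

All model fitting in the package funnels through :func:`fit_binomial_glm` so
that convergence failures and (quasi-)complete separation are detected in one
place and surfaced as flags rather than silently returned as huge
coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

# Coefficients / standard errors beyond these magnitudes on the logit scale
# are treated as diverging (separation): exp(30) ~ 1e13 as an odds ratio.
_MAX_ABS_COEF = 30.0
_MAX_SE = 1e3


@dataclass
class GLMFit:
    params: np.ndarray
    cov: np.ndarray
    llf: float
    fitted: np.ndarray
    converged: bool
    separation: bool
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.converged and not self.separation


def bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    """Log-likelihood of outcomes *y* under probabilities *p* (clipped)."""
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def fit_binomial_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> GLMFit:
    """Fit a logistic model by IRLS, flagging non-convergence and separation."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset)
            res = model.fit(maxiter=maxiter, tol=tol)
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        k = X.shape[1]
        nan = np.full(k, np.nan)
        return GLMFit(
            params=nan,
            cov=np.full((k, k), np.nan),
            llf=np.nan,
            fitted=np.full(len(y), np.nan),
            converged=False,
            separation=True,
            message=str(exc),
        )
    params = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    separation = bool(
        np.any(~np.isfinite(params))
        or np.any(np.abs(params) > _MAX_ABS_COEF)
        or np.any(~np.isfinite(se))
        or np.any(se > _MAX_SE)
    )
    return GLMFit(
        params=params,
        cov=cov,
        llf=float(res.llf),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        converged=bool(getattr(res, "converged", True)),
        separation=separation,
    )
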