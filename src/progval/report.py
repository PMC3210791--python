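"""Pipeline orchestration and rendering of validation reports.

A :class:`ValidationReport` collects the four validation surfaces in the
order the analysis asks its questions — first *agreement* (is the external
prediction calibrated, overall and per subgroup?), then *added value* (what
does each predictor contribute beyond it?) — plus a baseline cohort summary,
accuracy metrics and binned calibration-curve data.  Rendering is a pure
function of the serialized report: a report written to JSON and re-rendered
produces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .accuracy import AccuracyResult, BootstrapConfig, accuracy_table
from .calibration import (
    AgreementRow,
    CalibrationFit,
    agreement_table,
    bin_predictions,
    fit_calibration,
)
from .cohort import Cohort, CohortValidationError, SubgroupSpec
from .offset_models import OffsetModelResult, OffsetModelSpec, fit_offset_model

__all__ = [
    "PipelineConfig",
    "ValidationReport",
    "run_pipeline",
    "summarize_cohort",
    "render_summary",
    "render_agreement",
    "render_added_value",
    "render_accuracy",
    "render_bins",
]

log = logging.getLogger("progval")


@dataclass(frozen=True)
class PipelineConfig:
    """What to compute: variable lists, test level, bootstrap and binning."""

    adjuvant_vars: tuple[str, ...] = ()  # already in the external model
    new_vars: tuple[str, ...] = ()       # candidate additions
    alpha: float = 0.05                  # two-sided significance level
    bootstrap_B: int = 200
    bin_width: float = 0.05
    subgroup_test: str = "joint"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "adjuvant_vars": list(self.adjuvant_vars),
            "new_vars": list(self.new_vars),
            "alpha": self.alpha,
            "bootstrap_B": self.bootstrap_B,
            "bin_width": self.bin_width,
            "subgroup_test": self.subgroup_test,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(
            adjuvant_vars=tuple(d.get("adjuvant_vars", ())),
            new_vars=tuple(d.get("new_vars", ())),
            alpha=float(d.get("alpha", 0.05)),
            bootstrap_B=int(d.get("bootstrap_B", 200)),
            bin_width=float(d.get("bin_width", 0.05)),
            subgroup_test=d.get("subgroup_test", "joint"),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def summarize_cohort(
    cohort: Cohort, continuous: Mapping[str, Sequence[float]] | None = None
) -> dict:
    """Baseline-characteristics summary: level counts and percentages.

    *continuous* optionally maps a name (e.g. ``"age_years"``) to per-patient
    values, summarized as mean (SD).
    """
    out: dict = {"label": cohort.label, "n": cohort.n, "covariates": {}}
    for cov in cohort.schema.covariates:
        counts = cohort.level_counts(cov)
        out["covariates"][cov] = [
            {
                "level": lvl,
                "count": c,
                "percent": 100.0 * c / cohort.n,
            }
            for lvl, c in counts.items()
        ]
    if continuous:
        out["continuous"] = {
            name: {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
            for name, vals in continuous.items()
        }
    return out


# ---------------------------------------------------------------------------
# report object
# ---------------------------------------------------------------------------

def _calibration_dict(fit: CalibrationFit) -> dict:
    return {
        "alpha": None if not np.isfinite(fit.alpha) else fit.alpha,
        "beta": None if not np.isfinite(fit.beta) else fit.beta,
        "vcov": [[None if not np.isfinite(v) else float(v) for v in row]
                 for row in np.asarray(fit.vcov)],
        "joint_stat": None if not np.isfinite(fit.joint_stat) else fit.joint_stat,
        "p_value": fit.p_value,
        "df": fit.df,
        "n": fit.n,
        "events": fit.events,
        "test": fit.test,
        "estimable": fit.estimable,
    }


def _agreement_dicts(rows: Sequence[AgreementRow]) -> list[dict]:
    return [
        {
            "covariate": r.subgroup.covariate,
            "level": r.subgroup.level,
            "n": r.n,
            "mean_predicted": r.mean_predicted,
            "observed": r.observed,
            "difference": r.difference,
            "p_value": r.p_value,
        }
        for r in rows
    ]


def _offset_dict(res: OffsetModelResult) -> dict:
    return {
        "mode": res.mode,
        "variables": list(res.variables),
        "intercept": None if not np.isfinite(res.intercept) else res.intercept,
        "levels": [
            {
                "variable": l.variable,
                "level": l.level,
                "coef": None if not np.isfinite(l.coef) else l.coef,
                "odds_ratio": None if not np.isfinite(l.odds_ratio) else l.odds_ratio,
                "ci_low": None if not np.isfinite(l.ci_low) else l.ci_low,
                "ci_high": None if not np.isfinite(l.ci_high) else l.ci_high,
                "estimable": l.estimable,
            }
            for l in res.levels
        ],
        "factor_p": dict(res.factor_p),
        "loglik": None if not np.isfinite(res.loglik) else res.loglik,
        "n": res.n,
        "estimable": res.estimable,
        "dropped_levels": dict(res.dropped_levels),
    }


def _accuracy_dicts(rows: Sequence[AccuracyResult]) -> list[dict]:
    out = []
    for r in rows:
        out.append(
            {
                "model": r.model_label,
                "pi": None if not np.isfinite(r.pi) else r.pi,
                "pi_se": r.pi_se,
                "ev": r.ev,
                "ev_se": r.ev_se,
                "auc": None if r.auc is None else r.auc.auc,
                "auc_ci_low": None if r.auc is None else r.auc.ci_low,
                "auc_ci_high": None if r.auc is None else r.auc.ci_high,
                "n_failed_resamples": r.n_failed_resamples,
            }
        )
    return out


@dataclass
class ValidationReport:
    """Serializable container for one full validation run."""

    payload: dict

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.payload, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        return cls(payload=json.loads(text))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def run_pipeline(
    cohort: Cohort,
    config: PipelineConfig,
    continuous: Mapping[str, Sequence[float]] | None = None,
) -> ValidationReport:
    """Run the full two-stage validation and assemble the report.

    Stage 1: baseline summary, overall recalibration fit, agreement table
    and binned calibration-curve data.  Stage 2: multivariate offset model
    for the variables the external model already uses, univariate offset
    models and accuracy metrics for the candidate additions.  Deterministic
    given cohort + config (the only randomness is the seeded bootstrap).
    Single-level variables are skipped from stage 2 with a logged warning;
    any other stage failure halts with the stage name.
    """
    payload: dict = {
        "meta": {
            "label": cohort.label,
            "n": cohort.n,
            "n_excluded": cohort.n_excluded,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "version": __version__,
        }
    }
    if cohort.n_excluded:
        log.info("excluded %d record(s) with missing outcome/prediction",
                 cohort.n_excluded)

    try:
        payload["summary"] = summarize_cohort(cohort, continuous)
        payload["calibration"] = _calibration_dict(fit_calibration(cohort))
        payload["agreement"] = _agreement_dicts(
            agreement_table(cohort, subgroup_test=config.subgroup_test)
        )
        payload["bins"] = [
            {
                "lower": b.lower, "upper": b.upper, "count": b.count,
                "mean_predicted": b.mean_predicted,
                "observed_fraction": b.observed_fraction,
            }
            for b in bin_predictions(cohort, config.bin_width, keep_empty=True)
        ]
    except Exception as exc:
        raise RuntimeError(f"agreement stage failed: {exc}") from exc

    def usable(vars_: tuple[str, ...]) -> list[str]:
        keep = []
        for v in vars_:
            if v not in cohort.schema.covariates:
                raise CohortValidationError(f"unknown variable {v!r} in config")
            if cohort.data[v].nunique() < 2:
                log.warning("skipping single-level variable %r", v)
            else:
                keep.append(v)
        return keep

    try:
        added: dict = {}
        adj = usable(config.adjuvant_vars)
        if adj:
            added["multivariate"] = _offset_dict(
                fit_offset_model(
                    cohort, OffsetModelSpec(tuple(adj), "multivariate")
                )
            )
        new = usable(config.new_vars)
        if new:
            fits = fit_offset_model(cohort, OffsetModelSpec(tuple(new), "univariate"))
            added["univariate"] = {v: _offset_dict(r) for v, r in fits.items()}
        payload["added_value"] = added
    except Exception as exc:
        raise RuntimeError(f"added-value stage failed: {exc}") from exc

    try:
        if new:
            cfg = BootstrapConfig(B=config.bootstrap_B, seed=config.seed)
            payload["accuracy"] = _accuracy_dicts(
                accuracy_table(cohort, tuple(new), cfg)
            )
        else:
            payload["accuracy"] = []
    except Exception as exc:
        raise RuntimeError(f"accuracy stage failed: {exc}") from exc

    return ValidationReport(payload=payload)


# ---------------------------------------------------------------------------
# rendering (pure functions of the serialized payload)
# ---------------------------------------------------------------------------

def _fmt(x, nd=1, missing="") -> str:
    return missing if x is None else f"{x:.{nd}f}"


def _fmt_p(p, missing="") -> str:
    if p is None:
        return missing
    return "<0.01" if p < 0.005 else f"{p:.2f}"


def render_summary(payload: dict) -> str:
    lines = ["covariate\tlevel\tn (%)"]
    for cov, rows in sorted(payload["summary"]["covariates"].items()):
        for r in rows:
            lines.append(f"{cov}\t{r['level']}\t{r['count']} ({r['percent']:.1f})")
    for name, s in sorted(payload["summary"].get("continuous", {}).items()):
        lines.append(f"{name}\t\t{s['mean']:.1f} ({s['sd']:.1f})")
    return "\n".join(lines) + "\n"


def render_agreement(payload: dict) -> str:
    lines = ["covariate\tlevel\tn\tpredicted\tobserved\tpredicted-observed\tp"]
    for r in payload["agreement"]:
        lines.append(
            "\t".join(
                [
                    r["covariate"], r["level"], str(r["n"]),
                    _fmt(r["mean_predicted"]), _fmt(r["observed"]),
                    _fmt(r["difference"]), _fmt_p(r["p_value"]),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def render_added_value(payload: dict) -> str:
    lines = ["mode\tvariable\tlevel\tOR [95% CI]\tp"]

    def emit(mode: str, res: dict) -> None:
        seen = set()
        for l in res["levels"]:
            var = l["variable"]
            p = res["factor_p"].get(var)
            first = var not in seen
            seen.add(var)
            or_txt = (
                f"{l['odds_ratio']:.2f} [{l['ci_low']:.2f}; {l['ci_high']:.2f}]"
                if l["estimable"] and l["odds_ratio"] is not None
                else "NE"
            )
            lines.append(
                "\t".join(
                    [mode, var, l["level"], or_txt, _fmt_p(p) if first else ""]
                )
            )

    added = payload.get("added_value", {})
    if "multivariate" in added:
        emit("multivariate", added["multivariate"])
    for var, res in sorted(added.get("univariate", {}).items()):
        emit("univariate", res)
    return "\n".join(lines) + "\n"


def render_accuracy(payload: dict) -> str:
    lines = ["model\tPI +/- SE\tEV (%) +/- SE\tAUC [95% CI]"]
    for r in payload.get("accuracy", []):
        pi = (
            f"{r['pi']:.3f}+/-{r['pi_se']:.3f}"
            if r["pi"] is not None and r["pi_se"] is not None
            else "NE"
        )
        ev = (
            f"{r['ev']:.1f}+/-{r['ev_se']:.1f}"
            if r["ev"] is not None and r["ev_se"] is not None
            else "-"
        )
        a = (
            f"{r['auc']:.3f} [{r['auc_ci_low']:.3f};{r['auc_ci_high']:.3f}]"
            if r["auc"] is not None
            else "NE"
        )
        lines.append("\t".join([r["model"], pi, ev, a]))
    return "\n".join(lines) + "\n"


def render_bins(payload: dict) -> str:
    lines = ["lower\tupper\tcount\tmean_predicted\tobserved_fraction"]
    for b in payload.get("bins", []):
        lines.append(
            "\t".join(
                [
                    f"{b['lower']:.3f}", f"{b['upper']:.3f}", str(b["count"]),
                    _fmt(b["mean_predicted"], 4), _fmt(b["observed_fraction"], 4),
                ]
            )
        )
    return "\n".join(lines) + "\n"
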