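"""Recalibration fitting, agreement tables and calibration-curve binning."""

import numpy as np
import pandas as pd
import pytest

from progval import (
    Cohort,
    CohortSchema,
    SubgroupSpec,
    agreement_table,
    bin_predictions,
    fit_calibration,
    simulate_cohort,
)
from progval.calibration import calibration_in_the_large

from conftest import calibrated_profile, two_point_cohort


# ---------------------------------------------------------------------------
# recalibration fit
# ---------------------------------------------------------------------------

def test_saturated_two_point_fit_is_exactly_calibrated():
    """Observed cell proportions equal the predictions, so the fitted curve
    must pass through them: alpha=0, beta=1, LR statistic 0, p=1."""
    fit = fit_calibration(two_point_cohort())
    assert fit.alpha == pytest.approx(0.0, abs=1e-6)
    assert fit.beta == pytest.approx(1.0, abs=1e-6)
    assert fit.joint_stat == pytest.approx(0.0, abs=1e-8)
    assert fit.p_value == pytest.approx(1.0, abs=1e-6)


def test_separated_design_is_flagged_non_estimable():
    """All deaths at p=0.2 and all survivors at p=0.8 separate perfectly;
    the slope diverges and no p-value may be fabricated."""
    data = pd.DataFrame(
        {
            "outcome": [0] * 5 + [1] * 5,
            "prediction": [0.2] * 5 + [0.8] * 5,
            "x": ["a"] * 10,
        }
    )
    cohort = Cohort(data, CohortSchema(levels={"x": ("a",)}))
    fit = fit_calibration(cohort)
    assert not fit.estimable
    assert fit.p_value is None


def test_single_outcome_class_non_estimable():
    data = pd.DataFrame(
        {"outcome": [1, 1, 1], "prediction": [0.7, 0.8, 0.9], "x": ["a"] * 3}
    )
    cohort = Cohort(data, CohortSchema(levels={"x": ("a",)}))
    fit = fit_calibration(cohort)
    assert not fit.estimable and fit.p_value is None


def test_parameters_recovered_on_miscalibrated_simulation():
    prof = calibrated_profile(n=5000, true_alpha=0.5, true_beta=0.7)
    fit = fit_calibration(simulate_cohort(prof, seed=21))
    se = np.sqrt(np.diag(fit.vcov))
    assert abs(fit.alpha - 0.5) < 3 * se[0]
    assert abs(fit.beta - 0.7) < 3 * se[1]


def test_wald_and_lr_tests_agree_at_large_n():
    prof = calibrated_profile(n=20_000, true_alpha=0.3)
    cohort = simulate_cohort(prof, seed=2)
    lr = fit_calibration(cohort, test="lr")
    wald = fit_calibration(cohort, test="wald")
    assert lr.joint_stat == pytest.approx(wald.joint_stat, rel=0.15)


def test_calibration_in_the_large_detects_intercept_shift():
    prof = calibrated_profile(n=5000, true_alpha=0.6)
    fit = calibration_in_the_large(simulate_cohort(prof, seed=4))
    assert fit.df == 1
    assert fit.p_value < 0.01
    assert fit.alpha > 0.3


# ---------------------------------------------------------------------------
# agreement table
# ---------------------------------------------------------------------------

def test_agreement_difference_is_predicted_minus_observed_percent():
    """Overall row: mean predicted 85.1% vs observed 87.4% gives -2.3."""
    rng = np.random.default_rng(0)
    n = 1000
    pred = np.full(n, 0.851)
    y = np.zeros(n, int)
    y[: round(0.874 * n)] = 1
    data = pd.DataFrame({"outcome": y, "prediction": pred, "x": ["a"] * n})
    cohort = Cohort(data, CohortSchema(levels={"x": ("a",)}))
    row = agreement_table(cohort, [])[0]
    assert row.subgroup.is_all
    assert row.mean_predicted == pytest.approx(85.1)
    assert row.observed == pytest.approx(87.4)
    assert row.difference == pytest.approx(-2.3, abs=1e-9)


def test_all_row_difference_identity(simple_cohort):
    row = agreement_table(simple_cohort, [])[0]
    y = simple_cohort.outcomes
    p = simple_cohort.predictions
    assert row.difference == pytest.approx(-100.0 * np.mean(y - p), abs=1e-12)


def test_agreement_rows_partition_and_order(simple_cohort):
    rows = agreement_table(simple_cohort)
    assert rows[0].subgroup.is_all
    for cov in simple_cohort.schema.covariates:
        total = sum(r.n for r in rows if r.subgroup.covariate == cov)
        assert total == simple_cohort.n


def test_empty_subgroup_yields_missing_row(simple_cohort):
    schema = CohortSchema(
        levels={"age": ("<40", ">=40"), "her2": ("positive", "negative"),
                "treatment": ("none", "both")},
    )
    data = simple_cohort.data.copy()
    data["treatment"] = "none"
    cohort = Cohort(data, schema)
    rows = agreement_table(cohort, [SubgroupSpec("treatment", "both")])
    empty = [r for r in rows if r.subgroup.level == "both"][0]
    assert empty.n == 0
    assert empty.mean_predicted is None
    assert empty.p_value is None


def test_injected_shift_shows_in_agreement_direction():
    """Mimics the young-patient over-optimism pattern: the shifted stratum's
    predicted-minus-observed gap is large and positive, the other small."""
    prof = calibrated_profile(
        n=20_000,
        marginals={"age": {"<40": 0.25, ">=40": 0.75}},
        shifts={("age", "<40"): -1.3},
    )
    cohort = simulate_cohort(prof, seed=13)
    rows = agreement_table(cohort)
    by_level = {r.subgroup.level: r for r in rows if r.subgroup.covariate == "age"}
    assert by_level["<40"].difference > 10.0
    assert by_level[">=40"].difference < by_level["<40"].difference


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_point_mass_lands_in_single_bin():
    data = pd.DataFrame(
        {"outcome": [1, 0, 1], "prediction": [0.87] * 3, "x": ["a"] * 3}
    )
    cohort = Cohort(data, CohortSchema(levels={"x": ("a",)}))
    bins = bin_predictions(cohort)
    assert len(bins) == 1
    assert (bins[0].lower, bins[0].upper) == (pytest.approx(0.85), pytest.approx(0.90))
    assert bins[0].mean_predicted == pytest.approx(0.87)
    assert bins[0].count == 3


def test_uniform_predictions_fill_all_bins_evenly():
    rng = np.random.default_rng(5)
    n = 100_000
    data = pd.DataFrame(
        {
            "outcome": rng.integers(0, 2, n),
            "prediction": rng.random(n),
            "x": ["a"] * n,
        }
    )
    cohort = Cohort(data, CohortSchema(levels={"x": ("a",)}))
    bins = bin_predictions(cohort)
    assert len(bins) == 20
    assert sum(b.count for b in bins) == n
    for b in bins:
        assert b.count == pytest.approx(n / 20, rel=0.1)


def test_bins_tile_unit_interval_when_empty_kept(simple_cohort):
    bins = bin_predictions(simple_cohort, keep_empty=True)
    assert bins[0].lower == 0.0
    assert bins[-1].upper == pytest.approx(1.0)
    assert sum(b.count for b in bins) == simple_cohort.n
    for prev, nxt in zip(bins, bins[1:]):
        assert prev.upper == pytest.approx(nxt.lower)


def test_calibrated_bins_scatter_around_identity():
    prof = calibrated_profile(n=50_000, mean=0.0, sd=1.5)
    cohort = simulate_cohort(prof, seed=17)
    bins = [b for b in bin_predictions(cohort) if b.count >= 200]
    x = np.array([b.mean_predicted for b in bins])
    yv = np.array([b.observed_fraction for b in bins])
    slope, intercept = np.polyfit(x, yv, 1)
    assert slope == pytest.approx(1.0, abs=0.1)
    assert intercept == pytest.approx(0.0, abs=0.05)


def test_invalid_bin_width_rejected(simple_cohort):
    with pytest.raises(ValueError):
        bin_predictions(simple_cohort, width=0.0)
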