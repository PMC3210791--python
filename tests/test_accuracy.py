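"""Predictive inaccuracy, explained variation, bootstrap SEs and AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from progval import (
    BootstrapConfig,
    Cohort,
    CohortSchema,
    accuracy_table,
    auc,
    bootstrap_se,
    explained_variation,
    predictive_inaccuracy,
    simulate_cohort,
)
from progval.cohort import CohortValidationError

from conftest import calibrated_profile


# ---------------------------------------------------------------------------
# predictive inaccuracy
# ---------------------------------------------------------------------------

def test_pi_perfect_prediction_is_zero():
    assert predictive_inaccuracy([1, 0, 1], [1.0, 0.0, 1.0]) == 0.0


def test_pi_direct_arithmetic():
    assert predictive_inaccuracy([1, 0, 1], [0.8, 0.3, 0.6]) == pytest.approx(0.3)


def test_pi_length_mismatch():
    with pytest.raises(ValueError):
        predictive_inaccuracy([1, 0], [0.5])


def test_pi_constant_predictor_closed_form():
    """For the constant predictor m = mean(Y): |1-m| on the m-fraction of
    survivors and |0-m| on the rest, so PI = m(1-m) + (1-m)m = 2m(1-m)."""
    rng = np.random.default_rng(12)
    for _ in range(100):
        n = rng.integers(2, 300)
        y = rng.integers(0, 2, size=n)
        m = y.mean()
        assert predictive_inaccuracy(y, np.full(n, m)) == pytest.approx(
            2 * m * (1 - m), abs=1e-12
        )


# ---------------------------------------------------------------------------
# explained variation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pi_ref,pi_model,expected",
    [
        (0.212, 0.205, 3.3),  # proliferation-index gain, one decimal
        (0.212, 0.207, 2.4),
        (0.3, 0.3, 0.0),
    ],
)
def test_ev_proportional_reduction(pi_ref, pi_model, expected):
    assert round(explained_variation(pi_ref, pi_model), 1) == expected


def test_ev_can_be_negative():
    assert explained_variation(0.393, 0.396) < 0


def test_ev_zero_reference_flagged():
    with pytest.raises(ValueError):
        explained_variation(0.0, 0.1)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _brute_force_auc(y, s):
    y = np.asarray(y)
    s = np.asarray(s)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_perfect_separation():
    assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]).auc == 1.0


def test_auc_all_ties_is_half():
    assert auc([0, 1, 0, 1], [0.5] * 4).auc == 0.5


def test_auc_small_example_brute_force():
    # survivors at 0.9 and 0.4 vs non-survivor at 0.6: one concordant,
    # one discordant pair
    assert auc([1, 1, 0], [0.9, 0.4, 0.6]).auc == pytest.approx(0.5)


def test_auc_single_class_flagged():
    with pytest.raises(ValueError):
        auc([1, 1, 1], [0.2, 0.5, 0.9])


def test_auc_matches_pairwise_oracle_with_ties():
    rng = np.random.default_rng(99)
    for _ in range(200):
        n = int(rng.integers(4, 120))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = rng.choice(np.round(rng.random(6), 2), size=n)  # heavy ties
        assert auc(y, s).auc == pytest.approx(_brute_force_auc(y, s), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(7)
    y = rng.integers(0, 2, 200)
    y[0], y[1] = 0, 1
    s = rng.normal(size=200)
    a = auc(y, s).auc
    assert auc(y, np.exp(s)).auc == pytest.approx(a, abs=1e-12)
    assert auc(y, 3 * s - 10).auc == pytest.approx(a, abs=1e-12)


def test_auc_ci_contains_point_and_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 300)
    s = rng.normal(size=300) + y
    res = auc(y, s)
    assert res.ci_low <= res.auc <= res.ci_high
    assert res.auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_auc_delong_se_order_matches_bootstrap():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 400)
    s = rng.normal(size=400) + 0.8 * y
    res = auc(y, s)
    boots = []
    for _ in range(300):
        idx = rng.integers(0, 400, 400)
        if y[idx].min() == y[idx].max():
            continue
        boots.append(auc(y[idx], s[idx], ci=False).auc)
    assert res.se == pytest.approx(np.std(boots, ddof=1), rel=0.25)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _two_block_cohort(n_each=40):
    """Identical rows within each outcome class, so a stratified resample
    reproduces the cohort exactly."""
    data = pd.DataFrame(
        {
            "outcome": [1] * n_each + [0] * n_each,
            "prediction": [0.8] * n_each + [0.3] * n_each,
            "x": (["low"] * (n_each // 2) + ["high"] * (n_each // 2)) * 2,
        }
    )
    return Cohort(data, CohortSchema(levels={"x": ("low", "high")}))


def test_stratified_bootstrap_of_invariant_cohort_has_zero_se():
    cohort = _two_block_cohort()
    data = cohort.data.copy()
    data["x"] = "low"  # covariate constant: model reduces to offset-only
    invariant = Cohort(data, cohort.schema)
    se, failed = bootstrap_se(
        invariant, (), "pi", BootstrapConfig(B=30, seed=1, stratified=True)
    )
    assert se == pytest.approx(0.0, abs=1e-12)
    assert failed == 0


def test_bootstrap_deterministic_under_fixed_seed():
    prof = calibrated_profile(n=300)
    cohort = simulate_cohort(prof, seed=8)
    cfg = BootstrapConfig(B=50, seed=5)
    a, _ = bootstrap_se(cohort, ("x",), "pi", cfg)
    b, _ = bootstrap_se(cohort, ("x",), "pi", cfg)
    assert a == b


def test_bootstrap_se_magnitude_on_french_scale_cohort():
    """Offset-only PI bootstrap SE at n=435 with ~13% mortality is of order
    0.02 — the scale reported for a cohort of this size."""
    from progval import builtin_profiles

    cohort = simulate_cohort(builtin_profiles()["french"])
    se, _ = bootstrap_se(cohort, (), "pi", BootstrapConfig(B=200, seed=2))
    assert 0.005 < se < 0.05


# ---------------------------------------------------------------------------
# accuracy table
# ---------------------------------------------------------------------------

def test_accuracy_table_layout_and_reference_row():
    prof = calibrated_profile(n=600, effects={("x", "high"): 1.0})
    cohort = simulate_cohort(prof, seed=41)
    rows = accuracy_table(cohort, ("x",), BootstrapConfig(B=40, seed=3))
    assert rows[0].model_label == "model without predictors"
    assert rows[0].ev is None
    assert rows[1].model_label == "model with x"
    assert rows[1].ev == pytest.approx(
        explained_variation(rows[0].pi, rows[1].pi), abs=1e-12
    )


def test_uninformative_constant_covariate_matches_reference_row():
    prof = calibrated_profile(n=400)
    cohort = simulate_cohort(prof, seed=42)
    data = cohort.data.copy()
    data["x"] = "low"
    constant = Cohort(data, cohort.schema)
    rows = accuracy_table(constant, ("x",), BootstrapConfig(B=30, seed=4))
    assert rows[1].pi == pytest.approx(rows[0].pi, abs=1e-12)
    assert rows[1].ev == pytest.approx(0.0, abs=1e-12)


def test_strong_marker_improves_ev_and_auc():
    prof = calibrated_profile(n=2000, effects={("x", "high"): 1.5})
    cohort = simulate_cohort(prof, seed=43)
    rows = accuracy_table(cohort, ("x",), BootstrapConfig(B=40, seed=5))
    assert rows[1].ev > 0
    assert rows[1].auc.auc > rows[0].auc.auc


def test_offset_only_auc_equals_auc_of_prediction_itself():
    """The offset-only fitted probability is a monotone transform of the
    external prediction, so their AUCs coincide."""
    prof = calibrated_profile(n=3000)
    cohort = simulate_cohort(prof, seed=44)
    rows = accuracy_table(cohort, (), BootstrapConfig(B=10, seed=6))
    direct = auc(cohort.outcomes, cohort.predictions)
    assert rows[0].auc.auc == pytest.approx(direct.auc, abs=1e-9)
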