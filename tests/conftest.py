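import numpy as np
import pandas as pd
import pytest

from progval import Cohort, CohortSchema
from progval.simulate import CohortProfile


@pytest.fixture
def simple_schema():
    return CohortSchema(
        levels={"age": ("<40", ">=40"), "her2": ("positive", "negative")},
        reference={"age": "<40", "her2": "positive"},
    )


@pytest.fixture
def simple_cohort(simple_schema):
    data = pd.DataFrame(
        {
            "outcome": [1, 0, 1, 1, 0, 1],
            "prediction": [0.9, 0.5, 0.7, 0.8, 0.4, 0.6],
            "age": ["<40", ">=40", ">=40", "<40", ">=40", ">=40"],
            "her2": ["positive", "negative", "negative", "negative",
                     "positive", "negative"],
        }
    )
    return Cohort(data=data, schema=simple_schema, label="toy")


def two_point_cohort():
    """Saturated design: 5 patients at p=0.2 (1 survivor), 5 at p=0.8 (4).

    Observed proportions equal the predictions in both cells, so the
    two-parameter recalibration fit must pass through them exactly:
    alpha=0, beta=1, likelihood ratio 0.
    """
    data = pd.DataFrame(
        {
            "outcome": [1, 0, 0, 0, 0, 1, 1, 1, 1, 0],
            "prediction": [0.2] * 5 + [0.8] * 5,
            "x": ["a"] * 10,
        }
    )
    schema = CohortSchema(levels={"x": ("a", "b")})
    return Cohort(data=data, schema=schema, label="two-point")


def calibrated_profile(n, true_alpha=0.0, true_beta=1.0, mean=1.0, sd=1.2,
                       effects=None, shifts=None, marginals=None, seed=0):
    """Single-covariate profile for simulation studies."""
    return CohortProfile(
        label="sim",
        n=n,
        covariate_marginals=marginals or {"x": {"low": 0.5, "high": 0.5}},
        risk_logit_mean=mean,
        risk_logit_sd=sd,
        true_alpha=true_alpha,
        true_beta=true_beta,
        covariate_effects=effects or {},
        subgroup_shifts=shifts or {},
        seed=seed,
    )
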