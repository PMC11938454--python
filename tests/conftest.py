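import numpy as np
import pandas as pd
import pytest

from brainpath.synthetic import (
    CohortConfig,
    OutcomeParams,
    VariantSpec,
    default_outcome_params,
    default_panel,
    generate_cohort,
)
from brainpath.pipeline import build_analysis_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def case_control_cohort():
    """Small ADNI-style cohort with the default planted pathways."""
    config = CohortConfig(
        n_participants=1500,
        seed=202,
        cohort_style="case_control",
        outcome_params=default_outcome_params("case_control"),
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def analysis_table(case_control_cohort):
    table, variant_ids, measure_cols = build_analysis_table(
        case_control_cohort.genotypes,
        case_control_cohort.phenotypes,
        "case_control",
    )
    return table, variant_ids, measure_cols


def make_linear_mediation_frame(
    n=2000,
    a=0.5,
    b=0.8,
    c_prime=0.3,
    noise_m=1.0,
    noise_y=1.0,
    freq=0.3,
    seed=0,
    with_covariates=False,
):
    """Single-variant, single-mediator frame with a continuous outcome."""
    r = np.random.default_rng(seed)
    d = r.binomial(2, freq, size=n).astype(float)
    cols = {"dosage": d}
    extra_m = extra_y = 0.0
    if with_covariates:
        age = r.normal(64, 8, size=n)
        sex = r.binomial(1, 0.5, size=n).astype(float)
        site = r.integers(0, 3, size=n)
        cols.update(age=age, sex=sex, site=site)
        extra_m = 0.01 * (age - 64) + 0.1 * sex
        extra_y = -0.005 * (age - 64) + 0.2 * sex
    m = a * d + extra_m + (r.normal(0, noise_m, size=n) if noise_m else 0.0)
    y = b * m + c_prime * d + extra_y + (r.normal(0, noise_y, size=n) if noise_y else 0.0)
    cols["mediator"] = m
    cols["outcome"] = y
    return pd.DataFrame(cols)
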