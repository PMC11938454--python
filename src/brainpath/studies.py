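"""Parameter-recovery and calibration studies.

These reusable study designs exercise the full stack on synthetic cohorts
whose generating coefficients are set to effect sizes of the magnitude
reported for medial-temporal structures in case-control neuroimaging
cohorts: a mediator-model (path a) recovery study, an indirect-effect
(ACME) recovery study, and the type-I-error study for the non-normal
family-history proxy outcome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import Type1Result, proxy_null_generator, type1_sim
from .mediation import MediationResult, MediationSpec, bootstrap_acme, fit_path_a
from .synthetic import (
    CohortConfig,
    VariantSpec,
    generate_apoe_genotypes,
    generate_covariates,
    generate_genotypes,
    generate_mediators,
)


def _covariate_frame(n: int, seed: int, rng: np.random.Generator) -> pd.DataFrame:
    config = CohortConfig(n_participants=n, seed=seed)
    cov = generate_covariates(config, rng=rng)
    icv = rng.normal(1.5e6, 1.4e5, size=n)
    cov["icv"] = (icv - icv.mean()) / icv.std(ddof=1)
    return cov


def _dosage(n: int, rng: np.random.Generator, apoe: bool, allele_frequency: float) -> pd.Series:
    if apoe:
        hap = generate_apoe_genotypes(n, {"e3": 1.0 - allele_frequency, "e4": allele_frequency}, rng=rng)
        return hap["e4_count"].astype(float)
    config = CohortConfig(n_participants=n, seed=0)
    panel = [VariantSpec("snp", "A", allele_frequency)]
    return generate_genotypes(config, panel, rng=rng)["snp"]


def path_a_recovery(
    true_coefficient: float,
    n: int = 5000,
    allele_frequency: float = 0.15,
    apoe: bool = True,
    residual_sd: float = 1.0,
    seed: int = 0,
) -> float:
    """Generate a cohort whose standardized measure follows the linear
    mediator model with a known genotype coefficient, refit the mediator
    regression (dosage + age + sex + ICV), and return the fitted genotype
    coefficient."""
    rng = np.random.default_rng(seed)
    dosage = _dosage(n, rng, apoe, allele_frequency)
    cov = _covariate_frame(n, seed, rng)
    genotypes = pd.DataFrame({"dosage": dosage})
    panel = [VariantSpec("dosage", "C", allele_frequency, mediator_effects={"m__volume": true_coefficient})]
    measure = generate_mediators(genotypes, cov, panel, residual_sd=residual_sd, rng=rng)
    frame = pd.concat([genotypes, cov, measure], axis=1)
    spec = MediationSpec(
        variant="dosage", measure="m__volume", outcome="m__volume",
        covariates=("age", "sex"), global_covariate="icv", bootstrap_reps=0,
    )
    return fit_path_a(frame, spec)["dosage"][0]


def acme_recovery(
    path_a: float,
    indirect_effect: float,
    n: int = 10_000,
    direct_effect: float = 0.1,
    bootstrap_reps: int = 500,
    allele_frequency: float = 0.15,
    apoe: bool = True,
    seed: int = 0,
) -> MediationResult:
    """Linear-linear mediation recovery: the mediator follows the path-a
    model, the continuous outcome adds path b = indirect/path_a times the
    mediator plus a direct dosage effect, both with unit residual SD; the
    indirect effect is re-estimated as the bootstrap-tested product of
    fitted coefficients."""
    rng = np.random.default_rng(seed)
    dosage = _dosage(n, rng, apoe, allele_frequency)
    cov = _covariate_frame(n, seed, rng)
    b = indirect_effect / path_a
    m = path_a * dosage.to_numpy() + rng.normal(0.0, 1.0, size=n)
    y = b * m + direct_effect * dosage.to_numpy() + rng.normal(0.0, 1.0, size=n)
    frame = pd.concat(
        [pd.DataFrame({"dosage": dosage, "measure": m, "outcome": y}), cov], axis=1
    )
    spec = MediationSpec(
        variant="dosage", measure="measure", outcome="outcome",
        outcome_family="linear", covariates=("age", "sex"), global_covariate="icv",
        bootstrap_reps=bootstrap_reps, seed=seed,
    )
    return bootstrap_acme(frame, spec)


def proxy_type1_study(
    n_reps: int = 5000,
    n_participants: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> Type1Result:
    """Type-I error of the total-effect test under the null with the
    proxy-score-shaped (bounded, bimodal, non-normal) outcome."""
    return type1_sim(
        proxy_null_generator(),
        n_participants=n_participants,
        n_reps=n_reps,
        alpha=alpha,
        seed=seed,
    )
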