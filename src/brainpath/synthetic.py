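"""Synthetic cohort generation.

Builds cohorts with the statistical structure the downstream analysis
assumes: Hardy-Weinberg genotypes at specified allele frequencies, APOE
haplotype structure at rs429358/rs7412, regional brain measures generated
from linear mediator models, and either a binary case/control outcome
(logistic model, ADNI-style) or per-participant parental records that
induce a family-history proxy score correlated with genetic risk
(UKB-style).

All randomness flows through a single :class:`numpy.random.Generator`
seeded from the cohort configuration, so a fixed seed reproduces a cohort
bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .catalog import measure_catalog, measure_name
from .errors import ValidationError

_NUCLEOTIDES = frozenset("ACGT")

# Haplotype -> (rs429358, rs7412) nucleotides.  e1 is vanishingly rare in
# European-ancestry samples and is omitted from the default generator
# frequencies, but the map carries it so the coding logic can be exercised.
APOE_HAPLOTYPE_MAP: Mapping[str, tuple] = {
    "e1": ("C", "T"),
    "e2": ("T", "T"),
    "e3": ("T", "C"),
    "e4": ("C", "C"),
}

# Raw-unit baselines (mean, SD) per measure type used when emitting
# left/right regional tables; genetic effects are specified in SD units.
_BASELINES = {"area": (2500.0, 250.0), "thickness": (2.5, 0.12), "volume": (4000.0, 450.0)}


@dataclass(frozen=True)
class VariantSpec:
    """A genetic variant in the analysis panel.

    ``mediator_effects`` maps measure names (``region__measure_type``) to
    standardized per-allele coefficients (SD of the measure per effect
    allele); ``direct_outcome_effect`` acts on the outcome's linear
    predictor per allele, bypassing all mediators.
    """

    variant_id: str
    effect_allele: str
    allele_frequency: float
    mediator_effects: Mapping[str, float] = field(default_factory=dict)
    direct_outcome_effect: float = 0.0

    def __post_init__(self):
        if not self.variant_id:
            raise ValidationError("variant_id must be non-empty")
        if self.effect_allele not in _NUCLEOTIDES:
            raise ValidationError(
                f"{self.variant_id}: effect_allele must be one of A/C/G/T, got {self.effect_allele!r}"
            )
        af = self.allele_frequency
        if not (isinstance(af, (int, float)) and math.isfinite(af) and 0.0 < af < 1.0):
            raise ValidationError(
                f"{self.variant_id}: allele_frequency must be finite and in (0, 1), got {af!r}"
            )


@dataclass(frozen=True)
class ParentRecord:
    """Self-reported parental disease status and (current or death) age."""

    affected: bool
    age_years: float
    available: bool = True

    def __post_init__(self):
        if self.available and not (math.isfinite(self.age_years) and self.age_years > 0):
            raise ValidationError(f"parental age must be positive, got {self.age_years!r}")


@dataclass(frozen=True)
class OutcomeParams:
    """Outcome-model coefficients.

    ``mediator_coefficients`` (path b, per SD of the mediator) act on the
    outcome linear predictor together with the panel's direct effects.  For
    the proxy style, each parent's affection probability is logistic in
    ``intercept + 0.5 * liability_slope * participant liability``; the 0.5
    is the expected allele-transmission share between parent and offspring.
    """

    intercept: float = logit(0.16)
    mediator_coefficients: Mapping[str, float] = field(default_factory=dict)
    age_coefficient: float = 0.0
    sex_coefficient: float = 0.0
    liability_slope: float = 1.0
    parent_age_mean: float = 78.0
    parent_age_sd: float = 9.0


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int
    seed: int
    cohort_style: str = "proxy"  # "proxy" (UKB-style) or "case_control" (ADNI-style)
    age_mean: float = 64.4
    age_sd: float = 7.7
    sex_ratio: float = 0.477  # proportion male
    n_sites: int = 3
    mediator_residual_sd: float = 1.0
    outcome_params: OutcomeParams = field(default_factory=OutcomeParams)

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if self.mediator_residual_sd <= 0:
            raise ValidationError("mediator_residual_sd must be > 0")
        if self.cohort_style not in ("proxy", "case_control"):
            raise ValidationError(
                f"cohort_style must be 'proxy' or 'case_control', got {self.cohort_style!r}"
            )
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")


def default_panel() -> List[VariantSpec]:
    """The default 11-variant panel: APOE e4 allele count, the two named
    risk SNPs with their region-level effects, and eight null lead SNPs.

    Standardized mediator effects for APOE4 and rs75627662 follow the
    magnitudes observed for medial-temporal structures in case-control
    data; the remaining SNPs are null so that grid-level error rates can
    be studied.
    """
    panel = [
        VariantSpec(
            "APOE4",
            "C",
            0.15,
            mediator_effects={
                measure_name("entorhinal", "thickness"): -0.333,
                measure_name("amygdala", "volume"): -0.409,
                measure_name("hippocampus", "volume"): -0.424,
                measure_name("inferior_lateral_ventricle", "volume"): 0.317,
            },
            direct_outcome_effect=0.40,
        ),
        VariantSpec(
            "rs75627662",
            "T",
            0.20,
            mediator_effects={
                measure_name("entorhinal", "thickness"): -0.246,
                measure_name("amygdala", "volume"): -0.242,
                measure_name("hippocampus", "volume"): -0.291,
            },
            direct_outcome_effect=0.15,
        ),
        VariantSpec(
            "rs7384878",
            "C",
            0.30,
            mediator_effects={
                measure_name("superiorparietal", "thickness"): 0.019,
                measure_name("putamen", "volume"): 0.248,
            },
            direct_outcome_effect=-0.10,
        ),
    ]
    null_freqs = (0.11, 0.18, 0.24, 0.31, 0.37, 0.08, 0.42, 0.27)
    for i, af in enumerate(null_freqs, start=1):
        panel.append(VariantSpec(f"rs_sim{i:02d}", "A", af))
    return panel


def default_outcome_params(style: str = "case_control") -> OutcomeParams:
    """Outcome coefficients that make the default panel's mediated paths
    detectable (products a*b near the case-control magnitudes)."""
    b = {
        measure_name("entorhinal", "thickness"): -0.26,
        measure_name("amygdala", "volume"): -0.32,
        measure_name("hippocampus", "volume"): -0.33,
        measure_name("inferior_lateral_ventricle", "volume"): 0.34,
        measure_name("putamen", "volume"): -0.17,
    }
    intercept = 0.0 if style == "case_control" else logit(0.16)
    return OutcomeParams(intercept=intercept, mediator_coefficients=b)


# ---------------------------------------------------------------------------
# building blocks


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _truncated_normal(rng, n, mean, sd, low=40.0, high=100.0) -> np.ndarray:
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_covariates(config: CohortConfig, rng=None) -> pd.DataFrame:
    """Age (Gaussian truncated to [40, 100]), sex (1 = male), site label."""
    rng = _as_rng(config.seed if rng is None else rng)
    n = config.n_participants
    age = _truncated_normal(rng, n, config.age_mean, config.age_sd)
    sex = (rng.random(n) < config.sex_ratio).astype(int)
    site = rng.integers(0, config.n_sites, size=n)
    return pd.DataFrame({"age": age, "sex": sex, "site": site})


def generate_genotypes(
    config: CohortConfig,
    panel: Sequence[VariantSpec],
    rng=None,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Dosage matrix (n x p) with independent Hardy-Weinberg draws per variant.

    Dosage counts effect alleles (0/1/2); missingness, if any, is applied
    missing-completely-at-random as NaN.
    """
    if not panel:
        raise ValidationError("panel must be non-empty")
    ids = [v.variant_id for v in panel]
    if len(set(ids)) != len(ids):
        raise ValidationError("variant_id must be unique within a panel")
    if not (0.0 <= missing_rate < 1.0):
        raise ValidationError(f"missing_rate must be in [0, 1), got {missing_rate!r}")
    rng = _as_rng(config.seed if rng is None else rng)
    n = config.n_participants
    cols = {}
    for v in panel:
        dosage = rng.binomial(2, v.allele_frequency, size=n).astype(float)
        if missing_rate > 0:
            dosage[rng.random(n) < missing_rate] = np.nan
        cols[v.variant_id] = dosage
    return pd.DataFrame(cols)


def generate_apoe_genotypes(
    n: int,
    haplotype_frequencies: Mapping[str, float],
    seed=None,
    rng=None,
) -> pd.DataFrame:
    """Draw two APOE haplotypes per participant and emit unphased genotypes.

    Returns a DataFrame with string genotypes at rs429358 and rs7412
    (alphabetically ordered, e.g. ``"C/T"``) and the true e4 allele count
    used as an oracle for the haplotype-coding logic.
    """
    freqs = dict(haplotype_frequencies)
    unknown = set(freqs) - set(APOE_HAPLOTYPE_MAP)
    if unknown:
        raise ValidationError(f"unknown APOE haplotypes: {sorted(unknown)}")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-8:
        raise ValidationError(f"haplotype frequencies must sum to 1, got {total}")
    rng = _as_rng(rng if rng is not None else seed)
    names = sorted(freqs)
    p = np.array([freqs[k] for k in names], dtype=float)
    if np.any(p < 0):
        raise ValidationError("haplotype frequencies must be non-negative")
    hap1 = rng.choice(len(names), size=n, p=p)
    hap2 = rng.choice(len(names), size=n, p=p)

    def site_genotype(h1, h2, site):
        a = APOE_HAPLOTYPE_MAP[names[h1]][site]
        b = APOE_HAPLOTYPE_MAP[names[h2]][site]
        return "/".join(sorted((a, b)))

    rs429358 = [site_genotype(a, b, 0) for a, b in zip(hap1, hap2)]
    rs7412 = [site_genotype(a, b, 1) for a, b in zip(hap1, hap2)]
    e4_idx = names.index("e4") if "e4" in names else -1
    e4 = (hap1 == e4_idx).astype(int) + (hap2 == e4_idx).astype(int)
    return pd.DataFrame({"rs429358": rs429358, "rs7412": rs7412, "e4_count": e4})


def generate_mediators(
    genotypes: pd.DataFrame,
    covariates: Optional[pd.DataFrame],
    panel: Sequence[VariantSpec],
    residual_sd: float,
    rng=None,
    covariate_effects: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> pd.DataFrame:
    """Regional measures from the linear mediator model.

    Each measure is ``sum_v beta_v * dosage_v + covariate terms +
    N(0, residual_sd)`` on the standardized (SD-unit) scale.  Only measures
    named by at least one panel variant are emitted; downstream code
    standardizes, this function does not.
    """
    if residual_sd < 0:
        raise ValidationError("residual_sd must be >= 0")
    if covariates is not None and len(covariates) != len(genotypes):
        raise ValidationError(
            f"genotypes ({len(genotypes)}) and covariates ({len(covariates)}) row counts differ"
        )
    rng = _as_rng(rng)
    n = len(genotypes)
    measures: Dict[str, np.ndarray] = {}
    names = sorted({m for v in panel for m in v.mediator_effects})
    for m in names:
        signal = np.zeros(n)
        for v in panel:
            beta = v.mediator_effects.get(m, 0.0)
            if beta:
                if v.variant_id not in genotypes.columns:
                    raise ValidationError(f"panel variant {v.variant_id} missing from genotypes")
                signal = signal + beta * genotypes[v.variant_id].to_numpy(float)
        if covariate_effects and m in covariate_effects:
            for cov, coef in covariate_effects[m].items():
                if covariates is None or cov not in covariates.columns:
                    raise ValidationError(f"covariate {cov!r} not available for measure {m!r}")
                signal = signal + coef * covariates[cov].to_numpy(float)
        noise = rng.normal(0.0, residual_sd, size=n) if residual_sd > 0 else 0.0
        measures[m] = signal + noise
    return pd.DataFrame(measures, index=genotypes.index)


def _participant_liability(
    genotypes: pd.DataFrame,
    mediators: Optional[pd.DataFrame],
    covariates: Optional[pd.DataFrame],
    panel: Sequence[VariantSpec],
    params: OutcomeParams,
) -> np.ndarray:
    n = len(genotypes)
    eta = np.zeros(n)
    for v in panel:
        if v.direct_outcome_effect and v.variant_id in genotypes.columns:
            eta = eta + v.direct_outcome_effect * genotypes[v.variant_id].to_numpy(float)
    if mediators is not None:
        for m, b in params.mediator_coefficients.items():
            if b and m in mediators.columns:
                eta = eta + b * mediators[m].to_numpy(float)
    if covariates is not None:
        if params.age_coefficient:
            eta = eta + params.age_coefficient * covariates["age"].to_numpy(float)
        if params.sex_coefficient:
            eta = eta + params.sex_coefficient * covariates["sex"].to_numpy(float)
    return eta


def generate_outcome(
    genotypes: pd.DataFrame,
    mediators: Optional[pd.DataFrame],
    covariates: Optional[pd.DataFrame],
    config: CohortConfig,
    rng=None,
    panel: Sequence[VariantSpec] = (),
) -> pd.DataFrame:
    """Outcome columns for the configured cohort style.

    case_control: a single binary ``status`` column, Bernoulli with
    logistic probability in the participant's linear predictor (direct
    per-variant effects from ``panel``, path-b mediator terms and covariate
    terms from ``config.outcome_params``).

    proxy: two parental records per participant (``father_*``,
    ``mother_*``).  Each parent's affection probability is logistic in the
    participant's own liability scaled by the 0.5 transmission share, so
    the derived proxy score correlates positively with risk dosage without
    simulating parental genotypes explicitly.  Parental ages are Gaussian
    truncated to [40, 100].
    """
    rng = _as_rng(rng)
    liability = _participant_liability(genotypes, mediators, covariates, panel, config.outcome_params)
    return _outcome_from_liability(liability, config, rng)


def _outcome_from_liability(liability: np.ndarray, config: CohortConfig, rng) -> pd.DataFrame:
    params = config.outcome_params
    n = len(liability)
    if config.cohort_style == "case_control":
        p = expit(params.intercept + liability)
        return pd.DataFrame({"status": rng.binomial(1, p).astype(int)})
    # proxy style: two parents per participant
    p_aff = expit(params.intercept + 0.5 * params.liability_slope * liability)
    out = {}
    for parent in ("father", "mother"):
        affected = rng.binomial(1, p_aff).astype(bool)
        age = _truncated_normal(rng, n, params.parent_age_mean, params.parent_age_sd)
        out[f"{parent}_affected"] = affected
        out[f"{parent}_age"] = age
        out[f"{parent}_available"] = np.ones(n, dtype=bool)
    return pd.DataFrame(out)


def generate_gaussian_outcome(
    genotypes: pd.DataFrame,
    mediators: Optional[pd.DataFrame],
    covariates: Optional[pd.DataFrame],
    panel: Sequence[VariantSpec],
    params: OutcomeParams,
    residual_sd: float = 1.0,
    rng=None,
) -> pd.Series:
    """Continuous outcome with Gaussian residuals: the identity-link analogue
    of the logistic model, used for linear-outcome recovery studies."""
    rng = _as_rng(rng)
    eta = params.intercept + _participant_liability(genotypes, mediators, covariates, panel, params)
    noise = rng.normal(0.0, residual_sd, size=len(eta)) if residual_sd > 0 else 0.0
    return pd.Series(eta + noise, index=genotypes.index, name="outcome")


# ---------------------------------------------------------------------------
# full-cohort assembly


@dataclass
class Cohort:
    """A generated cohort: dosages, phenotype table and provenance."""

    genotypes: pd.DataFrame  # participant x variant dosages (APOE4 = e4 count)
    phenotypes: pd.DataFrame  # covariates, outcome columns, regional L/R table, icv
    config: CohortConfig
    panel: List[VariantSpec]
    apoe_frequencies: Mapping[str, float]
    latent_measures: pd.DataFrame  # standardized combined measures pre split (oracle)

    @property
    def n(self) -> int:
        return len(self.genotypes)


DEFAULT_APOE_FREQUENCIES = {"e2": 0.08, "e3": 0.77, "e4": 0.15}


def generate_cohort(
    config: CohortConfig,
    panel: Optional[Sequence[VariantSpec]] = None,
    apoe_frequencies: Optional[Mapping[str, float]] = None,
    genotype_missing_rate: float = 0.0,
) -> Cohort:
    """Generate a complete analysis-ready cohort.

    The full regional table carries all 93 measures as left/right columns in
    raw units (plus ICV); standardized latent measures drive the outcome so
    that path-b coefficients refer to SD units, matching the downstream
    z-scoring step.
    """
    panel = list(default_panel() if panel is None else panel)
    apoe_frequencies = dict(DEFAULT_APOE_FREQUENCIES if apoe_frequencies is None else apoe_frequencies)
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    covariates = generate_covariates(config, rng=rng)

    snp_panel = [v for v in panel if v.variant_id != "APOE4"]
    genotypes = generate_genotypes(config, snp_panel, rng=rng, missing_rate=genotype_missing_rate) \
        if snp_panel else pd.DataFrame(index=range(n))
    apoe_columns = None
    if any(v.variant_id == "APOE4" for v in panel):
        apoe = generate_apoe_genotypes(n, apoe_frequencies, rng=rng)
        genotypes = genotypes.assign(APOE4=apoe["e4_count"].astype(float))
        apoe_columns = apoe[["rs429358", "rs7412"]]

    # standardized latent measures for every catalog entry
    latent = {}
    for region, mtype in measure_catalog():
        m = measure_name(region, mtype)
        signal = np.zeros(n)
        for v in panel:
            beta = v.mediator_effects.get(m, 0.0)
            if beta:
                signal = signal + beta * genotypes[v.variant_id].to_numpy(float)
        latent[m] = signal + rng.normal(0.0, config.mediator_residual_sd, size=n)
    latent = pd.DataFrame(latent)

    outcome = generate_outcome(genotypes, latent, covariates, config, rng=rng, panel=panel)

    # emit raw-unit left/right columns consistent with the latent measures
    regional = {}
    for region, mtype in measure_catalog():
        m = measure_name(region, mtype)
        mu, sd = _BASELINES[mtype]
        combined = mu + sd * latent[m].to_numpy()
        asym = rng.normal(0.0, sd / 10.0, size=n)
        if mtype == "thickness":  # combined is the L/R mean
            left, right = combined + asym, combined - asym
        else:  # combined is the L/R sum
            left, right = combined / 2.0 + asym, combined / 2.0 - asym
        regional[f"{m}__L"] = left
        regional[f"{m}__R"] = right
    regional = pd.DataFrame(regional)
    icv = pd.Series(rng.normal(1.5e6, 1.4e5, size=n), name="icv")

    pieces = [covariates, outcome]
    if apoe_columns is not None:
        pieces.append(apoe_columns)
    pieces.extend([icv.to_frame(), regional])
    phenotypes = pd.concat(pieces, axis=1)
    phenotypes.insert(0, "participant_id", [f"P{i:06d}" for i in range(n)])
    genotypes = genotypes.copy()
    genotypes.insert(0, "participant_id", phenotypes["participant_id"])

    return Cohort(
        genotypes=genotypes,
        phenotypes=phenotypes,
        config=config,
        panel=panel,
        apoe_frequencies=apoe_frequencies,
        latent_measures=latent,
    )
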