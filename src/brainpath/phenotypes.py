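"""Analysis-ready phenotype and genotype derivation.

Covers APOE e4 allele counting from unphased rs429358/rs7412 genotypes,
the family-history proxy score for late-onset Alzheimer's disease,
hemisphere combination and global brain measures, z-scoring, and
per-variant genotype quality control (missingness and Hardy-Weinberg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .catalog import CORTICAL_REGIONS, hemisphere_column, measure_name
from .errors import ExclusionSignal, ValidationError
from .synthetic import ParentRecord

#: Ceiling on an unaffected parent's proxy-score contribution: the maximum
#: population prevalence of Alzheimer's disease in the oldest age bands.
UNAFFECTED_CAP = 0.32

MISSINGNESS_THRESHOLD = 0.10
HWE_P_THRESHOLD = 1e-9


# ---------------------------------------------------------------------------
# APOE coding


@dataclass(frozen=True)
class ApoeCall:
    """e4 allele count with an ambiguity flag for the unphased
    double-heterozygote (C/T at both sites: e2/e4 vs e1/e3)."""

    e4_count: int
    ambiguous: bool = False

    def __post_init__(self):
        if self.e4_count not in (0, 1, 2):
            raise ValidationError(f"e4_count must be 0, 1 or 2, got {self.e4_count}")


_GenotypeInput = Union[str, Tuple[str, str], None]


def _parse_pair(genotype: _GenotypeInput, site: str) -> Optional[Tuple[str, str]]:
    if genotype is None or (isinstance(genotype, float) and math.isnan(genotype)):
        return None
    if isinstance(genotype, str):
        alleles = tuple(genotype.split("/"))
    else:
        alleles = tuple(genotype)
    if len(alleles) != 2:
        raise ValidationError(f"{site}: expected an unordered pair, got {genotype!r}")
    for a in alleles:
        if a not in ("C", "T"):
            raise ValidationError(f"{site}: allele must be C or T, got {a!r}")
    return tuple(sorted(alleles))  # type: ignore[return-value]


# haplotypes as (rs429358, rs7412): e1=(C,T), e2=(T,T), e3=(T,C), e4=(C,C)
_HAPLOTYPES = {"e1": ("C", "T"), "e2": ("T", "T"), "e3": ("T", "C"), "e4": ("C", "C")}


def count_apoe4(rs429358_genotype: _GenotypeInput, rs7412_genotype: _GenotypeInput) -> Optional[ApoeCall]:
    """Count e4 haplotypes consistent with the two unphased genotypes.

    Enumerates all haplotype-pair assignments compatible with the observed
    site genotypes.  The only genuinely ambiguous configuration is the
    double heterozygote, which is consistent with both e2/e4 and e1/e3;
    because e1 is vanishingly rare it is resolved to e2/e4 (one e4 allele)
    and flagged.  A missing genotype at either site yields ``None`` so the
    participant can be dropped from APOE models.
    """
    g1 = _parse_pair(rs429358_genotype, "rs429358")
    g2 = _parse_pair(rs7412_genotype, "rs7412")
    if g1 is None or g2 is None:
        return None

    counts = set()
    haps = list(_HAPLOTYPES.values())
    for h_a in haps:
        for h_b in haps:
            if tuple(sorted((h_a[0], h_b[0]))) == g1 and tuple(sorted((h_a[1], h_b[1]))) == g2:
                counts.add(int(h_a == ("C", "C")) + int(h_b == ("C", "C")))
    if not counts:  # cannot happen for C/T-coded inputs, but be defensive
        raise ValidationError(f"no haplotype pair consistent with {g1}/{g2}")
    if len(counts) == 1:
        return ApoeCall(e4_count=counts.pop(), ambiguous=False)
    # double heterozygote: {0 (e1/e3), 1 (e2/e4)} -> resolve to e2/e4
    return ApoeCall(e4_count=1, ambiguous=True)


def apoe4_dosage(table: pd.DataFrame, rs429358: str = "rs429358", rs7412: str = "rs7412") -> pd.Series:
    """Vectorized e4 count over a table of string genotypes (NaN = missing)."""
    calls = [
        count_apoe4(a, b)
        for a, b in zip(table[rs429358], table[rs7412])
    ]
    return pd.Series(
        [float(c.e4_count) if c is not None else np.nan for c in calls],
        index=table.index,
        name="APOE4",
    )


# ---------------------------------------------------------------------------
# proxy score


def unaffected_contribution(age_years: float) -> float:
    """Age weight (100 - age)/100 of an unaffected parent, floored at 0 and
    capped at the maximum population prevalence (0.32)."""
    if not math.isfinite(age_years) or age_years < 0:
        raise ValidationError(f"parental age must be non-negative, got {age_years!r}")
    return min(UNAFFECTED_CAP, max(0.0, (100.0 - age_years) / 100.0))


def proxy_score(parents: Sequence[ParentRecord]) -> float:
    """Family-history proxy score for late-onset Alzheimer's disease.

    Each affected parent contributes 1 (the score reflects the number of
    affected biological parents); each unaffected parent contributes the
    age weight ``min(0.32, max(0, (100 - age)/100))``, discounting parents
    who have not yet passed through the period of risk.
    """
    available = [p for p in parents if p.available]
    if not available:
        raise ExclusionSignal("no parental information; participant must be excluded")
    score = 0.0
    for p in available:
        if p.affected:
            score += 1.0
        else:
            score += unaffected_contribution(p.age_years)
    return score


def proxy_scores(phenotypes: pd.DataFrame) -> pd.Series:
    """Proxy score per participant from ``father_*``/``mother_*`` columns;
    NaN where no parent is available."""
    out = np.full(len(phenotypes), np.nan)
    for i, row in enumerate(phenotypes.itertuples(index=False)):
        parents = []
        for parent in ("father", "mother"):
            if getattr(row, f"{parent}_available", True):
                parents.append(
                    ParentRecord(
                        affected=bool(getattr(row, f"{parent}_affected")),
                        age_years=float(getattr(row, f"{parent}_age")),
                    )
                )
        if parents:
            out[i] = proxy_score(parents)
    return pd.Series(out, index=phenotypes.index, name="proxy_score")


# ---------------------------------------------------------------------------
# brain measures


@dataclass(frozen=True)
class RegionalMeasure:
    region: str
    measure_type: str
    left: float
    right: float

    @property
    def combined(self) -> float:
        return combine_hemispheres(self)


def combine_hemispheres(measure: RegionalMeasure) -> float:
    """Sum left and right for area and volume; average for thickness.
    Missing on either side propagates (model-specific exclusion)."""
    if measure.measure_type not in ("area", "thickness", "volume"):
        raise ValidationError(f"unknown measure_type {measure.measure_type!r}")
    left, right = measure.left, measure.right
    if not (math.isfinite(left) and math.isfinite(right)):
        return math.nan
    if measure.measure_type == "thickness":
        return (left + right) / 2.0
    return left + right


def combine_hemisphere_table(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse ``region__type__L/R`` column pairs into combined columns."""
    out = {}
    for col in table.columns:
        if col.endswith("__L"):
            base = col[:-3]
            right = f"{base}__R"
            if right not in table.columns:
                raise ValidationError(f"missing right-hemisphere column for {base}")
            mtype = base.rpartition("__")[2]
            if mtype == "thickness":
                out[base] = (table[col] + table[right]) / 2.0
            else:
                out[base] = table[col] + table[right]
    return pd.DataFrame(out, index=table.index)


def global_measures(combined: pd.DataFrame) -> pd.DataFrame:
    """Total surface area and surface-area-weighted global mean thickness.

    total area = sum of the 34 cortical region areas; global thickness =
    sum over regions of (area_i / total_area) * thickness_i.  ICV, when
    present, passes through unchanged.
    """
    area_cols, thick_cols = [], []
    for region in CORTICAL_REGIONS:
        a, t = measure_name(region, "area"), measure_name(region, "thickness")
        if a not in combined.columns:
            raise ValidationError(f"missing cortical region column: {a}")
        if t not in combined.columns:
            raise ValidationError(f"missing cortical region column: {t}")
        area_cols.append(a)
        thick_cols.append(t)
    areas = combined[area_cols].to_numpy(float)
    thicks = combined[thick_cols].to_numpy(float)
    total_area = areas.sum(axis=1)
    global_thickness = (areas * thicks).sum(axis=1) / total_area
    out = pd.DataFrame(
        {"total_surface_area": total_area, "global_mean_thickness": global_thickness},
        index=combined.index,
    )
    if "icv" in combined.columns:
        out["icv"] = combined["icv"]
    return out


def zscore(values: pd.Series) -> pd.Series:
    """Standardize to mean 0, sample SD 1 (n-1 denominator) over non-missing
    entries; missing values stay missing."""
    x = pd.Series(values, dtype=float)
    ok = x.notna()
    if ok.sum() < 2:
        raise ValidationError("zscore needs at least 2 non-missing values")
    sd = x[ok].std(ddof=1)
    if sd == 0 or not math.isfinite(sd):
        raise ValidationError("zscore undefined for a zero-variance column")
    return (x - x[ok].mean()) / sd


# ---------------------------------------------------------------------------
# genotype QC


@dataclass(frozen=True)
class QcReport:
    variant_id: str
    missingness: float
    hwe_p: float
    monomorphic: bool = False

    @property
    def passed(self) -> bool:
        return self.missingness <= MISSINGNESS_THRESHOLD and self.hwe_p >= HWE_P_THRESHOLD


def hwe_chi2_p(n_ref: int, n_het: int, n_alt: int) -> float:
    """1-df chi-square Hardy-Weinberg test from genotype class counts.

    Expected counts come from the sample allele frequency; monomorphic
    variants return p = 1 (no test possible).
    """
    n = n_ref + n_het + n_alt
    if n == 0:
        return 1.0
    q = (n_het + 2 * n_alt) / (2 * n)
    if q in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2])
    obs = np.array([n_ref, n_het, n_alt], dtype=float)
    stat = float(((obs - exp) ** 2 / exp).sum())
    return float(chi2.sf(stat, df=1))


def qc_variants(genotypes: pd.DataFrame, variant_ids: Optional[Iterable[str]] = None) -> List[QcReport]:
    """Missingness and Hardy-Weinberg QC for each dosage column.

    Dosages must be hard calls in {0, 1, 2} (NaN = missing); a variant
    passes when missingness <= 10% and the HWE chi-square p >= 1e-9.
    """
    if variant_ids is None:
        variant_ids = [c for c in genotypes.columns if c != "participant_id"]
    reports = []
    for vid in variant_ids:
        d = genotypes[vid].to_numpy(float)
        missing = np.isnan(d)
        observed = d[~missing]
        bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
        if bad.size:
            raise ValidationError(f"{vid}: dosages must be in {{0,1,2}} or missing, found {bad[0]!r}")
        counts = [int((observed == g).sum()) for g in (0.0, 1.0, 2.0)]
        monomorphic = sum(c > 0 for c in counts) <= 1
        reports.append(
            QcReport(
                variant_id=vid,
                missingness=float(missing.mean()) if d.size else 1.0,
                hwe_p=hwe_chi2_p(*counts),
                monomorphic=monomorphic,
            )
        )
    return reports
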