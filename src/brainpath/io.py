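"""Reading and writing the package's on-disk formats.

Cohorts travel as two TSV files plus a JSON sidecar: a genotype dosage
table (participant_id + one column per variant, missing as empty cell)
and a phenotype table (covariates, parental records or case status,
regional measures as ``region__type__L/R`` columns, ICV).  Genotypes can
alternatively be read from a VCF (diploid GT fields of biallelic records
only; requires cyvcf2).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthetic import Cohort, CohortConfig, OutcomeParams, VariantSpec

PathLike = Union[str, Path]


def write_table(frame: pd.DataFrame, path: PathLike) -> None:
    """Schema-stable TSV: fixed column order, empty cell for missing,
    round-trippable floats."""
    frame.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")


def read_genotypes(path: PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    if "participant_id" not in table.columns:
        raise ValidationError(f"{path}: genotype TSV must have a participant_id column")
    return table


def read_phenotypes(path: PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    if "participant_id" not in table.columns:
        raise ValidationError(f"{path}: phenotype TSV must have a participant_id column")
    return table


def _panel_to_json(panel) -> List[dict]:
    out = []
    for v in panel:
        d = dataclasses.asdict(v)
        d["mediator_effects"] = dict(v.mediator_effects)
        out.append(d)
    return out


def panel_from_json(items) -> List[VariantSpec]:
    return [VariantSpec(**item) for item in items]


def write_cohort(cohort: Cohort, outdir: PathLike) -> dict:
    """Write genotypes.tsv, phenotypes.tsv and a manifest.json recording the
    generating parameters and seed.  Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(cohort.genotypes, outdir / "genotypes.tsv")
    write_table(cohort.phenotypes, outdir / "phenotypes.tsv")
    cfg = dataclasses.asdict(cohort.config)
    cfg["outcome_params"]["mediator_coefficients"] = dict(
        cohort.config.outcome_params.mediator_coefficients
    )
    manifest = {
        "config": cfg,
        "panel": _panel_to_json(cohort.panel),
        "apoe_frequencies": dict(cohort.apoe_frequencies),
        "n_participants": cohort.n,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_cohort_tables(directory: PathLike):
    directory = Path(directory)
    genotypes = read_genotypes(directory / "genotypes.tsv")
    phenotypes = read_phenotypes(directory / "phenotypes.tsv")
    manifest = None
    manifest_path = directory / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    return genotypes, phenotypes, manifest


def config_from_manifest(manifest: dict) -> CohortConfig:
    cfg = dict(manifest["config"])
    cfg["outcome_params"] = OutcomeParams(**cfg["outcome_params"])
    return CohortConfig(**cfg)


def read_vcf_dosages(path: PathLike, variant_ids: Optional[List[str]] = None) -> pd.DataFrame:
    """Effect-allele (ALT) dosages from the GT fields of a VCF.

    Only diploid biallelic records are accepted; missing calls become NaN.
    Requires the optional cyvcf2 dependency.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("reading VCF genotypes requires the 'vcf' extra (cyvcf2)") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns = {}
    for record in vcf:
        vid = record.ID or f"{record.CHROM}:{record.POS}"
        if variant_ids is not None and vid not in variant_ids:
            continue
        if len(record.ALT) != 1:
            raise ValidationError(f"{vid}: only biallelic records are supported")
        gts = np.asarray(record.genotype.array(), dtype=float)[:, :2]
        dosage = np.where(np.any(gts < 0, axis=1), np.nan, gts.clip(min=0).sum(axis=1))
        columns[vid] = dosage
    frame = pd.DataFrame(columns)
    frame.insert(0, "participant_id", samples)
    return frame
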