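"""Config-driven orchestration of the full analysis.

Stage order: genotype QC -> phenotype derivation (APOE coding, proxy
score or case status, hemisphere combination, global measures,
z-scoring) -> mediation grid -> Li-Ji/FDR significance flags ->
bidirectional MR on the significant mediators.  Cross-cohort meta-analysis
pools two mediation result tables.  A run manifest records the
configuration, seed and per-stage row counts; rerunning the same
configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import measure_catalog, measure_name
from .errors import ValidationError
from .inference import ivw_meta, se_from_ci
from .io import (
    config_from_manifest,
    panel_from_json,
    read_genotypes,
    read_phenotypes,
    write_cohort,
    write_table,
)
from .mediation import results_table, run_grid
from .mr import run_bidirectional
from .phenotypes import (
    apoe4_dosage,
    combine_hemisphere_table,
    global_measures,
    proxy_scores,
    qc_variants,
    zscore,
)
from .synthetic import CohortConfig, OutcomeParams, default_outcome_params, default_panel, generate_cohort


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    Exactly one of ``genotypes_path`` or ``simulate`` must be set; the
    simulation block is a CohortConfig plus optional panel overrides.
    """

    out_dir: str = "brainpath_run"
    seed: int = 0
    genotypes_path: Optional[str] = None
    phenotypes_path: Optional[str] = None
    simulate: Optional[dict] = None
    cohort_style: str = "proxy"
    bootstrap_reps: int = 5000
    fdr_q: float = 0.05
    run_qc: bool = True
    run_mediation: bool = True
    run_mr: bool = True
    mr_measures: Optional[List[str]] = None  # explicit mediator list for MR
    wm_boot: int = 200

    def __post_init__(self):
        has_paths = self.genotypes_path is not None
        has_sim = self.simulate is not None
        if has_paths == has_sim:
            raise ValidationError("exactly one of genotypes_path or simulate must be given")
        if has_paths and self.phenotypes_path is None:
            raise ValidationError("phenotypes_path is required with genotypes_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_analysis_table(
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    cohort_style: str,
    variant_ids: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, List[str], List[str]]:
    """Merge genotypes and derived phenotypes into one analysis frame.

    Returns (table, variant columns, measure columns).  Measures are
    combined across hemispheres and z-scored within the cohort; the global
    covariates (total surface area, global mean thickness, ICV) are
    z-scored the same way.  The outcome column is ``proxy_score`` or
    ``status`` according to the cohort style.
    """
    table = genotypes.merge(phenotypes, on="participant_id", how="inner")
    if variant_ids is None:
        variant_ids = [c for c in genotypes.columns if c != "participant_id"]
    variant_ids = list(variant_ids)

    # APOE e4 dosage from raw site genotypes when not already present
    if "APOE4" not in table.columns and {"rs429358", "rs7412"} <= set(table.columns):
        table["APOE4"] = apoe4_dosage(table)
        variant_ids.append("APOE4")

    hemi_cols = [c for c in table.columns if c.endswith("__L") or c.endswith("__R")]
    combined = combine_hemisphere_table(table[hemi_cols])
    if "icv" in table.columns:
        combined["icv"] = table["icv"]
    globals_ = global_measures(combined)

    measure_cols = [measure_name(r, t) for r, t in measure_catalog() if measure_name(r, t) in combined.columns]
    columns = {c: table[c] for c in ("participant_id", "age", "sex", "site") if c in table.columns}
    columns.update({vid: table[vid] for vid in variant_ids})
    columns.update({mcol: zscore(combined[mcol]) for mcol in measure_cols})
    columns.update(
        {g: zscore(globals_[g]) for g in ("total_surface_area", "global_mean_thickness", "icv") if g in globals_.columns}
    )
    if cohort_style == "proxy":
        columns["proxy_score"] = proxy_scores(table)
        outcome = "proxy_score"
    else:
        if "status" not in table.columns:
            raise ValidationError("case_control cohorts need a 'status' column")
        columns["status"] = table["status"]
        outcome = "status"
    out = pd.DataFrame(columns, index=table.index)
    out.attrs["outcome"] = outcome
    return out, variant_ids, measure_cols


def run_pipeline(config: RunConfig) -> Dict:
    """Execute all enabled stages; returns the run manifest."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        sim = dict(config.simulate)
        panel = panel_from_json(sim.pop("panel")) if "panel" in sim else default_panel()
        outcome_params = (
            OutcomeParams(**sim.pop("outcome_params"))
            if "outcome_params" in sim
            else default_outcome_params(sim.get("cohort_style", config.cohort_style))
        )
        sim.setdefault("seed", config.seed)
        sim.setdefault("cohort_style", config.cohort_style)
        cohort_config = CohortConfig(outcome_params=outcome_params, **sim)
        cohort = generate_cohort(cohort_config, panel=panel)
        write_cohort(cohort, outdir / "cohort")
        genotypes, phenotypes = cohort.genotypes, cohort.phenotypes
        cohort_style = cohort_config.cohort_style
    else:
        genotypes = read_genotypes(config.genotypes_path)
        phenotypes = read_phenotypes(config.phenotypes_path)
        cohort_style = config.cohort_style
    manifest["stages"]["input"] = {"n_participants": len(genotypes)}

    # --- QC ---------------------------------------------------------------
    variant_ids = [c for c in genotypes.columns if c != "participant_id"]
    if config.run_qc:
        reports = qc_variants(genotypes, variant_ids)
        qc_table = pd.DataFrame(
            [
                {
                    "variant_id": r.variant_id,
                    "missingness": r.missingness,
                    "hwe_p": r.hwe_p,
                    "monomorphic": r.monomorphic,
                    "passed": r.passed,
                }
                for r in reports
            ]
        )
        write_table(qc_table, outdir / "qc.tsv")
        variant_ids = [r.variant_id for r in reports if r.passed]
        manifest["stages"]["qc"] = {
            "n_variants_tested": len(reports),
            "n_variants_passed": len(variant_ids),
        }

    # --- phenotype derivation --------------------------------------------
    table, variant_ids, measure_cols = build_analysis_table(
        genotypes, phenotypes, cohort_style, variant_ids
    )
    outcome = table.attrs["outcome"]
    site_column = "site" if "site" in table.columns and cohort_style == "proxy" else None
    manifest["stages"]["phenotypes"] = {
        "n_measures": len(measure_cols),
        "n_variants": len(variant_ids),
        "outcome": outcome,
    }

    significant_measures: List[str] = []
    if config.run_mediation:
        results = run_grid(
            table,
            variant_ids,
            measure_cols,
            outcome=outcome,
            outcome_family="logistic" if cohort_style == "case_control" else "linear",
            site_column=site_column,
            bootstrap_reps=config.bootstrap_reps,
            seed=config.seed,
            q=config.fdr_q,
        )
        grid_table = results_table(results)
        write_table(grid_table, outdir / "mediation.tsv")
        significant_measures = sorted(
            grid_table.loc[grid_table["significant"].fillna(False).astype(bool), "measure"].unique()
        )
        manifest["stages"]["mediation"] = {
            "n_models": len(results),
            "n_significant": int(grid_table["significant"].fillna(False).astype(bool).sum()),
        }

    if config.run_mr:
        if config.mr_measures is not None:
            mr_measures = list(config.mr_measures)
        elif config.run_mediation:
            mr_measures = significant_measures
        else:
            raise ValidationError(
                "MR without the mediation stage requires an explicit mr_measures list"
            )
        if mr_measures:
            mr_table = run_bidirectional(
                table,
                mr_measures,
                variant_ids,
                outcome=outcome,
                outcome_family="logistic" if cohort_style == "case_control" else "linear",
                site_column=site_column,
                q=config.fdr_q,
                wm_boot=config.wm_boot,
                seed=config.seed,
            )
            write_table(mr_table.drop(columns=[], errors="ignore"), outdir / "mr.tsv")
            loo = {
                f"{measure}|{direction}": [
                    {"dropped": vid, "theta": est.theta, "se": est.se, "p": est.p}
                    for vid, est in entries
                ]
                for (measure, direction), entries in mr_table.attrs.get("leave_one_out", {}).items()
            }
            with open(outdir / "mr_leave_one_out.json", "w") as fh:
                json.dump(loo, fh, indent=2, sort_keys=True)
            manifest["stages"]["mr"] = {"n_measures": len(mr_measures), "n_rows": len(mr_table)}
        else:
            manifest["stages"]["mr"] = {"n_measures": 0, "n_rows": 0}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def meta_analyze_mediation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    level: float = 0.95,
) -> pd.DataFrame:
    """Fixed-effect IVW pooling of two cohorts' mediation effects.

    Each cohort's standard error is recovered from the width of its
    bootstrap confidence interval; models are matched on variant and
    measure.
    """
    merged = table_a.merge(table_b, on=["variant", "measure"], suffixes=("_a", "_b"))
    rows = []
    for row in merged.itertuples(index=False):
        try:
            se_a = se_from_ci(row.ci_low_a, row.ci_high_a, level)
            se_b = se_from_ci(row.ci_low_b, row.ci_high_b, level)
            if se_a == 0 or se_b == 0 or not np.isfinite(se_a * se_b):
                raise ValidationError("degenerate bootstrap interval")
            pooled = ivw_meta([row.acme_a, row.acme_b], [se_a, se_b])
            rows.append(
                {
                    "variant": row.variant,
                    "measure": row.measure,
                    "estimate_a": row.acme_a,
                    "estimate_b": row.acme_b,
                    "se_a": se_a,
                    "se_b": se_b,
                    "pooled": pooled.estimate,
                    "pooled_se": pooled.se,
                    "pooled_p": pooled.p,
                    "error": None,
                }
            )
        except (ValidationError, ValueError) as exc:
            rows.append(
                {
                    "variant": row.variant,
                    "measure": row.measure,
                    "estimate_a": row.acme_a,
                    "estimate_b": row.acme_b,
                    "se_a": np.nan,
                    "se_b": np.nan,
                    "pooled": np.nan,
                    "pooled_se": np.nan,
                    "pooled_p": np.nan,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)
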