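"""Causal mediation analysis: variant -> brain measure -> disease outcome.

For each variant x measure pair the engine fits

* path a   - mediator model: standardized measure ~ dosage + covariates
* path b   - outcome model coefficient of the measure given the dosage
* path c   - total effect: outcome ~ dosage + covariates
* path c'  - direct effect: dosage coefficient in the outcome model

and estimates the indirect (mediation) effect with a nonparametric
bootstrap over participants.  For a linear outcome the indirect effect is
the product of coefficients a*b; for a logistic outcome it is the average
causal mediation effect on the risk-difference scale computed by
g-computation over the empirical covariate distribution.

Covariates follow the mediation design throughout: age and sex always, a
site fixed effect when available, and a global brain measure matched to
the mediator's type (total surface area for areas, global mean thickness
for thicknesses, intracranial volume for volumes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy import stats

from .catalog import GLOBAL_COVARIATE, parse_measure_name
from .errors import ValidationError
from .regress import (
    FitResult,
    design_matrix,
    logistic,
    logistic_coefs_only,
    ols,
    ols_coefs_only,
)

MIN_EXTRA_OBSERVATIONS = 10  # fits need >= params + 10 complete rows


@dataclass(frozen=True)
class MediationSpec:
    """One mediation model of the analysis grid."""

    variant: str
    measure: str
    outcome: str
    outcome_family: str = "linear"  # "linear" (proxy score) or "logistic" (case/control)
    covariates: Tuple[str, ...] = ("age", "sex")
    site_column: Optional[str] = None
    global_covariate: Optional[str] = None  # inferred from measure type when None
    bootstrap_reps: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.outcome_family not in ("linear", "logistic"):
            raise ValidationError(f"outcome_family must be linear or logistic, got {self.outcome_family!r}")

    def resolved_global(self) -> Optional[str]:
        if self.global_covariate is not None:
            return self.global_covariate
        try:
            _, mtype = parse_measure_name(self.measure)
        except ValueError:
            return None
        return GLOBAL_COVARIATE[mtype]

    def adjustment_columns(self) -> List[str]:
        cols = list(self.covariates)
        g = self.resolved_global()
        if g is not None and g not in cols:
            cols.append(g)
        return cols


@dataclass(frozen=True)
class PathEstimates:
    a: float
    se_a: float
    p_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    p_c: float
    c_prime: float
    se_c_prime: float


@dataclass
class MediationResult:
    spec: MediationSpec
    paths: Optional[PathEstimates]
    acme: float
    ci_low: float
    ci_high: float
    p_boot: float
    n_used: int
    significant: Optional[bool] = None
    threshold: Optional[float] = None
    error: Optional[str] = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def _complete_cases(data: pd.DataFrame, spec: MediationSpec) -> pd.DataFrame:
    cols = [spec.variant, spec.measure, spec.outcome] + spec.adjustment_columns()
    if spec.site_column:
        cols.append(spec.site_column)
    cols = list(dict.fromkeys(cols))
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"missing columns in data: {missing}")
    return data[cols].dropna()


def _require_size(frame: pd.DataFrame, n_params: int) -> None:
    if len(frame) < n_params + MIN_EXTRA_OBSERVATIONS:
        raise ValidationError(
            f"too few complete observations ({len(frame)}) for {n_params} parameters"
        )


def fit_path_a(data: pd.DataFrame, spec: MediationSpec) -> FitResult:
    """Mediator model: standardized measure ~ dosage + covariates."""
    frame = _complete_cases(data, spec)
    X, names = design_matrix(frame, [spec.variant] + spec.adjustment_columns(), spec.site_column)
    _require_size(frame, X.shape[1])
    return ols(X, frame[spec.measure].to_numpy(float), names)


def fit_outcome(data: pd.DataFrame, spec: MediationSpec) -> FitResult:
    """Outcome model: outcome ~ dosage + measure + covariates.

    The measure coefficient is path b; the dosage coefficient is the
    direct effect c'.  Logistic non-convergence or separation yields a
    flagged FitResult, not an exception.
    """
    frame = _complete_cases(data, spec)
    X, names = design_matrix(
        frame, [spec.variant, spec.measure] + spec.adjustment_columns(), spec.site_column
    )
    _require_size(frame, X.shape[1])
    y = frame[spec.outcome].to_numpy(float)
    if spec.outcome_family == "logistic":
        return logistic(X, y, names)
    return ols(X, y, names)


def fit_total(data: pd.DataFrame, spec: MediationSpec) -> FitResult:
    """Total-effect model: outcome ~ dosage + covariates (no mediator)."""
    frame = _complete_cases(data, spec)
    X, names = design_matrix(frame, [spec.variant] + spec.adjustment_columns(), spec.site_column)
    _require_size(frame, X.shape[1])
    y = frame[spec.outcome].to_numpy(float)
    if spec.outcome_family == "logistic":
        return logistic(X, y, names)
    return ols(X, y, names)


def _gcomp_acme(
    spec: MediationSpec,
    med_X: np.ndarray,
    med_names: Sequence[str],
    med_coef: np.ndarray,
    out_X: np.ndarray,
    out_names: Sequence[str],
    out_coef: np.ndarray,
) -> float:
    """Average causal mediation effect on the risk-difference scale.

    For each participant (observed dosage d, covariates held fixed) the
    mediator's model-predicted mean is shifted from its value at d to its
    value at d + 1 while the direct path stays at d; the ACME is the mean
    change in the predicted outcome probability.
    """
    d_idx = med_names.index(spec.variant)
    m_hat_d = med_X @ med_coef
    m_hat_d1 = m_hat_d + med_coef[d_idx]  # dosage enters linearly
    out_m_idx = out_names.index(spec.measure)
    eta_base = out_X @ out_coef
    m_obs = out_X[:, out_m_idx]
    eta_d = eta_base + out_coef[out_m_idx] * (m_hat_d - m_obs)
    eta_d1 = eta_base + out_coef[out_m_idx] * (m_hat_d1 - m_obs)
    return float(np.mean(expit(eta_d1) - expit(eta_d)))


def bootstrap_acme(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Point estimates for all paths plus a bootstrap test of the ACME.

    Nonparametric bootstrap over participants: each resample refits the
    mediator and outcome models and records the indirect effect.  The CI is
    the 95% percentile interval and the two-sided bootstrap p-value is
    ``2 * min(P(draws <= 0), P(draws >= 0))``.  With ``bootstrap_reps=0``
    the result is analytic only (Sobel-type p, no CI) - used for fast grid
    screening.
    """
    if spec.bootstrap_reps != 0 and spec.bootstrap_reps < 200:
        raise ValidationError("bootstrap_reps must be 0 (analytic) or >= 200")
    frame = _complete_cases(data, spec)
    med_cols = [spec.variant] + spec.adjustment_columns()
    out_cols = [spec.variant, spec.measure] + spec.adjustment_columns()
    med_X, med_names = design_matrix(frame, med_cols, spec.site_column)
    out_X, out_names = design_matrix(frame, out_cols, spec.site_column)
    _require_size(frame, out_X.shape[1])

    m = frame[spec.measure].to_numpy(float)
    y = frame[spec.outcome].to_numpy(float)
    n = len(frame)

    a_fit = ols(med_X, m, med_names)
    if spec.outcome_family == "logistic":
        out_fit = logistic(out_X, y, out_names)
        tot_fit = logistic(med_X, y, med_names)
    else:
        out_fit = ols(out_X, y, out_names)
        tot_fit = ols(med_X, y, med_names)

    a, se_a, p_a = a_fit[spec.variant]
    if out_fit.error is not None:
        return MediationResult(
            spec=spec, paths=None, acme=math.nan, ci_low=math.nan, ci_high=math.nan,
            p_boot=math.nan, n_used=n, error=out_fit.error,
        )
    b, se_b, _ = out_fit[spec.measure]
    c_prime, se_cp, _ = out_fit[spec.variant]
    c, se_c, p_c = tot_fit[spec.variant]
    paths = PathEstimates(a, se_a, p_a, b, se_b, c, se_c, p_c, c_prime, se_cp)

    if spec.outcome_family == "logistic":
        acme = _gcomp_acme(spec, med_X, med_names, a_fit.coef, out_X, out_names, out_fit.coef)
    else:
        acme = a * b

    if spec.bootstrap_reps == 0:
        # Sobel normal-approximation p on the product of coefficients
        var = b**2 * se_a**2 + a**2 * se_b**2
        p = 2 * stats.norm.sf(abs(a * b) / math.sqrt(var)) if var > 0 else math.nan
        return MediationResult(
            spec=spec, paths=paths, acme=acme, ci_low=math.nan, ci_high=math.nan,
            p_boot=float(p), n_used=n,
        )

    rng = np.random.default_rng(spec.seed)
    draws = np.empty(spec.bootstrap_reps)
    failures = 0
    a_idx = med_names.index(spec.variant)
    b_idx = out_names.index(spec.measure)
    for r in range(spec.bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        mX, oX = med_X[idx], out_X[idx]
        mr, yr = m[idx], y[idx]
        try:
            med_coef = ols_coefs_only(mX, mr)
        except np.linalg.LinAlgError:
            failures += 1
            draws[r] = np.nan
            continue
        if spec.outcome_family == "logistic":
            out_coef = logistic_coefs_only(oX, yr)
            if out_coef is None:
                failures += 1
                draws[r] = np.nan
                continue
            draws[r] = _gcomp_acme(spec, mX, med_names, med_coef, oX, out_names, out_coef)
        else:
            try:
                out_coef = ols_coefs_only(oX, yr)
            except np.linalg.LinAlgError:
                failures += 1
                draws[r] = np.nan
                continue
            draws[r] = med_coef[a_idx] * out_coef[b_idx]

    if failures > 0.2 * spec.bootstrap_reps:
        return MediationResult(
            spec=spec, paths=paths, acme=acme, ci_low=math.nan, ci_high=math.nan,
            p_boot=math.nan, n_used=n,
            error=f"{failures}/{spec.bootstrap_reps} bootstrap resamples failed",
        )
    good = draws[np.isfinite(draws)]
    ci_low, ci_high = np.percentile(good, [2.5, 97.5])
    frac_le = float(np.mean(good <= 0))
    frac_ge = float(np.mean(good >= 0))
    p_boot = min(1.0, 2.0 * min(frac_le, frac_ge))
    return MediationResult(
        spec=spec, paths=paths, acme=float(acme),
        ci_low=float(ci_low), ci_high=float(ci_high),
        p_boot=p_boot, n_used=n,
    )


# ---------------------------------------------------------------------------
# grid


def run_grid(
    data: pd.DataFrame,
    variants: Sequence[str],
    measures: Sequence[str],
    outcome: str,
    outcome_family: str = "linear",
    covariates: Sequence[str] = ("age", "sex"),
    site_column: Optional[str] = None,
    bootstrap_reps: int = 5000,
    seed: int = 0,
    q: float = 0.05,
    flag: bool = True,
) -> List[MediationResult]:
    """One mediation model per variant x measure, in deterministic order.

    Listwise deletion is model-specific: a participant missing one
    variant's dosage is dropped only from that variant's models.  After the
    grid is fitted, significance flags come from Benjamini-Hochberg step-up
    with the Li-Ji effective number of tests (see
    :func:`flag_significance`).
    """
    results: List[MediationResult] = []
    for i, variant in enumerate(variants):
        for j, measure in enumerate(measures):
            spec = MediationSpec(
                variant=variant,
                measure=measure,
                outcome=outcome,
                outcome_family=outcome_family,
                covariates=tuple(covariates),
                site_column=site_column,
                bootstrap_reps=bootstrap_reps,
                # one deterministic substream per grid cell
                seed=(seed * 1_000_003 + i * 1009 + j) % (2**31),
            )
            try:
                res = bootstrap_acme(data, spec)
            except ValidationError as exc:
                res = MediationResult(
                    spec=spec, paths=None, acme=math.nan, ci_low=math.nan,
                    ci_high=math.nan, p_boot=math.nan, n_used=0, error=str(exc),
                )
            results.append(res)
    if flag:
        flag_significance(results, data, variants, measures, q=q)
    return results


def grid_meff(data: pd.DataFrame, variants: Sequence[str], measures: Sequence[str]) -> float:
    """Effective number of tests for the grid: the Li-Ji rule applied to the
    Kronecker product of the measure and dosage correlation matrices (its
    eigenvalues are the pairwise products)."""
    def corr_of(cols):
        sub = data[list(cols)].dropna()
        if len(cols) == 1 or len(sub) < 3:
            return np.eye(len(cols))
        c = np.corrcoef(sub.to_numpy(float), rowvar=False)
        return np.nan_to_num(c, nan=0.0) + np.diag(1.0 - np.diag(np.nan_to_num(c, nan=0.0)))

    lam_m = np.abs(np.linalg.eigvalsh(corr_of(measures)))
    lam_v = np.abs(np.linalg.eigvalsh(corr_of(variants)))
    lam = np.outer(lam_m, lam_v).ravel()
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def flag_significance(
    results: List[MediationResult],
    data: pd.DataFrame,
    variants: Sequence[str],
    measures: Sequence[str],
    q: float = 0.05,
    m_eff: Optional[float] = None,
) -> float:
    """Assign per-test thresholds and significance flags in place.

    Uses Benjamini-Hochberg step-up over the bootstrap p-values with the
    Li-Ji effective number of tests in place of the raw grid size.  Models
    in an error state keep ``significant=None``.  Returns the m_eff used.
    """
    from .inference import adjusted_thresholds

    if m_eff is None:
        m_eff = grid_meff(data, variants, measures)
    ok = [r for r in results if r.error is None and math.isfinite(r.p_boot)]
    if ok:
        table = adjusted_thresholds([r.p_boot for r in ok], m_eff=m_eff, q=q)
        for r, thr, sig in zip(ok, table["threshold"], table["significant"]):
            r.threshold = float(thr)
            r.significant = bool(sig)
    return m_eff


def results_table(results: Sequence[MediationResult]) -> pd.DataFrame:
    """Flat one-row-per-model table of a mediation grid."""
    rows = []
    for r in results:
        p = r.paths
        rows.append(
            {
                "variant": r.spec.variant,
                "measure": r.spec.measure,
                "outcome_family": r.spec.outcome_family,
                "n_used": r.n_used,
                "a": p.a if p else math.nan,
                "se_a": p.se_a if p else math.nan,
                "p_a": p.p_a if p else math.nan,
                "b": p.b if p else math.nan,
                "c": p.c if p else math.nan,
                "c_prime": p.c_prime if p else math.nan,
                "acme": r.acme,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_boot": r.p_boot,
                "threshold": r.threshold,
                "significant": r.significant,
                "error": r.error,
            }
        )
    return pd.DataFrame(rows)
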