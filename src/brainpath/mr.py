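"""One-sample bidirectional Mendelian randomization.

Per-variant exposure and outcome associations are estimated in the same
participants with the mediation covariates, then combined with the
classic summary-data estimators: inverse-variance weighted (IVW),
weighted median, and MR-Egger with its pleiotropy-testing intercept.
Diagnostics cover Cochran's Q heterogeneity, the I2_GX instrument-strength
statistic for MR-Egger, and leave-one-out re-estimation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .regress import design_matrix, logistic, ols

__all__ = [
    "InstrumentSet",
    "MREstimate",
    "MRDiagnostics",
    "assoc_scan",
    "ivw",
    "weighted_median",
    "mr_egger",
    "cochran_q",
    "i2_gx",
    "leave_one_out",
    "run_bidirectional",
]

I2_FLAG_THRESHOLD = 0.80


@dataclass(frozen=True)
class InstrumentSet:
    """Per-variant summary associations feeding the MR estimators."""

    variant_ids: Tuple[str, ...]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray

    def __post_init__(self):
        k = len(self.variant_ids)
        arrays = {
            "beta_exposure": self.beta_exposure,
            "se_exposure": self.se_exposure,
            "beta_outcome": self.beta_outcome,
            "se_outcome": self.se_outcome,
        }
        for name, arr in arrays.items():
            object.__setattr__(self, name, np.asarray(arr, dtype=float))
        if k < 1:
            raise ValidationError("an InstrumentSet needs at least one variant")
        for name in arrays:
            arr = getattr(self, name)
            if arr.shape != (k,):
                raise ValidationError(f"{name} must have shape ({k},), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValidationError("standard errors must be positive")

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    def oriented(self) -> "InstrumentSet":
        """Flip (beta_exposure, beta_outcome) jointly so every beta_exposure
        is non-negative (the MR-Egger orientation convention)."""
        sign = np.where(self.beta_exposure < 0, -1.0, 1.0)
        return InstrumentSet(
            self.variant_ids,
            self.beta_exposure * sign,
            self.se_exposure,
            self.beta_outcome * sign,
            self.se_outcome,
        )

    def drop(self, variant_id: str) -> "InstrumentSet":
        keep = [i for i, v in enumerate(self.variant_ids) if v != variant_id]
        if len(keep) == self.k:
            raise ValidationError(f"{variant_id!r} not in instrument set")
        return InstrumentSet(
            tuple(self.variant_ids[i] for i in keep),
            self.beta_exposure[keep],
            self.se_exposure[keep],
            self.beta_outcome[keep],
            self.se_outcome[keep],
        )


@dataclass(frozen=True)
class MREstimate:
    method: str
    theta: float
    se: float
    p: float
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None

    @property
    def ci(self) -> Tuple[float, float]:
        z = stats.norm.ppf(0.975)
        return self.theta - z * self.se, self.theta + z * self.se


@dataclass(frozen=True)
class MRDiagnostics:
    cochran_q: float
    q_df: int
    q_p: float
    i2_gx: float
    leave_one_out: Tuple[Tuple[str, MREstimate], ...]
    instrument_strength_flag: bool  # True when I2_GX < 0.80 (Egger unreliable)


def _ivw_weights(instruments: InstrumentSet) -> np.ndarray:
    return instruments.beta_exposure**2 / instruments.se_outcome**2


def ivw(instruments: InstrumentSet) -> MREstimate:
    """Inverse-variance-weighted estimate: weighted regression of the
    variant-outcome on the variant-exposure associations through the
    origin, fixed-effect standard error."""
    bx, by = instruments.beta_exposure, instruments.beta_outcome
    w = 1.0 / instruments.se_outcome**2
    denom = float((bx**2 * w).sum())
    if denom == 0:
        raise ValidationError("all exposure associations are zero; IVW undefined")
    theta = float((bx * by * w).sum() / denom)
    se = math.sqrt(1.0 / denom)
    z = theta / se
    return MREstimate("IVW", theta, se, float(2 * stats.norm.sf(abs(z))))


def weighted_median(instruments: InstrumentSet, n_boot: int = 200, seed: int = 0) -> MREstimate:
    """Weighted median of the variant-specific Wald ratios.

    Ratios are sorted and the estimate interpolates where the cumulative
    standardized weight ``s_j = sum_{i<=j} w_i - w_j / 2`` (normalized
    weights ``w_j = beta_exposure_j^2 / se_outcome_j^2``) crosses one half.
    Consistent when at least half the weight comes from valid instruments.
    The SE comes from a parametric bootstrap of the per-variant summary
    statistics.
    """
    if instruments.k < 3:
        raise ValidationError("weighted median needs at least 3 instruments")
    theta = _weighted_median_point(
        instruments.beta_exposure, instruments.beta_outcome, _ivw_weights(instruments)
    )
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for r in range(n_boot):
        bx = rng.normal(instruments.beta_exposure, instruments.se_exposure)
        by = rng.normal(instruments.beta_outcome, instruments.se_outcome)
        w = bx**2 / instruments.se_outcome**2
        boots[r] = _weighted_median_point(bx, by, w)
    se = float(np.std(boots, ddof=1))
    z = theta / se if se > 0 else math.inf
    return MREstimate("weighted_median", float(theta), se, float(2 * stats.norm.sf(abs(z))))


def _weighted_median_point(bx: np.ndarray, by: np.ndarray, weights: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = by / bx
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(s, 0.5))
    # linear interpolation between the bracketing standardized weights
    return float(r[j - 1] + (r[j] - r[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1]))


def mr_egger(instruments: InstrumentSet) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure associations
    with a free intercept (weights 1/se_outcome^2, exposure orientation
    normalized).  The slope is the causal estimate; a nonzero intercept
    indicates directional horizontal pleiotropy."""
    if instruments.k < 3:
        raise ValidationError("MR-Egger needs at least 3 instruments")
    inst = instruments.oriented()
    bx, by = inst.beta_exposure, inst.beta_outcome
    if np.allclose(bx, bx[0]):
        raise ValidationError("all exposure associations equal; Egger slope unidentifiable")
    w = 1.0 / inst.se_outcome**2
    sw = np.sqrt(w)
    X = np.column_stack([sw, sw * bx])
    yw = sw * by
    beta, _, _, _ = np.linalg.lstsq(X, yw, rcond=None)
    resid = yw - X @ beta
    dof = inst.k - 2
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    # summary-data Egger convention: variance floor at 1 (no deflation
    # below the fixed-effect model when the fit is better than expected)
    sigma2 = max(sigma2, 1.0)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t_slope = beta[1] / se[1]
    t_int = beta[0] / se[0]
    p_slope = float(2 * stats.t.sf(abs(t_slope), dof))
    p_int = float(2 * stats.t.sf(abs(t_int), dof))
    return MREstimate(
        "MR_Egger",
        float(beta[1]),
        float(se[1]),
        p_slope,
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        intercept_p=p_int,
    )


def egger_through_origin(instruments: InstrumentSet) -> float:
    """Egger regression with the intercept constrained to zero; algebraically
    identical to IVW (used as a cross-check)."""
    inst = instruments.oriented()
    w = 1.0 / inst.se_outcome**2
    return float((inst.beta_exposure * inst.beta_outcome * w).sum() / (inst.beta_exposure**2 * w).sum())


def cochran_q(instruments: InstrumentSet) -> Tuple[float, int, float]:
    """Heterogeneity of the variant-specific Wald ratios around the IVW
    estimate; chi-square with k - 1 df under homogeneity."""
    if instruments.k < 2:
        raise ValidationError("Cochran's Q needs at least 2 instruments")
    theta = ivw(instruments).theta
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = instruments.beta_outcome / instruments.beta_exposure
    w = _ivw_weights(instruments)
    q = float((w * (ratios - theta) ** 2).sum())
    df = instruments.k - 1
    return q, df, float(stats.chi2.sf(q, df))


def i2_gx(instruments: InstrumentSet) -> float:
    """Instrument-strength I2 for MR-Egger from the heterogeneity of the
    exposure associations: ``max(0, (Q_GX - (k-1)) / Q_GX)`` with Q_GX the
    inverse-variance-weighted dispersion of beta_exposure.  Values below
    0.80 indicate meaningful regression-dilution bias."""
    if instruments.k < 2:
        raise ValidationError("I2_GX needs at least 2 instruments")
    inst = instruments.oriented()
    w = 1.0 / inst.se_exposure**2
    mean_w = float((w * inst.beta_exposure).sum() / w.sum())
    q_gx = float((w * (inst.beta_exposure - mean_w) ** 2).sum())
    if q_gx == 0:
        return 0.0
    return max(0.0, (q_gx - (inst.k - 1)) / q_gx)


def leave_one_out(instruments: InstrumentSet) -> List[Tuple[str, MREstimate]]:
    """IVW re-estimates dropping one variant at a time (k entries)."""
    if instruments.k < 2:
        raise ValidationError("leave-one-out needs at least 2 instruments")
    out = []
    for vid in instruments.variant_ids:
        out.append((vid, ivw(instruments.drop(vid))))
    return out


def diagnostics(instruments: InstrumentSet) -> MRDiagnostics:
    q, df, q_p = cochran_q(instruments)
    i2 = i2_gx(instruments)
    return MRDiagnostics(
        cochran_q=q,
        q_df=df,
        q_p=q_p,
        i2_gx=i2,
        leave_one_out=tuple(leave_one_out(instruments)),
        instrument_strength_flag=i2 < I2_FLAG_THRESHOLD,
    )


# ---------------------------------------------------------------------------
# one-sample association scan and orchestration


def assoc_scan(
    data: pd.DataFrame,
    target: str,
    variants: Sequence[str],
    covariates: Sequence[str] = ("age", "sex"),
    site_column: Optional[str] = None,
    family: str = "linear",
) -> pd.DataFrame:
    """Per-variant association with the target, adjusted for covariates.

    One single-variant regression per panel member (least squares for a
    continuous target, logistic for binary), with model-specific listwise
    deletion.  Variants whose fit fails or that are monomorphic in the
    analysis sample are dropped with a warning.
    """
    if target not in data.columns:
        raise ValidationError(f"target column {target!r} not in data")
    rows = []
    for vid in variants:
        cols = [vid, target, *covariates] + ([site_column] if site_column else [])
        frame = data[cols].dropna()
        if frame[vid].nunique() < 2:
            warnings.warn(f"{vid}: monomorphic in analysis sample; dropped", stacklevel=2)
            continue
        X, names = design_matrix(frame, [vid, *covariates], site_column)
        y = frame[target].to_numpy(float)
        fit = logistic(X, y, names) if family == "logistic" else ols(X, y, names)
        if fit.error is not None or not np.isfinite(fit[vid][1]):
            warnings.warn(f"{vid}: association fit failed ({fit.error}); dropped", stacklevel=2)
            continue
        beta, se, p = fit[vid]
        rows.append({"variant": vid, "beta": beta, "se": se, "p": p, "n": fit.nobs})
    return pd.DataFrame(rows)


def instruments_from_scans(exposure_scan: pd.DataFrame, outcome_scan: pd.DataFrame) -> InstrumentSet:
    merged = exposure_scan.merge(outcome_scan, on="variant", suffixes=("_x", "_y"))
    if merged.empty:
        raise ValidationError("no overlapping variants between exposure and outcome scans")
    return InstrumentSet(
        tuple(merged["variant"]),
        merged["beta_x"].to_numpy(),
        merged["se_x"].to_numpy(),
        merged["beta_y"].to_numpy(),
        merged["se_y"].to_numpy(),
    )


def run_bidirectional(
    data: pd.DataFrame,
    measures: Sequence[str],
    variants: Sequence[str],
    outcome: str,
    outcome_family: str = "linear",
    covariates: Sequence[str] = ("age", "sex"),
    site_column: Optional[str] = None,
    q: float = 0.05,
    wm_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Bidirectional MR for each measure against the disease outcome.

    Forward: exposure = brain measure, outcome = disease.  Reverse:
    exposure = disease (log-odds scale when binary), outcome = measure.
    All three estimators run per direction, with diagnostics, and p-values
    are Benjamini-Hochberg adjusted across measures within each
    direction x method stratum.
    """
    from .inference import bh_fdr

    records: List[Dict] = []
    loo_store: Dict[Tuple[str, str], Tuple[Tuple[str, MREstimate], ...]] = {}
    outcome_scan = assoc_scan(data, outcome, variants, covariates, site_column, family=outcome_family)
    for mi, measure in enumerate(measures):
        measure_scan = assoc_scan(data, measure, variants, covariates, site_column, family="linear")
        for direction, exp_scan, out_scan in (
            ("forward", measure_scan, outcome_scan),
            ("reverse", outcome_scan, measure_scan),
        ):
            try:
                inst = instruments_from_scans(exp_scan, out_scan)
                diag = diagnostics(inst) if inst.k >= 2 else None
                estimates = [ivw(inst)]
                if inst.k >= 3:
                    estimates.append(weighted_median(inst, n_boot=wm_boot, seed=(seed * 97 + mi) % (2**31)))
                    estimates.append(mr_egger(inst))
            except ValidationError as exc:
                records.append(
                    {"measure": measure, "direction": direction, "method": "IVW",
                     "theta": math.nan, "se": math.nan, "p": math.nan, "error": str(exc)}
                )
                continue
            if diag is not None:
                loo_store[(measure, direction)] = diag.leave_one_out
            for est in estimates:
                records.append(
                    {
                        "measure": measure,
                        "direction": direction,
                        "method": est.method,
                        "theta": est.theta,
                        "se": est.se,
                        "p": est.p,
                        "egger_intercept": est.intercept,
                        "egger_intercept_p": est.intercept_p,
                        "q": diag.cochran_q if diag else math.nan,
                        "q_p": diag.q_p if diag else math.nan,
                        "i2_gx": diag.i2_gx if diag else math.nan,
                        "weak_instrument_flag": diag.instrument_strength_flag if diag else None,
                        "k": inst.k,
                        "error": None,
                    }
                )
    table = pd.DataFrame(records)
    if table.empty:
        return table
    table["p_fdr"] = np.nan
    table["significant"] = pd.array([None] * len(table), dtype="boolean")
    for (_, _), idx in table.groupby(["direction", "method"]).groups.items():
        sub = table.loc[idx]
        ok = sub["p"].notna()
        if ok.any():
            adj = bh_fdr(sub.loc[ok, "p"].to_numpy(), q=q)
            table.loc[sub.index[ok], "p_fdr"] = adj["p_adjusted"].to_numpy()
            table.loc[sub.index[ok], "significant"] = adj["significant"].to_numpy()
    table.attrs["leave_one_out"] = loo_store
    table.attrs["reverse_exposure_scale"] = "log-odds" if outcome_family == "logistic" else "identity"
    return table
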