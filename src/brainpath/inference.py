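"""Multiple-testing control, meta-analysis and calibration utilities.

Implements the Li-Ji effective number of independent tests, the
Benjamini-Hochberg step-up procedure (optionally with the effective test
count in place of the raw count), standard-error recovery from bootstrap
confidence intervals, fixed-effect inverse-variance meta-analysis, and a
type-I-error simulation harness for non-normal outcomes such as the
family-history proxy score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .regress import ols

__all__ = [
    "MeffResult",
    "MetaResult",
    "li_ji_meff",
    "adjusted_thresholds",
    "bh_fdr",
    "se_from_ci",
    "ivw_meta",
    "type1_sim",
]


@dataclass(frozen=True)
class MeffResult:
    m_total: int
    m_eff: float
    eigenvalues: Tuple[float, ...]


@dataclass(frozen=True)
class MetaResult:
    estimate: float
    se: float
    z: float
    p: float
    n_cohorts: int


def li_ji_meff(correlation: np.ndarray) -> MeffResult:
    """Effective number of independent tests from a correlation matrix.

    Each eigenvalue lambda contributes ``I(|lambda| >= 1) + frac(|lambda|)``:
    an eigenvalue's integer part witnesses one fully independent dimension
    and its fractional part a partially independent one.  m_eff equals the
    matrix dimension for the identity and 1 for an all-ones matrix.
    """
    c = np.asarray(correlation, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValidationError(f"correlation matrix must be square, got shape {c.shape}")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-8):
        raise ValidationError("correlation matrix must have unit diagonal")
    lam = np.abs(np.linalg.eigvalsh(c))
    m_eff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    return MeffResult(m_total=c.shape[0], m_eff=m_eff, eigenvalues=tuple(lam.tolist()))


def adjusted_thresholds(
    p_values: Sequence[float],
    m_eff: float,
    q: float = 0.05,
) -> pd.DataFrame:
    """Benjamini-Hochberg step-up with the effective test count.

    The threshold for ascending rank i is ``i * q / m_eff``; all p-values up
    to the largest rank whose p-value sits below its threshold are rejected.
    With ``m_eff`` equal to the number of tests this is exactly standard BH.
    Returns a DataFrame aligned with the input order carrying each test's
    threshold and rejection flag.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return pd.DataFrame({"p": [], "threshold": [], "significant": []})
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must be finite and in [0, 1]")
    if m_eff < 1:
        raise ValidationError("m_eff must be >= 1")
    order = np.argsort(p, kind="stable")
    ranks = np.empty(p.size, dtype=int)
    ranks[order] = np.arange(1, p.size + 1)
    thresholds = ranks * q / m_eff
    sorted_p = p[order]
    below = sorted_p <= np.arange(1, p.size + 1) * q / m_eff
    k = int(np.max(np.nonzero(below)[0]) + 1) if below.any() else 0
    significant = ranks <= k
    return pd.DataFrame({"p": p, "threshold": thresholds, "significant": significant})


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> pd.DataFrame:
    """Standard Benjamini-Hochberg: monotone adjusted p-values and flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return pd.DataFrame({"p": [], "p_adjusted": [], "significant": []})
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame({"p": p, "p_adjusted": p_adj, "significant": reject})


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Normal-approximation SE from a confidence interval's width."""
    if not 0 < level < 1:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    if ci_low > ci_high:
        raise ValidationError("ci_low must not exceed ci_high")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (ci_high - ci_low) / (2.0 * z)


def ivw_meta(estimates: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Fixed-effect inverse-variance pooling across cohorts."""
    e = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if e.size == 0:
        raise ValidationError("no estimates to pool")
    if np.any(s <= 0):
        raise ValidationError("standard errors must be positive")
    if e.size == 1:
        import warnings

        warnings.warn("single cohort: pooled estimate is a pass-through", stacklevel=2)
    w = 1.0 / s**2
    pooled = float((w * e).sum() / w.sum())
    se = float(math.sqrt(1.0 / w.sum()))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(estimate=pooled, se=se, z=z, p=p, n_cohorts=int(e.size))


# ---------------------------------------------------------------------------
# type-I error harness


@dataclass
class Type1Result:
    rejection_rate: float
    ci_low: float
    ci_high: float
    n_reps: int
    alpha: float

    @property
    def calibrated(self) -> bool:
        return self.ci_low <= self.alpha <= self.ci_high


def type1_sim(
    null_generator: Callable[[np.random.Generator, int], Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]],
    n_participants: int,
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> Type1Result:
    """Empirical rejection rate of the total-effect (path c) test under a null.

    ``null_generator(rng, n)`` must return ``(dosage, outcome, covariates)``
    with zero genotype effect on the outcome; ``covariates`` may be None or
    an (n x c) array.  Per replicate the linear regression
    ``outcome ~ dosage (+ covariates)`` is tested at ``alpha`` on the dosage
    coefficient.  Used to confirm that linear models keep their nominal
    type-I error under the non-normal proxy-score outcome.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        dosage, y, cov = null_generator(rng, n_participants)
        n = len(y)
        blocks = [np.ones((n, 1)), np.asarray(dosage, float).reshape(-1, 1)]
        names = ["const", "dosage"]
        if cov is not None:
            cov = np.asarray(cov, float)
            if cov.ndim == 1:
                cov = cov.reshape(-1, 1)
            blocks.append(cov)
            names += [f"cov{i}" for i in range(cov.shape[1])]
        X = np.hstack(blocks)
        fit = ols(X, np.asarray(y, float), names, check_rank=False)
        if fit["dosage"][2] < alpha:
            rejections += 1
    rate = rejections / n_reps
    lo, hi = stats.binom.interval(0.99, n_reps, alpha)
    return Type1Result(
        rejection_rate=rate,
        ci_low=lo / n_reps,
        ci_high=hi / n_reps,
        n_reps=n_reps,
        alpha=alpha,
    )


def proxy_null_generator(
    allele_frequency: float = 0.2,
    parent_affect_prob: float = 0.16,
    parent_age_mean: float = 78.0,
    parent_age_sd: float = 9.0,
) -> Callable[[np.random.Generator, int], Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]]:
    """Null generator with the proxy-score-shaped (non-normal) outcome.

    The dosage is Hardy-Weinberg; the proxy outcome is built from two
    parental records whose affection is independent of the dosage, so the
    genotype has exactly zero effect and any rejection is a type-I error.
    """
    cap = 0.32

    def gen(rng: np.random.Generator, n: int):
        dosage = rng.binomial(2, allele_frequency, size=n).astype(float)
        score = np.zeros(n)
        for _parent in range(2):
            affected = rng.random(n) < parent_affect_prob
            age = np.clip(rng.normal(parent_age_mean, parent_age_sd, size=n), 40.0, 100.0)
            contribution = np.where(affected, 1.0, np.minimum(cap, np.maximum(0.0, (100.0 - age) / 100.0)))
            score += contribution
        return dosage, score, None

    return gen
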