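"""Small regression layer shared by the mediation and MR engines.

Ordinary least squares is done directly in numpy (classical SEs, t-based
p-values) because the bootstrap loops need thousands of refits; logistic
fits go through statsmodels GLM.  Rank deficiency is detected with a
pivoted QR so errors can name the collinear columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

import statsmodels.api as sm

from .errors import RankDeficientDesign, ValidationError


@dataclass
class FitResult:
    names: List[str]
    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    nobs: int
    converged: bool = True
    error: Optional[str] = None

    def __getitem__(self, name: str) -> Tuple[float, float, float]:
        i = self.names.index(name)
        return float(self.coef[i]), float(self.se[i]), float(self.p[i])


def design_matrix(
    data: pd.DataFrame,
    columns: Sequence[str],
    site_column: Optional[str] = None,
) -> Tuple[np.ndarray, List[str]]:
    """Intercept + requested columns (+ site indicator contrasts).

    Site levels are sorted before dummy-coding (first level as reference) so
    results do not depend on row order or level labels.
    """
    n = len(data)
    blocks = [np.ones((n, 1))]
    names = ["const"]
    for c in columns:
        blocks.append(data[c].to_numpy(float).reshape(-1, 1))
        names.append(c)
    if site_column is not None:
        levels = sorted(pd.unique(data[site_column].dropna()))
        for lev in levels[1:]:
            blocks.append((data[site_column] == lev).to_numpy(float).reshape(-1, 1))
            names.append(f"{site_column}[{lev}]")
    return np.hstack(blocks), names


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[piv[i]] for i in range(rank, X.shape[1])]
        raise RankDeficientDesign(bad)


def ols(X: np.ndarray, y: np.ndarray, names: Sequence[str], check_rank: bool = True) -> FitResult:
    n, k = X.shape
    if n <= k:
        raise ValidationError(f"need more observations ({n}) than parameters ({k})")
    if check_rank:
        _check_rank(X, names)
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return FitResult(list(names), beta, se, p, nobs=n)


def ols_coefs_only(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fast path for bootstrap loops: coefficients only, no diagnostics."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def logistic(X: np.ndarray, y: np.ndarray, names: Sequence[str], check_rank: bool = True) -> FitResult:
    n, k = X.shape
    if n <= k:
        raise ValidationError(f"need more observations ({n}) than parameters ({k})")
    uniq = np.unique(y)
    if uniq.size < 2:
        return FitResult(
            list(names),
            np.full(k, np.nan),
            np.full(k, np.nan),
            np.full(k, np.nan),
            nobs=n,
            converged=False,
            error="degenerate outcome: single class",
        )
    if check_rank:
        _check_rank(X, names)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit(maxiter=100)
        coef = np.asarray(res.params, float)
        se = np.asarray(res.bse, float)
        p = np.asarray(res.pvalues, float)
        # flag quasi-separation: exploding coefficients or SEs
        ok = bool(np.all(np.isfinite(se)) and np.all(np.abs(coef) < 50) and np.all(se < 1e3))
        return FitResult(
            list(names), coef, se, p, nobs=n,
            converged=ok, error=None if ok else "possible separation or non-convergence",
        )
    except Exception as exc:  # noqa: BLE001 - fit failures become error states
        return FitResult(
            list(names),
            np.full(k, np.nan),
            np.full(k, np.nan),
            np.full(k, np.nan),
            nobs=n,
            converged=False,
            error=f"logistic fit failed: {exc}",
        )


def logistic_coefs_only(X: np.ndarray, y: np.ndarray, maxiter: int = 50) -> Optional[np.ndarray]:
    """IRLS logistic coefficients for bootstrap loops; None on failure."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=maxiter)
        coef = np.asarray(res.params, float)
        if not np.all(np.isfinite(coef)) or np.any(np.abs(coef) > 50):
            return None
        return coef
    except Exception:  # noqa: BLE001
        return None
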