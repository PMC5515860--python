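"""Robust association of behavioral ratings with regional CBF.

Fits are Huber M-estimates computed by iteratively reweighted least
squares: residuals beyond ``c`` robust standard deviations are linearly
downweighted, the scale is re-estimated each iteration from the median
absolute residual (MAD / 0.6745), and iteration stops when the
coefficients move less than ``tol``.  A family of such scans (group x
condition x region) is Bonferroni-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConvergenceError, InputError

logger = logging.getLogger(__name__)

MAD_CONSTANT = 0.6745  # normal-consistency factor for the MAD scale


@dataclass
class RobustFit:
    intercept: float
    slope: float
    scale: float
    t: float
    p: float
    n: int
    n_iter: int
    converged: bool


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def huber_fit(
    x: np.ndarray,
    y: np.ndarray,
    tuning: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> RobustFit:
    """Huber robust simple regression of ``y`` on ``x``.

    The tuning constant 1.345 gives 95% efficiency at the Gaussian model.
    The slope standard error is the weighted-least-squares one at the
    final weights, sigma^2 * (X' W X)^-1 with sigma^2 = sum(w r^2)/(n - 2),
    and the p-value comes from the t distribution with n - 2 df.  An exact
    fit (zero residual scale) reports t = inf, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1D arrays of equal length")
    n = len(x)
    if n < 4:
        raise InputError("robust fit requires n >= 4")
    if np.ptp(x) == 0:
        raise InputError("predictor has zero variance")
    X = np.column_stack([np.ones(n), x])

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    trace = [beta.copy()]
    w = np.ones(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = y - X @ beta
        scale = np.median(np.abs(r)) / MAD_CONSTANT
        if scale < 1e-12 * max(1.0, float(np.abs(y).max())):
            # exact (or numerically exact) fit: all weights 1, done
            w = np.ones(n)
            converged = True
            scale = 0.0
            break
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, tuning * scale / np.abs(r))
        w = np.where(np.isfinite(w), w, 1.0)
        beta_new = _wls(X, y, w)
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        trace.append(beta.copy())
        if step < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Huber IRLS did not converge in {max_iter} iterations", trace=trace
        )

    r = y - X @ beta
    df = n - 2
    if scale == 0.0:
        se_slope = 0.0
    else:
        xtwx = X.T @ (X * w[:, None])
        sigma2 = float((w * r ** 2).sum()) / df
        se_slope = float(np.sqrt(sigma2 * np.linalg.inv(xtwx)[1, 1]))
    if se_slope > 0:
        t = float(beta[1] / se_slope)
        p = float(2.0 * sps.t.sf(abs(t), df))
    else:
        t = float(np.inf) if beta[1] != 0 else 0.0
        p = 0.0 if beta[1] != 0 else 1.0
    return RobustFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        scale=float(scale),
        t=t,
        p=p,
        n=n,
        n_iter=it,
        converged=converged,
    )


def bonferroni(p: float, m_tests: int) -> float:
    """Family-wise corrected p-value, capped at 1 and monotone in m."""
    return float(min(1.0, p * m_tests))


def association_scan(
    cbf_table: pd.DataFrame,
    ratings: pd.DataFrame,
    m_tests: int = 6,
    alpha: float = 0.05,
    tuning: float = 1.345,
    min_n: int = 4,
) -> pd.DataFrame:
    """Huber regression of ratings on regional CBF per (group, condition, region).

    ``cbf_table`` needs columns subject_id, group, condition, region, cbf;
    ``ratings`` needs subject_id, condition, rating.  Sessions with missing
    ratings are dropped listwise (logged).  Every scanned cell is reported
    with its Bonferroni-adjusted p (``p_adj = min(1, p * m_tests)``) and a
    significance flag at ``alpha``.
    """
    required = {"subject_id", "group", "condition", "region", "cbf"}
    if not required.issubset(cbf_table.columns):
        raise InputError(f"cbf_table missing columns {sorted(required - set(cbf_table.columns))}")
    if not {"subject_id", "condition", "rating"}.issubset(ratings.columns):
        raise InputError("ratings table needs subject_id, condition, rating columns")
    merged = cbf_table.merge(
        ratings[["subject_id", "condition", "rating"]], on=["subject_id", "condition"], how="left"
    )
    n_missing = int(merged["rating"].isna().sum())
    if n_missing:
        logger.info("association_scan: dropping %d rows with missing ratings", n_missing)
        merged = merged.dropna(subset=["rating"])

    rows = []
    for (group, condition, region), cell in merged.groupby(
        ["group", "condition", "region"], sort=True
    ):
        row: dict = {
            "group": group,
            "condition": condition,
            "region": region,
            "n": len(cell),
        }
        if len(cell) < min_n or np.ptp(cell["cbf"].to_numpy()) == 0:
            row.update({"slope": np.nan, "t": np.nan, "p": np.nan, "p_adj": np.nan,
                        "significant": False})
        else:
            fit = huber_fit(cell["cbf"].to_numpy(), cell["rating"].to_numpy(), tuning=tuning)
            p_adj = bonferroni(fit.p, m_tests)
            row.update(
                {
                    "slope": fit.slope,
                    "t": fit.t,
                    "p": fit.p,
                    "p_adj": p_adj,
                    "significant": bool(p_adj < alpha),
                }
            )
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["group", "condition", "region", "n", "slope", "t", "p", "p_adj", "significant"]
    )
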