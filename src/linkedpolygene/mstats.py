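"""Multivariate linear-hypothesis statistics.

Implements Wilks' Lambda (ratio of residual to total generalized variance)
with Rao's F approximation, which is exact for hypotheses of rank 1 or 2
and for up to two response variables.  A rank-1 fast path computes Lambda
for many single-column hypotheses at once, which is what makes
genome scans with permutation thresholds cheap: for a focal column g and
responses Y, both residualized against the covariates,

    Lambda = 1 - (g'Y) (Y'Y)^{-1} (Y'g) / (g'g).

Pillai's trace is available as an alternative statistic; for rank-1
hypotheses V = 1 - Lambda and the two tests coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

_EPS = 1e-12


@dataclass(frozen=True)
class MultivariateTest:
    statistic: float  # Wilks' Lambda or Pillai's trace
    F: float
    df1: float
    df2: float
    p_value: float
    kind: str = "wilks"

    @property
    def neglog10_p(self) -> float:
        # survival-function accuracy keeps this finite for tiny p
        return float(-math.log10(max(self.p_value, 5e-324)))


def residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each column of Y on the column space of X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def rao_f_from_wilks(lam: float, p: int, q: int, v: float) -> tuple[float, float, float]:
    """Rao's F approximation for Wilks' Lambda.

    p = number of responses, q = hypothesis degrees of freedom,
    v = error degrees of freedom (n minus rank of the full design).
    Returns (F, df1, df2).
    """
    den = p * p + q * q - 5
    s = math.sqrt((p * p * q * q - 4) / den) if den > 0 else 1.0
    df1 = p * q
    df2 = s * (v - (p - q + 1) / 2) - (p * q - 2) / 2
    lam = min(max(lam, _EPS), 1.0)
    F = (lam ** (-1 / s) - 1) * df2 / df1
    return max(F, 0.0), df1, df2


def pillai_f(V: float, p: int, q: int, v: float) -> tuple[float, float, float]:
    """F approximation for Pillai's trace V (s = min(p, q) roots)."""
    s = min(p, q)
    m = (abs(p - q) - 1) / 2
    n_ = (v - p - 1) / 2
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_ + s + 1)
    V = min(max(V, 0.0), s - _EPS)
    F = (V / (s - V)) * (df2 / df1)
    return F, df1, df2


def wilks_test(
    Y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    statistic: str = "wilks",
) -> MultivariateTest:
    """Test the columns of X_full absent from X_reduced, multivariately.

    Fits the multivariate linear model of Y (n x p) on each design and
    compares residual SSCP matrices.  Hypothesis df is the rank
    difference between the designs.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    r_full = np.linalg.matrix_rank(X_full)
    r_red = np.linalg.matrix_rank(X_reduced)
    q = r_full - r_red
    if q < 1:
        raise ValueError("full design adds no estimable degrees of freedom")
    v = n - r_full
    if v < p:
        raise ValueError(f"too few error degrees of freedom ({v}) for {p} responses")
    E = _sscp(residualize(Y, X_full))
    E_red = _sscp(residualize(Y, X_reduced))
    H = E_red - E
    if statistic == "wilks":
        lam = _det_ratio(E, E + H)
        F, df1, df2 = rao_f_from_wilks(lam, p, q, v)
        stat = lam
    elif statistic == "pillai":
        V = _pillai_trace(H, E)
        F, df1, df2 = pillai_f(V, p, q, v)
        stat = V
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    pval = float(stats.f.sf(F, df1, df2))
    return MultivariateTest(statistic=float(stat), F=float(F), df1=df1, df2=df2,
                            p_value=min(max(pval, 5e-324), 1.0), kind=statistic)


def _sscp(R: np.ndarray) -> np.ndarray:
    return R.T @ R


def _det_ratio(E: np.ndarray, T: np.ndarray) -> float:
    """det(E)/det(T), computed stably via slogdet."""
    se, lde = np.linalg.slogdet(E)
    st, ldt = np.linalg.slogdet(T)
    if st <= 0:
        return 1.0  # degenerate total SSCP: no testable variation
    if se <= 0:
        return _EPS
    return float(np.exp(lde - ldt))


def _pillai_trace(H: np.ndarray, E: np.ndarray) -> float:
    T = H + E
    return float(np.trace(H @ np.linalg.pinv(T)))


def rank_one_wilks_batch(
    Y_r: np.ndarray,
    G_r: np.ndarray,
    v: float,
    min_ss: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Wilks' Lambda for many single-column (rank-1) hypotheses at once.

    Y_r (n x p) and G_r (n x m) must already be residualized against the
    shared covariate design; v is the error df of the full model
    (n - rank of covariates - 1).  Columns of G_r with residual sum of
    squares below ``min_ss`` (monomorphic or collinear with covariates)
    yield NaN.

    Returns (lambda, F, p) arrays of length m plus (df1, df2).
    """
    n, p = Y_r.shape
    T = Y_r.T @ Y_r
    Tinv = np.linalg.pinv(T)
    A = Y_r.T @ G_r  # p x m
    d = np.einsum("ij,ij->j", G_r, G_r)  # residual SS per focal column
    valid = d > min_ss
    lam = np.full(G_r.shape[1], np.nan)
    quad = np.einsum("ij,ik,kj->j", A[:, valid], Tinv, A[:, valid])
    lam_v = 1.0 - quad / d[valid]
    lam[valid] = np.clip(lam_v, _EPS, 1.0)
    df1 = float(p)
    df2 = float(v - p + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (1.0 - lam) / lam * (df2 / df1)
    pvals = np.full_like(lam, np.nan)
    pvals[valid] = np.clip(stats.f.sf(F[valid], df1, df2), 5e-324, 1.0)
    return lam, F, pvals, df1, df2


def neglog10(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return -np.log10(p)
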