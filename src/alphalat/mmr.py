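"""Multivariate multiple regression of condition-wise HLM(alpha) outcomes.

One shared design (LV regressors plus intercept) predicts several outcome
variables jointly: the coefficient matrix equals column-wise univariate
least squares, while hypothesis tests pool information across outcomes.

* Per-regressor test: Hotelling T^2 on one coefficient row across the p
  outcomes, ``T^2 = b_j' S^-1 b_j / c_jj`` with ``S`` the residual
  covariance (dof ``ve = n - k - 1``) and ``c_jj`` the j-th diagonal of
  ``(X'X)^-1``; converted to F with dfs ``(p, ve - p + 1)``.  For a
  single-row hypothesis this is equivalent to Pillai or Wilks.
* Nested-model comparison: Wilks' Lambda = det(E_full)/det(E_reduced) from
  residual cross-product matrices, converted to F by Rao's approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MMRFit:
    """Shared-design multivariate least squares fit (intercept included)."""

    names: list                  # regressor names, intercept first
    outcome_names: list
    B: np.ndarray                # (k+1) x p coefficient matrix
    bse: np.ndarray              # (k+1) x p standard errors
    tvalues: np.ndarray
    pvalues: np.ndarray
    resid: np.ndarray            # n x p
    resid_cov: np.ndarray        # p x p, dof n-k-1
    xtx_inv: np.ndarray          # (k+1) x (k+1)
    E: np.ndarray                # p x p residual cross-products
    n: int
    k: int

    @property
    def df_resid(self) -> int:
        return self.n - self.k - 1

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "outcome_names": list(self.outcome_names),
            "B": self.B.tolist(),
            "bse": self.bse.tolist(),
            "tvalues": self.tvalues.tolist(),
            "pvalues": self.pvalues.tolist(),
            "n": int(self.n),
            "k": int(self.k),
            "df_resid": int(self.df_resid),
        }


@dataclass
class RegressorTest:
    regressor: str
    t2: float
    fvalue: float
    df1: int
    df2: int
    pvalue: float


@dataclass
class NestedTest:
    wilks: float
    fvalue: float
    df1: float
    df2: float
    pvalue: float
    hypothesis_df: int


def fit_mmr(outcomes, design, add_intercept: bool = True,
            names=None, outcome_names=None) -> MMRFit:
    """Fit ``outcomes`` (n x p) on ``design`` (n x k) by shared least squares.

    Column j of the coefficient matrix equals the univariate OLS fit for
    outcome j; the residual covariance is the residual cross-product matrix
    divided by ``n - k - 1``.
    """
    if isinstance(outcomes, pd.DataFrame):
        Y = outcomes.to_numpy(dtype=float)
        outcome_names = outcome_names or list(outcomes.columns)
    else:
        Y = np.asarray(outcomes, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
    if isinstance(design, pd.DataFrame):
        X0 = design.to_numpy(dtype=float)
        names = names or list(design.columns)
    else:
        X0 = np.asarray(design, dtype=float)
        if X0.ndim == 1:
            X0 = X0[:, None]
    n, p = Y.shape
    if p < 1:
        raise ValueError("need at least one outcome")
    if outcome_names is None:
        outcome_names = [f"y{j + 1}" for j in range(p)]
    if names is None:
        names = [f"x{i + 1}" for i in range(X0.shape[1])]
    if X0.shape[0] != n:
        raise ValueError("design and outcomes lengths differ")
    if add_intercept:
        X = np.column_stack([np.ones(n), X0])
        all_names = ["intercept"] + list(names)
    else:
        X = X0
        all_names = list(names)
    k = X.shape[1] - 1 if add_intercept else X.shape[1]
    if n <= X.shape[1]:
        raise ValueError(f"need n > {X.shape[1]} observations, got {n}")
    Q, R = np.linalg.qr(X)
    rdiag = np.abs(np.diag(R))
    if rdiag.min() <= max(n, X.shape[1]) * np.finfo(float).eps * rdiag.max():
        raise ValueError("design matrix is rank deficient")
    B = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ B
    E = resid.T @ resid
    ve = n - X.shape[1]
    S = E / ve
    Rinv = np.linalg.inv(R)
    xtx_inv = Rinv @ Rinv.T
    with np.errstate(divide="ignore", invalid="ignore"):
        bse = np.sqrt(np.outer(np.diag(xtx_inv), np.diag(S)))
        tvals = B / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), ve)
    return MMRFit(names=all_names, outcome_names=outcome_names, B=B, bse=bse,
                  tvalues=tvals, pvalues=pvals, resid=resid, resid_cov=S,
                  xtx_inv=xtx_inv, E=E, n=n, k=k)


def test_regressor_across_outcomes(fit: MMRFit, regressor) -> RegressorTest:
    """Hotelling T^2 test that one regressor's coefficient row is zero
    across all outcomes."""
    if isinstance(regressor, str):
        if regressor not in fit.names:
            raise ValueError(f"unknown regressor {regressor!r}")
        j = fit.names.index(regressor)
    else:
        j = int(regressor)
    if fit.names[j] == "intercept":
        raise ValueError("per-regressor test applies to non-intercept rows")
    p = fit.B.shape[1]
    ve = fit.df_resid
    if ve - p + 1 <= 0:
        raise ValueError("insufficient residual dof for the multivariate test")
    b = fit.B[j]
    c_jj = fit.xtx_inv[j, j]
    sign, logdet = np.linalg.slogdet(fit.resid_cov)
    if sign <= 0:
        raise ValueError("singular residual covariance")
    t2 = float(b @ np.linalg.solve(fit.resid_cov, b) / c_jj)
    df1, df2 = p, ve - p + 1
    fval = t2 * df2 / (p * ve)
    pval = float(stats.f.sf(fval, df1, df2))
    return RegressorTest(regressor=fit.names[j], t2=t2, fvalue=float(fval),
                         df1=df1, df2=df2, pvalue=pval)


def _rao_f(lam: float, p: int, vh: int, ve: int):
    """Rao's F approximation for Wilks' Lambda with p outcomes, vh hypothesis
    dof and ve error dof.  Exact when min(p, vh) <= 2."""
    num = p * p * vh * vh - 4.0
    den = p * p + vh * vh - 5.0
    t = np.sqrt(num / den) if den > 0 and num > 0 else 1.0
    w = ve + vh - (p + vh + 1) / 2.0
    df1 = p * vh
    df2 = w * t - (p * vh - 2.0) / 2.0
    lam_t = lam ** (1.0 / t)
    fval = (1.0 - lam_t) / lam_t * df2 / df1
    return float(fval), float(df1), float(df2)


def compare_nested_mmr(full: MMRFit, reduced: MMRFit) -> NestedTest:
    """Wilks' Lambda comparison of two nested shared-design fits.

    The reduced design's regressors must be a subset of the full design's
    (same subjects, same outcomes).  Lambda = det(E_full)/det(E_reduced);
    identical designs give Lambda = 1, F = 0, p = 1.
    """
    if full.n != reduced.n:
        raise ValueError("fits use different numbers of subjects")
    if full.B.shape[1] != reduced.B.shape[1]:
        raise ValueError("fits have different outcome sets")
    if not set(reduced.names) <= set(full.names):
        raise ValueError("reduced design is not nested in the full design")
    vh = full.k - reduced.k
    if vh < 0:
        raise ValueError("full model has fewer regressors than reduced")
    p = full.B.shape[1]
    ve = full.df_resid
    if vh == 0:
        return NestedTest(wilks=1.0, fvalue=0.0, df1=0.0, df2=float(ve),
                          pvalue=1.0, hypothesis_df=0)
    sign_f, logdet_f = np.linalg.slogdet(full.E)
    sign_r, logdet_r = np.linalg.slogdet(reduced.E)
    if sign_f <= 0 or sign_r <= 0:
        raise ValueError("singular residual cross-product matrix")
    lam = float(np.exp(logdet_f - logdet_r))
    lam = min(lam, 1.0)
    fval, df1, df2 = _rao_f(lam, p, vh, ve)
    pval = float(stats.f.sf(fval, df1, df2))
    return NestedTest(wilks=lam, fvalue=fval, df1=df1, df2=df2, pvalue=pval,
                      hypothesis_df=vh)
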