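"""Linear modelling of HLM(alpha) on lateralization volumes.

The model search fits every non-empty subset of the candidate LV regressors
(2^7 - 1 = 127 models for the full structure set), always with an
intercept, and ranks subsets by an information criterion.  The criteria use
the Gaussian log-likelihood with all constants retained,

    AIC = -2 logLik + 2 (k + 2),    BIC = -2 logLik + log(n) (k + 2),

counting the intercept and the residual variance among the parameters, so
values are comparable across subsets (rankings are invariant to the
constant).  Fits are computed directly via QR; no random effects are
modelled since the design has one observation per subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ModelFitResult:
    """Ordinary least-squares fit with intercept.

    ``names`` includes ``"intercept"`` first; arrays are aligned with it.
    """

    names: list
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    df_model: int
    fvalue: float
    f_pvalue: float
    rsquared: float
    rsquared_adj: float
    llf: float
    aic: float
    bic: float
    resid: np.ndarray
    nobs: int

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "params": [float(v) for v in self.params],
            "bse": [float(v) for v in self.bse],
            "tvalues": [float(v) for v in self.tvalues],
            "pvalues": [float(v) for v in self.pvalues],
            "df_resid": int(self.df_resid),
            "df_model": int(self.df_model),
            "fvalue": float(self.fvalue),
            "f_pvalue": float(self.f_pvalue),
            "rsquared": float(self.rsquared),
            "rsquared_adj": float(self.rsquared_adj),
            "llf": float(self.llf),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "nobs": int(self.nobs),
        }


@dataclass
class SearchResult:
    """Exhaustive subset search over candidate regressors."""

    entries: list            # dicts: subset, k, aic, bic, r2, adj_r2
    winning_aic: tuple
    winning_bic: tuple
    criterion: str

    @property
    def winning(self) -> tuple:
        return self.winning_aic if self.criterion == "aic" else self.winning_bic

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame([
            {"subset": "+".join(e["subset"]), "k": e["k"], "aic": e["aic"],
             "bic": e["bic"], "r2": e["r2"], "adj_r2": e["adj_r2"]}
            for e in self.entries
        ])
        return df.sort_values(self.criterion, kind="mergesort").reset_index(drop=True)


def _as_matrix(design, names=None):
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i + 1}" for i in range(X.shape[1])]
    return X, list(names)


def fit_ols(design, response, add_intercept: bool = True,
            names=None) -> ModelFitResult:
    """Ordinary least squares of ``response`` on ``design`` (n x k) with an
    intercept prepended by default.

    Reports coefficients, standard errors, two-sided t tests on ``n - k - 1``
    residual degrees of freedom, the overall F test against the
    intercept-only model with dfs ``(k, n - k - 1)``, R^2 / adjusted R^2, and
    the Gaussian-likelihood information criteria described in the module
    docstring.  Raises on rank deficiency or ``n <= k + 1``.
    """
    X0, xnames = _as_matrix(design, names)
    y = np.asarray(response, dtype=float).ravel()
    n = len(y)
    if X0.shape[0] != n:
        raise ValueError("design and response lengths differ")
    if add_intercept:
        X = np.column_stack([np.ones(n), X0])
        names_all = ["intercept"] + xnames
    else:
        X = X0
        names_all = xnames
    k = X.shape[1] - 1 if add_intercept else X.shape[1]
    if n <= X.shape[1]:
        raise ValueError(f"need n > {X.shape[1]} observations, got {n}")
    Q, R = np.linalg.qr(X)
    rdiag = np.abs(np.diag(R))
    if rdiag.min() <= max(n, X.shape[1]) * np.finfo(float).eps * rdiag.max():
        raise ValueError("design matrix is rank deficient")
    params = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ params
    rss = float(resid @ resid)
    df_resid = n - X.shape[1]
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    Rinv = np.linalg.inv(R)
    xtx_inv_diag = np.sum(Rinv * Rinv, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bse = np.sqrt(sigma2 * xtx_inv_diag)
        tvals = params / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    tss = float(((y - y.mean()) ** 2).sum()) if add_intercept else float(y @ y)
    rsq = 1.0 - rss / tss if tss > 0 else 0.0
    adj = 1.0 - (1.0 - rsq) * (n - 1) / df_resid if df_resid > 0 else np.nan
    if k > 0:
        denom = (1.0 - rsq) / df_resid
        fval = (rsq / k) / denom if denom > 0 else np.inf
        fp = float(stats.f.sf(fval, k, df_resid))
    else:
        fval, fp = np.nan, np.nan
    with np.errstate(divide="ignore"):
        llf = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    n_par = X.shape[1] + 1  # coefficients + residual variance
    aic = -2.0 * llf + 2.0 * n_par
    bic = -2.0 * llf + np.log(n) * n_par
    return ModelFitResult(
        names=names_all, params=params, bse=bse, tvalues=tvals, pvalues=pvals,
        df_resid=df_resid, df_model=k, fvalue=float(fval), f_pvalue=fp,
        rsquared=rsq, rsquared_adj=adj, llf=float(llf), aic=float(aic),
        bic=float(bic), resid=resid, nobs=n)


def model_search(lv_matrix: pd.DataFrame, hlm, criterion: str = "aic",
                 max_subset_size: int | None = None) -> SearchResult:
    """Fit every non-empty subset of the candidate regressors and rank by
    information criterion.

    Raises if any candidate regressor has zero variance.  ``criterion`` is
    ``"aic"`` (default) or ``"bic"``; both rankings are always recorded.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    if not isinstance(lv_matrix, pd.DataFrame):
        lv_matrix = pd.DataFrame(np.asarray(lv_matrix, dtype=float))
        lv_matrix.columns = [f"x{i + 1}" for i in range(lv_matrix.shape[1])]
    y = np.asarray(hlm, dtype=float).ravel()
    cols = list(lv_matrix.columns)
    X = lv_matrix.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        bad = [c for c, s in zip(cols, X.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance regressor(s): {bad}")
    p = len(cols)
    max_size = p if max_subset_size is None else max_subset_size
    entries = []
    for r in range(1, max_size + 1):
        for sub in combinations(range(p), r):
            fit = fit_ols(X[:, sub], y, names=[cols[i] for i in sub])
            entries.append({
                "subset": tuple(cols[i] for i in sub), "k": r,
                "aic": fit.aic, "bic": fit.bic,
                "r2": fit.rsquared, "adj_r2": fit.rsquared_adj,
                "fit": fit,
            })
    win_aic = min(entries, key=lambda e: (e["aic"], e["subset"]))["subset"]
    win_bic = min(entries, key=lambda e: (e["bic"], e["subset"]))["subset"]
    return SearchResult(entries=entries, winning_aic=win_aic,
                        winning_bic=win_bic, criterion=criterion)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1/(1 - R^2_j), with R^2_j from
    regressing column j on the remaining columns plus an intercept.

    Raises on exact collinearity, naming the offending column.
    """
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design, dtype=float))
        design.columns = [f"x{i + 1}" for i in range(design.shape[1])]
    if design.shape[1] < 2:
        raise ValueError("vif needs at least 2 regressors")
    out = {}
    cols = list(design.columns)
    for j, col in enumerate(cols):
        others = [c for c in cols if c != col]
        try:
            fit = fit_ols(design[others], design[col])
        except ValueError as exc:
            raise ValueError(
                f"collinearity involving column {col!r}: {exc}") from exc
        r2 = fit.rsquared
        if r2 >= 1.0 - 1e-10:
            raise ValueError(f"column {col!r} is exactly collinear")
        out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out)


def one_sample_test(values, popmean: float = 0.0):
    """Two-sided one-sample t test of the mean against ``popmean``."""
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance")
    res = stats.ttest_1samp(x, popmean)
    return float(res.statistic), float(res.pvalue)


def normality_check(values):
    """Shapiro-Wilk test of normality; valid for 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float).ravel()
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)
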