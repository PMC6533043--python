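"""Linear-probability estimation with instrumental variables.

Implements ordinary least squares and two-stage least squares with
heteroscedasticity-consistent (HC1) sandwich standard errors, the
first-stage instrument-relevance F statistic, the regression-based
Wu-Hausman endogeneity test, and a Wald test of coefficient equality
across specifications (paired bootstrap by default, since two IV
specifications are typically fit on overlapping samples).

The structural model is Y = beta1*X1 + beta2*X2 + u with X1 endogenous;
an instrument set Z (excluded from the structural equation, correlated
with X1, uncorrelated with u given X2) identifies beta1. The 2SLS
covariance uses second-stage residuals computed with the *original*
endogenous regressors (proper 2SLS variance, not the naive two-step one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SingularDesignError, UnderIdentifiedError

__all__ = [
    "EstimationResult",
    "ols",
    "two_sls",
    "first_stage_F",
    "wu_hausman",
    "wu_hausman_contrast",
    "wald_equality",
    "wald_equality_analytic",
    "listwise_complete",
]

log = logging.getLogger(__name__)

CONST = "const"


@dataclass
class EstimationResult:
    """Coefficients, robust inference and diagnostics for one model fit."""

    estimator: str
    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    n_obs: int
    first_stage_F: Optional[Dict[str, float]] = None
    wu_hausman: Optional[Tuple[float, float]] = None
    first_stage: Dict[str, "EstimationResult"] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.params, "robust_se": self.se, "p": self.pvalues})


def listwise_complete(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Listwise deletion over the given columns, with a logged count."""
    sub = df[list(columns)]
    keep = sub.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("listwise deletion dropped %d of %d rows", dropped, len(df))
    return df.loc[keep]


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the columns whose removal restores full rank
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        bad = [names[i] for i in range(len(names)) if diag[i] <= tol]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]})", columns=bad
        )


def _with_const(X: pd.DataFrame, add_constant: bool) -> pd.DataFrame:
    if add_constant and CONST not in X.columns:
        X = X.copy()
        X[CONST] = 1.0
    return X


def _hc1_cov(X: np.ndarray, resid: np.ndarray, bread: np.ndarray) -> np.ndarray:
    n, k = X.shape
    meat = (X * resid[:, None] ** 2).T @ X
    return n / (n - k) * bread @ meat @ bread


def _finish(estimator, names, beta, cov, n) -> EstimationResult:
    params = pd.Series(beta, index=names)
    se = pd.Series(np.sqrt(np.diag(cov)), index=names)
    z = params / se
    pvals = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=names)
    return EstimationResult(
        estimator=estimator,
        params=params,
        se=se,
        pvalues=pvals,
        cov=pd.DataFrame(cov, index=names, columns=names),
        n_obs=n,
    )


def ols(y: pd.Series, X: pd.DataFrame, add_constant: bool = True) -> EstimationResult:
    """Least squares with HC1 sandwich standard errors."""
    X = _with_const(X, add_constant)
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    ym = np.asarray(y, dtype=float)
    _check_rank(Xm, names)
    XtX = Xm.T @ Xm
    beta = np.linalg.solve(XtX, Xm.T @ ym)
    resid = ym - Xm @ beta
    bread = np.linalg.inv(XtX)
    cov = _hc1_cov(Xm, resid, bread)
    return _finish("ols", names, beta, cov, len(ym))


def _robust_wald_F(result: EstimationResult, restricted: Sequence[str]) -> float:
    """Wald statistic / q for H0: the named coefficients are jointly zero.

    Uses the fit's HC1 covariance; with a single restriction this equals
    the squared robust t statistic.
    """
    b = result.params[list(restricted)].to_numpy()
    V = result.cov.loc[list(restricted), list(restricted)].to_numpy()
    return float(b @ np.linalg.solve(V, b) / len(restricted))


def first_stage_F(
    endog: pd.Series,
    exog: Optional[pd.DataFrame],
    instruments: pd.DataFrame,
    add_constant: bool = True,
) -> float:
    """Partial F for the excluded instruments in a first-stage regression.

    Regresses the endogenous variable on instruments plus exogenous
    covariates and returns the joint robust Wald statistic for the
    instrument coefficients divided by their number (an F statistic; for
    one instrument it is the squared robust t). Values above ~10 indicate
    adequate instrument strength.
    """
    W = instruments if exog is None else pd.concat([instruments, exog], axis=1)
    fit = ols(endog, W, add_constant=add_constant)
    return _robust_wald_F(fit, list(instruments.columns))


def two_sls(
    y: pd.Series,
    endog: pd.DataFrame,
    exog: Optional[pd.DataFrame],
    instruments: pd.DataFrame,
    add_constant: bool = True,
    compute_diagnostics: bool = True,
) -> EstimationResult:
    """Two-stage least squares with HC1 sandwich standard errors.

    Stage 1 regresses each endogenous column on [instruments, exog];
    stage 2 regresses y on [fitted endogenous, exog]. The covariance uses
    residuals from the structural equation evaluated at the *original*
    endogenous values, sandwiched with the projected regressors.
    """
    if instruments.shape[1] < endog.shape[1]:
        raise UnderIdentifiedError(
            f"{instruments.shape[1]} instruments for {endog.shape[1]} endogenous regressors"
        )
    exog_cols = [] if exog is None else list(exog.columns)
    W = instruments if exog is None else pd.concat([instruments, exog], axis=1)
    W = _with_const(W, add_constant)
    Wm = W.to_numpy(dtype=float)
    # identification: instruments must add rank beyond the exogenous block
    base = Wm[:, [W.columns.get_loc(c) for c in exog_cols + ([CONST] if CONST in W else [])]]
    if np.linalg.matrix_rank(Wm) - (np.linalg.matrix_rank(base) if base.size else 0) < endog.shape[1]:
        raise UnderIdentifiedError("instruments are collinear with the exogenous covariates")
    _check_rank(Wm, list(W.columns))

    WtW_inv = np.linalg.inv(Wm.T @ Wm)
    first_stage_fits: Dict[str, EstimationResult] = {}
    fs_F: Dict[str, float] = {}
    Xhat = pd.DataFrame(index=endog.index)
    for col in endog.columns:
        fs = ols(endog[col], W, add_constant=False)
        first_stage_fits[col] = fs
        fs_F[col] = _robust_wald_F(fs, list(instruments.columns))
        Xhat[col] = Wm @ fs.params.to_numpy()

    X2 = Xhat if exog is None else pd.concat([Xhat, exog], axis=1)
    X2 = _with_const(X2, add_constant)
    names = list(X2.columns)
    X2m = X2.to_numpy(dtype=float)
    _check_rank(X2m, names)
    XtX = X2m.T @ X2m
    beta = np.linalg.solve(XtX, X2m.T @ np.asarray(y, dtype=float))
    # structural residuals with the ORIGINAL endogenous regressors
    Xorig = endog if exog is None else pd.concat([endog, exog], axis=1)
    Xorig = _with_const(Xorig, add_constant)[names].to_numpy(dtype=float)
    resid = np.asarray(y, dtype=float) - Xorig @ beta
    bread = np.linalg.inv(XtX)
    cov = _hc1_cov(X2m, resid, bread)
    result = _finish("tsls", names, beta, cov, len(y))
    result.first_stage = first_stage_fits
    result.first_stage_F = fs_F
    if compute_diagnostics:
        result.wu_hausman = wu_hausman(y, endog, exog, instruments, add_constant=add_constant)
    return result


def wu_hausman(
    y: pd.Series,
    endog: pd.DataFrame,
    exog: Optional[pd.DataFrame],
    instruments: pd.DataFrame,
    add_constant: bool = True,
) -> Tuple[float, float]:
    """Regression-based (control-function) Wu-Hausman endogeneity test.

    Augments the structural equation with the first-stage residuals and
    tests their coefficients jointly (robust Wald / q, F(q, n-k)
    reference). Rejection indicates endogeneity, i.e. OLS and IV estimate
    different quantities.
    """
    W = instruments if exog is None else pd.concat([instruments, exog], axis=1)
    W = _with_const(W, add_constant)
    resid_cols = []
    aug = endog.copy()
    for col in endog.columns:
        fs = ols(endog[col], W, add_constant=False)
        name = f"_resid_{col}"
        aug[name] = endog[col] - W.to_numpy(dtype=float) @ fs.params.to_numpy()
        resid_cols.append(name)
    X = aug if exog is None else pd.concat([aug, exog], axis=1)
    fit = ols(y, X, add_constant=add_constant)
    q = len(resid_cols)
    H = _robust_wald_F(fit, resid_cols)
    dof = fit.n_obs - len(fit.params)
    p = float(stats.f.sf(H, q, dof))
    return float(H), p


def wu_hausman_contrast(
    ols_result: EstimationResult,
    tsls_result: EstimationResult,
    endog_names: Sequence[str],
) -> Tuple[float, float]:
    """Contrast-form Hausman statistic on the endogenous coefficients.

    H = d' (V_iv - V_ols)^+ d with d the coefficient difference; chi-square
    reference with q degrees of freedom. Exposed as an independent check of
    the control-function form; the two agree in decision asymptotically.
    """
    names = list(endog_names)
    d = (tsls_result.params[names] - ols_result.params[names]).to_numpy()
    V = (tsls_result.cov.loc[names, names] - ols_result.cov.loc[names, names]).to_numpy()
    H = float(d @ np.linalg.pinv(V) @ d)
    H = abs(H)
    p = float(stats.chi2.sf(H, len(names)))
    return H, p


def wald_equality(
    data: pd.DataFrame,
    fit_a: Callable[[pd.DataFrame], EstimationResult],
    fit_b: Callable[[pd.DataFrame], EstimationResult],
    coefficient: str,
    n_boot: int = 500,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Wald test of coefficient equality across two specifications.

    Default overlap-aware implementation: resample users (rows of
    ``data``) with replacement, refit both specifications per replicate,
    and studentise the full-sample paired difference with the bootstrap
    standard deviation of the difference. Returns (stat, p) with a
    chi-square(1) reference.
    """
    ra, rb = fit_a(data), fit_b(data)
    for r in (ra, rb):
        if coefficient not in r.params.index:
            raise KeyError(f"coefficient {coefficient!r} absent from a specification")
    d0 = float(ra.params[coefficient] - rb.params[coefficient])
    rng = np.random.default_rng(seed)
    diffs = []
    n = len(data)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = data.iloc[idx].reset_index(drop=True)
        try:
            da = fit_a(boot).params[coefficient]
            db = fit_b(boot).params[coefficient]
        except (SingularDesignError, np.linalg.LinAlgError):
            continue
        diffs.append(float(da - db))
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    if sd == 0.0:
        return 0.0, 1.0
    stat = (d0 / sd) ** 2
    return float(stat), float(stats.chi2.sf(stat, 1))


def wald_equality_analytic(
    result_a: EstimationResult, result_b: EstimationResult, coefficient: str
) -> Tuple[float, float]:
    """No-overlap analytic variant: d^2 / (se_a^2 + se_b^2), chi-square(1)."""
    for r in (result_a, result_b):
        if coefficient not in r.params.index:
            raise KeyError(f"coefficient {coefficient!r} absent from a specification")
    d = float(result_a.params[coefficient] - result_b.params[coefficient])
    v = float(result_a.se[coefficient] ** 2 + result_b.se[coefficient] ** 2)
    stat = d * d / v
    return float(stat), float(stats.chi2.sf(stat, 1))
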