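"""Survival estimation: Kaplan-Meier, Aalen additive hazards, and the
control-function instrumental-variables extension.

Aalen's model writes the hazard of user i at time t as
h_i(t) = b_0(t) + sum_k b_k(t) x_ik, and estimates the *cumulative*
coefficients B_k(t) = int_0^t b_k(s) ds by least squares over the at-risk
set at each event time: dB(t) = (X_R' X_R)^{-1} X_R' dN(t). The IV variant
follows the control-function approach: regress each endogenous covariate
on instruments plus exogenous covariates, then include the first-stage
residuals as additional covariates (with time-varying effects like all
others) in the Aalen fit; the endogenous covariates' coefficients are then
causal under the instrument assumptions.

Summaries report per-covariate "mean coefficients": the least-squares
slope of B_k(t) against t over the reliable estimation window, i.e. the
time-averaged instantaneous effect (per day) under a locally linear
approximation. Confidence intervals come from a nonparametric case
(user-level) bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateInputError,
    EstimationImpossibleError,
    UnderIdentifiedError,
)
from .linear import ols, _robust_wald_F, _with_const, CONST

__all__ = [
    "KaplanMeierCurve",
    "SurvivalFit",
    "kaplan_meier",
    "aalen_fit",
    "aalen_iv_fit",
    "mean_coefficient",
    "bootstrap_ci",
]

log = logging.getLogger(__name__)

BASELINE = "baseline"
COND_CAP = 1e8  # at-risk Gram matrices above this condition number end the window


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate over the observed event times."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: Optional[float]  # smallest t with S(t) <= 0.5; None if never reached

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalFit:
    """Aalen additive-hazards fit: event-time grid of cumulative coefficients."""

    event_times: np.ndarray  # times at which increments were estimated
    cumulative: pd.DataFrame  # B_k(t) step functions, one column per covariate
    mean_coefficients: pd.Series  # per-day slope over the reliable window
    mode: str = "standard"  # or "iv"
    t_max: float = np.inf  # end of the reliable estimation window
    n_times_used: int = 0
    ci_95: Optional[pd.DataFrame] = None  # lower/upper per covariate (bootstrap)
    n_boot: int = 0
    first_stage_F: Optional[Dict[str, float]] = None

    @property
    def covariates(self) -> list[str]:
        return list(self.cumulative.columns)


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod_{t_i<=t} (1 - d_i/n_i).

    ``events`` is 1 for an observed dropout, 0 for censoring. The median is
    the smallest event time with S(t) <= 0.5, None (flagged undefined) when
    the curve never reaches 0.5.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0 or e.sum() == 0:
        order = np.argsort(t)
        warnings.warn("no events observed; survival curve is flat", stacklevel=2)
        return KaplanMeierCurve(
            times=np.unique(t[order]), survival=np.ones(len(np.unique(t))),
            n_at_risk=np.zeros(0, int), n_events=np.zeros(0, int), median=None,
        )
    uniq = np.unique(t[e == 1])
    # at risk: T_i >= t ; events at exactly t
    n_at_risk = np.array([(t >= u).sum() for u in uniq])
    n_events = np.array([((t == u) & (e == 1)).sum() for u in uniq])
    surv = np.cumprod(1.0 - n_events / n_at_risk)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(uniq[below[0]]) if len(below) else None
    return KaplanMeierCurve(uniq, surv, n_at_risk, n_events, median)


def _prepare_design(X: pd.DataFrame, add_baseline: bool) -> pd.DataFrame:
    if add_baseline and BASELINE not in X.columns:
        X = X.copy()
        X.insert(0, BASELINE, 1.0)
    return X


def aalen_fit(
    times: Sequence[float],
    events: Sequence[int],
    X: pd.DataFrame,
    add_baseline: bool = True,
    cond_cap: float = COND_CAP,
) -> SurvivalFit:
    """Aalen least-squares increments of the cumulative coefficients.

    Covariates are constant per user. At each distinct event time the
    increment dB = (X_R' X_R)^{-1} X_R' dN is computed over the at-risk set
    (ties processed jointly); estimation stops at the first event time
    whose at-risk Gram matrix is singular or has condition number above
    ``cond_cap``, which defines the reliable window recorded in the fit.
    """
    X = _prepare_design(X, add_baseline)
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n, p = Xm.shape
    if len(t) != n or len(e) != n:
        raise ValueError("times, events and covariate rows must align")

    # sort subjects by time descending so the at-risk set is a prefix
    order = np.argsort(-t, kind="stable")
    ts, es, Xs = t[order], e[order], Xm[order]
    grams = np.cumsum(np.einsum("ij,ik->ijk", Xs, Xs), axis=0)  # (n, p, p)

    event_times = np.unique(t[e == 1])
    if len(event_times) == 0:
        raise EstimationImpossibleError("no events observed")
    m = np.searchsorted(-ts, -event_times, side="right")  # risk-set sizes
    G_all = grams[m - 1]  # (k, p, p) at-risk Gram per event time

    # scale-invariant conditioning: covariate units must not decide the window
    diag = np.diagonal(G_all, axis1=1, axis2=2)
    bad = (diag <= 0).any(axis=1)
    d = np.sqrt(np.where(diag > 0, diag, 1.0))
    scaled = G_all / (d[:, :, None] * d[:, None, :])
    with np.errstate(all="ignore"):
        conds = np.where(bad, np.inf, np.linalg.cond(scaled))
    over = np.nonzero(~np.isfinite(conds) | (conds > cond_cap))[0]
    k_use = int(over[0]) if len(over) else len(event_times)
    t_max = float(event_times[over[0]]) if len(over) else np.inf
    if k_use == 0:
        raise EstimationImpossibleError(
            "at-risk design is singular at the first event time"
        )

    # per-event-time covariate sums of the events (ties processed jointly)
    ev_order = np.nonzero(es == 1)[0]
    ev_t = ts[ev_order]
    asc = np.argsort(ev_t, kind="stable")
    ev_t, ev_X = ev_t[asc], Xs[ev_order][asc]
    starts = np.searchsorted(ev_t, event_times[:k_use], side="left")
    S = np.add.reduceat(ev_X, starts, axis=0)

    incs = np.linalg.solve(G_all[:k_use], S[:, :, None])[:, :, 0]
    used = event_times[:k_use]
    cum = pd.DataFrame(np.cumsum(incs, axis=0), index=used, columns=names)
    cum.index.name = "time"
    fit = SurvivalFit(
        event_times=used,
        cumulative=cum,
        mean_coefficients=pd.Series(dtype=float),
        mode="standard",
        t_max=t_max,
        n_times_used=len(used),
    )
    fit.mean_coefficients = mean_coefficient(fit)
    return fit


def mean_coefficient(fit: SurvivalFit, method: str = "slope") -> pd.Series:
    """Per-covariate time-averaged effect on the hazard (per day).

    ``slope`` (default): least-squares slope of B_k(t) against t over the
    reliable window — robust to early-time noise. ``terminal``: B_k(tau)/tau
    at the last usable event time. Requires at least two event times.
    """
    if fit.n_times_used < 2:
        raise DegenerateInputError("mean coefficient undefined: fewer than 2 event times")
    t = fit.cumulative.index.to_numpy(dtype=float)
    if method == "terminal":
        return fit.cumulative.iloc[-1] / t[-1]
    if method != "slope":
        raise ValueError(f"unknown method {method!r}")
    tc = t - t.mean()
    denom = float(tc @ tc)
    B = fit.cumulative.to_numpy(dtype=float)
    slopes = tc @ (B - B.mean(axis=0)) / denom
    return pd.Series(slopes, index=fit.cumulative.columns)


def aalen_iv_fit(
    times: Sequence[float],
    events: Sequence[int],
    endog: pd.DataFrame,
    exog: Optional[pd.DataFrame],
    instruments: pd.DataFrame,
    add_baseline: bool = True,
    cond_cap: float = COND_CAP,
) -> SurvivalFit:
    """Control-function IV estimator for the additive hazards model.

    Stage 1: linear regression of each endogenous covariate on the
    instruments plus exogenous covariates (per-endogenous joint robust F of
    the excluded instruments is recorded). Stage 2: Aalen fit on
    [endogenous, exogenous, first-stage residuals], the residuals entering
    as ordinary covariates with time-varying effects. The endogenous
    covariates' coefficients are the causal estimates.
    """
    if instruments.shape[1] < endog.shape[1]:
        raise UnderIdentifiedError(
            f"{instruments.shape[1]} instruments for {endog.shape[1]} endogenous covariates"
        )
    W = instruments if exog is None else pd.concat([instruments, exog], axis=1)
    W = _with_const(W, True)
    fs_F: Dict[str, float] = {}
    resid = pd.DataFrame(index=endog.index)
    for col in endog.columns:
        fs = ols(endog[col], W, add_constant=False)
        fs_F[col] = _robust_wald_F(fs, list(instruments.columns))
        r = endog[col] - W.to_numpy(dtype=float) @ fs.params.to_numpy()
        if float(np.std(r)) < 1e-10:
            # perfect first stage: the control function vanishes
            log.info("first-stage residuals for %r are zero; column dropped", col)
            continue
        resid[f"_resid_{col}"] = r
    parts = [endog] if exog is None else [endog, exog]
    X = pd.concat(parts + [resid], axis=1)
    fit = aalen_fit(times, events, X, add_baseline=add_baseline, cond_cap=cond_cap)
    fit.mode = "iv"
    fit.first_stage_F = fs_F
    return fit


def bootstrap_ci(
    fit_fn: Callable[[pd.DataFrame], pd.Series],
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, int]:
    """Case-bootstrap percentile 95% CIs for per-covariate mean coefficients.

    ``fit_fn`` maps a data frame of users to a Series of mean coefficients
    (for IV fits it must re-run the first stage inside each replicate).
    Users are resampled with replacement; replicates whose design turns
    singular are dropped and counted (a warning is emitted above 10%).
    Returns (frame with estimate/lower/upper/significant, n_dropped).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    point = fit_fn(data)
    rng = np.random.default_rng(seed)
    n = len(data)
    reps = []
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = data.iloc[idx].reset_index(drop=True)
        try:
            reps.append(fit_fn(boot))
        except (EstimationImpossibleError, DegenerateInputError, np.linalg.LinAlgError):
            dropped += 1
    if dropped > 0.1 * n_boot:
        warnings.warn(f"{dropped}/{n_boot} bootstrap replicates dropped", stacklevel=2)
    if not reps:
        raise EstimationImpossibleError("all bootstrap replicates failed")
    rep_frame = pd.DataFrame(reps)
    lower = rep_frame.quantile(0.025)
    upper = rep_frame.quantile(0.975)
    out = pd.DataFrame(
        {
            "estimate": point,
            "lower": lower.reindex(point.index),
            "upper": upper.reindex(point.index),
        }
    )
    out["significant"] = (out["lower"] > 0) | (out["upper"] < 0)
    return out, dropped
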