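"""Dropout outcome construction and estimation covariates.

Dropout is observed through posting inactivity between two observation
timestamps obs1 < obs2 (real-valued days). The binary status marks users
whose last post precedes obs1. Survival outcomes are built by interval
censoring: a user is declared dropped out when the silent gap before obs2
exceeds a threshold — a fixed pi (identical censoring) or the per-user
blend lambda*pi + (1-lambda)*I_i with I_i the user's mean inter-post
interval in the first observation window (personalized censoring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError

__all__ = [
    "SurvivalOutcome",
    "dropout_status",
    "censor_identical",
    "censor_personalized",
    "survival_outcomes",
    "tune_censoring",
    "lifetime",
    "mean_posting_interval",
    "sample_survival",
    "compute_covariates",
]


@dataclass(frozen=True)
class SurvivalOutcome:
    """One user's censored dropout outcome.

    ``event`` is 1 when dropout is declared, ``time`` the duration at risk
    in days since obs1, ``scheme`` "identical" or "personalized",
    ``threshold_used`` the gap threshold applied, ``fallback`` True when a
    personalized threshold fell back to the fixed pi (I_i undefined).
    """

    event: int
    time: float
    scheme: str
    threshold_used: float
    fallback: bool = False


def dropout_status(last_post: float, obs1: float) -> int:
    """0 (non-dropout) iff the user posted strictly after obs1, else 1.

    A last post exactly at obs1 counts as dropout (strict inequality)."""
    return 0 if last_post > obs1 else 1


def censor_identical(last_post: float, obs1: float, obs2: float, pi: float) -> SurvivalOutcome:
    """Identical interval censoring with fixed threshold pi (days).

    Dropout is declared when the silent gap obs2 - last_post strictly
    exceeds pi; then the survival time is last_post - obs1 (duration from
    the first observation to the last posting). Otherwise the user is
    censored at the full inter-observation window obs2 - obs1.

    Only valid for survival-sample users (last post after obs1).
    """
    if pi <= 0:
        raise InvalidConfigError("censoring threshold pi must be positive")
    if last_post <= obs1:
        raise ValueError(
            "user is not in the survival sample (last post not after obs1); "
            "filter with sample_survival first"
        )
    if obs2 - last_post > pi:
        return SurvivalOutcome(1, last_post - obs1, "identical", pi)
    return SurvivalOutcome(0, obs2 - obs1, "identical", pi)


def censor_personalized(
    last_post: float,
    obs1: float,
    obs2: float,
    pi: float,
    lam: float,
    mean_interval: Optional[float],
) -> SurvivalOutcome:
    """Personalized interval censoring with threshold lambda*pi + (1-lambda)*I_i.

    ``mean_interval`` is the user's average posting interval I_i in the
    first observation window; when it is undefined (fewer than two posts,
    passed as None/NaN) the threshold falls back to pi and the outcome is
    flagged. With lam = 1 this reduces exactly to identical censoring.
    """
    if not 0.0 <= lam <= 1.0:
        raise InvalidConfigError("lambda must lie in [0, 1]")
    if pi <= 0:
        raise InvalidConfigError("censoring threshold pi must be positive")
    if last_post <= obs1:
        raise ValueError(
            "user is not in the survival sample (last post not after obs1); "
            "filter with sample_survival first"
        )
    fallback = mean_interval is None or (isinstance(mean_interval, float) and np.isnan(mean_interval))
    threshold = pi if fallback else lam * pi + (1.0 - lam) * float(mean_interval)
    if obs2 - last_post > threshold:
        return SurvivalOutcome(1, last_post - obs1, "personalized", threshold, fallback)
    return SurvivalOutcome(0, obs2 - obs1, "personalized", threshold, fallback)


def mean_posting_interval(times: Sequence[float], obs1: float) -> float:
    """Mean inter-post interval I_i over posts at or before obs1.

    (last - first) / (n - 1) over the user's first-window posts; NaN when
    fewer than two such posts exist.
    """
    t = np.sort(np.asarray([x for x in times if x <= obs1], dtype=float))
    if len(t) < 2:
        return float("nan")
    return float((t[-1] - t[0]) / (len(t) - 1))


def survival_outcomes(
    last_post: pd.Series,
    obs1: float,
    obs2: float,
    scheme: str = "identical",
    pi: float = 30.0,
    lam: float = 1.0,
    mean_interval: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Vectorised censoring over a survival sample.

    ``last_post`` is indexed by user_id and must contain only survival-
    sample users (last post after obs1). Returns a DataFrame with columns
    event, time, threshold, fallback.
    """
    lp = last_post.astype(float)
    if (lp <= obs1).any():
        raise ValueError("survival_outcomes received users outside the survival sample")
    if scheme == "identical":
        thr = pd.Series(pi, index=lp.index, dtype=float)
        fallback = pd.Series(False, index=lp.index)
    elif scheme == "personalized":
        if mean_interval is None:
            raise InvalidConfigError("personalized censoring requires mean_interval")
        mi = mean_interval.reindex(lp.index).astype(float)
        fallback = mi.isna()
        thr = lam * pi + (1.0 - lam) * mi
        thr[fallback] = pi
    else:
        raise InvalidConfigError(f"unknown censoring scheme {scheme!r}")
    event = ((obs2 - lp) > thr).astype(int)
    time = np.where(event == 1, lp - obs1, obs2 - obs1)
    return pd.DataFrame(
        {"event": event, "time": time, "threshold": thr, "fallback": fallback},
        index=lp.index,
    )


def tune_censoring(
    last_obs1_post: pd.Series,
    observed_status: pd.Series,
    obs1: float,
    pi_grid: Sequence[float] = (7.0, 14.0, 30.0, 60.0, 90.0, 180.0),
    lambda_grid: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    mean_interval: Optional[pd.Series] = None,
) -> Tuple[float, float, float]:
    """Grid-search (pi, lambda) maximising first-window/second-window agreement.

    For each grid point the censoring rule is applied to first-observation
    activity only: a user is predicted dropped out when the silence before
    obs1 (obs1 - last first-window post) strictly exceeds the threshold.
    The fraction of users whose prediction matches the observed second-
    window dropout status is the agreement; the maximising grid point is
    returned with ties broken toward smaller pi, then larger lambda.
    """
    if len(pi_grid) == 0 or len(lambda_grid) == 0:
        raise InvalidConfigError("tuning grids must be non-empty")
    obs = observed_status.astype(int)
    if obs.nunique() < 2:
        warnings.warn("observed dropout statuses are constant; agreement is degenerate",
                      stacklevel=2)
    gap = (obs1 - last_obs1_post.reindex(obs.index)).astype(float)
    if mean_interval is not None:
        mi = mean_interval.reindex(obs.index).astype(float)
    else:
        mi = pd.Series(np.nan, index=obs.index)
    best: Tuple[float, float, float] | None = None
    for pi in pi_grid:
        for lam in lambda_grid:
            thr = lam * pi + (1.0 - lam) * mi
            thr = thr.fillna(pi)
            pred = (gap > thr).astype(int)
            agreement = float((pred == obs).mean())
            key = (agreement, -pi, lam)
            if best is None or key > (best[2], -best[0], best[1]):
                best = (float(pi), float(lam), agreement)
    return best


def lifetime(created_at: float | pd.Series, last_post: float | pd.Series):
    """Days from account creation to the last posting."""
    return last_post - created_at


def sample_survival(last_post: pd.Series, obs1: float) -> pd.Index:
    """User ids active past the first observation (last post strictly after obs1)."""
    lp = last_post.astype(float)
    return lp.index[lp > obs1]


def compute_covariates(
    users: pd.DataFrame,
    last_post: pd.Series,
    last_obs1_post: pd.Series,
    n_tweets_in_use: pd.Series,
    n_followees_used: pd.Series,
    followee_sets_map: Mapping[object, Iterable[object]],
    obs1: float,
    obs2: float,
) -> pd.DataFrame:
    """Estimation covariates for every user in ``users``.

    ``users`` is indexed by user_id with columns created_at, n_followees,
    n_posts, n_followers (profile counts). ``last_obs1_post`` is the last
    post at or before obs1 (NaN when none). Social-capital counts come from
    the profile; activity rates divide them by active days (creation to the
    last first-window posting); users with zero active days get missing
    rates and are flagged via NaN. The alternative-channel controls
    (pct_active_followees, avg_duration_followees) are computed over the
    instrument followee set using all users' last posts.
    """
    idx = users.index
    created = users["created_at"].astype(float)
    active_days = (last_obs1_post.reindex(idx) - created).astype(float)
    active_days[active_days < 0] = np.nan

    cov = pd.DataFrame(index=idx)
    cov["n_followees"] = users["n_followees"].astype(float)
    cov["n_posts"] = users["n_posts"].astype(float)
    cov["n_followers"] = users["n_followers"].astype(float)
    cov["active_days"] = active_days
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = active_days.where(active_days > 0)
        cov["followees_per_day"] = cov["n_followees"] / denom
        cov["posts_per_day"] = cov["n_posts"] / denom
        cov["followers_per_day"] = cov["n_followers"] / denom
    cov["n_tweets_in_use"] = n_tweets_in_use.reindex(idx).astype(float)
    cov["n_followees_in_use"] = n_followees_used.reindex(idx).astype(float)

    lp_all = last_post
    pct_active, avg_dur = {}, {}
    for uid in idx:
        fset = list(followee_sets_map.get(uid, ()))
        if not fset:
            pct_active[uid] = np.nan
            avg_dur[uid] = np.nan
            continue
        flp = lp_all.reindex(fset).dropna()
        if flp.empty:
            pct_active[uid] = np.nan
            avg_dur[uid] = np.nan
            continue
        pct_active[uid] = float((flp > obs1).mean())
        avg_dur[uid] = float(np.clip(np.minimum(flp, obs2) - obs1, 0.0, None).mean())
    cov["pct_active_followees"] = pd.Series(pct_active)
    cov["avg_duration_followees"] = pd.Series(avg_dur)
    return cov
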