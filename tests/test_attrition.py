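"""Dropout encoding, interval censoring, threshold tuning, covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from attrical.attrition import (
    censor_identical,
    censor_personalized,
    compute_covariates,
    dropout_status,
    lifetime,
    mean_posting_interval,
    sample_survival,
    survival_outcomes,
    tune_censoring,
)
from attrical.exceptions import InvalidConfigError


class TestDropoutStatus:
    def test_encoding_rule(self):
        assert dropout_status(last_post=200.0, obs1=180.0) == 0
        assert dropout_status(last_post=100.0, obs1=180.0) == 1
        # boundary: a last post exactly at obs1 counts as dropout
        assert dropout_status(last_post=180.0, obs1=180.0) == 1


class TestIdenticalCensoring:
    def test_gap_exactly_pi_is_censored(self):
        out = censor_identical(last_post=700.0, obs1=180.0, obs2=730.0, pi=30.0)
        assert out.event == 0 and out.time == pytest.approx(550.0)

    def test_event_time_is_duration_to_last_post(self):
        out = censor_identical(last_post=210.0, obs1=180.0, obs2=730.0, pi=30.0)
        assert out.event == 1 and out.time == pytest.approx(30.0)

    def test_posting_to_obs2_censored_at_full_window(self):
        out = censor_identical(last_post=730.0, obs1=180.0, obs2=730.0, pi=30.0)
        assert out.event == 0 and out.time == pytest.approx(550.0)

    def test_outside_survival_sample_rejected(self):
        with pytest.raises(ValueError):
            censor_identical(last_post=100.0, obs1=180.0, obs2=730.0, pi=30.0)


class TestPersonalizedCensoring:
    def test_threshold_blend_arithmetic(self):
        # pi = 10, lambda = 0.5, I_i = 2 -> threshold 6
        out = censor_personalized(last_post=723.0, obs1=180.0, obs2=730.0,
                                  pi=10.0, lam=0.5, mean_interval=2.0)
        assert out.threshold_used == pytest.approx(6.0)
        assert out.event == 1  # gap 7 > 6

    def test_lambda_zero_uses_personal_interval(self):
        out = censor_personalized(725.0, 180.0, 730.0, pi=10.0, lam=0.0, mean_interval=2.0)
        assert out.threshold_used == pytest.approx(2.0)

    def test_undefined_interval_falls_back_flagged(self):
        out = censor_personalized(725.0, 180.0, 730.0, pi=10.0, lam=0.3,
                                  mean_interval=float("nan"))
        assert out.fallback and out.threshold_used == pytest.approx(10.0)

    @given(
        st.floats(180.5, 729.5), st.floats(1.0, 120.0), st.floats(0.1, 90.0)
    )
    def test_lambda_one_equals_identical(self, last_post, pi, interval):
        a = censor_identical(last_post, 180.0, 730.0, pi)
        b = censor_personalized(last_post, 180.0, 730.0, pi, 1.0, interval)
        assert (a.event, a.time) == (b.event, b.time)

    def test_vectorised_lambda_one_bitwise_identical(self):
        rng = np.random.default_rng(5)
        lp = pd.Series(rng.uniform(181, 730, size=300))
        mi = pd.Series(rng.uniform(0.2, 50, size=300))
        a = survival_outcomes(lp, 180.0, 730.0, scheme="identical", pi=30.0)
        b = survival_outcomes(lp, 180.0, 730.0, scheme="personalized", pi=30.0,
                              lam=1.0, mean_interval=mi)
        assert (a["event"] == b["event"]).all()
        assert (a["time"] == b["time"]).all()

    def test_event_implies_shorter_than_window(self):
        rng = np.random.default_rng(6)
        lp = pd.Series(rng.uniform(181, 730, size=500))
        out = survival_outcomes(lp, 180.0, 730.0, pi=14.0)
        ev = out["event"] == 1
        assert (out.loc[ev, "time"] < 550.0).all()
        assert (out.loc[~ev, "time"] == 550.0).all()


class TestTuneCensoring:
    def _toy(self):
        last_obs1 = pd.Series({1: 160.0, 2: 100.0, 3: 179.0, 4: 60.0})
        observed = pd.Series({1: 0, 2: 1, 3: 0, 4: 1})
        return last_obs1, observed

    def test_perfect_grid_point_found(self):
        last_obs1, observed = self._toy()
        pi, lam, agreement = tune_censoring(last_obs1, observed, obs1=180.0,
                                            pi_grid=[7.0, 30.0], lambda_grid=[1.0])
        assert agreement == 1.0 and pi == 30.0

    def test_matches_exhaustive_grid_maximum(self):
        rng = np.random.default_rng(2)
        last_obs1 = pd.Series(rng.uniform(0, 180, size=200))
        observed = pd.Series((rng.uniform(size=200) < 0.5).astype(int),
                             index=last_obs1.index)
        mi = pd.Series(rng.uniform(0.5, 40, size=200), index=last_obs1.index)
        grid_pi = [7.0, 14.0, 30.0, 90.0]
        grid_lam = [0.0, 0.5, 1.0]
        pi, lam, agreement = tune_censoring(last_obs1, observed, 180.0,
                                            grid_pi, grid_lam, mean_interval=mi)
        best = -1.0
        for p in grid_pi:
            for l in grid_lam:
                thr = (l * p + (1 - l) * mi).fillna(p)
                pred = ((180.0 - last_obs1) > thr).astype(int)
                best = max(best, float((pred == observed).mean()))
        assert agreement == pytest.approx(best)

    def test_single_point_grid_returned(self):
        last_obs1, observed = self._toy()
        pi, lam, _ = tune_censoring(last_obs1, observed, 180.0, [42.0], [0.25])
        assert (pi, lam) == (42.0, 0.25)

    def test_constant_statuses_warn(self):
        last_obs1, _ = self._toy()
        const = pd.Series(1, index=last_obs1.index)
        with pytest.warns(UserWarning):
            tune_censoring(last_obs1, const, 180.0, [30.0], [1.0])

    def test_empty_grid_rejected(self):
        last_obs1, observed = self._toy()
        with pytest.raises(InvalidConfigError):
            tune_censoring(last_obs1, observed, 180.0, [], [1.0])


class TestLifetimeAndSample:
    def test_lifetime_subtraction(self):
        assert lifetime(0.0, 182.0) == pytest.approx(182.0)
        assert lifetime(50.0, 50.0) == 0.0

    def test_mean_posting_interval(self):
        assert mean_posting_interval([0.0, 2.0, 10.0], obs1=180.0) == pytest.approx(5.0)
        assert np.isnan(mean_posting_interval([5.0], obs1=180.0))
        # posts after obs1 excluded from the first-window interval
        assert mean_posting_interval([0.0, 10.0, 500.0], obs1=180.0) == pytest.approx(10.0)

    def test_sample_survival_rule(self):
        lp = pd.Series({1: 250.0, 2: 100.0, 3: 180.0})
        assert list(sample_survival(lp, 180.0)) == [1]
        assert len(sample_survival(pd.Series(dtype=float), 180.0)) == 0


class TestCovariates:
    def test_covariate_arithmetic(self):
        users = pd.DataFrame(
            {"created_at": [0.0], "n_followees": [100], "n_posts": [25], "n_followers": [10]},
            index=pd.Index([1], name="user_id"),
        )
        last_post = pd.Series({1: 60.0, 2: 400.0, 3: 190.0})
        cov = compute_covariates(
            users,
            last_post=last_post,
            last_obs1_post=pd.Series({1: 50.0}),
            n_tweets_in_use=pd.Series({1: 20}),
            n_followees_used=pd.Series({1: 2}),
            followee_sets_map={1: [2, 3]},
            obs1=180.0,
            obs2=730.0,
        )
        row = cov.loc[1]
        assert row["followees_per_day"] == pytest.approx(2.0)  # 100 over 50 days
        assert row["pct_active_followees"] == pytest.approx(1.0)  # both active past obs1
        # followee durations: 400-180=220 and 190-180=10 -> mean 115
        assert row["avg_duration_followees"] == pytest.approx(115.0)

    def test_zero_active_days_flagged_missing(self):
        users = pd.DataFrame(
            {"created_at": [10.0], "n_followees": [5], "n_posts": [1], "n_followers": [0]},
            index=pd.Index([1], name="user_id"),
        )
        cov = compute_covariates(
            users, pd.Series({1: 10.0}), pd.Series({1: 10.0}),
            pd.Series({1: 1}), pd.Series({1: 0}), {1: []}, 180.0, 730.0,
        )
        assert np.isnan(cov.loc[1, "posts_per_day"])
        assert np.isnan(cov.loc[1, "pct_active_followees"])
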