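"""End-to-end orchestration: simulate (or load) -> measure -> censor ->
estimate -> report.

The filter chain mirrors the sampling logic of the underlying study
design: the eligibility filter (enough original tweets and words to score
emotions) defines the linear estimation sample; the survival sample keeps
users active past the first observation; the single-way sample
additionally requires a non-empty single-way followee set. Every stage
logs its input and output sizes and the run manifest records them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import attrition, graphs, interests, linear, sentiment, survival
from .exceptions import MissingInputError
from .lexicon import DEFAULT_LEXICON, Lexicon
from .simulate import CommunityPanel, SimulationConfig, simulate_panel

__all__ = [
    "COVARIATES",
    "RunManifest",
    "measure",
    "estimation_table",
    "linear_estimates",
    "survival_estimates",
    "interests_analysis",
    "homophily_analysis",
    "run_pipeline",
]

log = logging.getLogger(__name__)

# Estimation covariates: social capital, activity level, observational
# bias, and the alternative-channel controls.
COVARIATES = [
    "n_followees",
    "n_posts",
    "n_followers",
    "active_days",
    "followees_per_day",
    "posts_per_day",
    "followers_per_day",
    "n_tweets_in_use",
    "n_followees_in_use",
    "pct_active_followees",
    "avg_duration_followees",
]


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    sample_sizes: Dict[str, int] = field(default_factory=dict)
    tuned_censoring: Optional[Dict[str, float]] = None
    outputs: Dict[str, str] = field(default_factory=dict)
    wall_times: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def measure(panel: CommunityPanel, lexicon: Lexicon = DEFAULT_LEXICON) -> pd.DataFrame:
    """Per-user measurements observable at the two observation times.

    Returns a frame indexed by user_id with measured emotion, the number
    of tweets used, in-coreness centrality, last post timestamps (overall
    and within the first window), mean first-window posting interval,
    lifetime, the binary dropout status, and the eligibility flag.
    """
    emo = sentiment.measure_emotions(panel.posts, lexicon)
    eligible = sentiment.eligibility_filter(panel.posts)
    out = pd.DataFrame(index=panel.users.index)
    out["emotion"] = emo["emotion"].reindex(out.index)
    out["n_tweets_in_use"] = emo["n_tweets_in_use"].reindex(out.index).fillna(0).astype(int)
    out["centrality"] = graphs.in_coreness(panel.graph).reindex(out.index)
    out["last_post"] = panel.last_post()
    out["last_obs1_post"] = panel.last_post_before(panel.obs1_time)
    mi = {
        uid: attrition.mean_posting_interval(sub["timestamp"].to_numpy(), panel.obs1_time)
        for uid, sub in panel.posts.groupby("user_id")
    }
    out["mean_interval"] = pd.Series(mi).reindex(out.index)
    out["lifetime"] = attrition.lifetime(panel.users["created_at"], out["last_post"])
    out["status"] = (~(out["last_post"] > panel.obs1_time)).astype(int)  # NaN last post -> dropout
    out["eligible"] = out.index.isin(eligible)
    log.info("measure: %d users, %d eligible", len(out), int(out["eligible"].sum()))
    return out


def estimation_table(
    panel: CommunityPanel,
    meas: pd.DataFrame,
    single_way: bool = False,
) -> pd.DataFrame:
    """Assemble outcome, regressors and instruments for the eligible sample.

    Instruments are followee means of the *measured* emotion and
    centrality (all followees or single-way per the flag); covariates
    follow the estimation covariate list. Rows are eligible users with a
    complete case over outcome, emotion, instruments and covariates.
    """
    attrs = meas[["emotion", "centrality"]]
    inst = graphs.build_instruments(panel.graph, attrs, single_way=single_way)
    fsets = graphs.followee_sets(panel.graph, single_way=single_way)
    cov = attrition.compute_covariates(
        panel.users,
        last_post=meas["last_post"],
        last_obs1_post=meas["last_obs1_post"],
        n_tweets_in_use=meas["n_tweets_in_use"],
        n_followees_used=inst.table["n_followees_used"],
        followee_sets_map=fsets,
        obs1=panel.obs1_time,
        obs2=panel.obs2_time,
    )
    table = pd.concat(
        [
            meas[["status", "emotion", "centrality", "last_post", "mean_interval"]],
            cov,
            inst.table[["followee_mean_emotion", "followee_mean_centrality"]],
        ],
        axis=1,
    )
    table = table.loc[meas["eligible"]]
    # users with an empty (single-way) followee set are excluded
    usable = inst.usable
    table = table.loc[table.index.isin(usable)]
    needed = ["status", "emotion", "followee_mean_emotion", "followee_mean_centrality"] + COVARIATES
    table = linear.listwise_complete(table, needed)
    log.info("estimation_table(single_way=%s): n=%d", single_way, len(table))
    return table


def linear_estimates(
    table: pd.DataFrame, instrument_cols: Tuple[str, ...] = ("followee_mean_emotion",)
) -> Dict[str, linear.EstimationResult]:
    """OLS and 2SLS of dropout status on emotion plus covariates.

    Centrality is excluded from the linear model: for users who dropped
    out long before the first observation, the network measured later
    would explain dropouts in the past. The 2SLS result carries the
    first-stage F and the Wu-Hausman test.
    """
    y = table["status"].astype(float)
    exog = table[COVARIATES]
    res_ols = linear.ols(y, pd.concat([table[["emotion"]], exog], axis=1))
    res_tsls = linear.two_sls(
        y, table[["emotion"]], exog, table[list(instrument_cols)]
    )
    return {"ols": res_ols, "tsls": res_tsls}


def survival_estimates(
    panel: CommunityPanel,
    meas: pd.DataFrame,
    table: pd.DataFrame,
    scheme: str = "identical",
    pi: float = 30.0,
    lam: float = 0.5,
    n_boot: int = 0,
    seed: Optional[int] = None,
) -> Dict[str, object]:
    """Kaplan-Meier plus standard and IV Aalen fits on the survival sample.

    The survival sample keeps users active past the first observation.
    Both emotion and centrality enter as endogenous covariates,
    instrumented by their followee means (two instruments, joint
    first-stage F recorded). ``n_boot`` > 0 adds case-bootstrap 95% CIs
    for the mean coefficients of both fits.
    """
    surv_ids = attrition.sample_survival(meas["last_post"].dropna(), panel.obs1_time)
    sub = table.loc[table.index.isin(surv_ids)].copy()
    out = attrition.survival_outcomes(
        sub["last_post"], panel.obs1_time, panel.obs2_time,
        scheme=scheme, pi=pi, lam=lam, mean_interval=sub["mean_interval"],
    )
    sub["time"], sub["event"] = out["time"], out["event"]
    log.info("survival sample (%s): n=%d, events=%d", scheme, len(sub), int(out["event"].sum()))

    km = survival.kaplan_meier(out["time"], out["event"])

    endog_cols = ["emotion", "centrality"]
    inst_cols = ["followee_mean_emotion", "followee_mean_centrality"]

    def _standard(df: pd.DataFrame) -> pd.Series:
        fit = survival.aalen_fit(df["time"], df["event"], df[endog_cols + COVARIATES])
        return survival.mean_coefficient(fit)

    def _iv(df: pd.DataFrame) -> pd.Series:
        fit = survival.aalen_iv_fit(
            df["time"], df["event"], df[endog_cols], df[COVARIATES], df[inst_cols]
        )
        return survival.mean_coefficient(fit)

    std_fit = survival.aalen_fit(sub["time"], sub["event"], sub[endog_cols + COVARIATES])
    iv_fit = survival.aalen_iv_fit(
        sub["time"], sub["event"], sub[endog_cols], sub[COVARIATES], sub[inst_cols]
    )
    result: Dict[str, object] = {
        "km": km,
        "standard": std_fit,
        "iv": iv_fit,
        "n": len(sub),
        "n_events": int(out["event"].sum()),
    }
    if n_boot:
        rng = np.random.SeedSequence(seed)
        s1, s2 = rng.spawn(2)
        ci_std, _ = survival.bootstrap_ci(_standard, sub, n_boot=n_boot,
                                          seed=int(s1.generate_state(1)[0] % 2**31))
        ci_iv, _ = survival.bootstrap_ci(_iv, sub, n_boot=n_boot,
                                         seed=int(s2.generate_state(1)[0] % 2**31))
        std_fit.ci_95, std_fit.n_boot = ci_std, n_boot
        iv_fit.ci_95, iv_fit.n_boot = ci_iv, n_boot
    return result


def interests_analysis(panel: CommunityPanel, meas: pd.DataFrame) -> pd.DataFrame:
    """Table of Spearman correlations: dropout states x emotion terciles.

    Groups eligible users by measured dropout state and, separately, by
    measured-emotion terciles; builds TF-IDF hashtag profiles over all
    five corpora jointly and correlates each dropout-state profile with
    each tercile profile over union vocabularies.
    """
    eligible = meas.loc[meas["eligible"]]
    terciles = interests.emotion_terciles(eligible["emotion"])
    posts = panel.posts[panel.posts["user_id"].isin(eligible.index)]
    tags_by_user = posts.groupby("user_id")["hashtags"].apply(
        lambda col: [t for tags in col for t in tags]
    )

    def corpus(ids) -> list:
        return [t for uid in ids if uid in tags_by_user.index for t in tags_by_user[uid]]

    corpora = {}
    for label in ("nondropout", "dropout"):
        want = 0 if label == "nondropout" else 1
        corpora[label] = corpus(eligible.index[eligible["status"] == want])
    for label in interests.TERCILE_LABELS:
        corpora[label] = corpus(terciles.index[terciles == label])
    profiles = interests.build_profiles(corpora)
    rows = {k: profiles[k] for k in ("nondropout", "dropout")}
    cols = {k: profiles[k] for k in interests.TERCILE_LABELS}
    return interests.correlation_matrix(rows, cols)


def homophily_analysis(
    panel: CommunityPanel, meas: pd.DataFrame, n_perm: int = 1000, seed: Optional[int] = None
) -> Dict[str, float]:
    """Newman assortativity of the follow graph by dropout state, with
    permutation z and p."""
    labels = meas["status"].astype(int).to_dict()
    r = graphs.newman_assortativity(panel.graph, labels)
    z, p = graphs.assortativity_null_z(panel.graph, labels, n_perm=n_perm, seed=seed)
    return {"r": r, "z": z, "p": p}


def run_pipeline(
    config: SimulationConfig,
    out_dir: Optional[str | Path] = None,
    panel: Optional[CommunityPanel] = None,
    n_boot: int = 0,
    pi: float = 30.0,
    lam: float = 0.5,
    tune: bool = False,
    n_perm: int = 1000,
) -> Tuple[RunManifest, Dict[str, object]]:
    """Full run: simulate (unless a panel is given), measure, censor,
    estimate linear and survival models under both instrument modes and
    both censoring schemes, profile interests, test homophily, and write
    all tables plus the manifest when ``out_dir`` is given.
    """
    cfg_yaml = yaml.safe_dump(
        {k: v for k, v in config.__dict__.items()}, sort_keys=True, default_flow_style=True
    )
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16], seed=config.seed
    )
    results: Dict[str, object] = {}
    t0 = time.perf_counter()
    if panel is None:
        panel = simulate_panel(config)
    manifest.wall_times["simulate"] = time.perf_counter() - t0
    manifest.sample_sizes["users"] = len(panel.users)
    manifest.sample_sizes["posts"] = len(panel.posts)

    t0 = time.perf_counter()
    meas = measure(panel)
    manifest.wall_times["measure"] = time.perf_counter() - t0
    manifest.sample_sizes["eligible"] = int(meas["eligible"].sum())
    results["measurements"] = meas

    if tune:
        pi_star, lam_star, agreement = attrition.tune_censoring(
            meas["last_obs1_post"], meas["status"], panel.obs1_time,
            mean_interval=meas["mean_interval"],
        )
        pi, lam = pi_star, lam_star
        manifest.tuned_censoring = {"pi": pi, "lambda": lam, "agreement": agreement}

    tables = {}
    for mode, single_way in (("all", False), ("single_way", True)):
        tables[mode] = estimation_table(panel, meas, single_way=single_way)
        manifest.sample_sizes[f"linear_{mode}"] = len(tables[mode])
    results["tables"] = tables

    t0 = time.perf_counter()
    lin = {mode: linear_estimates(tables[mode]) for mode in tables}
    # cross-specification equality of the emotion effect (analytic, the
    # paired-bootstrap variant is available via linear.wald_equality)
    lin["wald_equality_emotion"] = linear.wald_equality_analytic(
        lin["all"]["tsls"], lin["single_way"]["tsls"], "emotion"
    )
    manifest.wall_times["linear"] = time.perf_counter() - t0
    results["linear"] = lin

    t0 = time.perf_counter()
    surv = {}
    for scheme in ("identical", "personalized"):
        for mode in ("all", "single_way"):
            key = f"{scheme}_{mode}"
            surv[key] = survival_estimates(
                panel, meas, tables[mode], scheme=scheme, pi=pi, lam=lam,
                n_boot=n_boot, seed=config.seed + 1,
            )
            manifest.sample_sizes[f"survival_{key}"] = surv[key]["n"]
    manifest.wall_times["survival"] = time.perf_counter() - t0
    results["survival"] = surv

    # lifetime KM over all eligible users (account creation to last post)
    eligible = meas.loc[meas["eligible"]]
    life = eligible["lifetime"].dropna()
    results["km_lifetime"] = survival.kaplan_meier(life, np.ones(len(life), dtype=int))

    t0 = time.perf_counter()
    results["interests"] = interests_analysis(panel, meas)
    results["homophily"] = homophily_analysis(
        panel, meas, n_perm=n_perm, seed=config.seed + 2
    )
    manifest.wall_times["interests"] = time.perf_counter() - t0

    if out_dir is not None:
        _write_outputs(Path(out_dir), panel, results, manifest, lin, surv)
    return manifest, results


def _write_outputs(out, panel, results, manifest, lin, surv) -> None:
    out.mkdir(parents=True, exist_ok=True)

    def register(name: str, path: Path) -> None:
        manifest.outputs[name] = str(path)

    meas_path = out / "measurements.csv"
    results["measurements"].to_csv(meas_path)
    register("measurements", meas_path)

    rows = []
    for mode in ("all", "single_way"):
        for est in ("ols", "tsls"):
            r = lin[mode][est]
            frame = r.summary_frame()
            frame.insert(0, "estimator", est)
            frame.insert(0, "instruments", mode)
            frame["n"] = r.n_obs
            rows.append(frame.reset_index(names="variable"))
    lin_path = out / "linear_results.csv"
    pd.concat(rows).to_csv(lin_path, index=False)
    register("linear_results", lin_path)

    diag = {
        mode: {
            "first_stage_F": lin[mode]["tsls"].first_stage_F,
            "wu_hausman": lin[mode]["tsls"].wu_hausman,
            "n": lin[mode]["tsls"].n_obs,
        }
        for mode in ("all", "single_way")
    }
    diag["wald_equality_emotion"] = results["linear"]["wald_equality_emotion"]
    diag_path = out / "linear_diagnostics.json"
    diag_path.write_text(json.dumps(diag, indent=2))
    register("linear_diagnostics", diag_path)

    srows, crows = [], []
    for key, res in surv.items():
        for kind in ("standard", "iv"):
            fit = res[kind]
            for var in ("emotion", "centrality"):
                row = {
                    "model": key, "kind": kind, "variable": var,
                    "mean_coefficient": float(fit.mean_coefficients[var]),
                    "n": res["n"], "n_events": res["n_events"],
                }
                if fit.ci_95 is not None:
                    row["ci_lower"] = float(fit.ci_95.loc[var, "lower"])
                    row["ci_upper"] = float(fit.ci_95.loc[var, "upper"])
                srows.append(row)
            cum = fit.cumulative.reset_index().melt(
                id_vars="time", var_name="covariate", value_name="estimate"
            )
            cum.insert(0, "model", key)
            cum.insert(1, "kind", kind)
            crows.append(cum)
    surv_path = out / "survival_summary.csv"
    pd.DataFrame(srows).to_csv(surv_path, index=False)
    register("survival_summary", surv_path)
    cum_path = out / "cumulative_coefficients.tsv"
    pd.concat(crows).to_csv(cum_path, sep="\t", index=False)
    register("cumulative_coefficients", cum_path)

    inter_path = out / "interests_correlations.csv"
    results["interests"].map(
        lambda t: t if not isinstance(t, tuple) else round(t[0], 4)
    ).to_csv(inter_path)
    register("interests_correlations", inter_path)

    extra = {
        "homophily": results["homophily"],
        "km_median_lifetime_days": results["km_lifetime"].median,
    }
    extra_path = out / "descriptives.json"
    extra_path.write_text(json.dumps(extra, indent=2))
    register("descriptives", extra_path)

    manifest_path = out / "manifest.json"
    manifest.to_json(manifest_path)
    register("manifest", manifest_path)
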