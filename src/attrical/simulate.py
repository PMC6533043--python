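"""Synthetic community generator.

Generates directed follow networks with plantable homophily, peer-coupled
user emotions with an unobserved confounder (so emotion is endogenous for
dropout), additive-hazard dropout times, Poisson posting streams truncated
at dropout, lexicon-emitted post tokens whose sentiment tracks the user's
true emotion, and topic-conditioned hashtags. Everything downstream of the
generator sees only what an observational study would see (edges, posts,
profile counts, two observation timestamps); the true confounder, emotion
and dropout time are retained in a separate truth table for recovery
tests.

Causal structure planted by construction: followee attributes reach a
user's dropout only through the user's own emotion (the peer-influence
channel that makes followee means relevant instruments) and through the
followees' own dropout times (the alternative channel the covariates
control) — never directly, so the exclusion restriction holds.

Two small test-bed data sets for the estimators are also provided:
``linear_iv_dataset`` (linear outcome, network-built instrument) and
``hazard_iv_dataset`` (additive-hazard outcome, scalar instrument), both
with known true effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidConfigError
from .graphs import FollowGraph, in_coreness
from .interests import emotion_terciles
from .lexicon import DEFAULT_LEXICON, Lexicon

__all__ = [
    "SimulationConfig",
    "CommunityPanel",
    "default_topic_params",
    "generate_follow_graph",
    "generate_traits",
    "generate_activity",
    "generate_hashtags",
    "simulate_panel",
    "linear_iv_dataset",
    "hazard_iv_dataset",
]

log = logging.getLogger(__name__)

# neutral filler vocabulary; deliberately disjoint from the default lexicon
FILLER_TOKENS = (
    "today", "day", "feeling", "just", "really", "time", "want",
    "going", "think", "know", "still", "much", "people", "thing",
)


def default_topic_params() -> Dict[str, Dict[str, float]]:
    """Default per-group hashtag distributions.

    Disjoint topic supports; the negative-emotion tercile shares its topic
    with the nondropout group and the positive tercile with the dropout
    group, so matched groups have matched posting interests.
    """
    body_focus = {"thinideal": 0.3, "weightgoal": 0.3, "fastday": 0.2, "bodycheck": 0.2}
    recovery = {"recoveryjourney": 0.3, "selfcare": 0.3, "staystrong": 0.2, "healthyday": 0.2}
    everyday = {"daily": 0.3, "mood": 0.3, "life": 0.2, "random": 0.2}
    return {
        "negative": dict(body_focus),
        "neutral": dict(everyday),
        "positive": dict(recovery),
        "nondropout": dict(body_focus),
        "dropout": dict(recovery),
    }


@dataclass
class SimulationConfig:
    """All knobs of the community generator. Identical config + seed gives a
    bit-identical panel.

    Rates are per day, times are days since simulation start, emotions live
    on [-4, 4]. ``mean_out_degree`` draws Poisson out-degrees; setting
    ``edge_density`` instead fixes every out-degree to
    round(density * (n-1)).
    """

    n_users: int = 2000
    mean_out_degree: float = 12.0
    edge_density: Optional[float] = None
    homophily_strength: float = 2.0  # same-group edge weight multiplier is 1 + this
    group_emotion_shift: float = 0.7  # latent group shifts baseline emotion by +/- this
    engagement_sigma: float = 1.2  # lognormal dispersion of the engagement trait
    out_degree_sigma: float = 0.25  # extra out-degree noise beyond engagement
    degree_assortativity: float = 1.0  # engaged users preferentially follow engaged users

    peer_weight: float = 0.7  # coefficient of followee-mean emotion (instrument relevance)
    confounder_sd: float = 1.0
    confounder_loading: float = 0.8  # confounder weight inside emotion
    emotion_noise_sd: float = 0.6

    # linear-probability dropout mechanism (used when binary_mechanism="linear")
    binary_intercept: float = 0.5
    beta_emotion: float = 0.08
    beta_centrality: float = 0.0
    gamma_linear: float = -0.05
    binary_mechanism: str = "hazard"  # "hazard": binary dropout = dropout time < obs2

    # additive-hazard dropout mechanism (per day)
    hazard_baseline: float = 0.010
    hazard_emotion: float = 0.003
    hazard_centrality: float = -0.0003
    hazard_confounder: float = -0.004

    posting_rate_mean: float = 0.2  # posts per day
    posting_rate_sigma: float = 0.5  # lognormal dispersion of per-user rates
    retweet_prob: float = 0.15
    tokens_per_post_mean: float = 7.0
    post_sentiment_sd: float = 1.0  # noise of per-post sentiment around true emotion
    hashtag_rate: float = 0.4  # expected hashtags per post

    creation_max_time: float = 90.0  # accounts created uniformly in [0, this]
    obs1_time: float = 180.0
    obs2_time: float = 730.0

    topic_params: Dict[str, Dict[str, float]] = field(default_factory=default_topic_params)
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 2:
            raise InvalidConfigError("n_users must be at least 2")
        if not self.obs1_time < self.obs2_time:
            raise InvalidConfigError("obs1_time must precede obs2_time")
        for name in ("mean_out_degree", "posting_rate_mean", "hazard_baseline",
                     "hashtag_rate", "tokens_per_post_mean", "confounder_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")
        if self.edge_density is not None and not 0 <= self.edge_density <= 1:
            raise InvalidConfigError("edge_density must lie in [0, 1]")
        if not self.topic_params:
            raise InvalidConfigError("topic_params must be non-empty")
        if self.binary_mechanism not in ("hazard", "linear"):
            raise InvalidConfigError("binary_mechanism must be 'hazard' or 'linear'")

    # --- I/O -------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class CommunityPanel:
    """Users, posts, follow edges and observation timestamps for one run.

    ``users`` is indexed by user_id with created_at and profile counts;
    ``posts`` has one row per post (user_id, timestamp, tokens, hashtags,
    is_retweet), sorted by user then time; ``truth`` retains the hidden
    confounder, true emotion and true dropout time of simulated panels.
    """

    users: pd.DataFrame
    graph: FollowGraph
    posts: pd.DataFrame
    obs1_time: float
    obs2_time: float
    truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not self.posts.empty:
            joined = self.posts.merge(
                self.users[["created_at"]], left_on="user_id", right_index=True
            )
            if (joined["timestamp"] < joined["created_at"] - 1e-9).any():
                raise InvalidConfigError("post before account creation")
            if (self.posts["timestamp"] > self.obs2_time + 1e-9).any():
                raise InvalidConfigError("post after the second observation")
            if (self.posts.groupby("user_id")["timestamp"].diff().dropna() < 0).any():
                raise InvalidConfigError("per-user post stream is not time-ordered")

    def last_post(self) -> pd.Series:
        """Last post timestamp per user (NaN for users who never posted)."""
        lp = self.posts.groupby("user_id")["timestamp"].max()
        return lp.reindex(self.users.index)

    def last_post_before(self, t: float) -> pd.Series:
        sub = self.posts.loc[self.posts["timestamp"] <= t]
        return sub.groupby("user_id")["timestamp"].max().reindex(self.users.index)

    # --- serialization ---------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.users.to_csv(path / "users.csv")
        self.graph.to_tsv(path / "edges.tsv")
        with open(path / "posts.jsonl", "w") as fh:
            for row in self.posts.itertuples(index=False):
                fh.write(json.dumps({
                    "user_id": int(row.user_id),
                    "timestamp": float(row.timestamp),
                    "tokens": list(row.tokens),
                    "hashtags": list(row.hashtags),
                    "is_retweet": bool(row.is_retweet),
                }) + "\n")
        meta = {"obs1_time": self.obs1_time, "obs2_time": self.obs2_time}
        (path / "meta.json").write_text(json.dumps(meta))
        if self.truth is not None:
            self.truth.to_csv(path / "truth.csv")

    @classmethod
    def from_dir(cls, path: str | Path) -> "CommunityPanel":
        path = Path(path)
        users = pd.read_csv(path / "users.csv", index_col="user_id")
        graph = FollowGraph.from_tsv(path / "edges.tsv", nodes=users.index)
        records = [json.loads(line) for line in (path / "posts.jsonl").read_text().splitlines()]
        posts = pd.DataFrame(
            records, columns=["user_id", "timestamp", "tokens", "hashtags", "is_retweet"]
        )
        meta = json.loads((path / "meta.json").read_text())
        truth = None
        if (path / "truth.csv").exists():
            truth = pd.read_csv(path / "truth.csv", index_col="user_id")
        return cls(users, graph, posts, meta["obs1_time"], meta["obs2_time"], truth)


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def generate_follow_graph(
    config: SimulationConfig,
    rng: np.random.Generator,
    groups: Optional[np.ndarray] = None,
) -> FollowGraph:
    """Directed follow graph with plantable same-group assortativity.

    Each user follows a set of targets chosen with weight 1 for cross-group
    and 1 + homophily_strength for same-group candidates (Gumbel top-k
    sampling without replacement); with homophily_strength = 0 the edge
    probability is independent of the latent groups.
    """
    config.validate()
    n = config.n_users
    if groups is None:
        groups = rng.integers(0, 2, size=n)
    groups = np.asarray(groups)
    # a heavy-tailed engagement trait drives both how many accounts a user
    # follows and how attractive the user is to others; with assortative
    # attachment this nests a dense elite core inside a sparse periphery,
    # giving the in-coreness centrality realistic graded dispersion
    sa = config.engagement_sigma
    engagement = rng.lognormal(0.0, sa, size=n) if sa > 0 else np.ones(n)
    if config.edge_density is not None:
        degrees = np.full(n, int(round(config.edge_density * (n - 1))))
    else:
        s = config.out_degree_sigma
        noise = rng.lognormal(-s * s / 2.0, s, size=n) if s > 0 else np.ones(n)
        degrees = rng.poisson(config.mean_out_degree * noise * engagement / engagement.mean())
    degrees = np.clip(degrees, 0, n - 1)
    logw_same = np.log1p(config.homophily_strength)
    log_eng = np.log(engagement)
    own_z = (log_eng - log_eng.mean()) / log_eng.std() if log_eng.std() > 0 else np.zeros(n)
    # how strongly a user's own engagement amplifies the pull of highly
    # engaged targets (floored so the pull never flips sign)
    pull = np.clip(1.0 + config.degree_assortativity * own_z, 0.2, None)
    edges = []
    for i in range(n):
        d = int(degrees[i])
        if d == 0:
            continue
        scores = np.where(groups == groups[i], logw_same, 0.0) + pull[i] * log_eng
        scores += rng.gumbel(size=n)
        scores[i] = -np.inf
        targets = np.argpartition(-scores, d - 1)[:d]
        edges.extend((i, int(j)) for j in targets)
    return FollowGraph(range(n), edges)


def generate_traits(
    graph: FollowGraph,
    config: SimulationConfig,
    rng: np.random.Generator,
    groups: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-user emotion, confounder and independent covariates.

    Emotions are peer-coupled in two passes: a first-pass draw
    e0 = group shift + loading * confounder + noise, then one update
    emotion = group shift + peer_weight * mean(e0 over followees)
            + loading * confounder + noise, clamped to [-4, 4].
    Users without followees receive a zero peer term (the population mean).
    """
    n = graph.n_nodes
    if groups is None:
        groups = rng.integers(0, 2, size=n)
    groups = np.asarray(groups)
    mu = config.group_emotion_shift * (2.0 * groups - 1.0)
    confounder = rng.normal(0.0, config.confounder_sd, size=n) if config.confounder_sd > 0 else np.zeros(n)
    e0 = mu + config.confounder_loading * confounder + rng.normal(0.0, config.emotion_noise_sd, size=n)
    peer = np.zeros(n)
    out_deg = np.bincount(graph.src, minlength=n)
    np.add.at(peer, graph.src, e0[graph.dst])
    with np.errstate(invalid="ignore"):
        peer = np.where(out_deg > 0, peer / np.maximum(out_deg, 1), 0.0)
    emotion = mu + config.peer_weight * peer + config.confounder_loading * confounder
    emotion = emotion + rng.normal(0.0, config.emotion_noise_sd, size=n)
    emotion = np.clip(emotion, -4.0, 4.0)
    if config.posting_rate_mean > 0:
        s = config.posting_rate_sigma
        rate = rng.lognormal(np.log(config.posting_rate_mean) - s * s / 2.0, s, size=n)
    else:
        rate = np.zeros(n)
    created = rng.uniform(0.0, config.creation_max_time, size=n)
    traits = pd.DataFrame(
        {
            "group": groups,
            "confounder": confounder,
            "emotion_true": emotion,
            "peer_mean_emotion": peer,
            "posting_rate": rate,
            "created_at": created,
        },
        index=pd.Index(graph.nodes, name="user_id"),
    )
    return traits


def generate_activity(
    graph: FollowGraph,
    traits: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    lexicon: Lexicon = DEFAULT_LEXICON,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Dropout times from the additive hazard and Poisson posting streams.

    The per-user hazard h = baseline + b_e * emotion + b_c * in-coreness
    + b_u * confounder (constant in time, floored at 0 with a logged
    warning) draws an exponential dropout time from account creation. A
    Poisson posting process at the user's rate runs from creation to
    min(dropout, obs2). Post tokens are emitted from the lexicon so that
    each post's sentiment score equals the user's true emotion plus noise,
    rounded to the integer scale. Returns (posts, truth).
    """
    n = len(traits)
    centrality = in_coreness(graph).reindex(traits.index).to_numpy(dtype=float)
    h = (
        config.hazard_baseline
        + config.hazard_emotion * traits["emotion_true"].to_numpy()
        + config.hazard_centrality * centrality
        + config.hazard_confounder * traits["confounder"].to_numpy()
    )
    n_floored = int((h < 0).sum())
    if n_floored:
        log.warning("hazard floored at 0 for %d of %d users", n_floored, n)
    h = np.clip(h, 0.0, None)
    created = traits["created_at"].to_numpy()
    with np.errstate(divide="ignore"):
        scale = np.where(h > 0, 1.0 / np.where(h > 0, h, 1.0), np.inf)
    dropout_time = created + rng.exponential(scale)

    # binary outcome: joint with the hazard by default, or a separate
    # linear-probability draw when configured
    if config.binary_mechanism == "hazard":
        dropout_binary = (dropout_time < config.obs2_time).astype(int)
    else:
        p = (
            config.binary_intercept
            + config.beta_emotion * traits["emotion_true"].to_numpy()
            + config.beta_centrality * centrality
            + config.gamma_linear * traits["confounder"].to_numpy()
        )
        dropout_binary = (rng.uniform(size=n) < np.clip(p, 0.0, 1.0)).astype(int)

    # strength -> candidate terms, for planted-score token emission
    by_strength: Dict[int, list] = {}
    for term, s in lexicon.items():
        by_strength.setdefault(s, []).append(term)
    for s in by_strength:
        by_strength[s].sort()

    end = np.minimum(dropout_time, config.obs2_time)
    emotions = traits["emotion_true"].to_numpy()
    rows = []
    filler = np.array(FILLER_TOKENS)
    for i, uid in enumerate(traits.index):
        span = end[i] - created[i]
        if span <= 0 or traits["posting_rate"].iloc[i] <= 0:
            continue
        k = rng.poisson(traits["posting_rate"].iloc[i] * span)
        if k == 0:
            continue
        times = np.sort(rng.uniform(created[i], end[i], size=k))
        sentiments = np.clip(
            np.rint(emotions[i] + rng.normal(0.0, config.post_sentiment_sd, size=k)),
            -4, 4,
        ).astype(int)
        is_rt = rng.uniform(size=k) < config.retweet_prob
        n_fill = rng.poisson(config.tokens_per_post_mean, size=k)
        for j in range(k):
            tokens = list(filler[rng.integers(0, len(filler), size=max(int(n_fill[j]), 1))])
            s = int(sentiments[j])
            if s > 0:
                cands = by_strength[s + 1]
                tokens.append(cands[rng.integers(0, len(cands))])
            elif s < 0:
                cands = by_strength[s - 1]
                tokens.append(cands[rng.integers(0, len(cands))])
            rows.append((uid, float(times[j]), tokens, [], bool(is_rt[j])))
    posts = pd.DataFrame(rows, columns=["user_id", "timestamp", "tokens", "hashtags", "is_retweet"])
    truth = pd.DataFrame(
        {
            "group": traits["group"],
            "confounder": traits["confounder"],
            "emotion_true": traits["emotion_true"],
            "centrality_true": centrality,
            "hazard": h,
            "dropout_time": dropout_time,
            "dropout_binary": dropout_binary,
        },
        index=traits.index,
    )
    return posts, truth


def generate_hashtags(
    posts: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Attach topic-conditioned hashtags to every post.

    Each post samples Poisson(hashtag_rate) tags from an even mixture of
    the topic distribution of the user's true-emotion tercile and that of
    the user's true dropout status, as configured in ``topic_params``.
    """
    if not config.topic_params:
        raise InvalidConfigError("topic_params must be non-empty")
    if posts.empty:
        return posts
    terciles = emotion_terciles(truth["emotion_true"])
    status = truth["dropout_binary"].map({1: "dropout", 0: "nondropout"})

    def _dist(keys):
        merged: Dict[str, float] = {}
        for key in keys:
            dist = config.topic_params.get(key)
            if not dist:
                continue
            total = sum(dist.values())
            for tag, w in dist.items():
                merged[tag] = merged.get(tag, 0.0) + 0.5 * w / total
        tags = sorted(merged)
        probs = np.array([merged[t] for t in tags])
        return np.array(tags), probs / probs.sum() if len(tags) else probs

    cache: Dict[Tuple, Tuple[np.ndarray, np.ndarray]] = {}
    hashtags = []
    n_tags = rng.poisson(config.hashtag_rate, size=len(posts))
    for (uid, k) in zip(posts["user_id"], n_tags):
        if k == 0:
            hashtags.append([])
            continue
        key = (terciles.get(uid), status.get(uid))
        if key not in cache:
            cache[key] = _dist([key[0], key[1]])
        tags, probs = cache[key]
        if len(tags) == 0:
            hashtags.append([])
            continue
        hashtags.append(list(rng.choice(tags, size=k, p=probs)))
    out = posts.copy()
    out["hashtags"] = hashtags
    return out


def simulate_panel(config: SimulationConfig, lexicon: Lexicon = DEFAULT_LEXICON) -> CommunityPanel:
    """Run all generation stages and bundle a CommunityPanel.

    All randomness flows from config.seed through per-stage child
    generators, so identical (config, seed) gives a bit-identical panel.
    """
    config.validate()
    seq = np.random.SeedSequence(config.seed)
    r_graph, r_traits, r_activity, r_tags = [np.random.default_rng(s) for s in seq.spawn(4)]
    groups = r_graph.integers(0, 2, size=config.n_users)
    graph = generate_follow_graph(config, r_graph, groups=groups)
    traits = generate_traits(graph, config, r_traits, groups=groups)
    posts, truth = generate_activity(graph, traits, config, r_activity, lexicon=lexicon)
    posts = generate_hashtags(posts, truth, config, r_tags)
    n_posts = posts.groupby("user_id").size().reindex(traits.index).fillna(0).astype(int)
    users = pd.DataFrame(
        {
            "created_at": traits["created_at"],
            "n_followees": graph.out_degree().reindex(traits.index).fillna(0).astype(int),
            "n_followers": graph.in_degree().reindex(traits.index).fillna(0).astype(int),
            "n_posts": n_posts,
        },
        index=traits.index,
    )
    return CommunityPanel(
        users=users,
        graph=graph,
        posts=posts,
        obs1_time=config.obs1_time,
        obs2_time=config.obs2_time,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# estimator test-bed data sets with known truth
# ---------------------------------------------------------------------------

def linear_iv_dataset(
    n: int = 2000,
    beta: float = 0.3,
    instrument_strength: float = 0.6,
    confounder_loading: float = 0.8,
    outcome_confounding: float = 1.0,
    followee_attr_sd: float = 2.0,
    first_stage_noise_sd: float = 0.3,
    outcome_noise_sd: float = 0.5,
    mean_out_degree: float = 10.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Linear IV test bed with a network-built instrument.

    Structure: each user's instrument z is the mean of an i.i.d. followee
    attribute over a homophily-free follow graph; then
    x1 = instrument_strength * z + confounder_loading * u + nu and
    y = beta * x1 + outcome_confounding * u + eps with u standard normal.
    Users without followees are dropped. Columns: y, x1, z, u.
    """
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(n_users=n, mean_out_degree=mean_out_degree, homophily_strength=0.0)
    graph = generate_follow_graph(cfg, rng, groups=np.zeros(n, dtype=int))
    attr = rng.normal(0.0, followee_attr_sd, size=n)
    sums = np.zeros(n)
    np.add.at(sums, graph.src, attr[graph.dst])
    deg = np.bincount(graph.src, minlength=n)
    has = deg > 0
    z = sums[has] / deg[has]
    m = int(has.sum())
    u = rng.normal(size=m)
    x1 = instrument_strength * z + confounder_loading * u + rng.normal(0.0, first_stage_noise_sd, size=m)
    y = beta * x1 + outcome_confounding * u + rng.normal(0.0, outcome_noise_sd, size=m)
    return pd.DataFrame({"y": y, "x1": x1, "z": z, "u": u})


def hazard_iv_dataset(
    n: int = 1000,
    effect: float = 0.02,
    baseline: float = 0.15,
    confounder_effect: float = 0.02,
    instrument_strength: float = 0.6,
    confounder_loading: float = 0.8,
    first_stage_noise_sd: float = 0.3,
    admin_censor: float = 30.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Additive-hazard IV test bed with known true effect.

    x1 = instrument_strength * z + confounder_loading * u + nu with z, u
    standard normal; the hazard is baseline + effect * x1 +
    confounder_effect * u (floored at 1e-4/day), with administrative
    censoring at ``admin_censor`` days. Columns: time, event, x1, z, u.
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    u = rng.normal(size=n)
    x1 = instrument_strength * z + confounder_loading * u + rng.normal(0.0, first_stage_noise_sd, size=n)
    h = np.clip(baseline + effect * x1 + confounder_effect * u, 1e-4, None)
    t = rng.exponential(1.0 / h)
    event = (t <= admin_censor).astype(int)
    time = np.minimum(t, admin_censor)
    return pd.DataFrame({"time": time, "event": event, "x1": x1, "z": z, "u": u})
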