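"""The synthetic community generator: determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

from attrical.exceptions import InvalidConfigError
from attrical.graphs import FollowGraph, in_coreness, newman_assortativity
from attrical.lexicon import DEFAULT_LEXICON
from attrical.sentiment import eligibility_filter
from attrical.simulate import (
    CommunityPanel,
    SimulationConfig,
    default_topic_params,
    generate_follow_graph,
    generate_traits,
    simulate_panel,
)

from conftest import small_config


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(n_users=1).validate()
        with pytest.raises(InvalidConfigError):
            SimulationConfig(obs1_time=10.0, obs2_time=5.0).validate()
        with pytest.raises(InvalidConfigError):
            SimulationConfig(posting_rate_mean=-1.0).validate()
        with pytest.raises(InvalidConfigError):
            SimulationConfig(topic_params={}).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        cfg2 = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert cfg2 == cfg


class TestFollowGraphGeneration:
    def test_density_one_two_users_gives_both_edges(self, rng):
        cfg = SimulationConfig(n_users=2, edge_density=1.0)
        g = generate_follow_graph(cfg, rng)
        assert sorted(g.edge_list()) == [(0, 1), (1, 0)]

    def test_no_homophily_gives_null_assortativity(self):
        cfg = SimulationConfig(n_users=2000, mean_out_degree=10.0, homophily_strength=0.0)
        rng = np.random.default_rng(0)
        groups = rng.integers(0, 2, size=2000)
        g = generate_follow_graph(cfg, rng, groups=groups)
        r = newman_assortativity(g, dict(enumerate(groups)))
        assert abs(r) < 0.05

    def test_strong_homophily_plants_assortativity(self):
        cfg = small_config(n_users=800, homophily_strength=8.0)
        rng = np.random.default_rng(1)
        groups = rng.integers(0, 2, size=800)
        g = generate_follow_graph(cfg, rng, groups=groups)
        assert newman_assortativity(g, dict(enumerate(groups))) > 0.3


class TestTraits:
    def test_no_coupling_gives_independent_emotions(self):
        cfg = SimulationConfig(
            n_users=2000, peer_weight=0.0, confounder_sd=0.0,
            group_emotion_shift=0.0, homophily_strength=0.0,
        )
        rng = np.random.default_rng(2)
        groups = rng.integers(0, 2, size=2000)
        g = generate_follow_graph(cfg, rng, groups=groups)
        traits = generate_traits(g, cfg, rng, groups=groups)
        has_peers = traits["peer_mean_emotion"] != 0.0
        r = np.corrcoef(traits.loc[has_peers, "emotion_true"],
                        traits.loc[has_peers, "peer_mean_emotion"])[0, 1]
        assert abs(r) < 0.05

    def test_peer_weight_creates_relevance(self):
        cfg = SimulationConfig(n_users=2000, peer_weight=0.6, seed=3)
        panel = simulate_panel(cfg)
        # first-stage on the truth: emotion on followee-mean first-pass emotion
        from attrical.linear import first_stage_F
        t = panel.truth
        from attrical.graphs import build_instruments
        inst = build_instruments(panel.graph, t[["emotion_true"]])
        ok = inst.table["n_followees_used"] > 0
        F = first_stage_F(
            t.loc[ok, "emotion_true"], None,
            inst.table.loc[ok, ["followee_mean_emotion_true"]],
        )
        assert F > 10

    def test_emotions_clamped(self, small_panel):
        e = small_panel.truth["emotion_true"]
        assert e.between(-4.0, 4.0).all()


class TestActivity:
    def test_zero_hazard_effects_exponential_median(self):
        cfg = SimulationConfig(
            n_users=10000, hazard_emotion=0.0, hazard_centrality=0.0,
            hazard_confounder=0.0, hazard_baseline=0.005, mean_out_degree=2.0,
            posting_rate_mean=0.05, seed=4,
        )
        panel = simulate_panel(cfg)
        waits = panel.truth["dropout_time"] - panel.users["created_at"]
        assert np.median(waits) == pytest.approx(np.log(2) / 0.005, rel=0.05)

    def test_zero_posting_rate_nobody_eligible(self):
        cfg = small_config(posting_rate_mean=0.0)
        panel = simulate_panel(cfg)
        assert panel.posts.empty
        assert len(eligibility_filter(panel.posts)) == 0

    def test_emotion_raises_hazard_orders_km_terciles(self):
        from attrical.interests import emotion_terciles
        from attrical.survival import kaplan_meier
        cfg = SimulationConfig(n_users=6000, hazard_emotion=0.004,
                               hazard_centrality=0.0, hazard_confounder=0.0,
                               posting_rate_mean=0.05, seed=5)
        panel = simulate_panel(cfg)
        waits = (panel.truth["dropout_time"] - panel.users["created_at"]).clip(upper=2000)
        event = (panel.truth["dropout_time"] < 1e9).astype(int)
        labs = emotion_terciles(panel.truth["emotion_true"])
        med = {
            lab: kaplan_meier(waits[labs == lab], event[labs == lab]).median
            for lab in ("negative", "neutral", "positive")
        }
        assert med["negative"] > med["neutral"] > med["positive"]


class TestHashtags:
    def test_matched_groups_share_topics(self, small_panel):
        tags = {t for tags in small_panel.posts["hashtags"] for t in tags}
        topics = default_topic_params()
        assert tags <= set().union(*[set(d) for d in topics.values()])

    def test_empty_topics_rejected(self):
        from attrical.simulate import generate_hashtags
        cfg = small_config()
        cfg.topic_params = {}
        with pytest.raises(InvalidConfigError):
            generate_hashtags(pd.DataFrame({"user_id": [1]}), pd.DataFrame(),
                              cfg, np.random.default_rng(0))


class TestDeterminismAndSerialization:
    def test_identical_seed_bit_identical_serialization(self, tmp_path):
        cfg = small_config(n_users=120, seed=11)
        simulate_panel(cfg).to_dir(tmp_path / "a")
        simulate_panel(cfg).to_dir(tmp_path / "b")
        for name in ("users.csv", "edges.tsv", "posts.jsonl", "truth.csv", "meta.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_round_trip_preserves_panel(self, tmp_path):
        cfg = small_config(n_users=80, seed=12)
        panel = simulate_panel(cfg)
        panel.to_dir(tmp_path / "p")
        loaded = CommunityPanel.from_dir(tmp_path / "p")
        assert len(loaded.users) == len(panel.users)
        assert loaded.graph.n_edges == panel.graph.n_edges
        assert len(loaded.posts) == len(panel.posts)
        pd.testing.assert_series_equal(loaded.last_post(), panel.last_post())

    def test_post_streams_within_window_and_ordered(self, small_panel):
        joined = small_panel.posts.merge(
            small_panel.users[["created_at"]], left_on="user_id", right_index=True
        )
        assert (joined["timestamp"] >= joined["created_at"] - 1e-9).all()
        assert (small_panel.posts["timestamp"] <= small_panel.obs2_time).all()
        diffs = small_panel.posts.groupby("user_id")["timestamp"].diff().dropna()
        assert (diffs >= 0).all()


class TestEndogeneityStructure:
    def test_confounding_couples_emotion_and_error(self):
        # with confounder_sd > 0 the linear-model error (outcome minus the
        # structural emotion/centrality channels) correlates with emotion;
        # with confounder_sd = 0 it does not
        def emotion_error_corr(sd, seed):
            cfg = SimulationConfig(
                n_users=6000, confounder_sd=sd, seed=seed,
                binary_mechanism="linear", gamma_linear=-0.15,
                posting_rate_mean=0.02,
            )
            panel = simulate_panel(cfg)
            t = panel.truth
            error = t["dropout_binary"] - (
                cfg.binary_intercept
                + cfg.beta_emotion * t["emotion_true"]
                + cfg.beta_centrality * t["centrality_true"]
            )
            return np.corrcoef(t["emotion_true"], error)[0, 1]

        assert abs(emotion_error_corr(0.0, 21)) < 0.05
        assert abs(emotion_error_corr(1.0, 22)) > 0.1
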