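"""Network measurement: coreness, followee sets, instruments, assortativity."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from attrical.exceptions import DegenerateInputError, InvalidConfigError
from attrical.graphs import (
    FollowGraph,
    assortativity_null_z,
    build_instruments,
    followee_sets,
    in_coreness,
    newman_assortativity,
)

from conftest import peel_in_coreness, random_digraph


class TestFollowGraph:
    def test_rejects_self_loops_and_duplicates(self):
        with pytest.raises(InvalidConfigError):
            FollowGraph([0, 1], [(0, 0)])
        with pytest.raises(InvalidConfigError):
            FollowGraph([0, 1], [(0, 1), (0, 1)])
        with pytest.raises(InvalidConfigError):
            FollowGraph([0, 1], [(0, 2)])

    def test_tsv_round_trip(self, tmp_path):
        g = FollowGraph([0, 1, 2], [(0, 1), (1, 2), (2, 0)])
        g.to_tsv(tmp_path / "edges.tsv")
        g2 = FollowGraph.from_tsv(tmp_path / "edges.tsv", nodes=[0, 1, 2])
        assert sorted(g2.edge_list()) == sorted(g.edge_list())


class TestInCoreness:
    def test_edgeless_graph_is_all_zero(self):
        assert in_coreness(FollowGraph(range(5), [])).tolist() == [0] * 5

    def test_directed_cycle_and_complete_graph(self):
        cyc = FollowGraph(range(4), [(i, (i + 1) % 4) for i in range(4)])
        assert in_coreness(cyc).tolist() == [1, 1, 1, 1]
        comp = FollowGraph(range(4), [(i, j) for i in range(4) for j in range(4) if i != j])
        assert in_coreness(comp).tolist() == [3, 3, 3, 3]

    def test_empty_graph(self):
        assert in_coreness(FollowGraph([], [])).empty

    @pytest.mark.parametrize("batch", range(5))
    def test_matches_brute_force_peeling(self, batch):
        rng = np.random.default_rng(1000 + batch)
        for _ in range(20):
            nodes, edges = random_digraph(rng, n=50, p=float(rng.uniform(0.02, 0.15)))
            got = in_coreness(FollowGraph(nodes, edges)).to_dict()
            assert got == peel_in_coreness(nodes, edges)

    def test_monotone_under_edge_addition(self, rng):
        nodes, edges = random_digraph(rng, n=40, p=0.05)
        base = in_coreness(FollowGraph(nodes, edges))
        extra = [(i, (i + 7) % 40) for i in range(40)]
        new = [e for e in extra if e not in set(edges) and e[0] != e[1]]
        grown = in_coreness(FollowGraph(nodes, edges + new))
        assert (grown >= base).all()


class TestFolloweeSets:
    def test_mutual_pair_single_way_empty(self):
        g = FollowGraph([0, 1], [(0, 1), (1, 0)])
        sw = followee_sets(g, single_way=True)
        assert sw[0] == set() and sw[1] == set()

    def test_one_directional_edge_kept_in_both_modes(self):
        g = FollowGraph([0, 1], [(0, 1)])
        assert followee_sets(g)[0] == {1}
        assert followee_sets(g, single_way=True)[0] == {1}

    def test_star_with_one_reciprocal(self):
        g = FollowGraph("ABCD", [("A", "B"), ("A", "C"), ("A", "D"), ("D", "A")])
        assert followee_sets(g, single_way=True)["A"] == {"B", "C"}
        assert followee_sets(g)["A"] == {"B", "C", "D"}


class TestInstruments:
    def test_symmetric_and_singleton_means(self):
        g = FollowGraph([0, 1, 2, 3, 4], [(0, 1), (0, 2), (0, 3), (4, 1)])
        attrs = pd.Series({1: -2.0, 2: 0.0, 3: 2.0, 0: 9.0, 4: 9.0}, name="emotion")
        inst = build_instruments(g, attrs.to_frame())
        assert inst.table.loc[0, "followee_mean_emotion"] == pytest.approx(0.0)
        assert inst.table.loc[4, "followee_mean_emotion"] == pytest.approx(-2.0)

    def test_no_followees_marked_missing(self):
        g = FollowGraph([0, 1], [(0, 1), (1, 0)])
        inst = build_instruments(g, pd.Series({0: 1.0, 1: 7.0}).to_frame("centrality"),
                                 single_way=True)
        assert inst.table["n_followees_used"].tolist() == [0, 0]
        assert inst.table["followee_mean_centrality"].isna().all()
        assert len(inst.usable) == 0

    def test_missing_attribute_omitted_and_counted(self):
        g = FollowGraph([0, 1, 2], [(0, 1), (0, 2)])
        attrs = pd.Series({1: 5.0, 2: np.nan, 0: 0.0}).to_frame("emotion")
        inst = build_instruments(g, attrs)
        assert inst.table.loc[0, "followee_mean_emotion"] == pytest.approx(5.0)
        assert inst.table.loc[0, "n_followees_used"] == 1
        assert inst.n_attribute_missing == 1

    @given(st.integers(0, 2**31 - 1))
    def test_means_lie_in_followee_hull(self, seed):
        rng = np.random.default_rng(seed)
        nodes, edges = random_digraph(rng, n=30, p=0.1)
        g = FollowGraph(nodes, edges)
        vals = pd.Series(rng.normal(size=30), index=nodes).to_frame("a")
        inst = build_instruments(g, vals)
        sets = followee_sets(g)
        for u in nodes:
            if sets[u]:
                fv = vals.loc[list(sets[u]), "a"]
                m = inst.table.loc[u, "followee_mean_a"]
                assert fv.min() - 1e-12 <= m <= fv.max() + 1e-12


class TestAssortativity:
    def test_perfect_homophily(self):
        g = FollowGraph([0, 1, 2, 3], [(0, 1), (1, 0), (2, 3), (3, 2)])
        assert newman_assortativity(g, {0: "a", 1: "a", 2: "b", 3: "b"}) == pytest.approx(1.0)

    def test_balanced_heterophily_is_minus_one(self):
        # mixing matrix: sum e_ii = 0, sum a_i b_i = 0.5 -> r = -1
        g = FollowGraph([0, 1], [(0, 1), (1, 0)])
        assert newman_assortativity(g, {0: "a", 1: "b"}) == pytest.approx(-1.0)

    def test_random_labels_near_zero(self, rng):
        nodes, edges = random_digraph(rng, n=400, p=0.05)
        labels = {v: int(rng.integers(0, 2)) for v in nodes}
        assert abs(newman_assortativity(FollowGraph(nodes, edges), labels)) < 0.05

    def test_single_label_degenerate(self):
        g = FollowGraph([0, 1], [(0, 1)])
        with pytest.raises(DegenerateInputError):
            newman_assortativity(g, {0: "a", 1: "a"})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_networkx_mixing_computation(self, seed):
        rng = np.random.default_rng(seed)
        nodes, edges = random_digraph(rng, n=60, p=0.08)
        labels = {v: ["a", "b", "c"][int(rng.integers(0, 3))] for v in nodes}
        G = nx.DiGraph()
        G.add_nodes_from(nodes)
        G.add_edges_from(edges)
        nx.set_node_attributes(G, labels, "lab")
        expected = nx.attribute_assortativity_coefficient(G, "lab")
        got = newman_assortativity(FollowGraph(nodes, edges), labels)
        assert got == pytest.approx(expected, abs=1e-12)


class TestAssortativityNull:
    def test_planted_homophily_large_z(self, rng):
        nodes = list(range(200))
        groups = {v: v % 2 for v in nodes}
        edges = []
        for v in nodes:
            same = [u for u in nodes if u != v and groups[u] == groups[v]]
            other = [u for u in nodes if groups[u] != groups[v]]
            targets = list(rng.choice(same, size=5, replace=False)) + \
                      list(rng.choice(other, size=1, replace=False))
            edges.extend((v, int(u)) for u in targets)
        z, p = assortativity_null_z(FollowGraph(nodes, edges), groups, n_perm=300, seed=0)
        assert z > 3
        assert p < 0.05

    def test_degenerate_null_gives_zero_z(self):
        # two nodes, one label per node: every permutation reproduces r_obs
        g = FollowGraph([0, 1], [(0, 1), (1, 0)])
        z, p = assortativity_null_z(g, {0: "a", 1: "b"}, n_perm=120, seed=0)
        assert z == 0.0

    def test_small_n_perm_warns(self):
        g = FollowGraph([0, 1, 2], [(0, 1), (1, 2), (2, 0)])
        with pytest.warns(UserWarning):
            assortativity_null_z(g, {0: "a", 1: "b", 2: "a"}, n_perm=50, seed=0)
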