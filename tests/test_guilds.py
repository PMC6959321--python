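import math

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

import guildnet as gn
from guildnet.guilds import (ANOMALOUS, CIVILIAN, GUARD, round_half_up)


def signed_graph(pos=(), neg=()):
    g = nx.Graph()
    for u, v in pos:
        g.add_edge(u, v, sign="positive", r=0.8)
    for u, v in neg:
        g.add_edge(u, v, sign="negative", r=-0.8)
    return g


def planted_balanced_graph(rng_seed, n_a, n_b, p_within=0.8, p_cross=0.4):
    """Random balanced signed graph with positively connected groups."""
    import random

    rng = random.Random(rng_seed)
    a = [f"a{i}" for i in range(n_a)]
    b = [f"b{i}" for i in range(n_b)]
    g = nx.Graph()
    g.add_nodes_from(a + b)
    for side in (a, b):  # spanning positive path keeps each group connected
        for u, v in zip(side, side[1:]):
            g.add_edge(u, v, sign="positive")
        for i in range(len(side)):
            for j in range(i + 2, len(side)):
                if rng.random() < p_within:
                    g.add_edge(side[i], side[j], sign="positive")
    for u in a:
        for v in b:
            if rng.random() < p_cross:
                g.add_edge(u, v, sign="negative")
    return g, frozenset(a), frozenset(b)


class TestPartition:
    def test_two_positive_pairs_with_cross_negatives(self):
        g = signed_graph(pos=[("a", "b"), ("c", "d")],
                         neg=[("a", "c"), ("b", "d")])
        p = gn.partition_subguilds(g)
        assert sorted(map(sorted, p.groups)) == [["a", "b"], ["c", "d"]]
        assert p.balanced

    def test_triangle_one_positive_edge(self):
        g = signed_graph(pos=[("a", "b")], neg=[("a", "c"), ("b", "c")])
        p = gn.partition_subguilds(g)
        assert sorted(map(sorted, p.groups)) == [["a", "b"], ["c"]]
        assert p.balanced

    def test_all_negative_triangle_gives_singletons(self):
        # no positive edges to merge on: three singleton groups, all negative
        # edges run between groups, so the partition is balanced
        g = signed_graph(neg=[("a", "b"), ("a", "c"), ("b", "c")])
        p = gn.partition_subguilds(g)
        assert len(p.groups) == 3
        assert p.balanced

    def test_frustrated_negative_inside_group(self):
        g = signed_graph(pos=[("a", "b"), ("b", "c")], neg=[("a", "c")])
        p = gn.partition_subguilds(g)
        assert len(p.groups) == 1
        assert not p.balanced
        assert [tuple(sorted(e)) for e in p.frustrated_edges] == [("a", "c")]

    def test_groups_ordered_by_descending_size(self):
        g = signed_graph(pos=[("a", "b"), ("a", "c"), ("x", "y")],
                         neg=[("a", "x")])
        p = gn.partition_subguilds(g)
        assert [len(grp) for grp in p.groups] == [3, 2]

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000), st.integers(2, 6), st.integers(2, 6))
    def test_agrees_with_exhaustive_bipartition_on_balanced_graphs(
        self, seed, n_a, n_b
    ):
        g, a, b = planted_balanced_graph(seed, n_a, n_b)
        if not any(d["sign"] == "negative" for _, _, d in g.edges(data=True)):
            return  # bipartition not unique without any negative edge
        p = gn.partition_subguilds(g)
        assert p.balanced
        assert sorted(map(sorted, p.groups)) == sorted(map(sorted, [a, b]))
        side_a, side_b, frustration = gn.min_frustration_bipartition(g)
        assert frustration == 0
        assert {side_a, side_b} == {a, b}


class TestRoles:
    def test_fixture_guard_counts(self, fba_graph, fba_partition):
        roles = gn.classify_roles(fba_graph, fba_partition)
        guards = {r.sub_guild: 0 for r in roles}
        for r in roles:
            if r.role == GUARD:
                guards[r.sub_guild] += 1
        assert guards["ASG"] == 14
        assert guards["FBSG"] == 16
        assert sum(1 for r in roles if r.role == ANOMALOUS) == 0

    def test_fixture_roles_match_transcription(self, fba_graph, fba_partition,
                                               membership):
        roles = {r.node: r.role for r in
                 gn.classify_roles(fba_graph, fba_partition)}
        for node, rec in membership.items():
            assert roles[node] == rec.role

    def test_all_positive_cluster_is_all_civilian(self):
        g = signed_graph(pos=[("a", "b"), ("b", "c"), ("a", "c")])
        p = gn.partition_subguilds(g)
        roles = gn.classify_roles(g, p)
        assert {r.role for r in roles} == {CIVILIAN}

    def test_within_group_negative_is_anomalous(self):
        g = signed_graph(pos=[("a", "b"), ("b", "c")], neg=[("a", "c")])
        p = gn.partition_subguilds(g)
        roles = {r.node: r.role for r in gn.classify_roles(g, p)}
        assert roles["a"] == ANOMALOUS and roles["c"] == ANOMALOUS
        assert roles["b"] == CIVILIAN

    def test_roles_partition_cluster_nodes(self, fba_graph, fba_partition):
        roles = gn.classify_roles(fba_graph, fba_partition)
        assert {r.node for r in roles} == set(fba_graph.nodes)
        assert len(roles) == fba_graph.number_of_nodes()

    def test_balanced_negative_edges_join_two_guards(self, fba_graph,
                                                     fba_partition):
        role_of = {r.node: r.role for r in
                   gn.classify_roles(fba_graph, fba_partition)}
        for u, v, d in fba_graph.edges(data=True):
            if d["sign"] == "negative":
                assert role_of[u] == GUARD and role_of[v] == GUARD


class TestComposition:
    def test_guild_composition_matches_printed_percentages(self, membership,
                                                           phylum_map):
        comp = gn.phylum_composition(membership.keys(), phylum_map)
        assert comp["Actinobacteria"] == (21, 38.2)
        assert comp["Firmicutes"] == (14, 25.5)
        assert comp["Bacteroidetes"] == (9, 16.4)
        assert comp["Others"] == (11, 20.0)

    def test_subguild_compositions(self, membership, phylum_map):
        asg = [k for k, v in membership.items() if v.sub_guild == "ASG"]
        fbsg = [k for k, v in membership.items() if v.sub_guild == "FBSG"]
        assert gn.phylum_composition(asg, phylum_map) == {
            "Actinobacteria": (14, 66.7),
            "Bacteroidetes": (2, 9.5),
            "Others": (5, 23.8),
        }
        assert gn.phylum_composition(fbsg, phylum_map) == {
            "Actinobacteria": (7, 20.6),
            "Firmicutes": (14, 41.2),
            "Bacteroidetes": (7, 20.6),
            "Others": (6, 17.6),
        }

    def test_empty_member_set(self, phylum_map):
        assert gn.phylum_composition([], phylum_map) == {}

    def test_rounding_is_half_up(self):
        assert round_half_up(66.65, 1) == 66.7
        assert round_half_up(25.4545, 1) == 25.5


class TestPhylumPairs:
    def test_negative_edge_blocks_match_transcription(self, fba_graph,
                                                      phylum_map):
        by_pair = {(s.phylum_a, s.phylum_b): s
                   for s in gn.phylum_pair_summary(fba_graph, phylum_map)}
        assert by_pair[("Actinobacteria", "Firmicutes")].n_negative == 13
        assert by_pair[("Actinobacteria", "Bacteroidetes")].n_negative == 6
        assert ("Firmicutes", "Bacteroidetes") not in by_pair  # zero edges

    def test_printed_ratio_arithmetic(self):
        assert gn.pn_ratio(74, 13) == pytest.approx(5.7, abs=0.05)
        assert gn.pn_ratio(57, 6) == pytest.approx(9.5, abs=0.0)
        assert gn.pn_ratio(85, 0) == math.inf

    def test_pair_totals_conserve_inter_phylum_edges(self, fba_graph,
                                                     phylum_map):
        from guildnet.guilds import node_phylum
        summaries = gn.phylum_pair_summary(fba_graph, phylum_map)
        inter = sum(
            1 for u, v in fba_graph.edges
            if node_phylum(u, phylum_map) != node_phylum(v, phylum_map)
        )
        assert sum(s.n_total for s in summaries) == inter
        for s in summaries:
            assert s.n_total == s.n_positive + s.n_negative

    def test_within_phylum_edges_on_diagonal_when_requested(self, fba_graph,
                                                            phylum_map):
        summaries = gn.phylum_pair_summary(fba_graph, phylum_map,
                                           include_within=True)
        diag = {(s.phylum_a, s.phylum_b): s for s in summaries
                if s.phylum_a == s.phylum_b}
        # 4 Actinobacteria-Actinobacteria and 2 Others-Others negatives
        assert diag[("Actinobacteria", "Actinobacteria")].n_negative == 4
        assert diag[("Others", "Others")].n_negative == 2
        assert sum(s.n_total for s in summaries) == fba_graph.number_of_edges()


class TestGuildReport:
    def test_fixture_report_dominants(self, fba_graph, phylum_map,
                                      fba_partition):
        rep = gn.guild_report(fba_graph, fba_graph.nodes, phylum_map,
                              partition=fba_partition)
        dom = {d["group"]: d for d in rep.dominant_phyla}
        assert dom["ASG"]["phyla"] == ["Actinobacteria"]
        assert dom["ASG"]["fraction"] == 66.7
        assert dom["FBSG"]["phyla"] == ["Firmicutes"]
        assert not dom["ASG"]["tied"]
        assert rep.to_dict()["role_counts"]["ASG"]["guard"] == 14

    def test_two_clique_synthetic_guild(self):
        pos = [(f"Corynebacterium_{i}", f"Corynebacterium_{j}")
               for i in range(3) for j in range(i + 1, 3)]
        pos += [(f"Streptococcus_{i}", f"Streptococcus_{j}")
                for i in range(3) for j in range(i + 1, 3)]
        neg = [("Corynebacterium_0", "Streptococcus_0")]
        g = signed_graph(pos=pos, neg=neg)
        rep = gn.guild_report(g, g.nodes, gn.default_phylum_map())
        assert sorted(map(sorted, rep.partition.groups)) == [
            sorted(f"Corynebacterium_{i}" for i in range(3)),
            sorted(f"Streptococcus_{i}" for i in range(3)),
        ]
        assert rep.partition.balanced
        counts = rep.role_counts()
        assert all(v.get("guard", 0) == 1 for v in counts.values())

    def test_single_group_all_positive(self):
        g = signed_graph(pos=[("Rothia_1", "Rothia_2"), ("Rothia_2", "Rothia_3")])
        rep = gn.guild_report(g, g.nodes, gn.default_phylum_map())
        assert len(rep.partition.groups) == 1
        assert all(r.role == CIVILIAN for r in rep.roles)

    def test_report_is_json_serializable(self, tmp_path, fba_graph, phylum_map):
        rep = gn.guild_report(fba_graph, fba_graph.nodes, phylum_map)
        rep.to_json(tmp_path / "rep.json")
        import json
        with open(tmp_path / "rep.json") as fh:
            d = json.load(fh)
        assert set(d) >= {"groups", "roles", "composition", "pair_summaries"}
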