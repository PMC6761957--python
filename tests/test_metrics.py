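"""Exact graph statistics: complexes, degrees, type III topology, D triplets."""

import warnings

import networkx as nx
import numpy as np
import pytest

from traitgraph import (
    build_network,
    count_d_triplets,
    find_complexes,
    recode,
    summarize,
    type2_degrees,
    type3_stats,
)

from conftest import (
    brute_d_triplets,
    brute_triangles,
    make_trait_matrix,
    small_random_matrix,
)


class TestComplexes:
    def test_identity_clique_is_one_complex(self):
        tm = make_trait_matrix([{"a", "b"}] * 3 + [{"c"}], taxa="abc")
        net = build_network(tm)
        assert find_complexes(net) == [{1, 2, 3}]

    def test_no_type1_edges_no_complexes(self, motif_example):
        _, _, net = motif_example
        assert find_complexes(net) == []


class TestType2Degrees:
    def test_nested_chain_degrees(self):
        """Supports {t1} ⊂ {t1,t2} ⊂ {t1,t2,t3} give in (0,1,2), out (2,1,0)."""
        tm = make_trait_matrix(
            [{"t1"}, {"t1", "t2"}, {"t1", "t2", "t3"}], taxa=["t1", "t2", "t3"]
        )
        recs = type2_degrees(build_network(tm))
        assert [(r.in_degree, r.out_degree) for r in recs] == [(0, 2), (1, 1), (2, 0)]
        assert [r.flag for r in recs] == ["precarious", "stable", "stable"]

    def test_isolated_node(self, motif_example):
        _, _, net = motif_example
        assert all((r.in_degree, r.out_degree) == (0, 0) for r in type2_degrees(net))

    @pytest.mark.parametrize("seed", range(10))
    def test_degree_sums_equal_edge_count(self, seed):
        cm = small_random_matrix(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = build_network(recode(cm))
        recs = type2_degrees(net)
        k = net.edge_counts()["II"]
        assert sum(r.in_degree for r in recs) == k
        assert sum(r.out_degree for r in recs) == k


class TestType3Stats:
    def test_worked_example_values(self, motif_example):
        _, _, net = motif_example
        s = type3_stats(net)
        assert s.k == 4
        assert s.density == pytest.approx(2 * 4 / (4 * 3))
        assert s.n_triangles == 1
        assert s.proportion_triangles == pytest.approx(0.25)
        assert s.diameter == 2  # e.g. 43 – 38 – 2

    def test_complete_overlap_graph_is_extremal(self):
        # four supports sharing taxon z pairwise overlap without nesting
        tm = make_trait_matrix(
            [{"z", "a"}, {"z", "b"}, {"z", "c"}, {"z", "d"}], taxa="zabcd"
        )
        s = type3_stats(build_network(tm))
        assert s.density == 1.0 and s.proportion_triangles == 1.0 and s.diameter == 1

    def test_small_n_errors(self):
        tm1 = make_trait_matrix([{"a"}], taxa="ab")
        with pytest.raises(ValueError, match="N < 2"):
            type3_stats(build_network(tm1))
        tm2 = make_trait_matrix([{"a"}, {"b"}], taxa="ab")
        with pytest.raises(ValueError, match="N < 3"):
            type3_stats(build_network(tm2))

    @pytest.mark.parametrize("seed", range(15))
    def test_triangles_match_networkx_and_handshake(self, seed):
        cm = small_random_matrix(seed, max_taxa=8, max_chars=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = build_network(recode(cm))
        if net.n_nodes < 3:  # degenerate draw: only the handshake applies
            g = net.graph("III")
            assert sum(d for _, d in g.degree()) == 2 * net.edge_counts()["III"]
            return
        s = type3_stats(net)
        g = net.graph("III")
        assert s.n_triangles == sum(nx.triangles(g).values()) // 3
        assert sum(d for _, d in g.degree()) == 2 * s.k

    def test_monotone_in_added_edge(self, motif_example):
        _, _, net = motif_example
        before = type3_stats(net)
        net2 = build_network(net.tm)
        # splice one extra type III edge (43–2) in place of its type IV slot
        i, j = 0, 3
        net2.adj_IV[i, j] = net2.adj_IV[j, i] = False
        net2.adj_III[i, j] = net2.adj_III[j, i] = True
        after = type3_stats(net2)
        assert after.k >= before.k
        assert after.n_triangles >= before.n_triangles
        assert after.density >= before.density


class TestTypeDTriplets:
    def test_worked_example_central_node(self, motif_example):
        _, ids, net = motif_example
        total, recs = count_d_triplets(net)
        cent = {r.node_id: r.d_centrality for r in recs}
        assert total == 2
        assert cent[ids["38"]] == 2
        assert all(v == 0 for nid, v in cent.items() if nid != ids["38"])

    def test_pure_overlap_graph_has_none(self):
        tm = make_trait_matrix([{"z", "a"}, {"z", "b"}, {"z", "c"}], taxa="zabc")
        total, _ = count_d_triplets(build_network(tm))
        assert total == 0

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_enumeration(self, seed):
        cm = small_random_matrix(seed + 500, max_taxa=8, max_chars=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = build_network(recode(cm))
        total, recs = count_d_triplets(net)
        oracle = brute_d_triplets(net.edges_III, net.edges_IV, net.n_nodes)
        assert {r.node_id: r.d_centrality for r in recs} == oracle
        assert total == sum(oracle.values())
        assert (
            type3_stats(net).n_triangles
            == brute_triangles(net.edges_III, net.n_nodes)
            if net.n_nodes >= 3
            else True
        )


class TestSummarize:
    def test_worked_example_report(self, motif_example):
        _, _, net = motif_example
        rep = summarize(net)
        assert rep.n_complexes == 0
        assert rep.n_edges == {"I": 0, "II": 0, "III": 4, "IV": 2}
        assert rep.n_typeD == 2
        d = rep.to_dict()
        assert d["n_nodes"] == 4 and d["diameter_III"] == 2

    def test_edgeless_network_is_all_zero(self):
        # three mutually absent... three disjoint singletons: only type IV
        tm = make_trait_matrix(
            [{"a", "b", "c"}] * 3, taxa="abc", characters=[1, 2, 3]
        )
        rep = summarize(build_network(tm))
        assert rep.n_edges["III"] == 0 and rep.n_typeD == 0
        assert rep.type3.density == 0.0 and rep.type3.diameter == 0
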