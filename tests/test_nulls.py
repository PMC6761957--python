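"""Permutation machinery: both null models, p-values, multiplicity control."""

import warnings
from collections import Counter
from itertools import permutations, product

import numpy as np
import pytest
from scipy.stats import chisquare

from traitgraph import (
    NullResult,
    bonferroni,
    build_network,
    null_distribution,
    parse_newick,
    parse_table,
    patristic_weights,
    permute_equiprobable,
    permute_phylogenetic,
    random_matrix,
    recode,
    significant_stable_traits,
    type2_degrees,
    SimulationConfig,
    STANDARD_STATISTICS,
    NODE_STATISTICS,
)
from traitgraph.nulls import check_permutation_count

from conftest import brute_edges, small_random_matrix


class TestEmpiricalPValues:
    def test_floor_at_one_over_m_plus_one(self):
        """Observed above all M=5000 replicates → p_high = 1/5001 ≈ 0.00019996."""
        r = NullResult(
            name="x", observed=10.0, replicates=np.zeros(5000),
            model="equiprobable", M=5000, seed=0,
        )
        assert r.p_high == pytest.approx(1 / 5001)
        assert f"{r.p_high:.8f}" == "0.00019996"

    def test_all_ties_give_p_one(self):
        r = NullResult(
            name="x", observed=3.0, replicates=np.full(100, 3.0),
            model="equiprobable", M=100, seed=0,
        )
        assert r.p_high == 1.0 and r.p_low == 1.0

    def test_direction_labels(self):
        high = NullResult("x", 10.0, np.zeros(99), "equiprobable", 99, 0)
        assert high.direction(alpha=0.05) == "Higher"
        assert high.direction(alpha=0.05, n_tests=10) == "NS"


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,n,expected", [(0.01, 5, 0.05), (0.5, 3, 1.0), (1 / 5001, 213, 213 / 5001)]
    )
    def test_values(self, p, n, expected):
        assert bonferroni(p, n) == pytest.approx(expected)

    def test_table_floor_times_node_family(self):
        assert bonferroni(1 / 5001, 213) == pytest.approx(0.0426, abs=5e-5)

    def test_contract(self):
        with pytest.raises(ValueError):
            bonferroni(0.0, 3)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)

    def test_permutation_count_check_warns(self):
        with pytest.warns(UserWarning, match="cannot reach"):
            assert not check_permutation_count(100, 213, 0.05)
        assert check_permutation_count(5000, 213, 0.05)


class TestEquiprobablePermutation:
    def test_constant_column_is_noop(self):
        cm = parse_table("a,0,0\nb,0,1\nc,0,1\n")
        pcm = permute_equiprobable(cm, np.random.default_rng(0))
        assert list(pcm.cells[:, 0]) == ["0", "0", "0"]

    def test_two_taxon_column_both_orders_occur(self):
        cm = parse_table("a,0\nb,1\n")
        rng = np.random.default_rng(0)
        seen = {tuple(permute_equiprobable(cm, rng).cells[:, 0]) for _ in range(50)}
        assert seen == {("0", "1"), ("1", "0")}

    @pytest.mark.parametrize("seed", range(10))
    def test_column_multisets_preserved(self, seed):
        cm = small_random_matrix(seed)
        pcm = permute_equiprobable(cm, np.random.default_rng(seed))
        for j in range(cm.n_characters):
            assert Counter(cm.cells[:, j]) == Counter(pcm.cells[:, j])


class TestPatristicWeights:
    def test_two_leaf_tree(self):
        tree = parse_newick("(A:1,B:1);")
        w = patristic_weights(tree, ("A", "B"), k=1.01)
        assert w.W[0, 1] == pytest.approx(0.01)
        assert w.W[0, 0] == pytest.approx(1.01)

    def test_star_tree_weights_equal(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1);")
        w = patristic_weights(tree, ("A", "B", "C", "D"), k=1.01)
        off = w.W[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_large_k_exchange_weights_near_uniform(self):
        tree = parse_newick("((A:1,B:2):3,(C:1,D:5):1);")
        w = patristic_weights(tree, ("A", "B", "C", "D"), k=1000)
        off = w.W[~np.eye(4, dtype=bool)]
        assert off.max() / off.min() < 1.001

    def test_k_must_exceed_one(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            patristic_weights(tree, ("A", "B"), k=1.0)

    def test_missing_taxon_reported(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="ZZ"):
            patristic_weights(tree, ("A", "ZZ"), k=1.01)


class TestPhylogeneticPermutation:
    def test_constant_column_is_noop(self):
        cm = parse_table("A,0\nB,0\nC,0\n")
        tree = parse_newick("(A:1,B:1,C:1);")
        w = patristic_weights(tree, cm.taxa, 1.01)
        pcm = permute_phylogenetic(cm, w, np.random.default_rng(0))
        assert list(pcm.cells[:, 0]) == ["0", "0", "0"]

    @pytest.mark.parametrize("seed", range(5))
    def test_column_multisets_preserved(self, seed):
        cfg = SimulationConfig(n_taxa=6, n_characters=8, n_states=3, seed=seed)
        cm = random_matrix(cfg)
        tree = parse_newick("(" + ",".join(f"{t}:1" for t in cm.taxa) + ");")
        w = patristic_weights(tree, cm.taxa, 1.01)
        pcm = permute_phylogenetic(cm, w, np.random.default_rng(seed))
        for j in range(cm.n_characters):
            assert Counter(cm.cells[:, j]) == Counter(pcm.cells[:, j])

    def test_exchangeable_limit_bijections_uniform(self):
        """In the exchangeable (large-k) limit on a star tree, π is uniform.

        At small k the self weight k dominates the off-diagonal k − 1, so
        star-tree permutations concentrate near the identity; uniformity is a
        property of the exchangeable limit, where all weights coincide.
        """
        cm = parse_table("A,0\nB,1\nC,2\n")
        tree = parse_newick("(A:1,B:1,C:1);")
        w = patristic_weights(tree, cm.taxa, k=1000.0)
        rng = np.random.default_rng(7)
        counts = Counter(
            tuple(permute_phylogenetic(cm, w, rng).cells[:, 0]) for _ in range(3000)
        )
        assert len(counts) == 6
        stat = chisquare(list(counts.values()))
        assert stat.pvalue > 0.01

    def test_short_branches_restrict_movement(self):
        """States swap far more readily inside a tight clade than across it."""
        cm = parse_table("A,0\nB,0\nC,1\nD,1\n")
        tree = parse_newick("((A:0.01,B:0.01):1,(C:0.01,D:0.01):1);")
        w = patristic_weights(tree, cm.taxa, 1.01)
        rng = np.random.default_rng(0)
        unchanged = sum(
            tuple(permute_phylogenetic(cm, w, rng).cells[:, 0]) == ("0", "0", "1", "1")
            for _ in range(500)
        )
        assert unchanged > 400  # cross-clade moves carry weight ≈ 0.01 vs ≈ 1


class TestNullDistribution:
    def test_reproducible_under_seed(self):
        cm = small_random_matrix(3)
        stats = {"n_edges_IV": STANDARD_STATISTICS["n_edges_IV"]}
        a = null_distribution(cm, "equiprobable", 30, stats, seed=11)["n_edges_IV"]
        b = null_distribution(cm, "equiprobable", 30, stats, seed=11)["n_edges_IV"]
        assert np.array_equal(a.replicates, b.replicates)
        assert a.p_high == b.p_high

    def test_empirical_matches_exact_enumeration(self):
        """Empirical p within 3 SE of the exact full-enumeration p (4×3 matrix)."""
        cm = parse_table("a,0,0,0\nb,0,1,1\nc,1,1,0\nd,1,2,1\n")

        def edges_iv(cells):
            tm = recode(cm.with_cells(cells))
            return len(brute_edges(tm)["IV"])

        observed = edges_iv(cm.cells)
        cols = [cm.cells[:, j] for j in range(3)]
        exact_ge = 0
        total = 0
        perms = list(permutations(range(4)))
        for p1, p2, p3 in product(perms, perms, perms):
            cells = np.stack(
                [cols[0][list(p1)], cols[1][list(p2)], cols[2][list(p3)]], axis=1
            )
            exact_ge += edges_iv(cells) >= observed
            total += 1
        p_exact = exact_ge / total

        M = 1500
        res = null_distribution(
            cm, "equiprobable", M,
            {"n_edges_IV": STANDARD_STATISTICS["n_edges_IV"]}, seed=5,
        )["n_edges_IV"]
        se = np.sqrt(p_exact * (1 - p_exact) / M)
        assert abs(res.p_high - p_exact) <= 3 * se + 1 / (M + 1)

    def test_phylogenetic_requires_weights(self):
        cm = small_random_matrix(1)
        with pytest.raises(ValueError, match="requires"):
            null_distribution(cm, "phylogenetic", 5, {}, seed=0)


class TestSignificanceCalls:
    def _nulls_for(self, cm, tree, M, seed):
        w = patristic_weights(tree, cm.taxa, 1.01)
        stats = {"in_degree_II": NODE_STATISTICS["in_degree_II"]}
        ne = null_distribution(cm, "equiprobable", M, stats, seed)
        np_ = null_distribution(
            cm, "phylogenetic", M, stats, seed + 1, weights=w
        )
        return ne["in_degree_II"], np_["in_degree_II"]

    def test_requires_phylogenetic_null(self):
        cm = small_random_matrix(2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = build_network(recode(cm))
        recs = type2_degrees(net)
        ne = null_distribution(
            cm, "equiprobable", 19,
            {"in_degree_II": NODE_STATISTICS["in_degree_II"]}, seed=0,
        )["in_degree_II"]
        with pytest.raises(ValueError):
            significant_stable_traits(recs, ne, None)

    def test_all_identical_columns_flag_nothing(self):
        """A permutation-invariant matrix can never yield significance."""
        cm = parse_table("a,0,0\nb,0,0\nc,1,1\nd,1,1\n")
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        net = build_network(recode(cm))
        recs = type2_degrees(net)
        ne, np_ = self._nulls_for(cm, tree, M=60, seed=1)
        assert significant_stable_traits(recs, ne, np_, alpha=0.05) == set()

    def test_zero_in_degree_never_flagged(self):
        cfg = SimulationConfig(n_taxa=8, n_characters=12, n_states=2, seed=4)
        cm = random_matrix(cfg)
        tree = parse_newick("(" + ",".join(f"{t}:1" for t in cm.taxa) + ");")
        net = build_network(recode(cm))
        recs = type2_degrees(net)
        ne, np_ = self._nulls_for(cm, tree, M=99, seed=2)
        flagged = significant_stable_traits(recs, ne, np_, alpha=0.99)
        zero_in = {r.node_id for r in recs if r.in_degree == 0}
        assert not flagged & zero_in
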