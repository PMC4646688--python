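"""Distance, NJ, bootstrap, consensus and Newick round-trip tests."""

import math
import random

import numpy as np
import pytest

from gasp.errors import InputError, NewickParseError, UndefinedDistanceError
from gasp.phylogeny import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    distance_matrix,
    majority_consensus,
    neighbor_joining,
    protein_distance,
    read_newick,
    write_newick,
)
from gasp.simulate import SimulationConfig, simulate_family
from oracles import (
    dendropy_splits,
    exhaustive_best_topology,
    enumerate_topologies,
    topology_splits,
    tree_distance_matrix,
)


class TestProteinDistance:
    def test_identical_sequences_are_zero_under_both_models(self):
        for model in ("p-distance", "poisson"):
            assert protein_distance("ACDEF", "ACDEF", model) == 0.0

    def test_p_distance_arithmetic(self):
        assert protein_distance("AAAAAAAAAA", "AAACCCAAAA", "p-distance") == pytest.approx(0.3)

    def test_poisson_closed_form_at_half(self):
        assert protein_distance("AC", "AG", "poisson") == pytest.approx(-math.log(0.5))

    def test_gaps_and_x_excluded_from_comparable_columns(self):
        # columns 2 and 3 are gapped/X on one side: 3 comparable, 1 mismatch
        assert protein_distance("A-XCA", "AG-CC", "p-distance") == pytest.approx(1 / 3)

    def test_saturation_capped_with_warning(self):
        with pytest.warns(UserWarning, match="saturation"):
            d = protein_distance("AAAA", "CCCC", "poisson")
        assert d == pytest.approx(-math.log(0.05))

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(UndefinedDistanceError):
            protein_distance("--AA", "AA--")

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InputError):
            protein_distance("AA", "AAA")


class TestNeighborJoining:
    def test_three_point_formulas(self):
        m = DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = neighbor_joining(m)
        lens = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lens == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(InputError):
            neighbor_joining(DistanceMatrix(("A", "B"), np.zeros((2, 2))))

    def test_four_taxon_additive_matrix_recovers_topology(self):
        # tree ((0,1),(2,3)) with internal branch 1.0
        edges = [(0, 4), (1, 4), (2, 5), (3, 5), (4, 5)]
        lengths = np.array([0.2, 0.3, 0.25, 0.4, 1.0])
        d = tree_distance_matrix(edges, lengths, 4)
        tree = neighbor_joining(DistanceMatrix(("t0", "t1", "t2", "t3"), d))
        splits = {frozenset(int(x[1:]) for x in bp) for bp in bipartitions(tree)}
        assert splits == set(exhaustive_best_topology(d))
        assert splits == {frozenset({2, 3})}
        # exact branch lengths on an additive matrix
        lens = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lens["t0"] == pytest.approx(0.2)
        assert lens["t3"] == pytest.approx(0.4)

    @pytest.mark.parametrize("n_leaves", [5, 6, 7])
    def test_additive_recovery_matches_exhaustive_oracle(self, n_leaves):
        rng = random.Random(100 + n_leaves)
        topologies = enumerate_topologies(n_leaves)
        for _ in range(10):
            edges = topologies[rng.randrange(len(topologies))]
            lengths = np.array([rng.uniform(0.1, 1.0) for _ in edges])
            d = tree_distance_matrix(edges, lengths, n_leaves)
            taxa = tuple(f"t{i}" for i in range(n_leaves))
            tree = neighbor_joining(DistanceMatrix(taxa, d))
            got = {frozenset(int(x[1:]) for x in bp) for bp in bipartitions(tree)}
            assert got == set(topology_splits(edges, n_leaves))
            assert got == set(exhaustive_best_topology(d))

    def test_equal_distances_tie_break_is_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), d))
        t2 = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), d))
        assert write_newick(t1) == write_newick(t2)
        # lowest-index join: a and b end up as siblings
        assert frozenset({"c", "d"}) in bipartitions(t1)

    def test_negative_branch_lengths_clamped(self):
        # triangle-inequality violation forces a negative three-point length
        d = np.array([[0, 10, 3], [10, 0, 3], [3, 3, 0]], float)
        with pytest.warns(UserWarning, match="clamped"):
            tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), d))
        assert all((e.length or 0) >= 0 for e in tree.edges())

    def test_bipartitions_match_dendropy_encoding(self):
        rng = random.Random(5)
        for n in (5, 6, 8):
            tops = enumerate_topologies(n)
            edges = tops[rng.randrange(len(tops))]
            lengths = np.array([rng.uniform(0.1, 1.0) for _ in edges])
            d = tree_distance_matrix(edges, lengths, n)
            tree = neighbor_joining(DistanceMatrix(tuple(f"t{i}" for i in range(n)), d))
            assert bipartitions(tree) == dendropy_splits(tree)

    def test_matches_skbio_on_generic_matrices(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(2)
        for _ in range(5):
            n = 6
            noise = rng.random((n, n))
            d = (noise + noise.T) * (1 - np.eye(n)) + 0.5
            np.fill_diagonal(d, 0)
            ids = [f"t{i}" for i in range(n)]
            ours = neighbor_joining(DistanceMatrix(tuple(ids), d))
            theirs = read_newick(str(sk_nj(SkDM(d, ids))))
            assert bipartitions(ours) == bipartitions(theirs)


class TestBootstrap:
    NAMES = ["A", "B", "C", "D", "E"]
    SEQS = ["AACC" * 40, "AACC" * 40, "CCAA" * 40, "CCAA" * 40, "ACAC" * 40]

    def test_uniform_column_patterns_give_full_support(self):
        tree = bootstrap_support(self.NAMES, self.SEQS, replicates=25, seed=3)
        supports = [
            n.support
            for n in tree.preorder_node_iter()
            if n is not tree.seed_node and not n.is_leaf() and hasattr(n, "support")
        ]
        assert supports and all(s == 100 for s in supports)

    def test_fixed_seed_is_bit_reproducible(self):
        cfg = SimulationConfig(n_leaves=10, mean_branch_length=0.2, seed=77)
        fam = simulate_family(cfg)
        names = sorted(fam.leaf_sequences)
        seqs = [fam.leaf_sequences[n] for n in names]
        t1 = bootstrap_support(names, seqs, replicates=30, seed=9)
        t2 = bootstrap_support(names, seqs, replicates=30, seed=9)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_within_range(self):
        tree = bootstrap_support(self.NAMES, self.SEQS, replicates=10, seed=1)
        for n in tree.preorder_node_iter():
            if hasattr(n, "support"):
                assert 0 <= n.support <= 100

    def test_true_split_outranks_alternatives_on_long_internal_branch(self):
        tree = read_newick("(A:0.05,B:0.05,(C:0.05,D:0.05):0.8);")
        cfg = SimulationConfig(tree=tree, substitution_rate=1.0, seed=13)
        fam = simulate_family(cfg)
        names = ["A", "B", "C", "D"]
        seqs = [fam.leaf_sequences[n] for n in names]
        # count all three possible splits across replicates
        counts = {frozenset({"C", "D"}): 0, frozenset({"B", "C"}): 0, frozenset({"B", "D"}): 0}
        streams = np.random.SeedSequence(4).spawn(100)
        L = len(seqs[0])
        for ss in streams:
            rng = np.random.default_rng(ss)
            cols = rng.integers(0, L, size=L)
            rs = ["".join(s[c] for c in cols) for s in seqs]
            rep = neighbor_joining(distance_matrix(names, rs))
            for bp in bipartitions(rep):
                if bp in counts:
                    counts[bp] += 1
        true = counts[frozenset({"C", "D"})]
        assert true > counts[frozenset({"B", "C"})]
        assert true > counts[frozenset({"B", "D"})]

    def test_zero_replicates_rejected(self):
        with pytest.raises(InputError):
            bootstrap_support(self.NAMES, self.SEQS, replicates=0, seed=1)


class TestConsensus:
    def test_identical_trees_return_same_splits_at_full_frequency(self):
        t = [read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);") for _ in range(4)]
        cons = majority_consensus(t)
        assert bipartitions(cons) == bipartitions(t[0])
        supports = [
            n.support for n in cons.preorder_node_iter() if hasattr(n, "support")
        ]
        assert all(s == 100 for s in supports)

    def test_two_of_three_included_at_default_threshold(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t3 = read_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        cons = majority_consensus([t1, t2, t3])
        assert frozenset({"C", "D"}) in bipartitions(cons)
        assert frozenset({"B", "D"}) not in bipartitions(cons)

    def test_counting_matches_exhaustive_oracle_on_random_tree_sets(self):
        rng = random.Random(8)
        n = 6
        taxa = [f"t{i}" for i in range(n)]
        tops = enumerate_topologies(n)
        for _ in range(10):
            trees = []
            chosen = [tops[rng.randrange(len(tops))] for _ in range(5)]
            for edges in chosen:
                lengths = np.array([1.0] * len(edges))
                d = tree_distance_matrix(edges, lengths, n)
                trees.append(neighbor_joining(DistanceMatrix(tuple(taxa), d)))
            cons = majority_consensus(trees, threshold=0.5)
            # oracle: count splits across the generating topologies
            from collections import Counter

            counter = Counter()
            for edges in chosen:
                for s in topology_splits(edges, n):
                    counter[frozenset(f"t{i}" for i in s)] += 1
            expected = {s for s, c in counter.items() if c / len(chosen) > 0.5}
            assert bipartitions(cons) == expected

    def test_mismatched_leaf_sets_rejected(self):
        t1 = read_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = read_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(InputError):
            majority_consensus([t1, t2])


class TestNewickIO:
    def test_basic_round_trip(self):
        s = "(A:1,B:1,(C:1,D:1):2);"
        tree = read_newick(s)
        back = read_newick(write_newick(tree))
        assert bipartitions(back) == bipartitions(tree)
        lens = sorted(l.edge.length for l in back.leaf_node_iter())
        assert lens == pytest.approx([1, 1, 1, 1], abs=1e-9)

    def test_support_values_round_trip(self):
        tree = read_newick("(A:1,B:1,(C:1,D:1)87:2);")
        node = next(
            n for n in tree.preorder_node_iter() if not n.is_leaf() and n.label == "87"
        )
        assert node.support == 87
        assert "87" in write_newick(tree)

    def test_quoted_labels_with_spaces_round_trip(self):
        s = "('taxon one':1,'taxon two':1,(C:1,D:1):2);"
        tree = read_newick(s)
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        assert "taxon one" in labels
        back = read_newick(write_newick(tree))
        assert {l.taxon.label for l in back.leaf_node_iter()} == labels

    def test_writer_reader_fuzz(self):
        rng = random.Random(12)
        n = 7
        tops = enumerate_topologies(n)
        for _ in range(10):
            edges = tops[rng.randrange(len(tops))]
            lengths = np.array([rng.uniform(0.01, 3.0) for _ in edges])
            d = tree_distance_matrix(edges, lengths, n)
            tree = neighbor_joining(DistanceMatrix(tuple(f"t{i}" for i in range(n)), d))
            back = read_newick(write_newick(tree))
            assert bipartitions(back) == bipartitions(tree)
            a = sorted(l.edge.length for l in tree.leaf_node_iter())
            b = sorted(l.edge.length for l in back.leaf_node_iter())
            assert b == pytest.approx(a, abs=1e-9)

    def test_malformed_newick_raises_parse_error(self):
        with pytest.raises(NewickParseError):
            read_newick("((A:1,B:1;")
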