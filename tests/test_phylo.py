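"""Distances, neighbor joining, bootstrap and Newick serialization."""

import io
import math

import numpy as np
import pytest
from Bio import Phylo

from bamboocad.phylo import (
    Alignment,
    DistanceMatrix,
    NoSharedColumnsError,
    SaturationError,
    bootstrap_support,
    neighbor_joining,
    newick_string,
    pairwise_distance,
    write_newick,
)
from bamboocad.simulate import evolve_alignment, random_additive_tree

from helpers import least_squares_topology


class TestPairwiseDistance:
    def test_identical_sequences_have_zero_distance(self):
        aln = Alignment(("a", "b", "c"), ("MKV", "MKV", "MKV"))
        for model in ("p_distance", "poisson"):
            dm = pairwise_distance(aln, model)
            assert np.allclose(dm.matrix, 0.0)

    def test_p_distance_quarter(self):
        aln = Alignment(("a", "b"), ("AAAA", "AAAT"))
        dm = pairwise_distance(aln, "p_distance")
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_poisson_correction_closed_form(self):
        aln = Alignment(("a", "b"), ("AAAA", "TTAA"))
        dm = pairwise_distance(aln, "poisson")
        assert dm.matrix[0, 1] == pytest.approx(-math.log(0.5), abs=1e-12)

    def test_pairwise_deletion_ignores_gapped_columns(self):
        aln = Alignment(("a", "b"), ("A-AT", "AC-T"))
        dm = pairwise_distance(aln, "p_distance")
        # only columns 1 and 4 are shared; both match
        assert dm.matrix[0, 1] == 0.0

    def test_complete_deletion_drops_any_gap_column(self):
        aln = Alignment(("a", "b", "c"), ("AAT", "A-T", "AAA"))
        dm = pairwise_distance(aln, "p_distance", gap_mode="complete")
        # column 2 dropped for every pair; a vs c differ at 1 of 2 columns
        assert dm.matrix[0, 2] == pytest.approx(0.5)

    def test_saturation_is_an_error_naming_the_pair(self):
        aln = Alignment(("sat1", "sat2"), ("AAAA", "TTTT"))
        with pytest.raises(SaturationError, match="sat1"):
            pairwise_distance(aln, "poisson")

    def test_no_shared_columns_is_an_error(self):
        aln = Alignment(("a", "b"), ("A--", "-AA"))
        with pytest.raises(NoSharedColumnsError):
            pairwise_distance(aln, "p_distance")


def _dm(labels, pairs):
    n = len(labels)
    m = np.zeros((n, n))
    idx = {lab: i for i, lab in enumerate(labels)}
    for (a, b), d in pairs.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = d
    return DistanceMatrix(labels=tuple(labels), matrix=m)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # generated by tree ((A:1,B:2):1,(C:3,D:4))
        dm = _dm(
            "ABCD",
            {
                ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
                ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
            },
        )
        tree = neighbor_joining(dm)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        recovered = tree.path_length_matrix()
        assert recovered.labels == tuple("ABCD")
        assert np.allclose(recovered.matrix, dm.matrix, atol=1e-9)
        # leaf and internal edge lengths
        lengths = {}
        for child in tree.root.children:
            if child.is_leaf:
                lengths[child.name] = child.length
            else:
                internal = child.length
                for leaf in child.children:
                    lengths[leaf.name] = leaf.length
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        assert internal == pytest.approx(1.0)

    def test_three_taxon_closed_form(self):
        dm = _dm("ABC", {("A", "B"): 2, ("A", "C"): 3, ("B", "C"): 4})
        tree = neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_equidistant_matrix_documented_tie_break(self):
        dm = _dm(
            "ABCD",
            {(a, b): 2.0 for a, b in
             [("A", "B"), ("A", "C"), ("A", "D"),
              ("B", "C"), ("B", "D"), ("C", "D")]},
        )
        tree = neighbor_joining(dm)
        # lowest-index pair (A, B) joined first; internal edge collapses to 0
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        internal = [c for c in tree.root.children if not c.is_leaf]
        assert internal[0].length == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_three_taxa_rejected(self):
        dm = _dm("AB", {("A", "B"): 1})
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_asymmetric_input_rejected(self):
        m = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=("a", "b", "c"), matrix=m)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_exact_on_random_additive_matrices(self, n_taxa):
        for seed in range(10):
            tree = random_additive_tree(n_taxa, seed=seed * 100 + n_taxa)
            dm = tree.path_length_matrix()
            nj = neighbor_joining(dm)
            assert nj.bipartitions() == tree.bipartitions()
            assert np.allclose(
                nj.path_length_matrix().matrix, dm.matrix, atol=1e-9
            )

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        for seed in range(5):
            tree = random_additive_tree(7, seed=seed + 50)
            dm = tree.path_length_matrix()
            mine = neighbor_joining(dm).bipartitions()
            sk_tree = skbio.tree.nj(
                skbio.DistanceMatrix(dm.matrix.copy(), ids=list(dm.labels))
            )
            theirs = set()
            n = len(dm.labels)
            for node in sk_tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= n - 2:
                    all_set = frozenset(dm.labels)
                    ref = min(all_set)
                    theirs.add(all_set - side if ref in side else side)
            assert mine == theirs

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_matches_least_squares_oracle_on_additive_input(self, n_taxa):
        for seed in range(3):
            tree = random_additive_tree(n_taxa, seed=seed * 31 + n_taxa)
            dm = tree.path_length_matrix()
            nj = neighbor_joining(dm)
            oracle = least_squares_topology(dm.labels, dm.matrix)
            assert nj.bipartitions() == oracle


def _separating_alignment():
    """Every column separates {A,B} from {C,D}."""
    return Alignment(
        ("A", "B", "C", "D"),
        ("AAAAAAAAAA", "AAAAAAAAAA", "TTTTTTTTTT", "TTTTTTTTTT"),
    )


class TestBootstrap:
    def test_perfect_separation_gives_full_support(self):
        res = bootstrap_support(
            _separating_alignment(), replicates=50, model="p_distance", seed=1
        )
        assert res.support == {frozenset({"C", "D"}): 100.0}

    def test_single_replicate_support_is_zero_or_hundred(self):
        tree = random_additive_tree(5, seed=2, min_length=0.05, max_length=0.3)
        aln = evolve_alignment(tree, 200, seed=2)
        res = bootstrap_support(aln, replicates=1, seed=3)
        assert set(res.support.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces_identical_supports(self):
        tree = random_additive_tree(6, seed=4, min_length=0.05, max_length=0.4)
        aln = evolve_alignment(tree, 300, seed=4)
        r1 = bootstrap_support(aln, replicates=30, seed=9)
        r2 = bootstrap_support(aln, replicates=30, seed=9)
        assert r1.support == r2.support

    def test_support_invariant_under_taxon_reordering(self):
        tree = random_additive_tree(6, seed=6, min_length=0.05, max_length=0.4)
        aln = evolve_alignment(tree, 300, seed=6)
        order = [3, 0, 5, 1, 4, 2]
        shuffled = Alignment(
            tuple(aln.ids[i] for i in order), tuple(aln.seqs[i] for i in order)
        )
        r1 = bootstrap_support(aln, replicates=40, seed=11)
        r2 = bootstrap_support(shuffled, replicates=40, seed=11)
        assert set(r1.support) == set(r2.support)

    def test_simulated_tree_bipartitions_recovered(self):
        tree = random_additive_tree(6, seed=8, min_length=0.08, max_length=0.5)
        aln = evolve_alignment(tree, 500, seed=8)
        res = bootstrap_support(aln, replicates=100, seed=13)
        assert res.tree.bipartitions() == tree.bipartitions()


class TestNewick:
    def test_three_taxon_star_string(self):
        dm = _dm("ABC", {("A", "B"): 2, ("A", "C"): 3, ("B", "C"): 4})
        s = newick_string(neighbor_joining(dm))
        assert s == "(A:0.5,B:1.5,C:2.5);"

    def test_round_trip_topology_lengths_supports(self, tmp_path):
        tree = random_additive_tree(7, seed=12)
        aln = evolve_alignment(tree, 300, seed=12)
        res = bootstrap_support(aln, replicates=20, seed=5)
        path = tmp_path / "tree.nwk"
        write_newick(res.tree, path)
        parsed = Phylo.read(str(path), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(
            res.tree.leaf_names
        )
        # branch lengths survive to 1e-9: compare path-length matrices
        mine = res.tree.path_length_matrix()
        for i, a in enumerate(mine.labels):
            for j in range(i + 1, len(mine.labels)):
                b = mine.labels[j]
                assert parsed.distance(a, b) == pytest.approx(
                    mine.matrix[i, j], abs=1e-9
                )
        # supports come back as internal-node confidences
        confidences = sorted(
            c.confidence for c in parsed.get_nonterminals() if c.confidence is not None
        )
        assert confidences == sorted(
            round(v, 6) for v in res.support.values()
        )

    def test_metacharacter_labels_are_quoted(self):
        dm = _dm(
            ("A B", "C:D", "E"),
            {("A B", "C:D"): 2, ("A B", "E"): 3, ("C:D", "E"): 4},
        )
        s = newick_string(neighbor_joining(dm))
        assert "'A B'" in s and "'C:D'" in s
        parsed = Phylo.read(io.StringIO(s), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == ["A B", "C:D", "E"]

    def test_empty_tree_rejected(self):
        from bamboocad.phylo import PhyloTree, TreeNode

        with pytest.raises(ValueError):
            newick_string(PhyloTree(root=TreeNode()))
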