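"""NJ, hierarchical clustering, tree metrics, Newick I/O, RF distance."""

import itertools

import dendropy
import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from funcphylo.seqdist import Alignment
from funcphylo.synthetic_data import EvolSimSpec, simulate_alignment
from funcphylo.trees import (bootstrap_support, neighbor_joining,
                             normalize_distances, read_newick, robinson_foulds,
                             specificity_tree, tree_distances, write_newick)

from conftest import random_binary_tree


def patristic(tree):
    d = tree_distances(tree)
    return d


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 2, 3], [2, 0, 3], [3, 3, 0]], ids=list("ABC"))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) -> additive distances by path sums
        d = {
            ("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
            ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9,
        }
        ids = list("ABCD")
        mat = np.zeros((4, 4))
        for (a, b), v in d.items():
            i, j = ids.index(a), ids.index(b)
            mat[i, j] = mat[j, i] = v
        tree = neighbor_joining(DistanceMatrix(mat, ids=ids))
        rec = patristic(tree)
        for (a, b), v in d.items():
            assert rec[a, b] == pytest.approx(v, abs=1e-9)
        # topology: AB vs CD split
        ref = read_newick("((A:1,B:2):3,(C:4,D:5):0);")
        assert robinson_foulds(tree, ref) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_matrices_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(5)]
        true = random_binary_tree(labels, rng, length_range=(0.5, 2.0))
        dm = tree_distances(true)
        tree = neighbor_joining(DistanceMatrix(dm.data, ids=dm.ids))
        assert robinson_foulds(tree, true) == 0
        rec = patristic(tree)
        for a, b in itertools.combinations(labels, 2):
            assert rec[a, b] == pytest.approx(dm[a, b], abs=1e-9)

    def test_matches_independent_nj_implementation(self, rng):
        n = 7
        noise = rng.uniform(0, 0.3, size=(n, n))
        base = rng.uniform(1, 2, size=(n, n))
        mat = (base + base.T) / 2 + (noise + noise.T) / 2
        np.fill_diagonal(mat, 0)
        ids = [f"t{i}" for i in range(n)]
        dm = DistanceMatrix(mat, ids=ids)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        assert robinson_foulds(ours, theirs) == 0

    def test_taxon_order_invariance(self, rng):
        labels = [f"t{i}" for i in range(6)]
        true = random_binary_tree(labels, rng, length_range=(0.5, 1.5))
        dm = tree_distances(true)
        perm = list(rng.permutation(labels))
        permuted = DistanceMatrix(
            [[dm[a, b] for b in perm] for a in perm], ids=perm
        )
        t1 = neighbor_joining(DistanceMatrix(dm.data, ids=dm.ids))
        t2 = neighbor_joining(permuted)
        assert robinson_foulds(t1, t2) == 0
        d1, d2 = patristic(t1), patristic(t2)
        for a, b in itertools.combinations(labels, 2):
            assert d1[a, b] == pytest.approx(d2[a, b], abs=1e-9)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))

    def test_negative_branches_clamped(self):
        # strongly non-additive matrix can force negative NJ lengths
        mat = np.array([
            [0, 1, 9, 9],
            [1, 0, 9, 1],
            [9, 9, 0, 1],
            [9, 1, 1, 0],
        ], dtype=float)
        tree = neighbor_joining(DistanceMatrix(mat, ids=list("ABCD")))
        assert all(
            n.length >= 0 for n in tree.traverse(include_self=False)
        )


class TestSpecificityTree:
    def test_two_taxa_merge_height(self):
        dm = DistanceMatrix([[0, 3.5], [3.5, 0]], ids=["A", "B"])
        tree = specificity_tree(dm)
        assert tree.height == pytest.approx(3.5)
        assert {t.name: t.length for t in tree.tips()} == {"A": 3.5, "B": 3.5}

    def test_three_taxa_average_linkage_arithmetic(self):
        dm = DistanceMatrix(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]], ids=["A", "B", "C"]
        )
        tree = specificity_tree(dm, linkage="average")
        assert tree.height == pytest.approx(10.0)
        first = [c for c in tree.children if not c.is_tip()][0]
        assert {t.name for t in first.tips()} == {"A", "B"}
        assert first.height == pytest.approx(1.0)

    def test_merge_order_matches_bruteforce_average_linkage(self, rng):
        n = 6
        m = rng.uniform(1, 10, size=(n, n))
        mat = (m + m.T) / 2
        np.fill_diagonal(mat, 0)
        ids = [f"r{i}" for i in range(n)]
        tree = specificity_tree(DistanceMatrix(mat, ids=ids), linkage="average")

        # brute-force agglomeration recomputing average linkage from scratch
        clusters = [frozenset([i]) for i in range(n)]
        merges = []
        while len(clusters) > 1:
            best, pair = np.inf, None
            for a, b in itertools.combinations(clusters, 2):
                avg = np.mean([mat[i, j] for i in a for j in b])
                if avg < best:
                    best, pair = avg, (a, b)
            a, b = pair
            clusters = [c for c in clusters if c not in (a, b)] + [a | b]
            merges.append((a | b, best))

        heights = {
            frozenset(int(t.name[1:]) for t in node.tips()): node.height
            for node in tree.non_tips(include_self=True)
        }
        for members, height in merges:
            assert heights[members] == pytest.approx(height)

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            specificity_tree(DistanceMatrix([[0.0]], ids=["A"]))


class TestTreeDistances:
    def test_three_taxon_example(self):
        tree = neighbor_joining(
            DistanceMatrix([[0, 2, 3], [2, 0, 3], [3, 3, 0]], ids=list("ABC"))
        )
        assert tree_distances(tree)["A", "C"] == pytest.approx(3.0)

    def test_zero_length_internal_edges_do_not_change_distances(self):
        t1 = read_newick("((A:1,B:2):0,(C:3,D:4):0);")
        t2 = read_newick("(A:1,B:2,C:3,D:4);")
        d1, d2 = tree_distances(t1), tree_distances(t2)
        for a, b in itertools.combinations("ABCD", 2):
            assert d1[a, b] == pytest.approx(d2[a, b])

    def test_missing_branch_lengths_rejected(self):
        tree = read_newick("((A:1,B:2),C:3);")
        with pytest.raises(ValueError, match="without lengths"):
            tree_distances(tree)


class TestNormalizeDistances:
    def test_max_is_exactly_one(self, rng):
        m = rng.uniform(1, 5, size=(4, 4))
        mat = (m + m.T) / 2
        np.fill_diagonal(mat, 0)
        rel = normalize_distances(DistanceMatrix(mat, ids=list("ABCD")))
        assert rel.data.max() == 1.0

    def test_idempotent_and_scale_invariant(self, rng):
        m = rng.uniform(1, 5, size=(4, 4))
        mat = (m + m.T) / 2
        np.fill_diagonal(mat, 0)
        dm = DistanceMatrix(mat, ids=list("ABCD"))
        rel = normalize_distances(dm)
        again = normalize_distances(rel)
        scaled = normalize_distances(DistanceMatrix(mat * 7, ids=list("ABCD")))
        assert np.allclose(rel.data, again.data)
        assert np.allclose(rel.data, scaled.data)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_distances(DistanceMatrix(np.zeros((3, 3)), ids=list("ABC")))


class TestNewick:
    def test_two_leaf_parse(self):
        tree = read_newick("(A:1,B:1);")
        assert {t.name: t.length for t in tree.tips()} == {"A": 1.0, "B": 1.0}

    def test_malformed_newick_reports_error(self):
        with pytest.raises(ValueError, match="[Nn]ewick"):
            read_newick("((A:1,B:1;")

    def test_nj_output_round_trip(self, rng):
        labels = [f"t{i}" for i in range(6)]
        tree = neighbor_joining(tree_distances(random_binary_tree(labels, rng)))
        back = read_newick(write_newick(tree))
        assert robinson_foulds(tree, back) == 0
        d1, d2 = tree_distances(tree), tree_distances(back)
        assert np.allclose(d1.data, d2.data, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_trees_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(int(rng.integers(4, 10)))]
        tree = random_binary_tree(labels, rng)
        back = read_newick(write_newick(tree))
        assert robinson_foulds(tree, back) == 0
        assert np.allclose(
            tree_distances(tree).data,
            tree_distances(back).filter(tree_distances(tree).ids).data,
            atol=1e-9,
        )


class TestRobinsonFoulds:
    def test_identical_trees_zero(self, rng):
        tree = random_binary_tree([f"t{i}" for i in range(6)], rng)
        assert robinson_foulds(tree, tree) == 0

    def test_two_four_taxon_resolutions_differ_by_two(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(t1, t2) == 2

    def test_mismatched_leaf_sets_rejected(self):
        t1 = read_newick("((A:1,B:1):1,C:1);")
        t2 = read_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError, match="leaf sets"):
            robinson_foulds(t1, t2)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dendropy_symmetric_difference(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(8)]
        t1 = random_binary_tree(labels, rng)
        t2 = random_binary_tree(labels, rng)
        ours = robinson_foulds(t1, t2)
        taxa = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                               taxon_namespace=taxa)
        d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                               taxon_namespace=taxa)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        theirs = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert ours == theirs


class TestBootstrapSupport:
    def test_conflict_free_signal_gives_full_support(self):
        # every column supports the same AB|CD split; no resample can disagree
        cols_ab = ["A", "A", "C", "C"]
        seqs = ["".join(cols_ab[i] for _ in range(40)) for i in range(4)]
        aln = Alignment(labels=list("ABCD"), sequences=seqs)
        tree = bootstrap_support(aln, n=50, seed=0)
        supports = [n.support for n in tree.non_tips(include_self=False)
                    if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_seeded_determinism(self, rng):
        true = random_binary_tree(list("ABCDEF"), rng)
        aln = simulate_alignment(EvolSimSpec(tree=true, seq_length=300, seed=4))
        t1 = bootstrap_support(aln, n=30, seed=11)
        t2 = bootstrap_support(aln, n=30, seed=11)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False)
                    if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False)
                    if hasattr(n, "support"))
        assert s1 == s2

    def test_support_matches_independent_replicate_replay(self):
        # 4 taxa, weak signal split across columns; replay the identical
        # column resamples independently and count the AB|CD split
        from funcphylo.seqdist import pairwise_distance
        from funcphylo.trees import _bipartitions

        rng = np.random.default_rng(99)
        base = rng.choice(list("ACDEFGHIKL"), size=(4, 60))
        # inject a weak AB|CD signal plus noise columns
        for col in range(0, 60, 4):
            base[:, col] = ["W", "W", "Y", "Y"]
        for col in range(1, 60, 9):
            base[:, col] = ["M", "H", "M", "H"]  # conflicting AC|BD-ish signal
        aln = Alignment(labels=list("ABCD"),
                        sequences=["".join(r) for r in base])
        n = 50
        tree = bootstrap_support(aln, n=n, seed=123)
        (support,) = [node.support for node in tree.non_tips(include_self=False)
                      if hasattr(node, "support")]

        point_bp = _bipartitions(tree)
        replay = np.random.default_rng(123)
        count = 0
        for _ in range(n):
            cols = replay.integers(0, 60, size=60)
            sub = Alignment(labels=list("ABCD"),
                            sequences=["".join(r) for r in base[:, cols]])
            rep = neighbor_joining(pairwise_distance(sub))
            count += _bipartitions(rep) >= point_bp
        assert support == pytest.approx(100.0 * count / n)
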