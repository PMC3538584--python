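"""Tree I/O, caterpillar fixtures, scaling, distance matrices, NJ, RF."""

import numpy as np
import pytest

import phylosr as ps
from phylosr.errors import InvalidInputError
from phylosr.trees import (nj_bipartitions, read_phylip_matrix, tree_bipartitions,
                           write_phylip_matrix)

from conftest import exact_distance_map, random_binary_tree


class TestNewickIO:
    def test_quartet_parse(self):
        t = ps.read_newick("((a:1,b:1):0.5,c:1,d:1);")
        labels = sorted(lf.taxon.label for lf in t.leaf_node_iter())
        assert labels == ["a", "b", "c", "d"]
        internal = [e.length for e in t.preorder_edge_iter()
                    if e.head_node.parent_node is not None
                    and not e.head_node.is_leaf()]
        assert internal == [0.5]

    def test_round_trip_preserves_lengths(self, caterpillar7):
        text = ps.write_newick(caterpillar7)
        back = ps.read_newick(text)
        assert ps.rf_distance(back, caterpillar7) == 0
        pdm1 = exact_distance_map(caterpillar7)
        pdm2 = exact_distance_map(back)
        assert np.allclose(pdm1.matrix, pdm2.matrix, atol=1e-12)

    def test_malformed_input(self):
        with pytest.raises(InvalidInputError):
            ps.read_newick("((a:1,b:1;")


class TestCaterpillar:
    def test_seven_leaves_has_four_internal_edges(self, caterpillar7):
        internal = [e for e in caterpillar7.preorder_edge_iter()
                    if e.head_node.parent_node is not None
                    and not e.head_node.is_leaf()]
        assert len(internal) == 4
        assert all(e.length == pytest.approx(0.1) for e in internal)

    def test_four_leaves_is_a_quartet(self):
        t = ps.caterpillar_tree(4, 0.2, 0.5)
        assert len(tree_bipartitions(t)) == 1

    def test_diameter_formula(self):
        for n in [4, 6, 9]:
            t = ps.caterpillar_tree(n, 0.1, 0.5)
            assert ps.tree_diameter(t) == pytest.approx(2 * 0.5 + (n - 3) * 0.1)

    def test_too_small(self):
        with pytest.raises(InvalidInputError):
            ps.caterpillar_tree(3, 0.1, 0.5)


class TestScaling:
    def test_scaling_hits_target(self, caterpillar7):
        for s in [0.1, 1.0, 2.0]:
            scaled = ps.scale_tree_to_diameter(caterpillar7, s)
            assert ps.tree_diameter(scaled) == pytest.approx(s, abs=1e-12)
            assert ps.rf_distance(scaled, caterpillar7) == 0

    def test_identity_scale(self, caterpillar7):
        d = ps.tree_diameter(caterpillar7)
        scaled = ps.scale_tree_to_diameter(caterpillar7, d)
        for e1, e2 in zip(caterpillar7.preorder_edge_iter(), scaled.preorder_edge_iter()):
            if e1.length is not None:
                assert e2.length == pytest.approx(e1.length, rel=1e-12)


class TestDistanceMatrix:
    def test_identical_sequences_give_zeros(self):
        aln = ps.Alignment(["a", "b", "c"], ["ACGT" * 5] * 3)
        D = ps.distance_matrix(aln, ps.JC)
        assert np.allclose(D.matrix, 0.0)

    def test_k2p_distances_converge_to_path_times(self):
        tree = ps.read_newick("((a:0.3,b:0.3):0.2,c:0.4,d:0.4);")
        aln = ps.simulate_alignment(tree, 2.0, 100_000, seed=21)
        D = ps.distance_matrix(aln, ps.K2P)
        truth = exact_distance_map(tree)
        assert D.labels == truth.labels
        assert np.allclose(D.matrix, truth.matrix, atol=0.03)

    def test_symmetry_and_saturation_flags(self):
        aln = ps.Alignment(["a", "b"], ["AAAA", "CGCG"])  # 4 tv differences
        D = ps.distance_matrix(aln, ps.TV)
        assert D.saturated[0, 1] and D.saturated[1, 0]
        assert D.matrix[0, 1] == D.matrix[1, 0] == 5.0  # default cap


class TestNeighborJoining:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_consistency_on_additive_input(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree(5 + seed, rng)
        nj = ps.neighbor_joining(exact_distance_map(tree))
        assert ps.rf_distance(nj, tree) == 0

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_affine_invariance_of_topology(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree(7, rng)
        D = exact_distance_map(tree)
        a = 0.2 + 3 * rng.random()
        b = rng.uniform(-0.05, 0.5)
        M = a * D.matrix + b
        np.fill_diagonal(M, 0.0)
        nj1 = ps.neighbor_joining(D)
        nj2 = ps.neighbor_joining(ps.DissimilarityMap(D.labels, M))
        assert ps.rf_distance(nj1, nj2) == 0

    def test_robust_below_atteson_radius(self, caterpillar7):
        """Perturbing each entry by less than half the minimal internal edge
        never changes the NJ topology."""
        D = exact_distance_map(caterpillar7)
        t_min = 0.1
        rng = np.random.default_rng(42)
        for _ in range(10):
            noise = rng.uniform(-0.49 * t_min, 0.49 * t_min, D.matrix.shape)
            noise = np.triu(noise, 1)
            M = D.matrix + noise + noise.T
            nj = ps.neighbor_joining(ps.DissimilarityMap(D.labels, M))
            assert ps.rf_distance(nj, caterpillar7) == 0

    def test_matches_scikit_bio(self):
        """Independent cross-check of the in-repo NJ against scikit-bio's
        implementation on a random additive matrix."""
        skbio_nj = pytest.importorskip("skbio.tree").nj
        from skbio import DistanceMatrix

        rng = np.random.default_rng(8)
        tree = random_binary_tree(8, rng)
        D = exact_distance_map(tree)
        ours = ps.neighbor_joining(D)
        theirs = ps.read_newick(str(skbio_nj(DistanceMatrix(D.matrix, D.labels))))
        assert ps.rf_distance(ours, theirs) == 0

    def test_non_finite_rejected(self):
        M = np.zeros((4, 4))
        M[0, 1] = M[1, 0] = np.inf
        with pytest.raises(InvalidInputError):
            ps.neighbor_joining(ps.DissimilarityMap(list("abcd"), M))

    def test_fast_path_matches_tree_object_path(self, caterpillar7):
        D = exact_distance_map(caterpillar7)
        fast = nj_bipartitions(D.matrix, D.labels)
        tree = ps.neighbor_joining(D)
        assert fast == tree_bipartitions(tree)


class TestRobinsonFoulds:
    def test_identity(self, caterpillar7):
        assert ps.rf_distance(caterpillar7, caterpillar7) == 0

    def test_maximal_seven_taxon_distance(self):
        """Two binary 7-taxon trees with disjoint split sets realize the
        maximum 2 * (n - 3) = 8."""
        t1 = ps.caterpillar_tree(7, 0.1, 0.5)  # order L1..L7
        t2 = ps.read_newick(
            "(((((L1:1,L4:1):1,L6:1):1,L2:1):1,L7:1):1,L3:1,L5:1);")
        assert ps.rf_distance(t1, t2) == 8
        assert ps.normalized_rf(t1, t2) == 1.0

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(30)
        trees = [random_binary_tree(6, rng) for _ in range(3)]
        # identical leaf label sets by construction
        d01 = ps.rf_distance(trees[0], trees[1])
        d10 = ps.rf_distance(trees[1], trees[0])
        d02 = ps.rf_distance(trees[0], trees[2])
        d12 = ps.rf_distance(trees[1], trees[2])
        assert d01 == d10
        assert d02 <= d01 + d12

    def test_normalized_range(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            a, b = random_binary_tree(7, rng), random_binary_tree(7, rng)
            assert 0.0 <= ps.normalized_rf(a, b) <= 1.0

    def test_leaf_set_mismatch(self, caterpillar7):
        other = ps.caterpillar_tree(6, 0.1, 0.5)
        with pytest.raises(InvalidInputError):
            ps.rf_distance(caterpillar7, other)

    def test_matches_dendropy(self):
        """Cross-check the bipartition-set RF against dendropy's
        implementation on random tree pairs."""
        import dendropy
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(32)
        for _ in range(5):
            a, b = random_binary_tree(7, rng), random_binary_tree(7, rng)
            tns = dendropy.TaxonNamespace()
            da = dendropy.Tree.get(data=ps.write_newick(a), schema="newick",
                                   taxon_namespace=tns)
            db = dendropy.Tree.get(data=ps.write_newick(b), schema="newick",
                                   taxon_namespace=tns)
            da.encode_bipartitions()
            db.encode_bipartitions()
            expected = treecompare.symmetric_difference(da, db)
            assert ps.rf_distance(a, b) == expected


class TestPhylipIO:
    def test_round_trip(self, caterpillar7):
        D = exact_distance_map(caterpillar7)
        text = write_phylip_matrix(D)
        back = read_phylip_matrix(text)
        assert back.labels == D.labels
        assert np.allclose(back.matrix, D.matrix, atol=1e-6)
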