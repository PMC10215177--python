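"""Neighbor joining, Newick/bipartition handling, and bootstrap support."""

import numpy as np
import pytest

from mitophylo.distances import DistanceMatrix, p_distances
from mitophylo.njtree import PhyloTree, bootstrap_support, neighbor_joining
from mitophylo.simulate import SimConfig, evolve_sequences, simulate_tree


def _dm(labels, values):
    return DistanceMatrix(labels=labels, values=np.asarray(values, float),
                          estimator="p")


class TestNeighborJoining:
    # path-length matrix of ((A:1,B:2):1,(C:3,D:4)) — additive by construction
    ADDITIVE = _dm(
        ["A", "B", "C", "D"],
        [[0, 3, 5, 6],
         [3, 0, 6, 7],
         [5, 6, 0, 7],
         [6, 7, 7, 0]],
    )

    def test_recovers_worked_additive_example(self):
        tree = neighbor_joining(self.ADDITIVE)
        assert tree.splits() == {frozenset({"C", "D"})}
        paths = tree.path_distance_matrix(["A", "B", "C", "D"])
        assert np.allclose(paths, self.ADDITIVE.values)
        # leaf edges 1,2,3,4 and internal edge 1
        lengths = sorted(
            round(e.length, 9)
            for e in tree.tree.preorder_edge_iter() if e.length is not None
        )
        assert lengths == [1.0, 1.0, 2.0, 3.0, 4.0]

    def test_three_taxon_limb_lengths(self):
        # ultrametric 3-taxon matrix: unique star resolution
        dm = _dm(["a", "b", "c"], [[0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree = neighbor_joining(dm)
        paths = tree.path_distance_matrix(["a", "b", "c"])
        assert np.allclose(paths, dm.values)

    def test_additive_matrices_reproduced_exactly(self):
        # dual route: dendropy path sums on simulated trees vs NJ reconstruction
        for seed in range(8):
            n = 4 + seed % 5
            cfg = SimConfig(seed=seed, n_taxa=n,
                            branch_length_range=(0.05, 0.6))
            true_tree = simulate_tree(cfg)
            labels = sorted(true_tree.leaf_labels)
            D = true_tree.path_distance_matrix(labels)
            rebuilt = neighbor_joining(_dm(labels, D))
            assert rebuilt.rf_distance(true_tree) == 0
            assert np.allclose(
                rebuilt.path_distance_matrix(labels), D, atol=1e-9
            )

    def test_label_permutation_equivariance(self):
        dm = self.ADDITIVE
        perm = [2, 0, 3, 1]
        labels = [dm.labels[i] for i in perm]
        values = dm.values[np.ix_(perm, perm)]
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(_dm(labels, values))
        assert t1.splits() == t2.splits()
        order = sorted(dm.labels)
        assert np.allclose(
            t1.path_distance_matrix(order), t2.path_distance_matrix(order)
        )

    def test_matches_reference_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        cfg = SimConfig(seed=13, n_taxa=7, branch_length_range=(0.05, 0.5))
        true_tree = simulate_tree(cfg)
        labels = sorted(true_tree.leaf_labels)
        D = true_tree.path_distance_matrix(labels)
        ours = neighbor_joining(_dm(labels, D))
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        theirs = PhyloTree.from_newick(str(ref))
        assert ours.rf_distance(theirs) == 0
        assert np.allclose(
            ours.path_distance_matrix(labels),
            theirs.path_distance_matrix(labels),
            atol=1e-6,
        )

    def test_missing_values_rejected_with_guidance(self):
        values = np.array([[0, np.nan, 1.0],
                           [np.nan, 0, 1.0],
                           [1.0, 1.0, 0]])
        with pytest.raises(ValueError, match="pairwise-deletion"):
            neighbor_joining(_dm(["a", "b", "c"], values))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(_dm(["a", "b"], [[0, 1], [1, 0]]))

    def test_negative_branch_lengths_clamped(self):
        # a non-additive matrix known to drive one NJ limb negative
        dm = _dm(
            ["a", "b", "c", "d"],
            [[0, 0.1, 0.4, 0.45],
             [0.1, 0, 0.45, 0.4],
             [0.4, 0.45, 0, 0.05],
             [0.45, 0.4, 0.05, 0]],
        )
        tree = neighbor_joining(dm)
        for e in tree.tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0


class TestNewickRoundTrip:
    def test_round_trip_preserves_splits_and_lengths(self):
        nwk = "((t1:0.1,t2:0.2):0.05,(t3:0.3,t4:0.4):0.07,t5:0.5);"
        tree = PhyloTree.from_newick(nwk)
        again = PhyloTree.from_newick(tree.to_newick())
        assert again.splits() == tree.splits()
        assert again.total_length() == pytest.approx(tree.total_length())

    def test_supports_survive_round_trip(self):
        tree = PhyloTree.from_newick(
            "((t1:0.1,t2:0.2):0.05,(t3:0.3,t4:0.4):0.07,t5:0.5);"
        )
        tree.set_supports({frozenset({"t3", "t4"}): 87.0,
                           frozenset({"t1", "t2"}): 100.0})
        again = PhyloTree.from_newick(tree.to_newick())
        # splits are stored normalized: on 5 leaves {t1,t2} == {t3,t4,t5}
        assert again.supports() == {frozenset({"t3", "t4"}): 87.0,
                                    frozenset({"t3", "t4", "t5"}): 100.0}


@pytest.fixture(scope="module")
def clean_alignment():
    # long sequences on well-separated branches: signal dwarfs noise
    cfg = SimConfig(seed=21, n_taxa=5, seq_length=4000,
                    branch_length_range=(0.05, 0.15))
    streams = cfg.streams()
    tree = simulate_tree(cfg, rng=streams["tree"])
    aln = evolve_sequences(tree, cfg, rng=streams["sequences"])
    return tree, aln


class TestBootstrap:
    def test_true_splits_get_full_support_on_clean_data(self, clean_alignment):
        tree, aln = clean_alignment
        bt = bootstrap_support(aln, estimator="p", n_reps=100, seed=3)
        assert bt.rf_distance(tree) == 0
        supports = bt.supports()
        assert supports and all(v == 100.0 for v in supports.values())

    def test_single_replicate_supports_are_binary(self, clean_alignment):
        _, aln = clean_alignment
        bt = bootstrap_support(aln, estimator="p", n_reps=1, seed=9)
        assert set(bt.supports().values()) <= {0.0, 100.0}

    def test_seed_determinism(self, clean_alignment):
        _, aln = clean_alignment
        a = bootstrap_support(aln, estimator="p", n_reps=25, seed=5)
        b = bootstrap_support(aln, estimator="p", n_reps=25, seed=5)
        assert a.to_newick() == b.to_newick()

    def test_unknown_estimator_rejected(self, clean_alignment):
        _, aln = clean_alignment
        with pytest.raises(ValueError, match="estimator"):
            bootstrap_support(aln, estimator="nope", n_reps=2, seed=0)
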