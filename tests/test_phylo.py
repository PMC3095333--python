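import math

import dendropy
import numpy as np
import pytest

from apctools import phylo
from apctools.phylo import (
    DistanceMatrix,
    PhyloError,
    bipartitions,
    bootstrap_support,
    condense,
    neighbor_joining,
    node_supports,
    poisson_distance,
)
from apctools.seqio import AlignedSet, Alphabet, SequenceRecord
from apctools.simulate import _random_topology, gen_tree_sequences

from oracles import best_fit_topology


def aln_from(rows):
    return AlignedSet([
        SequenceRecord(id=f"s{i}", residues=r, alphabet=Alphabet.protein)
        for i, r in enumerate(rows)
    ])


def tree_distances(tree):
    """Leaf-to-leaf path lengths of a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    return [t.label for t in taxa], d


class TestPoissonDistance:
    def test_identical_rows_zero(self):
        aln = aln_from(["MKVL", "MKVL"])
        dm = poisson_distance(aln)
        assert dm.d[0, 1] == 0.0

    def test_closed_form_p_01(self):
        # 1 mismatch over 10 usable sites
        aln = aln_from(["MKVLITAGWQ", "MKVLITAGWE"])
        dm = poisson_distance(aln)
        assert dm.d[0, 1] == pytest.approx(-math.log(0.9), abs=1e-12)

    def test_complete_deletion_drops_gap_columns(self):
        aln = aln_from(["MK-L", "MKVL", "MKVL"])
        dm = poisson_distance(aln, "complete")
        assert dm.d.max() == 0.0  # gap column dropped for everyone

    def test_pairwise_deletion_keeps_columns_per_pair(self):
        aln = aln_from(["MK-LW", "MKVLW", "MKVLF"])
        dm = poisson_distance(aln, "pairwise")
        # pair (1,2): 5 usable, 1 mismatch
        assert dm.d[1, 2] == pytest.approx(-math.log(1 - 0.2))
        # pair (0,1): 4 usable, 0 mismatches
        assert dm.d[0, 1] == 0.0

    def test_x_treated_as_missing(self):
        aln = aln_from(["MXVL", "MKVL"])
        dm = poisson_distance(aln)
        assert dm.d[0, 1] == 0.0

    def test_saturated_pair_errors(self):
        aln = aln_from(["MKVL", "WHEA"])
        with pytest.raises(PhyloError, match="p = 1"):
            poisson_distance(aln)

    def test_matches_naive_column_loop(self):
        rng = np.random.default_rng(7)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        rows = ["".join(rng.choice(list(aa + "-X"), 60)) for _ in range(5)]
        # ensure no saturated pair by anchoring half the columns
        rows = [r[:30] + rows[0][30:] for r in rows]
        aln = aln_from(rows)
        dm = poisson_distance(aln, "pairwise")
        for i in range(5):
            for j in range(i + 1, 5):
                usable = diffs = 0
                for ca, cb in zip(rows[i], rows[j]):
                    if ca in "-X" or cb in "-X":
                        continue
                    usable += 1
                    diffs += ca != cb
                expected = -math.log(1 - diffs / usable)
                assert dm.d[i, j] == pytest.approx(expected, abs=1e-12)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d_ab, d_ac, d_bc = 3.0, 4.0, 5.0
        dm = DistanceMatrix(taxa=["A", "B", "C"],
                            d=np.array([[0, d_ab, d_ac],
                                        [d_ab, 0, d_bc],
                                        [d_ac, d_bc, 0.0]]))
        tree = neighbor_joining(dm)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(taxa=["A", "B"], d=np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(PhyloError, match="at least 3"):
            neighbor_joining(dm)

    def test_additive_five_taxon_exact(self):
        rng = np.random.default_rng(3)
        true = _random_topology(5, lambda r: 0.05 + r.random() * 0.4, rng)
        labels, d = tree_distances(true)
        dm = DistanceMatrix(taxa=labels, d=d)
        tree = neighbor_joining(dm)
        assert bipartitions(tree) == bipartitions(true)
        out_labels, out_d = tree_distances(tree)
        assert out_labels == labels
        np.testing.assert_allclose(out_d, d, atol=1e-9)

    def test_matches_minimum_evolution_oracle_on_additive(self):
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            true = _random_topology(5, lambda r: 0.05 + r.random() * 0.5, rng)
            labels, d = tree_distances(true)
            nj = neighbor_joining(DistanceMatrix(taxa=labels, d=d))
            oracle_biparts, resid, _ = best_fit_topology(labels, d)
            assert resid < 1e-18
            assert bipartitions(nj) == oracle_biparts

    def test_negative_branch_lengths_clamped(self):
        d = np.array([
            [0.0, 0.1, 0.4, 0.5],
            [0.1, 0.0, 0.5, 0.4],
            [0.4, 0.5, 0.0, 0.1],
            [0.5, 0.4, 0.1, 0.0],
        ])
        tree = neighbor_joining(DistanceMatrix(taxa=list("ABCD"), d=d))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestBootstrap:
    def test_repeated_columns_full_support(self):
        # a perfectly repetitive alignment: every resample carries the same
        # single (A,B | C,D) signal, so the one bipartition gets support 100
        # (an alignment of literally identical columns would put p at 0 or 1
        # for every pair, making the Poisson distance undefined)
        block = ["MA", "MA", "MC", "MC"]
        aln = aln_from([row * 15 for row in block])
        tree = bootstrap_support(aln, 10, seed=1)
        supports = node_supports(tree)
        assert supports == {frozenset({"s2", "s3"}): 100}

    def test_same_seed_identical(self):
        aln, _ = gen_tree_sequences("random", 6, 0.2, 200, seed=5)
        t1 = bootstrap_support(aln, 30, seed=9)
        t2 = bootstrap_support(aln, 30, seed=9)
        assert node_supports(t1) == node_supports(t2)

    def test_different_seeds_within_sampling_noise(self):
        aln, _ = gen_tree_sequences("random", 6, 0.3, 400, seed=6)
        s1 = node_supports(bootstrap_support(aln, 80, seed=1))
        s2 = node_supports(bootstrap_support(aln, 80, seed=2))
        for bp in set(s1) & set(s2):
            assert abs(s1[bp] - s2[bp]) <= 40  # generous noise bound

    def test_supports_in_range(self):
        aln, _ = gen_tree_sequences("random", 7, 0.2, 150, seed=8)
        tree = bootstrap_support(aln, 25, seed=4)
        assert all(0 <= s <= 100 for s in node_supports(tree).values())

    def test_b_zero_rejected(self):
        aln = aln_from(["MKVL", "MKVW", "MRVL"])
        with pytest.raises(PhyloError, match="at least one"):
            bootstrap_support(aln, 0)


class TestCondense:
    def _supported_tree(self, labels_and_supports):
        tree = dendropy.Tree.get(data=labels_and_supports, schema="newick",
                                 suppress_internal_node_taxa=True)
        tree.is_rooted = False
        return tree

    def test_all_above_threshold_unchanged(self):
        tree = self._supported_tree("((A:1,B:1)80:1,(C:1,D:1)60:1,E:1);")
        out = condense(tree, 50)
        assert bipartitions(out) == bipartitions(tree)

    def test_low_support_edge_collapsed(self):
        tree = self._supported_tree("((A:1,B:1)49:1,(C:1,D:1)80:1,E:1);")
        out = condense(tree, 50)
        assert frozenset({"C", "D"}) in bipartitions(out)
        assert len(bipartitions(out)) == len(bipartitions(tree)) - 1

    def test_leaves_never_removed(self):
        tree = self._supported_tree("((A:1,B:1)10:1,(C:1,D:1)10:1,E:1);")
        out = condense(tree, 50)
        assert {lf.taxon.label for lf in out.leaf_node_iter()} == set("ABCDE")

    def test_idempotent(self):
        tree = self._supported_tree("((A:1,B:1)49:1,(C:1,D:1)80:1,E:1);")
        once = condense(tree, 50)
        twice = condense(once, 50)
        assert bipartitions(once) == bipartitions(twice)

    def test_set_difference_oracle_random_supports(self):
        rng = np.random.default_rng(12)
        for seed in range(5):
            aln, _ = gen_tree_sequences("random", 8, 0.25, 300,
                                        seed=200 + seed)
            tree = bootstrap_support(aln, 20, seed=seed)
            # overwrite supports randomly to exercise arbitrary patterns
            for nd in tree.preorder_node_iter():
                if nd is not tree.seed_node and not nd.is_leaf() \
                        and nd.label is not None:
                    nd.label = str(int(rng.integers(0, 101)))
            supports = node_supports(tree)
            out = condense(tree, 50)
            expected = bipartitions(tree) - {
                bp for bp, s in supports.items() if s < 50}
            assert bipartitions(out) == expected

    def test_input_tree_unmodified(self):
        tree = self._supported_tree("((A:1,B:1)49:1,(C:1,D:1)80:1,E:1);")
        before = bipartitions(tree)
        condense(tree, 50)
        assert bipartitions(tree) == before


class TestTopologyRecovery:
    def test_simulated_eight_taxon_recovery(self):
        # moderate branch lengths; NJ + bootstrap should recover the truth
        hits = trials = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            true = _random_topology(8, lambda r: 0.05 + r.random() * 0.15, rng)
            aln, _ = gen_tree_sequences(true, seq_len=600, seed=seed)
            tree = bootstrap_support(aln, 100, seed=seed)
            true_bps = bipartitions(true)
            supports = node_supports(tree)
            found = bipartitions(tree)
            trials += len(true_bps)
            hits += sum(1 for bp in true_bps
                        if bp in found and supports.get(bp, 0) >= 50)
        assert hits / trials >= 0.8
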