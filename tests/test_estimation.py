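import math
import random

import numpy as np
import pytest
import dendropy

from phyloconcord.estimation import (
    GeneTree,
    astrid_like,
    average_internode_distances,
    bootstrap_gene_tree,
    estimate_tree,
    jc_distance,
    neighbor_joining,
)
from phyloconcord.simulate import simulate_msc_gene_tree, simulate_sequences, \
    species_tree_from_newick
from phyloconcord.splits import rf_distance, split_set
from phyloconcord.trees_io import leaf_labels, parse_newick, restrict

from helpers import labels, locus, random_binary_tree


class TestJCDistance:
    def test_identical_sequences_distance_zero(self):
        taxa, dm = jc_distance(locus("x", {"a": "ACGT" * 10, "b": "ACGT" * 10,
                                           "c": "ACGT" * 10}))
        assert dm.max() == 0

    def test_closed_form_at_p_03(self):
        # 3 mismatches in 10 sites between a and b
        l = locus("x", {"a": "AAAAAAAAAA", "b": "TTTAAAAAAA",
                        "c": "AAAAAAAAAA"})
        taxa, dm = jc_distance(l)
        i, j = taxa.index("a"), taxa.index("b")
        assert dm[i, j] == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)

    def test_saturated_pair_capped(self):
        l = locus("x", {"a": "AAAA", "b": "TTTT", "c": "AAAA"})
        taxa, dm = jc_distance(l, max_distance=9.0)
        i, j = taxa.index("a"), taxa.index("b")
        assert dm[i, j] == 9.0

    def test_missing_data_excluded_from_overlap(self):
        l = locus("x", {"a": "AA--", "b": "AANN", "c": "AAAA"})
        taxa, dm = jc_distance(l)
        assert dm.max() == 0  # only the two shared A-columns compared

    def test_no_overlap_names_the_pair(self):
        l = locus("x", {"a": "AA--", "b": "--AA", "c": "AAAA"})
        with pytest.raises(ValueError, match="a, b"):
            jc_distance(l)


class TestNeighborJoining:
    def _additive_matrix(self, tree):
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        n = len(taxa)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = pdm.distance(taxa[i], taxa[j])
        return [t.label for t in taxa], dm

    def test_three_taxa_unique_topology(self):
        t = neighbor_joining(["a", "b", "c"],
                             np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0.]]))
        assert leaf_labels(t) == {"a", "b", "c"}
        assert split_set(t) == frozenset()

    def test_recovers_topology_from_additive_matrices(self):
        rnd = random.Random(101)
        for _ in range(100):
            n = rnd.randint(4, 10)
            tree = random_binary_tree(labels(n), rnd, lengths=True)
            taxa, dm = self._additive_matrix(tree)
            recovered = neighbor_joining(taxa, dm)
            assert rf_distance(recovered, tree) == 0

    def test_branch_lengths_recovered_on_additive_input(self):
        rnd = random.Random(5)
        tree = random_binary_tree(labels(6), rnd, lengths=True)
        taxa, dm = self._additive_matrix(tree)
        recovered = neighbor_joining(taxa, dm)
        _, dm2 = self._additive_matrix(recovered)
        assert np.allclose(dm, dm2, atol=1e-9)

    def test_taxon_order_invariance(self):
        rnd = random.Random(7)
        tree = random_binary_tree(labels(7), rnd, lengths=True)
        taxa, dm = self._additive_matrix(tree)
        perm = list(range(len(taxa)))
        rnd.shuffle(perm)
        shuffled = [taxa[i] for i in perm]
        dm_shuffled = dm[np.ix_(perm, perm)]
        assert rf_distance(neighbor_joining(taxa, dm),
                           neighbor_joining(shuffled, dm_shuffled)) == 0

    def test_negative_lengths_clamped_to_zero(self):
        dm = np.array([[0, 1, 1, 1], [1, 0, 1, 1],
                       [1, 1, 0, 1], [1, 1, 1, 0.]])
        t = neighbor_joining(list("abcd"), dm)
        assert all((e.length or 0) >= 0 for e in t.preorder_edge_iter())

    def test_non_finite_input_rejected(self):
        dm = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.]])
        with pytest.raises(ValueError):
            neighbor_joining(list("abc"), dm)


class TestBootstrap:
    def _strong_signal_locus(self):
        sp = species_tree_from_newick(
            "(((a:1,b:1):3,(c:1,d:1):3):3,(e:1,f:1):6);")
        gt = simulate_msc_gene_tree(sp, rng=3)
        return simulate_sequences(gt, 4000, rate_scale=0.05, rng=3,
                                  locus_id="strong"), gt

    def test_strong_signal_gives_high_supports(self):
        l, gt = self._strong_signal_locus()
        result = bootstrap_gene_tree(l, reps=50, seed=1)
        supports = [nd.support for nd in result.tree.preorder_internal_node_iter()
                    if getattr(nd, "support", None) is not None]
        assert supports and min(supports) >= 80
        assert rf_distance(result.tree, gt) == 0

    def test_constant_alignment_yields_star_tree(self):
        l = locus("flat", {t: "AAAA" for t in ("a", "b", "c", "d", "e")})
        result = bootstrap_gene_tree(l, reps=10, seed=0)
        assert split_set(result.tree) == frozenset()

    def test_same_seed_reproduces_supports(self):
        l, _ = self._strong_signal_locus()
        a = bootstrap_gene_tree(l, reps=20, seed=9)
        b = bootstrap_gene_tree(l, reps=20, seed=9)
        sa = sorted(nd.support for nd in a.tree.preorder_internal_node_iter()
                    if getattr(nd, "support", None) is not None)
        sb = sorted(nd.support for nd in b.tree.preorder_internal_node_iter()
                    if getattr(nd, "support", None) is not None)
        assert sa == sb

    def test_supports_increase_with_sequence_length(self):
        sp = species_tree_from_newick(
            "(((a:1,b:1):0.8,(c:1,d:1):0.8):0.8,(e:1,f:1):1.6);")
        gt = simulate_msc_gene_tree(sp, rng=11)
        means = []
        for L in (80, 2000):
            l = simulate_sequences(gt, L, rate_scale=0.02, rng=4,
                                   locus_id=f"len{L}")
            result = bootstrap_gene_tree(l, reps=40, seed=2)
            sup = [nd.support
                   for nd in result.tree.preorder_internal_node_iter()
                   if getattr(nd, "support", None) is not None]
            means.append(np.mean(sup) if sup else 0.0)
        assert means[1] > means[0]


class TestAstridLike:
    def test_single_gene_tree_identity(self):
        rnd = random.Random(31)
        t = random_binary_tree(labels(7), rnd)
        assert rf_distance(astrid_like([t]), t) == 0

    def test_recovery_under_random_taxon_deletion(self):
        rnd = random.Random(33)
        species = random_binary_tree(labels(10), rnd)
        genes = []
        while len(genes) < 50:
            keep = [x for x in labels(10) if rnd.random() > 0.2]
            if len(keep) >= 4:
                genes.append(restrict(species, set(keep)))
        assert rf_distance(astrid_like(genes), species) == 0

    def test_input_order_invariance(self):
        rnd = random.Random(37)
        genes = [random_binary_tree(labels(6), rnd) for _ in range(9)]
        a = astrid_like(genes)
        b = astrid_like(list(reversed(genes)))
        assert rf_distance(a, b) == 0

    def test_msc_gene_trees_recover_species_topology(self):
        sp = species_tree_from_newick(
            "((((a:1,b:1):2,c:3):2,(d:1,e:1):4):2,(f:1,g:1):6);")
        rng = np.random.default_rng(41)
        genes = [simulate_msc_gene_tree(sp, rng) for _ in range(200)]
        assert rf_distance(astrid_like(genes), sp) == 0

    def test_disconnected_pair_graph_is_error(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((w,x),(y,z));")
        with pytest.raises(ValueError, match="disconnected"):
            astrid_like([t1, t2])

    def test_internode_counts_track_cooccurrence(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,b),(c,e));")
        taxa, mean, count = average_internode_distances([t1, t2])
        i, j = taxa.index("a"), taxa.index("b")
        assert count[i, j] == 2
        k = taxa.index("e")
        assert count[i, k] == 1
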