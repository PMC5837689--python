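import math

import numpy as np
import pytest

from phyloconcord.simulate import (
    IntrogressionEvent,
    SimConfig,
    apply_missingness,
    distant_leaf_introgression,
    mean_informative_fraction,
    simulate_dataset,
    simulate_mito_tree,
    simulate_msc_gene_tree,
    simulate_sequences,
    simulate_yule_tree,
    species_tree_from_newick,
    substream,
)
from phyloconcord.splits import rf_distance
from phyloconcord.supermatrix import filter_by_completeness
from phyloconcord.trees_io import canonical_newick, leaf_labels, write_newick


def _is_cherry(tree, pair):
    for nd in tree.preorder_internal_node_iter():
        leaves = sorted(l.taxon.label for l in nd.leaf_iter())
        if leaves == sorted(pair):
            return True
    return False


class TestYule:
    def test_leaf_count_and_determinism(self):
        a = simulate_yule_tree(12, 1.0, rng=5)
        b = simulate_yule_tree(12, 1.0, rng=5)
        assert len(leaf_labels(a)) == 12
        assert write_newick(a) == write_newick(b)

    def test_internal_edge_count(self):
        t = simulate_yule_tree(10, 1.0, rng=1)
        internals = [nd for nd in t.preorder_internal_node_iter()
                     if nd is not t.seed_node]
        assert len(internals) == 10 - 2  # rooted binary tree

    def test_ultrametric_leaves_at_zero(self):
        t = simulate_yule_tree(8, 2.0, rng=3)
        depths = {}
        for nd in t.preorder_node_iter():
            depths[id(nd)] = (0.0 if nd.parent_node is None
                              else depths[id(nd.parent_node)]
                              + (nd.edge.length or 0.0))
        leaf_depths = [depths[id(l)] for l in t.leaf_node_iter()]
        assert max(leaf_depths) - min(leaf_depths) < 1e-9


class TestMSC:
    def test_deep_branches_reproduce_species_topology(self):
        sp = species_tree_from_newick(
            "(((a:1,b:1):50,(c:1,d:1):50):50,(e:1,f:1):100);")
        rng = np.random.default_rng(2)
        for _ in range(20):
            assert rf_distance(simulate_msc_gene_tree(sp, rng), sp) == 0

    def test_zero_internal_branch_gives_uniform_topologies(self):
        sp = species_tree_from_newick("((a:1,b:1):0,c:1);")
        rng = np.random.default_rng(4)
        n = 3000
        counts = {"ab": 0, "ac": 0, "bc": 0}
        for _ in range(n):
            g = simulate_msc_gene_tree(sp, rng)
            for pair in counts:
                if _is_cherry(g, tuple(pair)):
                    counts[pair] += 1
        for c in counts.values():
            assert abs(c / n - 1 / 3) < 3 * math.sqrt((1 / 3) * (2 / 3) / n)

    def test_concordance_matches_theory_at_t1(self):
        sp = species_tree_from_newick("((a:1,b:1):1,c:2);")
        rng = np.random.default_rng(8)
        n = 4000
        match = sum(_is_cherry(simulate_msc_gene_tree(sp, rng), ("a", "b"))
                    for _ in range(n))
        expected = 1 - (2 / 3) * math.exp(-1)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(match / n - expected) < 3 * se

    def test_gene_tree_has_coalescent_branch_lengths(self):
        sp = species_tree_from_newick("((a:1,b:1):1,c:2);")
        g = simulate_msc_gene_tree(sp, rng=3)
        for nd in g.preorder_node_iter():
            if nd.parent_node is not None:
                assert nd.edge.length is not None and nd.edge.length >= 0


class TestMitoTree:
    SP = "((a:2,b:2):2,(c:2,d:2):2);"

    def test_no_events_small_ne_tracks_species(self):
        sp = species_tree_from_newick(self.SP)
        for s in range(10):
            mt = simulate_mito_tree(sp, [], ne_scale=0.02, rng=s)
            assert rf_distance(mt, sp) == 0

    def test_certain_introgression_reroutes_donor(self):
        sp = species_tree_from_newick(self.SP)
        ev = IntrogressionEvent(donor="a", recipient="c", time=1.0,
                                probability=1.0)
        hits = sum(_is_cherry(simulate_mito_tree(sp, [ev], 0.02, rng=s),
                              ("a", "c"))
                   for s in range(50))
        assert hits >= 48  # ne -> 0 limit: donor joins the recipient clade
        mt = simulate_mito_tree(sp, [ev], 0.02, rng=0)
        assert rf_distance(mt, sp) > 0

    def test_event_outside_branch_span_rejected(self):
        sp = species_tree_from_newick(self.SP)
        ev = IntrogressionEvent(donor="a", recipient="c", time=3.0)
        with pytest.raises(ValueError, match="span"):
            simulate_mito_tree(sp, [ev], rng=0)

    def test_distant_leaf_event_constructor(self):
        sp = species_tree_from_newick("(((a:1,b:1):1,c:2):2,(d:2,e:2):2);")
        ev = distant_leaf_introgression(sp)
        assert ev.donor != ev.recipient
        # sanity: the event is accepted by the simulator
        simulate_mito_tree(sp, [ev], 0.1, rng=0)


class TestSequences:
    def test_zero_rate_gives_identical_sequences(self):
        sp = species_tree_from_newick("((a:1,b:1):1,c:2);")
        l = simulate_sequences(sp, 100, rate_scale=0.0, rng=0)
        assert len(set(l.sequences.values())) == 1

    def test_two_taxon_mismatch_matches_jc_expectation(self):
        d = 0.2
        sp = species_tree_from_newick(f"(a:{d / 2},b:{d / 2},c:0):0;")
        rng = np.random.default_rng(6)
        n = 60000
        l = simulate_sequences(sp, n, rate_scale=1.0, rng=rng)
        mism = sum(x != y for x, y in zip(l.sequences["a"], l.sequences["b"]))
        expected = 0.75 * (1 - math.exp(-4 * d / 3))
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(mism / n - expected) < 4 * se

    def test_informativeness_calibration_brackets_target(self):
        # study-shaped preset: mean informative fraction in the UCE-like band
        sp = simulate_yule_tree(37, 1.0, substream(0, "species"))
        rng = np.random.default_rng(3)
        loci = []
        for i in range(60):
            gt = simulate_msc_gene_tree(sp, rng)
            loci.append(simulate_sequences(gt, 378, rng=rng,
                                           locus_id=f"x{i}"))
        frac = mean_informative_fraction(loci)
        assert 0.005 <= frac <= 0.05

    def test_missing_branch_length_is_error(self):
        from phyloconcord.trees_io import parse_newick
        with pytest.raises(ValueError, match="branch length"):
            simulate_sequences(parse_newick("((a,b),c);"), 10, rng=0)


class TestMissingness:
    def _loci(self, n, taxa=20):
        sp = simulate_yule_tree(taxa, 1.0, rng=9)
        rng = np.random.default_rng(10)
        return [simulate_sequences(simulate_msc_gene_tree(sp, rng), 60,
                                   rng=rng, locus_id=f"L{i:03d}")
                for i in range(n)]

    def test_full_retention_unchanged(self):
        loci = self._loci(5)
        kept, dropped = apply_missingness(loci, 1.0, rng=0)
        assert dropped == []
        assert all(k.taxon_count == 20 for k in kept)

    def test_binomial_expectation_of_taxon_counts(self):
        loci = self._loci(300)
        kept, dropped = apply_missingness(loci, 0.5, rng=1)
        counts = [l.taxon_count for l in kept]
        # E = 10 per locus; conditioning on >= 3 survivors is negligible here
        assert abs(np.mean(counts) - 10) < 3 * math.sqrt(20 * 0.25 / 300)

    def test_completeness_spectrum_monotone(self):
        loci = self._loci(150)
        kept, _ = apply_missingness(loci, 0.6, rng=2)
        counts = [len(filter_by_completeness(kept, f, 20))
                  for f in (0.95, 0.75, 0.55, 0.35, 0.15)]
        assert counts == sorted(counts)


class TestDatasetGenerator:
    def test_same_seed_reproduces_everything(self):
        cfg = SimConfig(n_taxa=6, n_loci=8, locus_length_mean=150,
                        locus_length_sd=20, mito_length=500, seed=77)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert canonical_newick(a.species_tree) == canonical_newick(b.species_tree)
        assert [l.sequences for l in a.loci] == [l.sequences for l in b.loci]
        assert canonical_newick(a.mito_tree) == canonical_newick(b.mito_tree)

    def test_manifest_records_truth(self):
        cfg = SimConfig(n_taxa=6, n_loci=4, locus_length_mean=150,
                        locus_length_sd=10, mito_length=300, seed=5)
        data = simulate_dataset(cfg)
        m = data.manifest()
        assert m["n_loci"] == len(data.loci)
        assert m["species_topology"] == canonical_newick(data.species_tree)
        assert m["config"]["seed"] == 5
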