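import itertools
import random

import dendropy
import pytest
from dendropy.calculate import treecompare

from phyloconcord.splits import (
    Bipartition,
    compatible,
    extract_splits,
    majority_consensus,
    rf_distance,
    split_set,
    topology_census,
    tree_from_splits,
)
from phyloconcord.trees_io import TreeSet, leaf_labels, parse_newick

from helpers import labels, random_binary_newick, random_binary_tree


def dendropy_rf(nwk1: str, nwk2: str) -> int:
    """Independent RF oracle via dendropy's bipartition machinery."""
    tn = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tn)
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tn)
    t1.is_rooted = t2.is_rooted = False
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return treecompare.symmetric_difference(t1, t2)


class TestExtractSplits:
    def test_single_internal_edge(self):
        t = parse_newick("((a,b),(c,d));")
        bips = extract_splits(t)
        assert {b.side for b in bips} == {frozenset({"c", "d"})}

    def test_star_tree_has_no_splits(self):
        assert split_set(parse_newick("(a,b,c,d,e);")) == frozenset()

    def test_caterpillar_enumeration(self):
        t = parse_newick("(((((a,b),c),d),e),f);")
        assert split_set(t) == {frozenset("cdef"), frozenset("def"),
                                frozenset("ef")}

    def test_binary_tree_has_n_minus_3_splits(self):
        rnd = random.Random(11)
        for n in (4, 6, 9, 12):
            t = random_binary_tree(labels(n), rnd)
            assert len(split_set(t)) == n - 3


class TestCompatibility:
    U5 = frozenset("abcde")

    def test_nested_splits_compatible(self):
        b1 = Bipartition(frozenset("ab"), self.U5)
        b2 = Bipartition(frozenset("de"), self.U5)
        assert compatible(b1, b2)

    def test_classic_conflict(self):
        u = frozenset("abcd")
        b1 = Bipartition(frozenset("cd"), u)      # ab|cd
        b2 = Bipartition(frozenset("bd"), u)      # ac|bd
        assert not compatible(b1, b2)

    def test_self_compatible(self):
        b = Bipartition(frozenset("ab"), self.U5)
        assert compatible(b, b)

    def test_trivial_bipartition_rejected(self):
        with pytest.raises(ValueError):
            Bipartition(frozenset("a"), self.U5)


class TestRFDistance:
    def test_identity(self):
        t = parse_newick("((a,b),(c,d),e);")
        assert rf_distance(t, t) == 0

    def test_conflicting_quartets(self):
        assert rf_distance(parse_newick("((a,b),(c,d));"),
                           parse_newick("((a,c),(b,d));")) == 2

    def test_six_taxon_example(self):
        assert rf_distance(parse_newick("((a,b),(c,d),(e,f));"),
                           parse_newick("((a,c),(b,d),(e,f));")) == 4

    def test_matches_dendropy_oracle_on_random_pairs(self):
        rnd = random.Random(23)
        for _ in range(60):
            n = rnd.randint(4, 8)
            s1 = random_binary_newick(labels(n), rnd)
            s2 = random_binary_newick(labels(n), rnd)
            assert rf_distance(parse_newick(s1), parse_newick(s2)) == \
                dendropy_rf(s1, s2)

    def test_triangle_inequality_on_random_triples(self):
        rnd = random.Random(29)
        for _ in range(30):
            n = rnd.randint(5, 8)
            a, b, c = (random_binary_tree(labels(n), rnd) for _ in range(3))
            dab, dbc, dac = rf_distance(a, b), rf_distance(b, c), rf_distance(a, c)
            assert dac <= dab + dbc
            assert dab == rf_distance(b, a)

    def test_bound_and_maximum_at_six_taxa(self):
        rnd = random.Random(31)
        seen_max = 0
        for _ in range(300):
            t1 = random_binary_tree(labels(6), rnd)
            t2 = random_binary_tree(labels(6), rnd)
            d = rf_distance(t1, t2)
            assert 0 <= d <= 2 * (6 - 3)
            seen_max = max(seen_max, d)
        assert seen_max == 2 * (6 - 3)

    def test_missing_taxa_compared_on_shared_restriction(self):
        t1 = parse_newick("(((a,b),c),((d,e),f));")
        t2 = parse_newick("((a,b),(d,e),g);")
        assert rf_distance(t1, t2) == 0  # shared taxa {a,b,d,e} agree

    def test_too_few_shared_taxa_is_error(self):
        with pytest.raises(ValueError, match="shared taxa"):
            rf_distance(parse_newick("((a,b),(c,x));"),
                        parse_newick("((a,b),(y,z));"))


class TestMajorityConsensus:
    def test_two_to_one_majority(self):
        trees = [parse_newick(s) for s in
                 ["((a,b),(c,d));", "((a,b),(c,d));", "((a,c),(b,d));"]]
        cons = majority_consensus(trees)
        assert cons.frequencies == {frozenset("cd"): pytest.approx(2 / 3)}

    def test_unanimous_input_reproduced_with_frequency_one(self):
        trees = [parse_newick("(((a,b),c),(d,e));")] * 3
        cons = majority_consensus(trees)
        assert all(f == 1.0 for f in cons.frequencies.values())
        assert rf_distance(cons.tree, trees[0]) == 0

    def test_three_conflicting_quartets_give_star(self):
        trees = [parse_newick(s) for s in
                 ["((a,b),(c,d));", "((a,c),(b,d));", "((a,d),(b,c));"]]
        cons = majority_consensus(trees)
        assert cons.frequencies == {}
        assert split_set(cons.tree) == frozenset()

    def test_exactly_half_frequency_is_dropped(self):
        trees = [parse_newick("((a,b),(c,d));"), parse_newick("((a,c),(b,d));")]
        assert majority_consensus(trees).frequencies == {}

    def test_retained_splits_recount_and_compatibility(self):
        rnd = random.Random(37)
        for _ in range(30):
            n = rnd.randint(5, 8)
            m = rnd.randint(3, 9)
            base = random_binary_newick(labels(n), rnd)
            trees = [parse_newick(base if rnd.random() < 0.5
                                  else random_binary_newick(labels(n), rnd))
                     for _ in range(m)]
            cons = majority_consensus(trees)
            all_splits = [split_set(t) for t in trees]
            for side, freq in cons.frequencies.items():
                recount = sum(1 for ss in all_splits if side in ss) / m
                assert recount == pytest.approx(freq)
                assert recount > 0.5
            for s1, s2 in itertools.combinations(cons.frequencies, 2):
                assert compatible(s1, s2, universe=frozenset(labels(n)))

    def test_matches_dendropy_consensus_topology(self):
        rnd = random.Random(41)
        for _ in range(10):
            n = rnd.randint(5, 7)
            newicks = [random_binary_newick(labels(n), rnd) for _ in range(5)]
            mine = majority_consensus([parse_newick(s) for s in newicks])
            tl = dendropy.TreeList.get(data="\n".join(newicks), schema="newick")
            ref = tl.consensus(min_freq=0.5000001)
            assert rf_distance(mine.tree, ref) == 0

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            majority_consensus([])


class TestTreeFromSplits:
    def test_realizes_exactly_the_given_splits(self):
        rnd = random.Random(43)
        for _ in range(20):
            t = random_binary_tree(labels(8), rnd)
            rebuilt = tree_from_splits(split_set(t), leaf_labels(t))
            assert split_set(rebuilt) == split_set(t)


class TestTopologyCensus:
    def _tree_set(self, newicks):
        ts = TreeSet()
        for i, s in enumerate(newicks):
            ts.add(parse_newick(s, ts.taxon_namespace), "g", f"t{i}")
        return ts

    def test_identical_copies_form_one_class(self):
        ts = self._tree_set(["((a,b),(c,d));"] * 3)
        census = topology_census(ts)
        assert census.n_unique == 1
        assert census.modal_count == 3

    def test_distinct_topologies_form_distinct_classes(self):
        ts = self._tree_set(["((a,b),(c,d));", "((a,c),(b,d));"])
        census = topology_census(ts)
        assert census.n_unique == 2
        assert census.modal_count == 1

    def test_counts_sum_to_input_size_and_rooting_ignored(self):
        ts = self._tree_set(["((a,b),(c,d));", "(a,b,(c,d));",
                             "((a,c),(b,d));"])
        census = topology_census(ts)
        assert sum(census.counts().values()) == 3
        assert census.n_unique == 2  # first two are the same unrooted topology

    def test_trees_missing_taxa_are_excluded(self):
        ts = self._tree_set(["((a,b),(c,d));", "((a,b),(c,e));"])
        census = topology_census(ts)
        assert len(census.excluded) + sum(census.counts().values()) == 2
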