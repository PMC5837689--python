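"""Bipartition algebra: split extraction, compatibility, Robinson-Foulds
distance, majority-rule consensus, and the topology census.

A bipartition (split) is the two-way division of the leaf set induced by an
internal edge of the unrooted tree.  Splits are canonicalized to the side
*not* containing the reference taxon (the lexicographically smallest leaf
label), so that a plain ``frozenset`` of labels identifies a split uniquely
within a given universe.  Only nontrivial splits (both sides of size >= 2)
are kept.

The unweighted Robinson-Foulds distance is the size of the symmetric
difference of the two trees' nontrivial split sets ("symmetrical
differences"); binary trees on n leaves have n-3 splits each, so the
distance lies in [0, 2(n-3)] and equals 0 iff the topologies are identical.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .trees_io import (
    TreeSet,
    canonical_newick,
    leaf_labels,
    parse_newick,
    strip_metadata,
    unroot,
    write_newick,
)

__all__ = [
    "Bipartition",
    "ConsensusTree",
    "TopologyCensus",
    "extract_splits",
    "split_set",
    "compatible",
    "restrict_split",
    "rf_distance",
    "majority_consensus",
    "tree_from_splits",
    "topology_census",
]


@dataclass(frozen=True)
class Bipartition:
    """A nontrivial split of ``universe``, canonicalized so that ``side``
    excludes the reference taxon (min label of the universe)."""

    side: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self):
        ref = min(self.universe)
        side = frozenset(self.side)
        if ref in side:
            side = self.universe - side
        if not (2 <= len(side) <= len(self.universe) - 2):
            raise ValueError("bipartition must be nontrivial")
        object.__setattr__(self, "side", side)

    @property
    def other_side(self) -> frozenset[str]:
        return self.universe - self.side


def _canonical_side(clade: frozenset[str], universe: frozenset[str]) -> frozenset[str] | None:
    """Canonical side of the split induced by a clade, or None if trivial."""
    if not (2 <= len(clade) <= len(universe) - 2):
        return None
    if min(universe) in clade:
        return universe - clade
    return clade


def split_set(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """All nontrivial splits of ``tree`` as canonical frozensets of labels.

    Works on rooted or unrooted trees; the split set is that of the
    unrooted form (a degree-2 root contributes no extra split because its
    two child edges induce the same bipartition, deduplicated here).
    """
    universe = leaf_labels(tree)
    out: set[frozenset[str]] = set()
    clades: dict[int, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            clades[id(nd)] = frozenset([nd.taxon.label])
        else:
            clade = frozenset().union(*(clades[id(c)] for c in nd.child_nodes()))
            clades[id(nd)] = clade
            if nd is not tree.seed_node:
                side = _canonical_side(clade, universe)
                if side is not None:
                    out.add(side)
    return frozenset(out)


def extract_splits(tree: dendropy.Tree) -> set[Bipartition]:
    """One :class:`Bipartition` per internal edge of the unrooted tree."""
    universe = leaf_labels(tree)
    if len(universe) < 4:
        raise ValueError("split extraction requires at least 4 leaves")
    return {Bipartition(side, universe) for side in split_set(tree)}


def compatible(b1: Bipartition | frozenset[str], b2: Bipartition | frozenset[str],
               universe: frozenset[str] | None = None) -> bool:
    """True iff the two splits can coexist on one tree: at least one of the
    four pairwise side intersections is empty."""
    if isinstance(b1, Bipartition):
        u1, s1 = b1.universe, b1.side
    else:
        u1, s1 = universe, frozenset(b1)
    if isinstance(b2, Bipartition):
        u2, s2 = b2.universe, b2.side
    else:
        u2, s2 = universe, frozenset(b2)
    if u1 is None or u2 is None:
        raise ValueError("universe required for raw frozenset splits")
    shared = u1 & u2
    if u1 != u2:
        if len(shared) < 4:
            raise ValueError("fewer than 4 shared taxa between universes")
        a = _canonical_side(s1 & shared, shared)
        b = _canonical_side(s2 & shared, shared)
        if a is None or b is None:
            return True  # a split trivial on the shared taxa conflicts with nothing
        s1, s2, u1 = a, b, shared
    c1, c2 = u1 - s1, u1 - s2
    return not (s1 & s2) or not (s1 & c2) or not (c1 & s2) or not (c1 & c2)


def restrict_split(side: frozenset[str], universe: frozenset[str],
                   shared: frozenset[str]) -> frozenset[str] | None:
    """Project a split onto ``shared`` taxa; None if it becomes trivial."""
    inter = side & shared
    return _canonical_side(inter, shared)


def _projected_splits(tree: dendropy.Tree, shared: frozenset[str]
                      ) -> frozenset[frozenset[str]]:
    universe = leaf_labels(tree)
    if universe == shared:
        return split_set(tree)
    out = set()
    for side in split_set(tree):
        proj = restrict_split(side, universe, shared)
        if proj is not None:
            out.add(proj)
    return frozenset(out)


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance on the shared taxon set."""
    shared = leaf_labels(t1) & leaf_labels(t2)
    if len(shared) < 4:
        raise ValueError(
            f"RF distance needs >= 4 shared taxa, got {len(shared)}")
    s1 = _projected_splits(t1, shared)
    s2 = _projected_splits(t2, shared)
    return len(s1 ^ s2)


@dataclass
class ConsensusTree:
    """A (possibly multifurcating) consensus tree plus, for every retained
    split, its frequency among the input trees."""

    tree: dendropy.Tree
    frequencies: dict[frozenset[str], float]
    universe: frozenset[str]

    def newick_with_frequencies(self) -> str:
        """Consensus newick with split frequencies as internal labels."""
        t = self.tree.clone(depth=1)
        clades: dict[int, frozenset[str]] = {}
        for nd in t.postorder_node_iter():
            if nd.is_leaf():
                clades[id(nd)] = frozenset([nd.taxon.label])
                nd.support = None
            else:
                clade = frozenset().union(*(clades[id(c)] for c in nd.child_nodes()))
                clades[id(nd)] = clade
                side = _canonical_side(clade, self.universe)
                freq = self.frequencies.get(side) if side is not None else None
                nd.support = round(100.0 * freq, 4) if freq is not None else None
        return write_newick(t, lengths=False, supports=True)


def tree_from_splits(sides: Iterable[frozenset[str]],
                     universe: frozenset[str]) -> dendropy.Tree:
    """Build the (multifurcating) tree realizing a pairwise-compatible,
    hence laminar, family of canonical splits.

    The canonical sides all exclude the reference taxon, so they form a
    laminar family of clusters; each cluster becomes an internal node whose
    parent is the smallest strictly-containing cluster (or the root).
    """
    sides = sorted(set(sides), key=lambda s: (len(s), sorted(s)))
    for s in sides:
        if min(universe) in s:
            raise ValueError("splits must be canonicalized (exclude reference taxon)")
    tree = dendropy.Tree()
    tree.is_rooted = False
    nodes: list[tuple[frozenset[str], dendropy.Node]] = []
    root = tree.seed_node
    # largest clusters first so parents exist before children
    for s in sorted(sides, key=len, reverse=True):
        parent = root
        best: frozenset[str] | None = None
        for cs, cn in nodes:
            if s < cs and (best is None or len(cs) < len(best)):
                best, parent = cs, cn
        node = dendropy.Node()
        parent.add_child(node)
        nodes.append((s, node))
    tn = tree.taxon_namespace
    for label in sorted(universe):
        parent = root
        best = None
        for cs, cn in nodes:
            if label in cs and (best is None or len(cs) < len(best)):
                best, parent = cs, cn
        leaf = dendropy.Node()
        leaf.taxon = tn.require_taxon(label=label)
        parent.add_child(leaf)
    for nd in tree.preorder_node_iter():
        nd.support = None
    return tree


def majority_consensus(ts: TreeSet | Sequence[dendropy.Tree],
                       threshold: float = 0.5) -> ConsensusTree:
    """Majority-rule consensus: retain exactly the splits whose frequency
    among the input trees strictly exceeds ``threshold``.

    Input trees must span a common taxon set; trees with extra taxa are
    projected onto the shared universe first.  ``threshold >= 0.5``
    guarantees the retained set is pairwise compatible.
    """
    trees = list(ts.trees if isinstance(ts, TreeSet) else ts)
    if not trees:
        raise ValueError("consensus of an empty tree set is undefined")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    shared = leaf_labels(trees[0])
    for t in trees[1:]:
        shared &= leaf_labels(t)
    if len(shared) < 4:
        raise ValueError("consensus needs >= 4 shared taxa")
    counts: Counter[frozenset[str]] = Counter()
    for t in trees:
        counts.update(_projected_splits(t, shared))
    n = len(trees)
    retained = {s: c / n for s, c in counts.items() if c / n > threshold}
    if threshold < 0.5:
        keep: dict[frozenset[str], float] = {}
        for s in sorted(retained, key=lambda x: -retained[x]):
            if all(compatible(s, k, universe=shared) for k in keep):
                keep[s] = retained[s]
        retained = keep
    tree = tree_from_splits(retained.keys(), shared)
    return ConsensusTree(tree=tree, frequencies=retained, universe=shared)


@dataclass
class TopologyCensus:
    """Equivalence classes of identical topology (RF distance zero).

    ``classes`` maps the canonical newick of the stripped unrooted form to
    the member analysis ids; ``excluded`` lists trees not spanning the full
    taxon universe (they cannot be compared at RF 0 on the full label set).
    """

    classes: dict[str, list[str]]
    excluded: list[str] = field(default_factory=list)

    @property
    def n_unique(self) -> int:
        return len(self.classes)

    @property
    def modal_count(self) -> int:
        return max((len(v) for v in self.classes.values()), default=0)

    @property
    def modal_key(self) -> str | None:
        if not self.classes:
            return None
        return max(self.classes, key=lambda k: (len(self.classes[k]), k))

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.classes.items()}

    def to_rows(self) -> list[tuple[str, int, str]]:
        rows = sorted(self.classes.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        return [(k, len(v), ",".join(v)) for k, v in rows]


def topology_census(ts: TreeSet,
                    universe: frozenset[str] | None = None) -> TopologyCensus:
    """Group trees into identical-topology classes on the full taxon set.

    Two trees share a class iff their nontrivial split sets are equal
    (equivalently, RF distance 0).  Trees missing taxa from the universe
    are excluded and reported, not silently dropped.
    """
    if len(ts) == 0:
        raise ValueError("census of an empty tree set is undefined")
    if universe is None:
        universe = frozenset(ts.taxon_set.labels)
    by_key: dict[frozenset[frozenset[str]], list[str]] = {}
    key_tree: dict[frozenset[frozenset[str]], dendropy.Tree] = {}
    excluded = []
    for tree, _group, aid in ts:
        if leaf_labels(tree) != universe:
            excluded.append(aid)
            continue
        key = split_set(tree)
        by_key.setdefault(key, []).append(aid)
        key_tree.setdefault(key, tree)
    classes = {canonical_newick(key_tree[k]): sorted(v)
               for k, v in by_key.items()}
    return TopologyCensus(classes=classes, excluded=excluded)
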