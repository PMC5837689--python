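"""Statistical binning of gene trees into balanced, pairwise-compatible
supergene bins.

Gene trees are first collapsed to their well-supported splits (bootstrap
support strictly greater than a threshold, 50 by default).  Two collapsed
trees are *incompatible* when, restricted to their shared taxa, some split
of one conflicts with some split of the other.  The incompatibility graph
over loci is then colored greedily into balanced independent bins
(supergenes); pairwise compatibility is necessary but not sufficient for
joint compatibility of a bin, matching the published binning heuristic,
and the pairwise condition is re-verified post hoc on every assignment.

For species-tree summaries the supergene trees can be replicated by bin
size ("weighted" binning) so the multiset cardinality equals the original
locus count.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx

from .estimation import GeneTree
from .splits import compatible, split_set, tree_from_splits
from .supermatrix import LocusAlignment, Supermatrix, concatenate
from .trees_io import leaf_labels

__all__ = [
    "CollapsedTree",
    "BinAssignment",
    "collapse_low_support",
    "pair_incompatible",
    "build_graph",
    "balanced_bins",
    "balanced_sizes",
    "build_supergenes",
    "weight_supergene_trees",
]


@dataclass
class CollapsedTree:
    """A gene tree retaining only splits supported above ``threshold``."""

    tree: dendropy.Tree
    threshold: float
    locus_id: str

    @property
    def splits(self) -> frozenset[frozenset[str]]:
        return split_set(self.tree)

    @property
    def taxa(self) -> frozenset[str]:
        return leaf_labels(self.tree)


def collapse_low_support(gene: GeneTree | dendropy.Tree,
                         threshold: float = 50.0,
                         locus_id: str | None = None) -> CollapsedTree:
    """Contract internal edges with support <= threshold (strict rule:
    an edge at exactly the threshold is contracted).

    Every internal edge must carry a support value; trees straight from
    :func:`~phyloconcord.estimation.bootstrap_gene_tree` do.
    """
    if isinstance(gene, GeneTree):
        tree, lid = gene.tree, gene.locus_id
    else:
        tree, lid = gene, locus_id or "locus"
    universe = leaf_labels(tree)
    n = len(universe)
    clades: dict[int, frozenset[str]] = {}
    keep: set[frozenset[str]] = set()
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            clades[id(nd)] = frozenset([nd.taxon.label])
            continue
        clade = frozenset().union(*(clades[id(c)] for c in nd.child_nodes()))
        clades[id(nd)] = clade
        if nd is tree.seed_node:
            continue
        side = clade if min(universe) not in clade else universe - clade
        if not (2 <= len(side) <= n - 2):
            continue  # trivial edge (e.g. one child of a degree-2 root)
        support = getattr(nd, "support", None)
        if support is None:
            raise ValueError(
                f"internal edge of {lid} lacks a support value")
        if support > threshold:
            keep.add(side)
    collapsed = tree_from_splits(keep, universe)
    return CollapsedTree(tree=collapsed, threshold=threshold, locus_id=lid)


def _projected(sides: Iterable[frozenset[str]], universe: frozenset[str],
               shared: frozenset[str]) -> list[frozenset[str]]:
    out = []
    ref = min(shared)
    for s in sides:
        inter = s & shared
        if ref in inter:
            inter = shared - inter
        if 2 <= len(inter) <= len(shared) - 2:
            out.append(inter)
    return out


def pair_incompatible(a: CollapsedTree, b: CollapsedTree) -> bool:
    """True iff some retained split of one conflicts with one of the other
    on their shared taxa.  Fewer than 4 shared taxa means compatible."""
    shared = a.taxa & b.taxa
    if len(shared) < 4:
        return False
    pa = _projected(a.splits, a.taxa, shared)
    pb = _projected(b.splits, b.taxa, shared)
    for sa in pa:
        for sb in pb:
            if not compatible(sa, sb, universe=shared):
                return True
    return False


def build_graph(trees: Sequence[CollapsedTree]) -> nx.Graph:
    """Incompatibility graph: one node per locus, an edge per incompatible
    pair (deterministic O(m^2) scan in locus-id order)."""
    if len(trees) < 2:
        raise ValueError("need >= 2 collapsed trees")
    trees = sorted(trees, key=lambda t: t.locus_id)
    ids = [t.locus_id for t in trees]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate locus ids")
    g = nx.Graph()
    g.add_nodes_from(ids)
    for ta, tb in itertools.combinations(trees, 2):
        if pair_incompatible(ta, tb):
            g.add_edge(ta.locus_id, tb.locus_id)
    return g


def balanced_sizes(m: int, n_bins: int) -> list[int]:
    """Sizes of a maximally balanced partition of m items into n_bins."""
    base, extra = divmod(m, n_bins)
    return [base + 1] * extra + [base] * (n_bins - extra)


@dataclass
class BinAssignment:
    """A partition of loci into pairwise-compatible bins.

    ``weights`` maps each bin to its size, the replication factor used by
    weighted binning.
    """

    bins: dict[str, list[str]]
    balanced: bool = True

    @property
    def weights(self) -> dict[str, int]:
        return {b: len(v) for b, v in self.bins.items()}

    @property
    def n_loci(self) -> int:
        return sum(len(v) for v in self.bins.values())

    def size_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for v in self.bins.values():
            hist[len(v)] = hist.get(len(v), 0) + 1
        return dict(sorted(hist.items(), reverse=True))

    def to_tsv_rows(self) -> list[tuple[str, str]]:
        return [(b, lid) for b in sorted(self.bins) for lid in sorted(self.bins[b])]


def _greedy_assign(graph: nx.Graph, n_bins: int) -> dict[str, list[str]] | None:
    """Greedy balanced coloring: nodes in descending-degree order (ties by
    id) go to the smallest valid bin under the size cap; None on failure."""
    nodes = sorted(graph.nodes, key=lambda v: (-graph.degree[v], v))
    cap = math.ceil(len(nodes) / n_bins)
    bins: list[list[str]] = [[] for _ in range(n_bins)]
    members: list[set[str]] = [set() for _ in range(n_bins)]
    for v in nodes:
        neighbors = set(graph.neighbors(v))
        best = None
        for k in range(n_bins):
            if len(bins[k]) >= cap or members[k] & neighbors:
                continue
            if best is None or len(bins[k]) < len(bins[best]):
                best = k
        if best is None:
            return None
        bins[best].append(v)
        members[best].add(v)
    return {f"bin{k:04d}": sorted(b) for k, b in enumerate(bins) if b}


def balanced_bins(graph: nx.Graph, n_bins: int | None = None,
                  target_size: float = 7.0) -> BinAssignment:
    """Partition loci into balanced bins with no incompatible pair inside.

    With ``n_bins`` given, the greedy heuristic must succeed at that count
    or an error suggests the smallest feasible count.  In automatic mode
    the bin count starts at ceil(m / target_size) and grows until the
    heuristic succeeds.  Sizes differ by at most one whenever the size cap
    allows; otherwise balance is minimally relaxed with a warning.
    """
    m = graph.number_of_nodes()
    if m == 0:
        raise ValueError("empty graph")
    if n_bins is not None:
        assignment = _greedy_assign(graph, n_bins)
        if assignment is None:
            k = n_bins + 1
            while _greedy_assign(graph, k) is None:
                k += 1
            raise ValueError(
                f"no valid balanced assignment at {n_bins} bins; "
                f"smallest feasible count found: {k}")
    else:
        k = max(1, math.ceil(m / target_size))
        assignment = _greedy_assign(graph, k)
        while assignment is None:
            k += 1
            assignment = _greedy_assign(graph, k)
    sizes = sorted(len(v) for v in assignment.values())
    balanced = sizes[-1] - sizes[0] <= 1
    if not balanced:
        warnings.warn(
            "incompatibility structure forced unbalanced bins "
            f"(sizes {sizes[0]}..{sizes[-1]})", stacklevel=2)
    ba = BinAssignment(bins=assignment, balanced=balanced)
    _verify(ba, graph)
    return ba


def _verify(ba: BinAssignment, graph: nx.Graph) -> None:
    """Post-hoc independence check: no bin contains an incompatible pair."""
    assigned = [lid for v in ba.bins.values() for lid in v]
    if sorted(assigned) != sorted(graph.nodes):
        raise RuntimeError("bins do not partition the loci")
    for members in ba.bins.values():
        for a, b in itertools.combinations(members, 2):
            if graph.has_edge(a, b):
                raise RuntimeError(
                    f"incompatible pair ({a}, {b}) assigned to one bin")


def build_supergenes(ba: BinAssignment,
                     loci: Mapping[str, LocusAlignment] | Sequence[LocusAlignment],
                     ) -> dict[str, Supermatrix]:
    """Concatenate each bin's loci (sorted by id) into a supergene
    alignment with per-locus character sets."""
    if not isinstance(loci, Mapping):
        loci = {l.locus_id: l for l in loci}
    out = {}
    for bin_id in sorted(ba.bins):
        members = sorted(ba.bins[bin_id])
        missing = [m for m in members if m not in loci]
        if missing:
            raise ValueError(f"bin {bin_id}: missing loci {missing}")
        out[bin_id] = concatenate([loci[m] for m in members])
    return out


def weight_supergene_trees(trees: Mapping[str, dendropy.Tree],
                           ba: BinAssignment,
                           weighted: bool = True,
                           ) -> list[tuple[str, dendropy.Tree]]:
    """Supergene tree multiset for species-tree summarization.

    Weighted mode replicates each bin's tree by its size, so the multiset
    cardinality equals the input locus count; unweighted includes each
    tree once.
    """
    missing = [b for b in ba.bins if b not in trees]
    if missing:
        raise ValueError(f"missing supergene trees for bins {missing}")
    out = []
    for bin_id in sorted(ba.bins):
        copies = len(ba.bins[bin_id]) if weighted else 1
        out.extend((bin_id, trees[bin_id]) for _ in range(copies))
    return out
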