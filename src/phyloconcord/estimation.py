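"""Desk-scale tree estimation: Jukes-Cantor distances, neighbor joining
with nonparametric bootstrap supports, and an average-internode-distance
species-tree summary (ASTRID-style: mean topological distances across gene
trees, then a BIONJ-family distance method).

This estimator deliberately trades the likelihood machinery of external
engines for a transparent, dependency-free pipeline that runs anywhere;
externally computed newick gene trees are accepted interchangeably
wherever a gene tree is consumed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import dendropy
import networkx as nx

from .quartets import topological_distances
from .splits import split_set
from .supermatrix import LocusAlignment
from .trees_io import leaf_labels

__all__ = [
    "GeneTree",
    "DEFAULT_MAX_JC_DISTANCE",
    "jc_distance",
    "neighbor_joining",
    "bootstrap_gene_tree",
    "average_internode_distances",
    "astrid_like",
]

DEFAULT_MAX_JC_DISTANCE = 5.0
_NUC = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class GeneTree:
    """A per-locus tree with bootstrap supports on internal nodes."""

    tree: dendropy.Tree
    locus_id: str
    bootstrap_reps: int = 0

    @property
    def taxa_present(self) -> frozenset[str]:
        return leaf_labels(self.tree)


def _encode(locus: LocusAlignment) -> tuple[list[str], np.ndarray]:
    """Encode sequences as integer codes; anything not ACGT becomes -1."""
    taxa = sorted(locus.sequences)
    arr = np.full((len(taxa), locus.length), -1, dtype=np.int8)
    for i, t in enumerate(taxa):
        seq = locus.sequences[t].upper()
        arr[i] = [_NUC.get(ch, -1) for ch in seq]
    return taxa, arr


def jc_distance(locus: LocusAlignment,
                max_distance: float = DEFAULT_MAX_JC_DISTANCE,
                ) -> tuple[list[str], np.ndarray]:
    """Pairwise Jukes-Cantor distances d = -(3/4) ln(1 - 4p/3).

    ``p`` is the mismatch proportion over sites where both sequences carry
    an unambiguous nucleotide.  Saturated pairs (p >= 3/4) are capped at
    ``max_distance``.  A pair with zero overlapping sites is an error.
    """
    if locus.taxon_count < 3:
        raise ValueError("distance estimation needs >= 3 taxa")
    taxa, arr = _encode(locus)
    n = len(taxa)
    dm = np.zeros((n, n))
    valid = arr >= 0
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        overlap = int(both.sum())
        if overlap == 0:
            raise ValueError(
                f"no overlapping sites for pair ({taxa[i]}, {taxa[j]})")
        p = float((arr[i][both] != arr[j][both]).sum()) / overlap
        if p >= 0.75:
            d = max_distance
        else:
            d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
        dm[i, j] = dm[j, i] = d
    return taxa, dm


def _star_tree(taxa: Sequence[str]) -> dendropy.Tree:
    tree = dendropy.Tree()
    tree.is_rooted = False
    tn = tree.taxon_namespace
    for t in sorted(taxa):
        leaf = dendropy.Node()
        leaf.taxon = tn.require_taxon(label=t)
        tree.seed_node.add_child(leaf)
    for nd in tree.preorder_node_iter():
        nd.support = None
    return tree


def neighbor_joining(taxa: Sequence[str], dm: np.ndarray) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (cluster, cluster) name pair, where a cluster is named after its
    smallest leaf label.  Negative branch-length estimates are clamped to
    zero.  Returns an unrooted tree (trifurcating seed node).
    """
    taxa = list(taxa)
    n = len(taxa)
    dm = np.asarray(dm, dtype=float)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.isfinite(dm).all():
        raise ValueError("non-finite distances")
    tree = dendropy.Tree()
    tree.is_rooted = False
    tn = tree.taxon_namespace
    nodes: list[dendropy.Node] = []
    names: list[str] = []
    for t in sorted(taxa):
        leaf = dendropy.Node()
        leaf.taxon = tn.require_taxon(label=t)
        nodes.append(leaf)
        names.append(t)
    order = np.argsort(taxa)  # our working order is sorted labels
    d = dm[np.ix_(order, order)].copy()

    def _join(i: int, j: int, li: float, lj: float) -> None:
        parent = dendropy.Node()
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = max(li, 0.0)
        b.edge.length = max(lj, 0.0)
        nodes[i] = parent
        names[i] = min(names[i], names[j])
        del nodes[j], names[j]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [(tuple(sorted((names[i], names[j]))), i, j)
                      for i in range(m) for j in range(i + 1, m)
                      if q[i, j] <= qmin + 1e-12]
        _, i, j = min(candidates)
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        _join(i, j, li, lj)
        d[i] = dnew
        d[:, i] = dnew
        d[i, i] = 0.0
        d = np.delete(np.delete(d, j, axis=0), j, axis=1)

    if len(nodes) == 3:
        la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        for node, length in zip(nodes, (la, lb, lc)):
            tree.seed_node.add_child(node)
            node.edge.length = max(length, 0.0)
    for nd in tree.preorder_node_iter():
        if not hasattr(nd, "support"):
            nd.support = None
    return tree


def estimate_tree(locus: LocusAlignment,
                  max_distance: float = DEFAULT_MAX_JC_DISTANCE,
                  ) -> dendropy.Tree:
    """JC distances + neighbor joining on one alignment."""
    taxa, dm = jc_distance(locus, max_distance=max_distance)
    return neighbor_joining(taxa, dm)


def bootstrap_gene_tree(locus: LocusAlignment, reps: int = 100,
                        seed: int = 0, locus_id: str | None = None,
                        ) -> GeneTree:
    """Point-estimate tree with site-resampled bootstrap supports.

    Supports are the percentage of replicate trees containing each split
    of the point-estimate tree.  An alignment with no variable sites
    yields a star tree with no internal edges (and hence no supports).
    """
    if reps < 1:
        raise ValueError("need >= 1 bootstrap replicate")
    locus_id = locus_id or locus.locus_id
    taxa, arr = _encode(locus)
    variable = False
    for col in arr.T:
        states = set(col[col >= 0].tolist())
        if len(states) >= 2:
            variable = True
            break
    if not variable:
        return GeneTree(tree=_star_tree(taxa), locus_id=locus_id,
                        bootstrap_reps=reps)
    point = estimate_tree(locus)
    point_splits = split_set(point)
    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in point_splits}
    n_ok = 0
    for _ in range(reps):
        cols = rng.integers(0, locus.length, size=locus.length)
        boot = LocusAlignment(
            locus_id=locus_id,
            sequences={t: "".join(locus.sequences[t][c] for c in cols)
                       for t in taxa})
        try:
            rep_tree = estimate_tree(boot)
        except ValueError:  # a pair lost all overlapping sites in this draw
            continue
        n_ok += 1
        rep_splits = split_set(rep_tree)
        for s in point_splits:
            if s in rep_splits:
                counts[s] += 1
    denom = max(n_ok, 1)
    universe = leaf_labels(point)
    clades: dict[int, frozenset[str]] = {}
    for nd in point.postorder_node_iter():
        if nd.is_leaf():
            clades[id(nd)] = frozenset([nd.taxon.label])
            continue
        clade = frozenset().union(*(clades[id(c)] for c in nd.child_nodes()))
        clades[id(nd)] = clade
        if nd is point.seed_node:
            continue
        side = clade if min(universe) not in clade else universe - clade
        if 2 <= len(side) <= len(universe) - 2:
            nd.support = 100.0 * counts[side] / denom
    return GeneTree(tree=point, locus_id=locus_id, bootstrap_reps=reps)


def average_internode_distances(genes: Iterable[GeneTree | dendropy.Tree],
                                ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Mean topological (edge-count) leaf-pair distances across gene trees.

    Returns (taxa, mean matrix, count matrix); the mean is over the gene
    trees containing both taxa of a pair.  Entries with zero count are 0
    in the mean matrix and must be treated via the count matrix.
    """
    trees = [g.tree if isinstance(g, GeneTree) else g for g in genes]
    if not trees:
        raise ValueError("no gene trees")
    all_taxa = sorted(set().union(*(leaf_labels(t) for t in trees)))
    index = {t: i for i, t in enumerate(all_taxa)}
    n = len(all_taxa)
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for t in trees:
        labels, dist = topological_distances(t)
        idx = np.array([index[lab] for lab in labels])
        total[np.ix_(idx, idx)] += dist
        count[np.ix_(idx, idx)] += 1
    np.fill_diagonal(count, 0)
    mean = np.divide(total, count, out=np.zeros_like(total),
                     where=count > 0)
    return all_taxa, mean, count


def astrid_like(genes: Sequence[GeneTree | dendropy.Tree]) -> dendropy.Tree:
    """Species-tree summary: neighbor joining on the average internode
    distance matrix.

    Requires the taxon-pair support graph (pairs co-occurring in >= 1 gene
    tree) to be connected; a pair never observed together has its distance
    imputed additively along the shortest path of observed mean distances.
    """
    taxa, mean, count = average_internode_distances(genes)
    n = len(taxa)
    if n < 3:
        raise ValueError("species-tree summary needs >= 3 taxa")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if count[i, j] > 0:
            g.add_edge(i, j, weight=mean[i, j])
    if not nx.is_connected(g):
        comps = [sorted(taxa[i] for i in c) for c in nx.connected_components(g)]
        raise ValueError(
            f"taxon-pair graph disconnected; groups: {comps}")
    if (count[np.triu_indices(n, 1)] == 0).any():
        paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        for i, j in itertools.combinations(range(n), 2):
            if count[i, j] == 0:
                mean[i, j] = mean[j, i] = paths[i][j]
    return neighbor_joining(taxa, mean)
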