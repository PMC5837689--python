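"""Induced quartet topologies and the normalized quartet score.

For any four leaves {a, b, c, d} of a tree, the induced quartet topology is
one of the three resolved pairings ab|cd, ac|bd, ad|bc, or unresolved when
the four leaves meet at a single point of the tree.  The topology is read
off topological (edge-count) leaf-to-leaf distances via the four-point
condition: the pairing whose within-pair distance sum is strictly smallest
is induced; all three sums equal means unresolved.

The normalized quartet score of a candidate species tree against a set of
gene trees is the fraction of resolved induced gene-tree quartets that
agree with the species tree — the quantity summary methods such as ASTRAL
maximize.  Gene trees with missing taxa contribute only the C(k, 4)
quartets on their own k leaves.  Unresolved induced quartets are excluded
from both numerator and denominator, so a perfectly concordant but
partially unresolved gene set can still score 1.0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import dendropy

from .trees_io import TaxonSet, TreeSet, leaf_labels

__all__ = [
    "QuartetTopology",
    "QuartetScore",
    "enumerate_quartets",
    "topological_distances",
    "induced_quartet",
    "normalized_quartet_score",
]


@dataclass(frozen=True)
class QuartetTopology:
    """A 4-taxon subset plus its induced pairing (None = unresolved).

    The pairing is canonicalized: the pair containing the lexicographically
    smallest taxon comes first and each pair is sorted.
    """

    taxa: tuple[str, str, str, str]
    pairing: tuple[tuple[str, str], tuple[str, str]] | None

    @staticmethod
    def make(taxa: Iterable[str],
             pair: tuple[str, str] | None) -> "QuartetTopology":
        taxa = tuple(sorted(taxa))
        if pair is None:
            return QuartetTopology(taxa=taxa, pairing=None)
        first = tuple(sorted(pair))
        second = tuple(sorted(set(taxa) - set(first)))
        if first[0] != taxa[0]:
            first, second = second, first
        return QuartetTopology(taxa=taxa, pairing=(first, second))


def enumerate_quartets(taxa: TaxonSet | Iterable[str]
                       ) -> list[tuple[str, str, str, str]]:
    """All C(n, 4) four-taxon subsets in deterministic lexicographic order."""
    labels = sorted(taxa.labels if isinstance(taxa, TaxonSet) else taxa)
    if len(labels) < 4:
        raise ValueError("quartet enumeration requires >= 4 taxa")
    return list(itertools.combinations(labels, 4))


def topological_distances(tree: dendropy.Tree
                          ) -> tuple[list[str], np.ndarray]:
    """Edge-count (unit branch length) leaf-to-leaf distances.

    Returns the sorted leaf labels and the corresponding symmetric matrix.
    Computed by BFS from each leaf over the unrooted adjacency; a degree-2
    root would inflate paths through it, so it is bypassed.
    """
    adj: dict[int, list[int]] = {}
    node_of: dict[int, dendropy.Node] = {}
    for nd in tree.preorder_node_iter():
        node_of[id(nd)] = nd
        adj.setdefault(id(nd), [])
        for c in nd.child_nodes():
            adj[id(nd)].append(id(c))
            adj.setdefault(id(c), []).append(id(nd))
    # suppress a degree-2 seed node (rooted binary tree) for unrooted paths
    seed = tree.seed_node
    if len(adj[id(seed)]) == 2:
        a, b = adj[id(seed)]
        adj[a] = [x if x != id(seed) else b for x in adj[a]]
        adj[b] = [x if x != id(seed) else a for x in adj[b]]
        del adj[id(seed)]
    leaves = sorted((lf.taxon.label, id(lf)) for lf in tree.leaf_node_iter())
    labels = [lab for lab, _ in leaves]
    index = {nid: i for i, (_, nid) in enumerate(leaves)}
    n = len(labels)
    dist = np.zeros((n, n), dtype=np.int64)
    for src_label, src_id in leaves:
        seen = {src_id: 0}
        frontier = [src_id]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = seen[u] + 1
                        nxt.append(v)
            frontier = nxt
        i = index[src_id]
        for nid, d in seen.items():
            if nid in index:
                dist[i, index[nid]] = d
    return labels, dist


def _pairing_codes(dist: np.ndarray, quartet_idx: np.ndarray
                   ) -> np.ndarray:
    """Vectorized induced-quartet codes for rows of (a,b,c,d) leaf indices.

    Code 0: ab|cd, 1: ac|bd, 2: ad|bc, -1: unresolved.  Indices must be
    sorted within each row so codes are comparable across trees.
    """
    a, b, c, d = (quartet_idx[:, k] for k in range(4))
    s = np.stack([dist[a, b] + dist[c, d],
                  dist[a, c] + dist[b, d],
                  dist[a, d] + dist[b, c]], axis=1)
    code = np.argmin(s, axis=1)
    smin = s.min(axis=1)
    n_at_min = (s == smin[:, None]).sum(axis=1)
    code = np.where(n_at_min == 1, code, -1)
    return code


_CODE_PAIRS = {0: (0, 1), 1: (0, 2), 2: (0, 3)}


def induced_quartet(tree: dendropy.Tree,
                    quartet: Iterable[str]) -> QuartetTopology:
    """Induced topology of one 4-taxon subset of ``tree``'s leaves."""
    q = tuple(sorted(quartet))
    if len(set(q)) != 4:
        raise ValueError("quartet must contain 4 distinct taxa")
    labels, dist = topological_distances(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    missing = [x for x in q if x not in index]
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    idx = np.array([[index[x] for x in q]])
    code = int(_pairing_codes(dist, idx)[0])
    if code == -1:
        return QuartetTopology.make(q, None)
    i, j = _CODE_PAIRS[code]
    return QuartetTopology.make(q, (q[i], q[j]))


@dataclass
class QuartetScore:
    """Counts of resolved induced gene-tree quartets and agreement with a
    species tree; ``normalized`` is the exact quotient agreeing/total."""

    agreeing: int
    total_resolved: int
    per_gene: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def normalized(self) -> float:
        return self.agreeing / self.total_resolved

    def to_dict(self) -> dict:
        return {"agreeing": self.agreeing,
                "total_resolved": self.total_resolved,
                "normalized": self.normalized}


def normalized_quartet_score(species: dendropy.Tree,
                             genes: TreeSet | Sequence[dendropy.Tree],
                             gene_ids: Sequence[str] | None = None,
                             ) -> QuartetScore:
    """Fraction of resolved induced gene-tree quartets agreeing with
    ``species``.

    Each gene tree contributes the quartets on its own leaves intersected
    with the species tree's leaves (needs >= 4 shared taxa per gene tree).
    A resolved gene quartet *agrees* when the species tree induces the same
    resolved pairing; quartets the species tree leaves unresolved cannot
    agree but still count as resolved gene quartets.
    """
    if isinstance(genes, TreeSet):
        gene_trees = genes.trees
        ids = list(genes.analysis_ids)
    else:
        gene_trees = list(genes)
        ids = list(gene_ids) if gene_ids is not None else [
            f"gene{i}" for i in range(len(gene_trees))]
    sp_labels, sp_dist = topological_distances(species)
    sp_index = {lab: i for i, lab in enumerate(sp_labels)}
    agreeing = total = 0
    per_gene = []
    for gid, gt in zip(ids, gene_trees):
        g_labels, g_dist = topological_distances(gt)
        shared = [lab for lab in g_labels if lab in sp_index]
        if len(shared) < 4:
            raise ValueError(
                f"gene tree {gid} shares only {len(shared)} taxa with species tree")
        g_index = {lab: i for i, lab in enumerate(g_labels)}
        quads = np.array(list(itertools.combinations(shared, 4)))
        g_idx = np.vectorize(g_index.__getitem__)(quads)
        s_idx = np.vectorize(sp_index.__getitem__)(quads)
        g_codes = _pairing_codes(g_dist, g_idx)
        s_codes = _pairing_codes(sp_dist, s_idx)
        resolved = g_codes != -1
        agree = resolved & (s_codes != -1) & (g_codes == s_codes)
        n_res, n_agree = int(resolved.sum()), int(agree.sum())
        total += n_res
        agreeing += n_agree
        per_gene.append((gid, n_agree, n_res))
    if total == 0:
        raise ValueError("no resolved induced quartets: score undefined")
    return QuartetScore(agreeing=agreeing, total_resolved=total,
                        per_gene=per_gene)
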