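"""Synthetic multispecies-coalescent data with a discordant
mitochondrial-like locus.

The generator emulates the statistical structure the concordance analysis
assumes: a species tree from a Yule process (a neutral stand-in for a
rapid radiation), gene trees drawn under the standard multispecies
coalescent (MSC) so that short internal branches produce incomplete
lineage sorting, one non-recombining "mitochondrial" locus with a reduced
effective population size and optional introgression events that reroute
its lineages across the species tree, Jukes-Cantor sequence evolution with
a rate scale calibrated to UCE-like informativeness (~2.6% of sites
parsimony-informative), and per-locus taxon missingness.

All branch lengths are in coalescent units (time / 2N); within a species
branch, k gene lineages coalesce at rate C(k, 2) per unit, divided by the
locus's relative effective size (``ne_scale``, ~1/4 for the mitochondrial
locus).  Every stage draws from a named substream of one master seed so
any stage is independently replayable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import dendropy

from .supermatrix import LocusAlignment, locus_stats
from .trees_io import leaf_labels

__all__ = [
    "IntrogressionEvent",
    "SimConfig",
    "SyntheticDataset",
    "simulate_yule_tree",
    "species_tree_from_newick",
    "branch_id",
    "simulate_msc_gene_tree",
    "simulate_mito_tree",
    "simulate_sequences",
    "apply_missingness",
    "distant_leaf_introgression",
    "calibrate_rate_scale",
    "mean_informative_fraction",
    "simulate_dataset",
    "substream",
]

#: Default per-coalescent-unit substitution rate; calibrated so ~2.6% of
#: sites are parsimony-informative under the default Yule(1) 37-taxon tree.
DEFAULT_RATE_SCALE = 0.00113

def substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of one master seed."""
    names = ("species", "genetrees", "mito", "sequences", "masks", "other")
    if name not in names:
        raise ValueError(f"unknown substream {name!r}")
    ss = np.random.SeedSequence(seed).spawn(len(names))
    return np.random.default_rng(ss[names.index(name)])


@dataclass(frozen=True)
class IntrogressionEvent:
    """Reroute lineages of one species-tree branch into another.

    Backwards in time at ``time`` (coalescent units before present), each
    gene lineage currently in branch ``donor`` moves into branch
    ``recipient`` with probability ``probability``; with probability 1 the
    donor taxon's locus becomes sister to the recipient clade (in the
    small-``ne_scale`` limit).  Both branches must span the event time.
    """

    donor: str
    recipient: str
    time: float
    probability: float = 1.0

    def __post_init__(self):
        if not 0 < self.probability <= 1:
            raise ValueError("probability must be in (0, 1]")
        if self.time < 0:
            raise ValueError("event time must be >= 0")


def _label(i: int, n: int) -> str:
    width = max(2, len(str(n)))
    return f"t{i + 1:0{width}d}"


def simulate_yule_tree(n: int, birth_rate: float = 1.0,
                       rng: np.random.Generator | int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) species tree with exponential waiting times.

    Leaves are labeled t01..tNN (assigned in random order); edge lengths
    are in coalescent units; the tree is ultrametric with leaves at time 0.
    """
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    # forward simulation: record (birth_time, parent_record) per lineage
    t = 0.0
    records: list[dict] = [{"birth": 0.0, "parent": None, "children": []}]
    active = [records[0]]
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = rng.integers(0, k)
        parent = active.pop(idx)
        parent["split"] = t
        for _ in range(2):
            child = {"birth": t, "parent": parent, "children": []}
            parent["children"].append(child)
            records.append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * n))
    labels = [_label(i, n) for i in range(n)]
    perm = rng.permutation(n)
    tree = dendropy.Tree()
    tree.is_rooted = True
    tn = tree.taxon_namespace

    def _build(rec: dict, node: dendropy.Node) -> None:
        if rec["children"]:
            for child in rec["children"]:
                cn = dendropy.Node()
                cn.edge.length = (child.get("split", t_end) - child["birth"])
                node.add_child(cn)
                _build(child, cn)
        else:
            node.taxon = tn.require_taxon(
                label=labels[perm[_build.leaf_counter]])
            _build.leaf_counter += 1

    _build.leaf_counter = 0
    root_rec = records[0]
    tree.seed_node.edge.length = None
    if root_rec["children"]:
        for child in root_rec["children"]:
            cn = dendropy.Node()
            cn.edge.length = child.get("split", t_end) - child["birth"]
            tree.seed_node.add_child(cn)
            _build(child, cn)
    for nd in tree.preorder_node_iter():
        nd.support = None
    return tree


def species_tree_from_newick(text: str) -> dendropy.Tree:
    """Parse a rooted species tree whose branch lengths are coalescent units."""
    from .trees_io import parse_newick

    tree = parse_newick(text)
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            raise ValueError("species tree must have branch lengths on all edges")
    return tree


def branch_id(node: dendropy.Node) -> str:
    """Stable identifier of a species-tree branch: its child clade,
    written as the sorted leaf labels joined by '+'."""
    if node.is_leaf():
        return node.taxon.label
    return "+".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def _node_ages(tree: dendropy.Tree) -> dict[int, float]:
    """Ages (time before present) assuming leaves at age 0 (ultrametric)."""
    ages: dict[int, float] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            ages[id(nd)] = 0.0
        else:
            cand = [ages[id(c)] + (c.edge.length or 0.0)
                    for c in nd.child_nodes()]
            if max(cand) - min(cand) > 1e-6 * max(max(cand), 1.0):
                raise ValueError(
                    "species tree must be ultrametric in coalescent units")
            ages[id(nd)] = max(cand)
    return ages


class _Lineage:
    __slots__ = ("node", "height")

    def __init__(self, node: dendropy.Node, height: float):
        self.node = node
        self.height = height


def _coalesce_within(lineages: list[_Lineage], t0: float, t1: float,
                     ne_scale: float, rng: np.random.Generator) -> float:
    """Coalesce ``lineages`` in place over (t0, t1); returns final time."""
    t = t0
    while len(lineages) >= 2:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / ne_scale
        dt = rng.exponential(1.0 / rate)
        if t + dt >= t1:
            return t1
        t += dt
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = lineages[i], lineages[j]
        parent = dendropy.Node()
        parent.add_child(a.node)
        parent.add_child(b.node)
        a.node.edge.length = t - a.height
        b.node.edge.length = t - b.height
        merged = _Lineage(parent, t)
        del lineages[j], lineages[i]
        lineages.append(merged)
    return t1


def _simulate_coalescent(sp: dendropy.Tree,
                         events: Sequence[IntrogressionEvent],
                         ne_scale: float,
                         rng: np.random.Generator) -> dendropy.Tree:
    """Epoch-sliced multispecies coalescent over the species tree.

    Lineages live in species-tree branches; at each boundary (species
    divergence going rootward, or an introgression event) branch
    membership changes, and between boundaries each branch's lineages
    coalesce at rate C(k,2)/ne_scale.
    """
    ages = _node_ages(sp)
    by_id: dict[str, dendropy.Node] = {}
    for nd in sp.preorder_node_iter():
        by_id[branch_id(nd)] = nd
    root_age = ages[id(sp.seed_node)]

    def span(bid: str) -> tuple[float, float]:
        nd = by_id[bid]
        lo = ages[id(nd)]
        hi = ages[id(nd.parent_node)] if nd.parent_node is not None else math.inf
        return lo, hi

    for ev in events:
        for bid in (ev.donor, ev.recipient):
            if bid not in by_id:
                raise ValueError(f"unknown branch id {bid!r}")
            lo, hi = span(bid)
            if not (lo <= ev.time < hi):
                raise ValueError(
                    f"branch {bid!r} does not span event time {ev.time} "
                    f"(active on [{lo:g}, {hi:g}))")

    tn = dendropy.TaxonNamespace()
    active: dict[str, list[_Lineage]] = {}
    sim_time: dict[str, float] = {}
    for lf in sp.leaf_node_iter():
        node = dendropy.Node()
        node.taxon = tn.require_taxon(label=lf.taxon.label)
        active[branch_id(lf)] = [_Lineage(node, 0.0)]
        sim_time[branch_id(lf)] = 0.0

    boundaries: list[tuple[float, int, object]] = []
    for nd in sp.preorder_internal_node_iter():
        boundaries.append((ages[id(nd)], 0, nd))
    for ev in events:
        boundaries.append((ev.time, 1, ev))
    boundaries.sort(key=lambda b: (b[0], b[1]))

    def advance_to(t: float) -> None:
        for bid, lins in active.items():
            lo, hi = span(bid)
            target = min(t, hi)
            if target > sim_time[bid]:
                sim_time[bid] = _coalesce_within(
                    lins, sim_time[bid], target, ne_scale, rng)
                sim_time[bid] = target

    for t, kind, payload in boundaries:
        advance_to(t)
        if kind == 0:  # species divergence: children merge into parent branch
            nd = payload
            merged: list[_Lineage] = []
            for c in nd.child_nodes():
                merged.extend(active.pop(branch_id(c), []))
            pid = branch_id(nd)
            active.setdefault(pid, []).extend(merged)
            sim_time[pid] = t
        else:  # introgression: donor lineages move to recipient
            ev = payload
            donors = active.get(ev.donor, [])
            moved, stay = [], []
            for lin in donors:
                if rng.random() < ev.probability:
                    moved.append(lin)
                else:
                    stay.append(lin)
            active[ev.donor] = stay
            if moved:
                active.setdefault(ev.recipient, [])
                active[ev.recipient].extend(moved)
                sim_time.setdefault(ev.recipient, t)

    # above the root: all remaining lineages coalesce freely
    root_id = branch_id(sp.seed_node)
    remaining: list[_Lineage] = []
    for bid in list(active):
        remaining.extend(active.pop(bid))
    _coalesce_within(remaining, root_age, math.inf, ne_scale, rng)
    assert len(remaining) == 1
    gene = dendropy.Tree(taxon_namespace=tn)
    gene.seed_node = remaining[0].node
    gene.is_rooted = True
    for nd in gene.preorder_node_iter():
        nd.support = None
    return gene


def simulate_msc_gene_tree(sp: dendropy.Tree,
                           rng: np.random.Generator | int = 0,
                           ne_scale: float = 1.0) -> dendropy.Tree:
    """One gene tree under the standard multispecies coalescent
    (one sampled copy per species; branch lengths in coalescent units)."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return _simulate_coalescent(sp, (), ne_scale, rng)


def simulate_mito_tree(sp: dendropy.Tree,
                       events: Sequence[IntrogressionEvent] = (),
                       ne_scale: float = 0.25,
                       rng: np.random.Generator | int = 0) -> dendropy.Tree:
    """The mitochondrial-like locus: a single non-recombining gene tree
    with reduced effective size and optional introgression events."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return _simulate_coalescent(sp, tuple(events), ne_scale, rng)


def distant_leaf_introgression(sp: dendropy.Tree,
                               probability: float = 1.0,
                               ) -> IntrogressionEvent:
    """A certain-by-default introgression event between two distant leaf
    branches of ``sp``: the donor leaf's lineage is rerouted into the
    recipient leaf's branch at half the overlap of their spans.

    Picks the leaf pair with the largest topological separation (ties by
    label) so the rerouted history conflicts maximally with the species
    tree.
    """
    from .quartets import topological_distances

    ages = _node_ages(sp)
    labels, dist = topological_distances(sp)
    best = max(
        ((dist[i, j], labels[i], labels[j])
         for i in range(len(labels)) for j in range(len(labels)) if i != j),
        key=lambda x: (x[0], x[1], x[2]))
    _, donor, recipient = best
    tops = {}
    for lf in sp.leaf_node_iter():
        tops[lf.taxon.label] = ages[id(lf.parent_node)]
    t = 0.5 * min(tops[donor], tops[recipient])
    return IntrogressionEvent(donor=donor, recipient=recipient, time=t,
                              probability=probability)


def simulate_sequences(tree: dendropy.Tree, length: int,
                       rate_scale: float = DEFAULT_RATE_SCALE,
                       rng: np.random.Generator | int = 0,
                       gamma_shape: float | None = None,
                       locus_id: str = "locus") -> LocusAlignment:
    """Jukes-Cantor sequences along ``tree``.

    Expected substitutions per site on an edge are ``edge length *
    rate_scale`` (optionally multiplied by per-site Gamma(shape, 1/shape)
    rate factors).  The root sequence is uniform over A,C,G,T.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if length < 1:
        raise ValueError("length must be positive")
    if rate_scale < 0:
        raise ValueError("rate scale must be >= 0")
    rates = (rng.gamma(gamma_shape, 1.0 / gamma_shape, size=length)
             if gamma_shape else np.ones(length))
    alphabet = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    states: dict[int, np.ndarray] = {
        id(tree.seed_node): rng.integers(0, 4, size=length)}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            state = states[id(nd)]
        else:
            if nd.edge.length is None:
                raise ValueError("sequence simulation needs branch lengths")
            d = nd.edge.length * rate_scale * rates
            p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            parent_state = states[id(nd.parent_node)]
            change = rng.random(length) < p_change
            state = parent_state.copy()
            n_ch = int(change.sum())
            if n_ch:
                # jump uniformly to one of the three other states
                state[change] = (parent_state[change]
                                 + rng.integers(1, 4, size=n_ch)) % 4
            states[id(nd)] = state
        if nd.is_leaf():
            seqs[nd.taxon.label] = "".join(alphabet[state])
    return LocusAlignment(locus_id=locus_id, sequences=seqs)


def apply_missingness(loci: Sequence[LocusAlignment],
                      retention: float | Mapping[str, float],
                      rng: np.random.Generator | int = 0,
                      min_taxa: int = 3,
                      ) -> tuple[list[LocusAlignment], list[str]]:
    """Drop taxa independently per locus with probability 1 - retention.

    Loci left with fewer than ``min_taxa`` taxa are dropped entirely and
    reported in the second return value.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng

    def keep_prob(taxon: str) -> float:
        p = retention if isinstance(retention, (int, float)) else retention[taxon]
        if not 0 <= p <= 1:
            raise ValueError("retention probabilities must be in [0, 1]")
        return float(p)

    kept, dropped = [], []
    for locus in loci:
        taxa = sorted(locus.sequences)
        mask = {t: rng.random() < keep_prob(t) for t in taxa}
        survivors = {t: s for t, s in locus.sequences.items() if mask[t]}
        if len(survivors) < min_taxa:
            dropped.append(locus.locus_id)
        else:
            kept.append(LocusAlignment(locus_id=locus.locus_id,
                                       sequences=survivors))
    return kept, dropped


def mean_informative_fraction(loci: Iterable[LocusAlignment]) -> float:
    fracs = []
    for l in loci:
        st = locus_stats(l)
        fracs.append(st.informative / st.length)
    return float(np.mean(fracs))


def calibrate_rate_scale(sp: dendropy.Tree, target: float = 0.026,
                         n_loci: int = 40, length: int = 400,
                         seed: int = 0, iterations: int = 18,
                         ) -> float:
    """Bisection (on log scale) for the substitution rate scale whose mean
    parsimony-informative site fraction matches ``target``."""
    rng_master = np.random.default_rng(seed)
    lo, hi = 1e-5, 1.0

    def measure(rate: float) -> float:
        rng = np.random.default_rng(rng_master.integers(2 ** 31))
        loci = []
        for i in range(n_loci):
            gt = simulate_msc_gene_tree(sp, rng)
            loci.append(simulate_sequences(gt, length, rate, rng,
                                           locus_id=f"cal{i}"))
        return mean_informative_fraction(loci)

    for _ in range(iterations):
        mid = math.sqrt(lo * hi)
        if measure(mid) < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


@dataclass
class SimConfig:
    """Reproducibility envelope for one synthetic data set.

    Defaults are "study-shaped": 37 taxa, 3648 short loci of UCE-like
    length (~378 bp on average), a Yule(1) species tree whose short
    internal branches generate incomplete lineage sorting, a rate scale
    calibrated to ~2.6% informative sites, and a quarter-size
    mitochondrial locus.
    """

    n_taxa: int = 37
    n_loci: int = 3648
    locus_length_mean: float = 378.0
    locus_length_sd: float = 120.0
    locus_length_min: int = 120
    birth_rate: float = 1.0
    rate_scale: float = DEFAULT_RATE_SCALE
    gamma_shape: float | None = None
    mito_ne_scale: float = 0.25
    mito_length: int = 15520
    mito_rate_multiplier: float = 10.0
    introgression: tuple[IntrogressionEvent, ...] = ()
    retention: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["introgression"] = [asdict(e) for e in self.introgression]
        return d


@dataclass
class SyntheticDataset:
    """A generated data set plus the truth needed for recovery tests."""

    config: SimConfig
    species_tree: dendropy.Tree
    gene_trees: list[dendropy.Tree]
    mito_tree: dendropy.Tree
    loci: list[LocusAlignment]
    mito_locus: LocusAlignment
    dropped_loci: list[str] = field(default_factory=list)

    def manifest(self) -> dict:
        from .trees_io import canonical_newick, write_newick

        return {
            "config": self.config.to_dict(),
            "species_tree": write_newick(self.species_tree),
            "species_topology": canonical_newick(self.species_tree),
            "mito_topology": canonical_newick(self.mito_tree),
            "n_gene_trees": len(self.gene_trees),
            "n_loci": len(self.loci),
            "dropped_loci": self.dropped_loci,
        }


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate species tree, MSC gene trees, a mitochondrial-like locus,
    sequences, and missingness, all from named substreams of one seed."""
    rng_sp = substream(cfg.seed, "species")
    rng_gt = substream(cfg.seed, "genetrees")
    rng_mt = substream(cfg.seed, "mito")
    rng_sq = substream(cfg.seed, "sequences")
    rng_mk = substream(cfg.seed, "masks")

    sp = simulate_yule_tree(cfg.n_taxa, cfg.birth_rate, rng_sp)
    gene_trees = [simulate_msc_gene_tree(sp, rng_gt)
                  for _ in range(cfg.n_loci)]
    mito_tree = simulate_mito_tree(sp, cfg.introgression,
                                   cfg.mito_ne_scale, rng_mt)
    lengths = np.maximum(
        cfg.locus_length_min,
        rng_sq.normal(cfg.locus_length_mean, cfg.locus_length_sd,
                      size=cfg.n_loci).astype(int))
    loci = [simulate_sequences(gt, int(L), cfg.rate_scale, rng_sq,
                               cfg.gamma_shape, locus_id=f"locus{i:05d}")
            for i, (gt, L) in enumerate(zip(gene_trees, lengths))]
    mito_locus = simulate_sequences(
        mito_tree, cfg.mito_length,
        cfg.rate_scale * cfg.mito_rate_multiplier, rng_sq,
        locus_id="mito")
    kept, dropped = apply_missingness(loci, cfg.retention, rng_mk)
    return SyntheticDataset(config=cfg, species_tree=sp,
                            gene_trees=gene_trees, mito_tree=mito_tree,
                            loci=kept, mito_locus=mito_locus,
                            dropped_loci=dropped)
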