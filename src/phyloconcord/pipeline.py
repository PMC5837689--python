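"""End-to-end concordance analysis: simulate (or ingest) tree sets, build
matrix regimes, estimate trees, and summarize census, consensus, tree
space, quartet concordance and binning in one machine-readable report.

The run is fully deterministic for a fixed configuration: every stage
draws from substreams of the single configured seed, and the resolved
configuration is embedded in the report for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import dendropy

from . import binning as binning_mod
from . import estimation, quartets, splits, supermatrix, treespace
from .simulate import SimConfig, SyntheticDataset, simulate_dataset, substream
from .supermatrix import LocusAlignment
from .trees_io import (
    TreeSet,
    canonical_newick,
    leaf_labels,
    read_manifest,
    strip_metadata,
    unroot,
    write_newick,
)

log = logging.getLogger("phyloconcord")

__all__ = ["AnalysisConfig", "ConcordanceReport", "ingest_tree_sets",
           "run_concordance"]

#: The ten completeness fractions of the standard matrix-composition spectrum.
STANDARD_FRACTIONS = (1.0, 0.95, 0.85, 0.75, 0.65, 0.55, 0.45, 0.35, 0.25, 0.15)


@dataclass
class AnalysisConfig:
    """Configuration of a full concordance run.

    Defaults are study-shaped (ten completeness fractions, ten length
    bins, 100 random subsamples of 365 loci); desk-scale runs override
    the sizes.  At least one matrix regime must be enabled.
    """

    mode: str = "synthetic"                    # "synthetic" | "ingest"
    manifest: str | None = None                # ingest mode: tree manifest TSV
    sim: SimConfig = field(default_factory=SimConfig)
    completeness_fractions: tuple[float, ...] = STANDARD_FRACTIONS
    n_length_bins: int = 10
    subsample_k: int = 365
    subsample_reps: int = 100
    n_mito_analyses: int = 10
    bootstrap_reps: int = 50
    binning_threshold: float = 50.0
    rf_cutoff: int = 26
    do_quartets: bool = True
    do_binning: bool = True
    embed_dims: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("synthetic", "ingest"):
            raise ValueError("mode must be 'synthetic' or 'ingest'")
        if self.mode == "synthetic":
            if not (self.completeness_fractions or self.n_length_bins
                    or self.subsample_reps):
                raise ValueError("at least one matrix regime must be enabled")
            if any(not 0 < f <= 1 for f in self.completeness_fractions):
                raise ValueError("completeness fractions must lie in (0, 1]")
        # the simulation inherits the run seed unless set explicitly
        if self.sim.seed == 0 and self.seed != 0:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            from .simulate import IntrogressionEvent
            sim["introgression"] = tuple(
                IntrogressionEvent(**e) for e in sim.get("introgression", ()))
            d["sim"] = SimConfig(**sim)
        for key in ("completeness_fractions",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ConcordanceReport:
    """Machine-readable summary of one run; every number is recomputable
    from the embedded configuration and seed."""

    config: dict
    tree_counts: dict
    census: dict
    consensus: dict
    group_summary: dict
    embedding: dict
    quartet_score: dict | None = None
    binning: dict | None = None
    truth: dict | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def ingest_tree_sets(manifest: str | Path) -> TreeSet:
    """Load a manifest of newick files and canonicalize every tree to its
    unrooted, metadata-stripped form."""
    raw = read_manifest(manifest)
    ts = TreeSet(taxon_namespace=raw.taxon_namespace)
    for tree, group, aid in raw:
        ts.add(unroot(strip_metadata(tree)), group, aid)
    log.info("ingested %d trees in groups %s", len(ts), ts.groups())
    return ts


def _concat_tree(loci: Sequence[LocusAlignment]) -> dendropy.Tree:
    """Concatenation estimator: supermatrix -> JC distances -> NJ."""
    sm = supermatrix.concatenate(loci)
    merged = LocusAlignment(locus_id="concat", sequences=sm.sequences)
    return estimation.estimate_tree(merged)


def _synthetic_tree_set(cfg: AnalysisConfig, data: SyntheticDataset
                        ) -> tuple[TreeSet, list[estimation.GeneTree]]:
    """All nuclear analyses (one tree per matrix instance) plus the
    mitochondrial analyses, and per-locus gene trees for summary methods."""
    ts = TreeSet()
    loci = data.loci
    n_taxa = cfg.sim.n_taxa

    for frac in cfg.completeness_fractions:
        subset = supermatrix.filter_by_completeness(loci, frac, n_taxa)
        if not subset:
            log.warning("completeness %.2f: no loci pass; skipped", frac)
            continue
        tree = _concat_tree(subset)
        ts.add(tree, "nuclear", f"comp{int(round(frac * 100))}")
    log.info("completeness regime: %d trees", len(ts))

    if cfg.n_length_bins and len(loci) >= cfg.n_length_bins:
        for i, group in enumerate(
                supermatrix.bin_by_length(loci, cfg.n_length_bins)):
            ts.add(_concat_tree(group), "nuclear", f"len{i:02d}")
    log.info("after length regime: %d trees", len(ts))

    if cfg.subsample_reps:
        k = min(cfg.subsample_k, len(loci))
        by_id = {l.locus_id: l for l in loci}
        picks = supermatrix.random_subsets(
            loci, k=k, reps=cfg.subsample_reps,
            seed=int(substream(cfg.seed, "other").integers(2 ** 31)))
        for i, ids in enumerate(picks):
            ts.add(_concat_tree([by_id[x] for x in ids]),
                   "nuclear", f"rand{i:03d}")
    log.info("after subsample regime: %d trees", len(ts))

    # per-locus gene trees (with bootstrap supports when binning is on)
    gene_trees: list[estimation.GeneTree] = []
    rng = substream(cfg.seed, "other")
    boot_seeds = rng.integers(2 ** 31, size=len(loci))
    for locus, bs in zip(loci, boot_seeds):
        if cfg.do_binning:
            gene_trees.append(estimation.bootstrap_gene_tree(
                locus, reps=cfg.bootstrap_reps, seed=int(bs)))
        else:
            gene_trees.append(estimation.GeneTree(
                tree=estimation.estimate_tree(locus), locus_id=locus.locus_id))
    summary_tree = estimation.astrid_like(gene_trees)
    ts.add(summary_tree, "nuclear", "astrid")

    # mitochondrial analyses: point estimate + bootstrap-replicate analyses
    mito_boot = estimation.bootstrap_gene_tree(
        data.mito_locus, reps=max(cfg.n_mito_analyses - 1, 1),
        seed=int(rng.integers(2 ** 31)))
    ts.add(mito_boot.tree, "mitochondrial", "mito_nj")
    reps_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    L = data.mito_locus.length
    for i in range(cfg.n_mito_analyses - 1):
        cols = reps_rng.integers(0, L, size=L)
        boot = LocusAlignment(
            locus_id="mito",
            sequences={t: "".join(data.mito_locus.sequences[t][c] for c in cols)
                       for t in data.mito_locus.sequences})
        ts.add(estimation.estimate_tree(boot), "mitochondrial", f"mito_bs{i:02d}")
    log.info("total analyses: %d", len(ts))
    return ts, gene_trees


def _canonical_ts(ts: TreeSet) -> TreeSet:
    out = TreeSet(taxon_namespace=ts.taxon_namespace)
    for tree, g, a in ts:
        out.add(unroot(strip_metadata(tree)), g, a)
    return out


def run_concordance(cfg: AnalysisConfig,
                    out_dir: str | Path | None = None) -> ConcordanceReport:
    """Execute all enabled stages and return the concordance report.

    With ``out_dir`` given, intermediate artifacts (trees, distance
    matrix, embedding, report JSON) are written as they are produced.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    gene_trees: list[estimation.GeneTree] = []
    data: SyntheticDataset | None = None
    if cfg.mode == "synthetic":
        log.info("stage simulate: %d taxa, %d loci", cfg.sim.n_taxa,
                 cfg.sim.n_loci)
        data = simulate_dataset(cfg.sim)
        ts, gene_trees = _synthetic_tree_set(cfg, data)
    else:
        if cfg.manifest is None:
            raise ValueError("ingest mode requires a manifest path")
        ts = ingest_tree_sets(cfg.manifest)
    ts = _canonical_ts(ts)
    if out is not None:
        from .trees_io import write_manifest
        write_manifest(ts, out / "trees")

    counts = {g: sum(1 for x in ts.group_labels if x == g)
              for g in ts.groups()}

    # census over trees spanning the full taxon set (nuclear group)
    nuclear = ts.subset("nuclear") if "nuclear" in ts.groups() else ts
    census = splits.topology_census(nuclear)
    census_dict = {
        "n_trees": len(nuclear),
        "n_unique": census.n_unique,
        "modal_count": census.modal_count,
        "modal_topology": census.modal_key,
        "n_excluded": len(census.excluded),
    }
    log.info("census: %d trees, %d unique topologies, modal %d",
             len(nuclear), census.n_unique, census.modal_count)

    consensus = {}
    for g in ts.groups():
        sub = ts.subset(g)
        if len(sub) >= 1:
            cons = splits.majority_consensus(sub)
            consensus[g] = cons.newick_with_frequencies()
    if out is not None:
        (out / "consensus.json").write_text(json.dumps(consensus, indent=2))

    dm = treespace.pairwise_rf_matrix(ts)
    groups = dict(zip(ts.analysis_ids, ts.group_labels))
    gs = treespace.group_summary(dm, groups, cutoff=cfg.rf_cutoff)
    emb = treespace.embed_cmds(dm, dims=cfg.embed_dims)
    emb_dict = {"stress": emb.stress,
                "negative_eigenvalue_mass": emb.negative_eigenvalue_mass}
    if out is not None:
        dm.to_tsv(out / "rf_matrix.tsv")
        emb.to_tsv(out / "embedding.tsv", groups=groups)

    quartet_dict = None
    if cfg.do_quartets and gene_trees:
        species = next(t for t, g, a in ts if a == "astrid")
        qs = quartets.normalized_quartet_score(
            species, [g.tree for g in gene_trees],
            gene_ids=[g.locus_id for g in gene_trees])
        quartet_dict = qs.to_dict()
        log.info("normalized quartet score: %.4f", qs.normalized)

    binning_dict = None
    if cfg.do_binning and gene_trees and data is not None:
        collapsed = [binning_mod.collapse_low_support(g, cfg.binning_threshold)
                     for g in gene_trees]
        graph = binning_mod.build_graph(collapsed)
        ba = binning_mod.balanced_bins(graph)
        supergenes = binning_mod.build_supergenes(ba, data.loci)
        sg_trees = {b: estimation.estimate_tree(
            LocusAlignment(locus_id=b, sequences=sm.sequences))
            for b, sm in supergenes.items()}
        weighted = binning_mod.weight_supergene_trees(sg_trees, ba, weighted=True)
        unweighted = binning_mod.weight_supergene_trees(sg_trees, ba, weighted=False)
        binned_species = {
            "weighted": estimation.astrid_like([t for _, t in weighted]),
            "unweighted": estimation.astrid_like([t for _, t in unweighted]),
        }
        binned_scores = {}
        for name, tr in binned_species.items():
            s = quartets.normalized_quartet_score(
                tr, [g.tree for g in gene_trees])
            binned_scores[name] = s.normalized
        binning_dict = {
            "n_loci": ba.n_loci,
            "n_bins": len(ba.bins),
            "size_histogram": {str(k): v for k, v in ba.size_histogram().items()},
            "incompatible_pairs": graph.number_of_edges(),
            "weighted_multiset_size": len(weighted),
            "unweighted_multiset_size": len(unweighted),
            "binned_quartet_scores": binned_scores,
        }
        log.info("binning: %d loci -> %d bins (%d incompatible pairs)",
                 ba.n_loci, len(ba.bins), graph.number_of_edges())

    truth = None
    if data is not None:
        truth = {
            "species_topology": canonical_newick(data.species_tree),
            "mito_topology": canonical_newick(data.mito_tree),
            "species_recovered_by_consensus": _same_topology(
                consensus.get("nuclear", ""), data.species_tree),
            "species_recovered_by_astrid": _same_topology(
                write_newick(next(t for t, g, a in ts if a == "astrid")),
                data.species_tree),
        }

    report = ConcordanceReport(
        config=cfg.to_dict(),
        tree_counts=counts,
        census=census_dict,
        consensus=consensus,
        group_summary=gs.to_dict(),
        embedding=emb_dict,
        quartet_score=quartet_dict,
        binning=binning_dict,
        truth=truth,
    )
    if out is not None:
        report.to_json(out / "report.json")
    return report


def _same_topology(newick: str, reference: dendropy.Tree) -> bool:
    from .trees_io import parse_newick

    try:
        tree = parse_newick(newick)
        return splits.rf_distance(tree, reference) == 0
    except ValueError:
        return False
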