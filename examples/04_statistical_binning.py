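"""Statistical binning: pool weakly supported gene trees into supergenes.

Short loci carry few informative sites, so their bootstrap supports are
weak and their trees noisy.  Binning keeps only well-supported splits
(>50% bootstrap), groups loci whose supported splits are pairwise
compatible into balanced bins, concatenates each bin into a supergene,
and optionally replicates each supergene tree by its bin size.
"""

import numpy as np

from phyloconcord import balanced_bins, bootstrap_gene_tree, build_graph, \
    build_supergenes, collapse_low_support, weight_supergene_trees
from phyloconcord.estimation import estimate_tree
from phyloconcord.simulate import (simulate_msc_gene_tree, simulate_sequences,
                                   simulate_yule_tree)
from phyloconcord.supermatrix import LocusAlignment

sp = simulate_yule_tree(8, birth_rate=1.0, rng=19)
rng = np.random.default_rng(19)

loci, gene_trees = [], []
for i in range(24):
    gt = simulate_msc_gene_tree(sp, rng)
    locus = simulate_sequences(gt, 300, rate_scale=0.01, rng=rng,
                               locus_id=f"L{i:02d}")
    loci.append(locus)
    gene_trees.append(bootstrap_gene_tree(locus, reps=50, seed=1000 + i))

collapsed = [collapse_low_support(g, threshold=50) for g in gene_trees]
graph = build_graph(collapsed)
print(f"{len(loci)} loci; {graph.number_of_edges()} incompatible pairs "
      "among their well-supported splits")

assignment = balanced_bins(graph)
print(f"binned into {len(assignment.bins)} supergene bins, "
      f"size histogram {assignment.size_histogram()}")

supergenes = build_supergenes(assignment, loci)
trees = {b: estimate_tree(LocusAlignment(locus_id=b, sequences=sm.sequences))
         for b, sm in supergenes.items()}
weighted = weight_supergene_trees(trees, assignment, weighted=True)
print(f"weighted supergene-tree multiset: {len(weighted)} trees "
      f"(= {len(loci)} input loci, each bin's tree repeated by its size)")
# Each supergene concatenates compatible loci, so its tree rests on more
# informative sites than any single locus - the point of binning.
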