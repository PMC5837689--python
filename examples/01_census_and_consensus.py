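"""Topology census and majority-rule consensus of a small tree set.

Simulates 60 gene trees under the multispecies coalescent on a rapid
8-taxon radiation, then asks: how many distinct topologies did the
analyses produce, which is the most common, and which clades survive in
the >50% consensus?
"""

import numpy as np

from phyloconcord import TreeSet, majority_consensus, topology_census
from phyloconcord.simulate import simulate_msc_gene_tree, simulate_yule_tree

sp = simulate_yule_tree(8, birth_rate=1.5, rng=42)
rng = np.random.default_rng(42)

ts = TreeSet()
for i in range(60):
    ts.add(simulate_msc_gene_tree(sp, rng), "nuclear", f"locus{i:02d}")

census = topology_census(ts)
print(f"{len(ts)} gene trees contain {census.n_unique} distinct topologies")
print(f"the most common topology occurs {census.modal_count} times:")
print(f"  {census.modal_key}")
# Short internal branches mean incomplete lineage sorting: many gene trees
# disagree with each other even though one species history generated them.

cons = majority_consensus(ts)
print("\nmajority-rule consensus (internal labels = % of trees with that clade):")
print(f"  {cons.newick_with_frequencies()}")
for side, freq in sorted(cons.frequencies.items(), key=lambda kv: -kv[1]):
    print(f"  {{{','.join(sorted(side))}}}  {100 * freq:.0f}%")
# Clades above 50% are the parts of the species tree that survive the
# gene-tree discordance; everything else collapses into polytomies.
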