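# Methods

This note records the models, conventions and numerical choices behind
`phyloconcord`, in the order data flows through the package.

## Canonical tree forms

All cross-tree comparisons operate on unrooted, metadata-stripped trees.
Rooted inputs (e.g. Bayesian consensus trees) are derooted by suppressing a
degree-2 root; branch lengths and supports are dropped because the trees
being compared come from methods whose branch lengths are not commensurable
(substitutions per site, coalescent units, or absent). A bipartition is
stored as the side of the split *not* containing the reference taxon (the
lexicographically smallest label), so a plain set of labels identifies it.
The canonical newick of a topology is produced by rebuilding the tree from
its canonical split set and writing children sorted by smallest descendant
label; two trees produce the same string exactly when their unrooted
topologies are identical, which makes the string a safe census key.

Newick dialect: internal node labels that parse as numbers in [0, 100] are
read as support values (the RAxML/consensus convention); other labels are
kept as names. Negative branch lengths are rejected at parse time; zero
lengths are allowed and ignored by topology-only analyses.

## Robinson–Foulds machinery

`RF(T1, T2)` is the size of the symmetric difference of the two nontrivial
split sets, computed after projecting both trees onto their shared taxa
(at least four required). Both unmatched splits are counted and no
normalization is applied, so binary trees on n leaves have even distances
in [0, 2(n−3)]. Polytomous trees are handled by the same rule — their
split sets are simply smaller.

Majority-rule consensus retains exactly the splits whose frequency is
*strictly* greater than the threshold (default 0.5); at that threshold the
retained family is automatically pairwise compatible and hence laminar, so
the consensus tree is rebuilt from it by containment. For thresholds below
0.5 retained splits are admitted greedily in frequency order with explicit
compatibility checks. The topology census groups trees into `RF = 0`
classes on the full taxon universe; trees missing taxa are excluded and
reported rather than silently compared on partial overlap.

## Tree space

Classical (Torgerson) metric MDS embeds the RF matrix: double-center the
squared distances, eigendecompose, keep the top-d non-negative components.
This replaces nonlinear stochastic projections used elsewhere for the same
figure: it is deterministic, has no tuning parameters, and preserves the
only feature the analysis relies on — separation between marker-type
clusters. RF matrices are generally non-Euclidean; negative eigenvalues
are truncated at zero and their total magnitude is reported next to a
Kruskal stress-1 value, so a reader can judge how literally to take the
picture. A fixed sign convention (largest-magnitude coordinate per axis
positive) makes embeddings reproducible bit-for-bit. Hexagonal-bin
occupancy uses matplotlib's tessellation; counts are checked to conserve
the number of points.

Group statistics (within-group means, pooled between-group mean, minimum
between-group distance, counts of pairs strictly above a cutoff) are the
quantities that carry the discordance argument; groups of size one report
an absent within-mean rather than zero.

## Quartets

The induced topology of four leaves is read off topological (edge-count)
leaf-to-leaf distances via the four-point condition: pairing `ab|cd` holds
iff `d(a,b) + d(c,d)` is strictly smallest; all three sums equal means the
quartet is unresolved. The normalized quartet score counts, over every
gene tree and every 4-subset of its leaves shared with the species tree,
the resolved induced gene quartets agreeing with the species tree, divided
by all resolved induced gene quartets. Unresolved gene quartets are
excluded from both numerator and denominator, so multifurcating gene trees
consistent with the species tree can still score 1.0; quartets the species
tree leaves unresolved stay in the denominator but cannot agree.
Enumeration is exhaustive (C(n,4) is ~66k at n = 37, vectorized per gene
tree); no quartet subsampling is implemented.

## Matrix regimes and site statistics

Completeness filtering keeps loci present in at least `floor(f · N)` taxa —
the only rule consistent with the standard ten (percent, minimum-taxon)
pairs at N = 37 (100%→37 ... 15%→5). The ten groups are nested, not
exclusive. Length binning sorts loci by (length, id) and cuts the order
into contiguous groups whose sizes differ by at most one, larger groups
first. Random subsampling draws k loci uniformly without replacement
within each replicate; replicates are independent, so collisions between
replicates are possible and expected.

A site is variable when at least two distinct unambiguous nucleotides
occur, and parsimony-informative when at least two states each occur in at
least two sequences; gaps, N and ambiguity codes count as missing.
Concatenation pads absent taxa with `?`, records 1-based inclusive
character sets per locus, and writes relaxed PHYLIP, NEXUS with a charset
block, or RAxML-style partition files.

## Tree estimation

The in-package estimator is deliberately simple and transparent:
Jukes–Cantor distances `d = −(3/4) ln(1 − 4p/3)` over pairwise shared
unambiguous sites (saturated pairs capped at 5.0 substitutions/site), then
Saitou–Nei neighbor joining with deterministic tie-breaking (smallest
cluster-name pair, clusters named by their smallest leaf) and negative
branch estimates clamped to zero. Bootstrap supports are the percentage of
site-resampled replicates containing each split of the point-estimate
tree. The summary species-tree method averages topological internode
distances over the gene trees containing each leaf pair and runs neighbor
joining on the result; the pair-co-occurrence graph must be connected, and
a pair never observed together has its distance imputed additively along
the shortest path of observed mean distances (a documented convenience —
with any realistic missingness profile every pair is observed directly).
Likelihood and Bayesian engines are intentionally out of scope; their
newick outputs are ingested interchangeably anywhere a gene tree is
consumed.

## Statistical binning

Gene trees are collapsed to the splits with bootstrap support strictly
above the threshold (default 50; an edge at exactly 50 is contracted).
Two collapsed trees are incompatible when, projected onto their shared
taxa (at least four), some retained split of one conflicts with some
retained split of the other. Binning colors the incompatibility graph
greedily — vertices in descending-degree order (ties by id), each assigned
to the currently smallest bin with no conflicting member under a size cap
of `ceil(m/b)` — and in automatic mode grows the bin count from
`ceil(m/target)` until the heuristic succeeds. Pairwise compatibility is
necessary but not sufficient for joint compatibility of a bin; that is the
published binning heuristic, and the pairwise condition is re-verified on
every assignment. When the conflict structure forces imbalance the
balance constraint is relaxed minimally and a warning recorded. Weighted
mode replicates each supergene tree by its bin size, so the multiset
cardinality equals the input locus count.

## Synthetic data

Gene trees are drawn directly under the multispecies coalescent: the
species tree (coalescent-unit branch lengths, leaves at time zero —
ultrametricity is required and validated) is processed in epoch slices
between divergence times; within a branch holding k lineages, coalescences
occur at rate C(k,2)/`ne_scale`. The mitochondrial locus is a single
non-recombining gene tree with `ne_scale = 0.25` (haploid, uniparental
inheritance) and optional introgression events: backwards in time at the
event time, each lineage in the donor branch moves to the recipient branch
with the event's probability, both branches having to span that time. With
probability 1 and a small `ne_scale` the donor taxon becomes sister to the
recipient clade — the hybrid-capture scenario. Loci are independent (free
recombination between, none within), the standard assumption behind
summary methods.

Sequences evolve by Jukes–Cantor along gene-tree branches (optionally with
gamma-distributed site rates); the expected substitutions per site on an
edge are its coalescent length times a rate scale. The default rate scale
0.00113 was fixed once by bisection so that ~378 bp loci on the default
37-taxon Yule(1) species tree average ~2.6% parsimony-informative sites,
the UCE-like regime; because tree height varies between Yule draws, the
realized fraction varies by a factor of ~2 around that value across seeds.
Missingness drops taxa independently per locus; loci left with fewer than
three taxa are removed and logged.

The generator defaults describe a study-shaped instance: 37 taxa, 3648
loci of mean length 378 bp, a Yule(1) radiation (short internal branches,
hence substantial incomplete lineage sorting), quarter-size mitochondrial
locus of 15,520 bp evolving ~10× faster. What the generator does *not*
emulate: within-locus recombination, demographic change through time,
alignment/assembly error, or base-composition and rate heterogeneity
between loci. Tests passing on this generator therefore demonstrate the
correctness of the analysis machinery under the model's assumptions, not
robustness to real-data violations of them.

All randomness flows from one master seed through named substreams
(species tree, gene trees, mito, sequences, masks), so any stage can be
replayed independently and every run is bit-reproducible.

## Pipeline and problem sizes

A run enumerates one tree per (matrix instance × estimator): completeness
fractions, length bins and random subsamples each yield a concatenation
(JC+NJ) tree, one summary-method tree is added, and the mitochondrial
group holds the point estimate plus bootstrap-replicate analyses. The
report embeds the resolved configuration; identical configurations yield
identical reports.

The test suite and the acceptance script run desk-scale instances chosen
to keep the full suite under a minute of simulation time while leaving the
statistical checks well-powered: 3-taxon concordance uses 10,000 gene
trees per branch length (Monte-Carlo s.e. ≈ 0.005), species-tree recovery
uses 20 replicates of 200 gene trees on 8 taxa with internal branches ≥ 2
coalescent units, and the end-to-end discordance demonstration uses 10
taxa and 40 loci. The study-scale numbers (37 taxa, 3648 loci, 100
subsamples of 365) remain the configuration defaults.

## Known limitations

* Pairwise-compatibility binning can admit jointly incompatible triples
  into one bin (inherent to the heuristic); only the pairwise invariant is
  guaranteed.
* The greedy coloring gives no optimality guarantee on the bin count;
  automatic mode finds the smallest count the heuristic can satisfy, not
  the chromatic number.
* Classical MDS of non-Euclidean RF matrices is a controlled distortion;
  interpret coordinates through the reported stress and negative-eigenvalue
  mass.
* The JC+NJ estimator understates support and accuracy relative to
  likelihood methods on real data; it exists to make the pipeline
  self-contained and its statistical behavior predictable.
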