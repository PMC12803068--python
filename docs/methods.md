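# Methods

## Prefix-suffix k-mer screen

Each query gene (coding nucleotide sequence, length *L*) contributes two
exact anchors: the prefix k-mer at [*g*, *g*+*k*) and the suffix k-mer at
[*L*−*g*−*k*, *L*−*g*), 0-based half-open. Defaults *k* = 27,
*g* = 4; the gap keeps the anchors clear of start/stop codons and, because
4 is not a multiple of 3, shifts them out of frame relative to the CDS.
Extraction requires *L* ≥ 2(*k*+*g*) and pure-ACGT windows; violations are
rejected per gene with distinct error types.

Matching is exact, both strands, exhaustive, and independent of batching
order; positions containing ambiguous bases never match. The in-memory
backend is a straightforward per-contig string scan — the contract (every
occurrence reported exactly once) is what matters, and an FM-index backend
could be dropped in behind the same interface for larger collections.

A locus measurement exists for a (gene, genome) pair only when a prefix and
a suffix match co-occur on one contig in the same orientation with positive
span. Span endpoints are prefix-window start to suffix-window end in gene
orientation (forward: `suffix_start + k − prefix_start`), so an intact gene
measures difference Δ = 0 exactly. When multiple valid pairs exist the pair
minimizing |Δ| is kept (ties: smallest prefix start) — deliberately biased
toward the intact interpretation, hence conservative for structural-variant
calls. Prefix/suffix matches in opposite orientations yield a `discordant`
status (inversions are outside the model); matches split across contigs
yield `missing`. Both the reverse-complement handling and the pair choice
are user-overridable (`allow_reverse`, CLI `--no-reverse`).

## Difference clustering

Per gene, each genome contributes one point (value multiplicities are
expanded), so `min_samples` counts genomes. The 1D DBSCAN is a sort-and-scan:
a point is core when ≥ `min_samples` points (itself included) lie within
ε; consecutive cores ≤ ε apart chain into one cluster; border points attach
to a core cluster with ties resolved to the left (lower-valued) cluster,
deterministically. Defaults ε = 800 bp, `min_samples` = 25. Noise points are
excluded from cluster statistics. Cluster ids are ordered by ascending
|mean| so cluster 0 is always the intact-most cluster.

Cascade calls: stage 1 (multimodal) needs ≥ 2 clusters; stage 2 needs a
cluster mean within the zero tolerance *and* a cluster mean > 800 bp. The
zero tolerance defaults to ε itself — the only length scale already in the
model — and is configurable, as is the positive-peak threshold.

## Ancestral state

Genomes are sampled evenly across clusters (default quota 300). Clusters
smaller than their even share contribute all members; the shortfall is
redistributed proportionally to remaining cluster capacity
(largest-remainder rounding). Sampling is deterministic given the seed.

For each sampled genome the locus (anchor to anchor, inclusive) is
extracted — reverse-complemented into gene orientation when needed — and the
same span is N-masked in the genome so that tree distances are not driven
by the very signal being classified. Distances between masked genomes are
Mash distances d = −ln(2j/(1+j))/k from bottom-s min-hash sketches
(s = 1000, k = 21, canonical k-mers via a splitmix64 finalizer; j estimated
from the s smallest hashes of the union). The pipeline computes each
genome's hash array once and derives per-gene masked sketches by excluding
k-mers overlapping the masked window, which is exactly equivalent to
sketching the N-masked sequence.

The tree is neighbor joining (scikit-bio; negative branch lengths clamped
to zero), rooted on whichever of the two candidate outgroups has the larger
mean distance to all other leaves. Outgroup leaves carry no cluster state
and are pruned before a bottom-up multi-state Fitch pass over the ingroup;
the parsimony score counts union events. Classification at the ingroup
MRCA: a single positive-cluster state with at least one zero-cluster
descendant → `split_ancestor` (deletion-born fusion, stage 3); exactly the
zero cluster → `intact_ancestor` (insertion-disrupted gene); any multi-state
Fitch set → `ambiguous`, excluded from fusion calls, since parsimony does
not justify either call.

## Selection analysis

Locus sequences from a cluster are deduplicated with genome-count weights.
Each unique sequence is codon-aligned to the canonical CDS by
translate-align-backmap (global protein alignment, BLOSUM62, gap open −11 /
extend −1; bacterial translation table 11), which preserves the reference
frame by construction. Codons overlapping gaps or ambiguous bases on either
side are skipped and counted. Differing codons are classified by path
averaging: all orderings of single-site steps are enumerated, paths through
a stop are excluded, and syn/nonsyn counts are averaged; a change whose end
state is a stop (or all of whose paths pass a stop) is a stop gain, tallied
separately. Weighted dN = Σ wᵢ·nonsynᵢ and dS = Σ wᵢ·synᵢ; the ratio is raw
dN/dS without per-site normalization (a per-site correction would be a
separate estimator, not a fix to this one) and is undefined when dS = 0.

Surrogate pre-deletion genes: local hits of the query against a split-state
locus are accepted greedily by score with ≤ 20% query overlap, projected
into the flanking context (forward or reverse-complement occurrence), and
intersected with exhaustively predicted ORFs (both strands, starts
ATG/GTG/TTG, ≥ 90 bp, first upstream start per stop); each segment takes
the maximal-overlap ORF and segments are stitched in query order with `NNN`
joints, which codon counting then skips.

## Local hit finding

The internal aligner used for MGE coverage and surrogate tiling is a seeded
gapless local-hit finder: exact 13-mers shared between query and subject are
grouped by diagonal and extended without gaps under an X-drop rule, scored
match +2 / mismatch −3. Full Smith–Waterman over multi-kilobase pairs for
*all* hits (not just the best) is quadratic per pair and unnecessary for
the gapless homology this screen consumes; hits found this way carry the
same interval/score contract, and externally computed 12-column tabular
hits can be imported instead. Coverage is the union length of query hit
intervals over query length; split-vs-intact groups are compared with a
two-sided Mann–Whitney U (exact null for both groups ≤ 20, tie-corrected
normal approximation otherwise).

The fragmented-alignment filter flags a gene in a target genome when merged
query coverage ≥ 80%, the best single hit spans ≤ 80% of the gene, and ≥ 2
hits are ≥ 1 kb apart in genome coordinates.

## Wright-Fisher simulator

Haploid population of fixed size N (default 10⁶); states 0 (no fusion,
fitness 1), 1 (non-functional fusion, fitness 1−c), 2 (functionalized,
absorbing: the run ends at its first appearance). Each generation:
fitness-proportionate multinomial resampling, then one trinomial split of
state 1 into functionalized (p_func), purged to state 0 (p_purge), and
unchanged — the two transitions are mutually exclusive within a generation,
a choice that matters only at rates where their collision probability is
non-negligible (far above the sweep range). p_func is the
functionalization rate often written μ. Initial state-1 count is
round(N·p_init), minimum 1 when p_init > 0, so p_init = 1/N seeds a lone
founder. Termination: first state-2 individual, state-1 extinction, or
t_max (default 10⁵).

When the population is homogeneous state-1, resampling is the identity and
event-free generations change nothing, so the waiting time to the first
event is drawn geometrically and the event counts conditioned on ≥ 1 event
— distributionally exact, and necessary for low-rate grid cells. Sweeps use
a root seed that spawns one substream per (cell, replicate); runs are
bit-reproducible and order-independent. The default grid is 20 log-spaced
p_func values in [10⁻¹⁶, 10⁻²] × 20 p_purge values in [10⁻⁸, 10⁻²], 100
replicates per cell, root seed 42.

A useful closed form for calibration: a lone founder with cost c accrues
≈ 1/c person-generations before loss, so its functionalization probability
is ≈ 1 − exp(−p_func/c). This is ≈ 0 in the mutation-limited regime but
reaches ~0.18 at p_func = 10⁻², c = 0.05 — the hitchhiking contrast (lone
founder ≈ 0 versus post-sweep p_init → 1 giving ≈ 1) is therefore asserted
in the mutation-limited cells and bounded by the closed form elsewhere.

## Synthetic data

The generator emulates a clonal bacterial collection: a random ancestor
(GC ≈ 0.5, single contig), a birth-death tree (depth normalized to 1),
Jukes–Cantor point substitutions per branch (rate default 0.005
substitutions/site per unit branch length — within-species-scale
divergence), and planted events. `deletion_fusion` places the *split*
configuration in the ancestor and deletes the intervening segment in a
derived clade (the query gene is the fusion, so the clade measures Δ = 0
and everyone else +size); `cargo_insertion` inserts a fixed pseudo-random
MGE-fixture cargo inside an intact gene in the clade. Indels enter only
through events and anchors sit in substitution-protected zones, so the
truth table of expected Δ per genome is exact at any substitution rate.
Clades are chosen nearest to the requested size among strictly nested
clades — children of the root are excluded because a derived event on a
basal lineage leaves the ingroup MRCA genuinely ambiguous under parsimony,
which is not the scenario being planted. Two outgroup genomes are evolved
from the ancestral state with ~3× and ~6× extra substitution load and
always carry the ancestral configuration.

The MGE fixture is a synthetic stand-in for a curated MGE/prophage
database: 20 fixed pseudo-random cargo sequences of 1–10 kb regenerated
deterministically from an internal seed. What passing tests show is that
the cascade separates planted deletion-born fusions from cargo insertions
under point-mutation divergence with exact anchors; they do not exercise
assembly fragmentation, anchor loss by mutation, recombination, repeat
content, or compositional structure of real genomes.

## Problem sizes and numerics

The end-to-end suites use 120 genomes × 200 kb with 5 kb deletions and
3 kb insertions (8 loci per group for the coverage contrast), chosen to
exercise every cascade stage at desk scale. DBSCAN border ties go left;
cluster relabeling is by |mean|; NJ leaf order is fixed by sorted ids, and
all sampling and simulation is seeded, so every pipeline stage is
deterministic for a fixed input and seed. Mann–Whitney p-values switch from
exact to asymptotic above group size 20. Degenerate inputs (empty
difference distributions, all-identical sketches, unlabeled ingroup leaves,
dS = 0) raise typed errors or return explicitly undefined values rather
than guessing.

## Known limitations

Exact anchor matching does not model sequencing error or mutations in the
anchor windows (real screens lose such genomes as `missing`). The NJ/Mash
tree is a sketch-distance approximation without support values; ambiguous
Fitch sets are dropped rather than resolved by likelihood. dN/dS is a raw
count ratio, suitable for the coarse contrast it serves, not for per-site
inference. The simulator omits diploidy, recombination, and explicit
sequence evolution by design.
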