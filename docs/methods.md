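# Methods

This note documents the models, statistics and numerical choices behind
`paleokaryo`, in the order the pipeline applies them.

## Alignment pooling: AL, CIP, CALP

A pairwise sequence search reports one or more HSPs (high-scoring pairs)
per gene pair.  The pair-level summary is

- **AL** (aligned length) = Σ HSP lengths after overlap resolution,
- **CIP** (cumulative identity percentage) = 100 · Σ identities / AL,
- **CALP** (cumulative aligned-length percentage) = 100 · AL / query
  length, capped at 100.

HSPs overlapping on the query are resolved before summation: HSPs are
consumed in decreasing identity-fraction order and each contributes only
the uncovered part of its query span, with aligned length and identities
scaled by the surviving fraction.  Disjoint HSPs therefore contribute
exactly their full lengths and identities (the plain Σ definitions), and a
fully shadowed HSP contributes nothing — this keeps CALP a true
percentage, which the unmerged sum does not guarantee.

Thresholds are divergence-dependent: both CIP and CALP must reach 70 % for
genome pairs whose common ancestor is younger than 50 Myr ("close") and
50 % otherwise ("distant").  Comparisons are inclusive (≥): the published
thresholds are stated without strictness, and the inclusive reading is the
conservative one for reproducing pass counts.  The divergence class is a
configuration input per genome pair (divergence times come from the
literature, not from the data), and the table also carries (g, g) entries
classifying the age of within-genome duplicates.

Among passing candidates, one call is retained per (query gene, target
genome): the pair maximising CIP, then CALP, then the lexicographically
smallest subject id.  Reciprocal-best-hit filtering is available as a
switch (default off); plain best-hit is the default because the selection
rule is "highest cumulative identity over the longest cumulative length",
not reciprocity.

## Synteny blocks and their validation

Anchors (homolog pairs with rank coordinates on their two chromosomes) are
chained into candidate blocks: strictly monotone runs on both sides, a
single direction per block (direct or inverted), consecutive anchors at
most `max_gap = 20` gene ranks apart on either side.  Chains are extracted
greedily longest-first; among equal-length chains the lexicographically
smallest anchor-index sequence wins (direct direction preferred), making
the partition deterministic and testable against an exhaustive oracle.
Each anchor belongs to at most one block per chromosome pair, preventing
double counting in coverage summaries.  The default gap of 20 genes
matches the cluster-length scale of the validation test.

Validation follows the CloseUp-style parameter triple (density ratio 2,
cluster length 20, match number 5):

- **match number**: the block needs ≥ 5 anchors;
- **density ratio**: the block's local density (match number / cluster
  length, where cluster length is the gene-rank span, maximum of the two
  sides) must be ≥ 2× the background density;
- **significance**: a Monte-Carlo permutation p < 0.05.

The background and the permutation null are defined by *genome-wide
scattering*: for a block between genome A and partner chromosome c_b, the
background is (number of anchors linking any part of A to c_b) / (genes in
A), and each permutation drops those anchors onto distinct uniform ranks
across all of A, scoring a success when any window of cluster-length
consecutive ranks collects at least the observed match number.  This is
the null in which gene order carries no information while chromosome
content is preserved.  A within-chromosome-only null would be vacuous for
blocks spanning their whole chromosome (the observed configuration would
be its own null), and a background of all anchors of the genome pair would
reject fully collinear genomes wholesale — both degenerate readings are
avoided deliberately.  The p-value uses the (hits + 1)/(n + 1) estimator,
which is exactly valid (sub-uniform under the null).  In the sparse limit
the Monte-Carlo agrees with the closed form
p ≈ 1 − (1 − P[Bin(k, L/N) ≥ m])^⌊N/L⌋ to within ~0.002; in dense regimes
the closed form's independence approximation itself drifts by a few
percent, so the closed form serves as a cross-check, not the
implementation.

Paralogous (within-genome) blocks are detected with the same machinery.
A duplicated block is dated **ancestral** (pre-speciation) when both of
its copies lie at positions orthologous — overlapping ortholog-block spans
by at least one anchor — to the two copies of a duplicated block in some
other genome, and **lineage-specific** (post-speciation) otherwise.

## Contiguous ancestral regions

Orthologous blocks touching a chosen reference genome are projected onto
it and the reference chromosomes are cut at every block boundary, yielding
atomic conserved segments (the common refinement).  Each genome then
orders these segments along its chromosomes (blocks sorted by position,
segments reversed inside inverted blocks).  Adjacencies observed in ≥ 2
genomes — the minimal multi-genome reading of "found at orthologous
positions between modern species" — become edges of the ancestral
adjacency graph, weighted by supporting-genome count.

The graph is resolved into simple paths (the CARs) deterministically:
branch nodes repeatedly lose their lowest-weight incident edge (ties: the
removal minimising the variance of component sizes, then lexicographic);
cycles are opened at their lowest-weight edge.  Every segment ends in
exactly one CAR.  Each CAR is reported as one reconstructed
protochromosome; with few rearrangements and no shared breakpoints this
count equals the ancestor's chromosome number, which the simulation tests
exercise.  When a shared WGD precedes speciation, the reconstruction
yields the post-WGD intermediate (duplicate copies are separate CARs);
merging copies into the pre-WGD karyotype is the role of the
ancestral-duplication calls, not of CAR assembly.

Protogene content comes from gene families — connected components of the
homolog graph restricted to genes inside validated blocks — and the
conserved gene-space size sums the minimal CDS length per family (the
"minimal physical size" reading of ancestral gene space).

## The event calculus

Chromosomes are signed sequences of (colour, copy, orientation) segments,
where colour identifies the founder protochromosome segment.  Events:

| event | n | notes |
|---|---|---|
| WGD | ×2 | copies get fresh copy indices |
| Cfis | +1 | split between segments |
| Cfus (TCF) | −1 | end-to-end concatenation |
| Cfus (CCF) | −1 | insertion into the body of the partner |
| inversion | 0 | span reversed, orientations flipped |
| translocation | 0 | reciprocal tail exchange |
| deletion | 0 | segment loss, never below one segment |

The count law n = n₀ + #Cfis − #Cfus (with WGD doubling the running value)
holds for every sequence, and `count_trace` computes it without segment
tracking.  Fusion products are classified from parent membership runs:
A⁺B⁺ is telomeric, A⁺B⁺A⁺ is centromeric/nested (1 CCF ≡ 1 Cfis +
2 Cfus), anything else "complex".  Non-reciprocal translocations are
expressed as fission + fusion so the count law stays exact; deletions are
count-neutral segment-loss events.

The shipped scenario library covers 19 plant and animal lineages from
their founder karyotypes.  Three of the curated vertebrate scripts
(chicken, human, chimpanzee) do not satisfy the count law against the
stated modern chromosome numbers; the scripts keep the curated event
counts and carry the stated number separately rather than silently
correcting either side.  The "three interchromosomal translocations and
fusions" between the two ancient vertebrate WGD rounds are modelled as
three chromosome-gaining events, consistent with the 10+10+3 = 23
arithmetic.

Minimal scenarios are found by A* over canonicalised karyotypes
(chromosomes normalised to their lexicographically smaller reading
direction and sorted, so chromosome order and whole-chromosome flips are
quotiented out).  The admissible lower bound is the maximum of the
chromosome-count gap and the adjacency-multiset differences halved (no
event creates more than two target adjacencies or destroys more than two
non-target ones), so returned scenarios are provably minimal within the
budget.  The heuristic mode cuts every chromosome to single segments,
fixes orientations, and reassembles the target end-to-end — always valid,
an upper bound by construction.

## Landscape profiles

Chromosomes are tiled with 500-kb windows (0-based half-open internally,
reported 1-based inclusive; last window truncated).  Gene counts assign
each gene to the window holding its start, so window counts partition the
chromosome total exactly (an overlap-counting mode is available).  TE
coverage is the per-class union of intervals intersected with the window
— nested or overlapping same-class copies count once; different classes
tally independently.

## The simulator

The generator emulates the study conditions end-to-end.  An ancestor of
`n_protochromosomes` (plant profile 5, animal 10) carries `n_protogenes`
(plant 12,000, animal 16,000; `scale_profile` shrinks counts for
desk-scale runs — the shipped tests use a 0.1 factor, 1,200 protogenes)
partitioned into 8 atomic segments per protochromosome, so fission and
fusion breakpoints fall between segments.  Scripted events (shared, then
per-lineage) are applied through the event calculus itself, which makes
the ground-truth scenario replayable by construction.  Descendant gene
orders follow the segment order; coordinates use exponential intergenic
gaps (mean 3.5 kb plant, 8 kb animal) and Gaussian CDS lengths (1200 ±
300 bp, floor 300).

Post-WGD diploidization removes, per family and per surplus copy, one
uniformly chosen copy with probability `gene_loss_rate` (default 0.4),
never below one copy — uniform loss is the null model in the absence of a
stated bias.  Sequence identity per homolog pair is truncated-Gaussian
with class means 85 % (close) and 60 % (distant), straddling the 70/50
thresholds; pairs separated by a shared WGD draw from the distant model
regardless of the genome pair's class, because they split at the WGD.
Alignments are fragmented into 1 + Poisson HSPs covering ≥ 88 % of the
query, and decoy alignments between unrelated genes (10 % of true-pair
count, ~40 % identity) give the CIP/CALP filter something to reject.  The
`noise_free` preset (no loss, no decoys, 95 ± 1 % identity, single-HSP
alignments) defines the idealised fixtures on which recovery is expected
to be exact.

TE annotations are placed window by window to hit coverage targets: the
plant model concentrates class I LTR elements in periodic hot-spot windows
(58 % coverage, with nested contained copies) over a 14.25 % background so
the genome-wide mean is ~23 % and the max/mean contrast exceeds 2; the
animal model is homogeneous (class I non-LTR 33 %, LTR 9 %, class II 3 %,
±15 % jitter, max/mean < 1.5).  Realized per-window coverage is written to
the ground-truth ledger.

What the simulator does **not** emulate: nucleotide sequences, tandem
duplications, segmental (non-whole-genome) duplications, gene movement
outside rearrangement events, TE insertion into genes, biased
fractionation after WGD, and lineage-specific rate variation.  Passing
tests therefore demonstrate correctness of the analytical chain under the
stated generative model, not robustness to every artefact of real
annotations.

## Problem sizes and numerical choices

Simulation-based tests run at 1,200 protogenes, 3 genomes, ~7,200 genes
total; Monte-Carlo validation uses 300 shuffles inside pipeline tests and
10,000 where the p-value itself is under test; the parsimony oracle runs
50 instances of ≤ 6 chromosomes and ≤ 4 events.  Percent coverage is
rounded to integers in the triplet summaries (the reporting convention);
identity counts reconstructed from percent-identity columns use
round-half-away-from-zero, reversible to one decimal for HSPs up to 5 kb.
All stochastic components take explicit seeds; the pipeline derives
per-stage seeds from one master seed via SHA-256, and reruns are
bit-identical.

## Known limitations

- CAR orientation is reported relative to the reference genome; outgroup
  orientation is not attempted.
- The exact parsimony search is exponential in the worst case; the budget
  caps the explored depth, and larger instances should use the heuristic
  mode.
- Duplication dating requires the duplicated region to survive in at
  least two genomes; heavily fractionated duplicates fall back to
  lineage-specific.
- The closed-form scan probability is an independence approximation,
  accurate only in the sparse regime; the Monte-Carlo value is
  authoritative.
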