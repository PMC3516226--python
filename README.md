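# paleokaryo

Comparative paleogenomics of plant and animal genomes: a pipeline for
reconstructing the history of modern karyotypes from pairwise gene
alignments, for researchers studying whole-genome duplication (WGD),
chromosome rearrangement and repeat dynamics across kingdoms.

Plant genomes descend from small founder karyotypes (an n = 5 ancestral
grass karyotype, a hexaploid n = 21 eudicot intermediate) through repeated
polyploidizations followed by diploidization — massive duplicate gene loss
and chromosome fusions, characteristically centromeric/nested (CCF) in
plants and telomeric/end-to-end (TCF) in vertebrates, whose n = 10
ancestral karyotype went through two ancient WGD rounds.  `paleokaryo`
implements the full analytical chain needed to recover such scenarios:

1. **Homology calling** (`paleokaryo.homology`) — per gene pair, HSPs from
   BLAST-style searches are pooled into AL (aligned length, the sum of HSP
   lengths), CIP (cumulative identity percentage, Σ identities / AL × 100)
   and CALP (cumulative aligned-length percentage, AL / query length ×
   100).  Pairs pass at CIP/CALP ≥ 70 % for closely related genomes
   (< 50 Myr of divergence) or ≥ 50 % for distant ones, and the best hit —
   highest CIP over the longest CALP — labels each pair ortholog or
   paralog.
2. **Synteny detection** (`paleokaryo.synteny`) — anchors are chained into
   collinear blocks (strictly monotone rank runs, gap ≤ 20 genes) and
   validated CloseUp-style: match number ≥ 5, local anchor density ≥ 2×
   the background density, and a Monte-Carlo permutation p < 0.05.
   Duplicated blocks found at orthologous positions in a second genome are
   dated as pre-speciation (ancestral WGD); the rest as lineage-specific.
3. **Ancestral karyotype reconstruction** (`paleokaryo.ancestor`) —
   validated blocks are cut into atomic conserved segments; adjacencies
   supported by ≥ 2 genomes form contiguous ancestral regions (CARs),
   summarised into protochromosome counts, protogene counts and conserved
   gene-space size.
4. **Event calculus** (`paleokaryo.scenario`) — karyotypes as signed
   sequences of ancestral-colour segments; WGD / fission (Cfis) / fusion
   (Cfus, TCF or CCF) / inversion / translocation events obeying the count
   law n = n₀ + #Cfis − #Cfus (WGD doubling), with 1 nested fusion ≡
   1 Cfis + 2 Cfus; exact (A*) and heuristic parsimony search for minimal
   scenarios.  Curated event scripts for 19 plant and animal lineages ship
   with the package (`paleokaryo.history`).
5. **Landscape profiling** (`paleokaryo.landscape`) — gene counts and
   cumulative TE coverage (class I LTR, class I non-LTR, class II) in
   500-kb windows along chromosomes.
6. **Simulator** (`paleokaryo.simulate`) — genomes descended from a
   protochromosome ancestor via scripted events, with post-WGD gene loss,
   divergence-dependent identity decay, HSP fragmentation, decoy
   alignments and plant-like (nested hot-spot) or animal-like
   (homogeneous) TE spatial models, plus a ground-truth ledger for every
   emitted object.

## Worked example

Replay the shipped poplar scenario — hexaploid eudicot ancestor (n = 21),
6 fissions and 15 fusions to the n = 12 *Malpighiales* intermediate, a
lineage-specific WGD, then 4 fissions and 9 fusions:

```text
$ paleokaryo scenario replay --kingdom plant --lineage poplar
poplar: 21 -> 27 -> 12 -> 24 -> 28 -> 19  n=19
```

The trace prints the chromosome number after each count-level step; n = 19
is the modern poplar karyotype.

Run the pipeline on a simulated pre-speciation WGD data set (three
descendants of an n = 5 ancestor, 1,200 protogenes):

```python
from paleokaryo import scenario as sc
from paleokaryo.simulate import SimConfig, noise_free, simulate
from paleokaryo.formats import group_hsps
from paleokaryo.homology import call_homologs, summarize_pair
from paleokaryo.synteny import SyntenyParams, detect_blocks, coverage_summary

cfg = noise_free(SimConfig(n_protogenes=1200, seed=3,
    shared_events=[sc.Event("WGD")],
    lineage_events={"g1": [sc.Event("Cfus_TCF", {"chrom_a": 0, "chrom_b": 5})],
                    "g2": [sc.Event("Cfis", {"chrom": 0, "pos": 2})],
                    "g3": []}))
res = simulate(cfg)
aligns = [summarize_pair(q, s, grp, res.gene_index[q].cds_length)
          for (q, s), grp in group_hsps(res.hsps).items()]
genome_map = {g: r.genome_id for g, r in res.gene_index.items()}
pairs = call_homologs(aligns, genome_map, res.divergence_classes)
blocks = detect_blocks(pairs, res.gene_index, SyntenyParams(seed=1, n_shuffles=300))

orth = [b for b in blocks if b.kind == "orthologous"
        and {b.genome_a, b.genome_b} == {"g1", "g2"}]
print("g1 vs g2 synteny: %d-%d-%d"
      % coverage_summary(orth, "g1", res.genome_bp_length("g1")))
par = [b for b in blocks if b.kind == "paralogous" and b.genome_a == "g1"]
print("g1 duplications: %d-%d-%d"
      % coverage_summary(par, "g1", res.genome_bp_length("g1")))
```

prints

```text
g1 vs g2 synteny: 2400-11-99
g1 duplications: 1200-5-99
```

i.e. 2,400 orthologous gene pairs in 11 collinear blocks covering 99 % of
genome g1, and 1,200 paralogous pairs in 5 duplicated blocks — the
signature of the shared WGD, which `classify_duplications` then dates as
ancestral because the duplicated blocks sit at orthologous positions in
the other genomes.

An end-to-end run (`paleokaryo run --config run.yaml --out rundir`) chains
all six stages and writes a manifest with per-stage seeds and checksums.

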