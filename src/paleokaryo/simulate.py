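"""Genome-evolution simulator with ground-truth ledgers.

The generator builds a founder ancestor (protochromosomes carrying
protogenes), replays a scripted evolutionary scenario per descendant
lineage through the event calculus (whole-genome duplication, fission,
fusion, inversion, translocation), applies post-WGD duplicate gene loss
(diploidization), and emits everything the analysis pipeline consumes:

- per-genome gene-order tables with bp coordinates and CDS lengths,
- per-HSP pairwise alignment tables with divergence-dependent sequence
  identity (plus sub-threshold decoy alignments),
- GFF3 TE annotations with plant-like (class I LTR hot-spots, nested) or
  animal-like (homogeneous, class I non-LTR dominant) spatial structure,
- a ground-truth ledger (gene families, true scenarios, realized TE
  coverage) against which every pipeline stage can be scored.

Defaults follow the contrast between the two kingdoms: a plant-like
profile with 5 protochromosomes and 12,000 protogenes, an animal-like
profile with 10 protochromosomes and 16,000 protogenes; a scale factor
shrinks gene counts (and with them chromosome lengths) for desk-scale
runs while leaving all rates untouched.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import scenario as sc
from .formats import (
    GeneRecord,
    HspRecord,
    TeRecord,
    write_gene_order,
    write_gff3,
    write_hsp_table,
)
from .homology import HomologPair

TE_TARGETS = {
    # per-class window-coverage targets (%): background, hotspot
    "plant": {
        "classI_LTR": (14.25, 58.0),
        "classI_nonLTR": (3.0, 3.0),
        "classII": (5.0, 5.0),
    },
    # animal profiles are homogeneous: hotspot == background
    "animal": {
        "classI_LTR": (9.0, 9.0),
        "classI_nonLTR": (33.0, 33.0),
        "classII": (3.0, 3.0),
    },
}
PLANT_HOTSPOT_PERIOD = 5  # every 5th window is a class-I LTR hot spot


@dataclass
class SimConfig:
    profile: str = "plant"  # "plant" | "animal"
    n_protochromosomes: int = 5
    n_protogenes: int = 12_000
    segments_per_protochromosome: int = 8
    shared_events: list[sc.Event] = field(default_factory=list)
    lineage_events: dict[str, list[sc.Event]] = field(default_factory=dict)
    gene_loss_rate: float = 0.4
    identity_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"close": (85.0, 5.0), "distant": (60.0, 5.0)}
    )
    divergence_classes: dict[tuple[str, str], str] = field(default_factory=dict)
    hsp_fragmentation: float = 2.0
    decoy_rate: float = 0.1
    decoy_identity: float = 40.0
    mean_cds: float = 1200.0
    sd_cds: float = 300.0
    mean_intergenic: float = 3500.0
    te_model: Optional[str] = None  # default: same as profile
    window_bp: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in ("plant", "animal"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if not 0.0 <= self.gene_loss_rate <= 1.0:
            raise ValueError("gene_loss_rate must lie in [0, 1]")
        if self.n_protochromosomes < 1 or self.n_protogenes < 1:
            raise ValueError("counts must be >= 1")
        if self.te_model is None:
            self.te_model = self.profile

    @classmethod
    def animal(cls, **kw) -> "SimConfig":
        defaults = dict(
            profile="animal",
            n_protochromosomes=10,
            n_protogenes=16_000,
            mean_intergenic=8000.0,
        )
        defaults.update(kw)
        return cls(**defaults)


def scale_profile(config: SimConfig, factor: float) -> SimConfig:
    """Scale gene counts (and hence chromosome lengths) by ``factor``.

    Rates, identity models and event scripts are unchanged; used to bring
    a genome-scale profile down to desk scale.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError("scale factor must lie in (0, 1]")
    cfg = dataclasses.replace(config)
    cfg.n_protogenes = max(1, round(config.n_protogenes * factor))
    return cfg


def noise_free(config: SimConfig) -> SimConfig:
    """Idealised variant: no gene loss, no decoys, near-perfect identity.

    Used for fixtures where the pipeline's recall/precision is expected to
    be exactly 1: sequence divergence stays far from the acceptance
    thresholds and every alignment is a single full-length HSP.
    """
    cfg = dataclasses.replace(config)
    cfg.gene_loss_rate = 0.0
    cfg.decoy_rate = 0.0
    cfg.identity_model = {"close": (95.0, 1.0), "distant": (55.0, 1.0)}
    cfg.hsp_fragmentation = 1.0
    return cfg


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    families: dict[str, str]  # gene_id -> family id
    copy_of: dict[str, int]  # gene_id -> ancestral copy index
    true_scenario: dict[str, list[sc.Event]]  # genome -> event list
    chromosome_counts: dict[str, int]
    realized_te_coverage: dict[str, dict[str, dict[str, float]]]
    ancestor_n: int
    ancestor_karyotype: sc.Karyotype

    def true_pairs(
        self, genome_a: str, genome_b: str, genes: Mapping[str, GeneRecord]
    ) -> set[frozenset]:
        """Same-family gene pairs between (or within) two genomes."""
        by_family: dict[str, list[str]] = {}
        for gid, fam in self.families.items():
            if gid in genes and genes[gid].genome_id in (genome_a, genome_b):
                by_family.setdefault(fam, []).append(gid)
        out: set[frozenset] = set()
        for members in by_family.values():
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    ga, gb = genes[a].genome_id, genes[b].genome_id
                    if {ga, gb} == {genome_a, genome_b} or (
                        genome_a == genome_b and ga == gb == genome_a
                    ):
                        out.add(frozenset((a, b)))
        return out

    def true_positional_orthologs(
        self, genome_a: str, genome_b: str, genes: Mapping[str, GeneRecord]
    ) -> set[frozenset]:
        """Copy-matched cross-genome pairs (the positional ortholog map)."""
        return {
            pair
            for pair in self.true_pairs(genome_a, genome_b, genes)
            if genome_a != genome_b
            and len({self.copy_of[g] for g in pair}) == 1
        }

    def evaluate_homologs(
        self,
        called: Sequence[HomologPair],
        genes: Mapping[str, GeneRecord],
    ) -> tuple[float, float]:
        """(precision, recall) of called pairs against the family ledger.

        Precision: called pairs joining two genes of the same family.
        Recall: genes having at least one same-family partner in another
        genome that received at least one correct ortholog call.
        """
        correct = 0
        called_genes: set[str] = set()
        for p in called:
            same = self.families.get(p.gene_a) == self.families.get(p.gene_b)
            if same:
                correct += 1
                called_genes.update((p.gene_a, p.gene_b))
        precision = correct / len(called) if called else 1.0

        has_partner: set[str] = set()
        by_family: dict[str, list[str]] = {}
        for gid in genes:
            by_family.setdefault(self.families[gid], []).append(gid)
        for members in by_family.values():
            genomes = {genes[g].genome_id for g in members}
            if len(genomes) > 1:
                for g in members:
                    if any(
                        genes[o].genome_id != genes[g].genome_id
                        for o in members
                    ):
                        has_partner.add(g)
        recall = (
            len(called_genes & has_partner) / len(has_partner)
            if has_partner
            else 1.0
        )
        return precision, recall

    def to_json(self) -> dict:
        return {
            "families": self.families,
            "copy_of": self.copy_of,
            "true_scenario": {
                g: [
                    {"kind": e.kind, "operands": e.operands}
                    for e in events
                ]
                for g, events in self.true_scenario.items()
            },
            "chromosome_counts": self.chromosome_counts,
            "realized_te_coverage": self.realized_te_coverage,
            "ancestor_n": self.ancestor_n,
        }


@dataclass
class SimResult:
    genomes: dict[str, list[GeneRecord]]
    gene_index: dict[str, GeneRecord]
    hsps: list[HspRecord]
    query_lengths: dict[str, int]
    tes: list[TeRecord]
    chrom_lengths: dict[tuple[str, str], int]
    divergence_classes: dict[tuple[str, str], str]
    ground_truth: GroundTruth

    def genome_bp_length(self, genome: str) -> int:
        return sum(
            length
            for (g, _), length in self.chrom_lengths.items()
            if g == genome
        )

    def write_outputs(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        write_gene_order(self.genomes, outdir / "genes.tsv")
        paths["genes"] = str(outdir / "genes.tsv")
        write_hsp_table(self.hsps, outdir / "hsps.tsv", dialect="nident")
        paths["hsps"] = str(outdir / "hsps.tsv")
        all_genes = [g for gs in self.genomes.values() for g in gs]
        write_gff3(all_genes, self.tes, outdir / "features.gff3")
        paths["gff3"] = str(outdir / "features.gff3")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth.to_json(), fh, indent=1)
        paths["ground_truth"] = str(outdir / "ground_truth.json")
        with open(outdir / "divergence.tsv", "w") as fh:
            fh.write("genome_a\tgenome_b\tclass\n")
            for (ga, gb), cls in sorted(self.divergence_classes.items()):
                fh.write(f"{ga}\t{gb}\t{cls}\n")
        paths["divergence"] = str(outdir / "divergence.tsv")
        return paths


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def build_ancestor(config: SimConfig) -> tuple[sc.Karyotype, dict[str, list[str]]]:
    """Founder karyotype plus the protogene content of each atomic segment.

    Every protochromosome is pre-cut into atomic segments (each its own
    colour, prefixed by the protochromosome id) so that fission/fusion
    breakpoints always fall between segments.
    """
    seg_genes: dict[str, list[str]] = {}
    chroms: list[list[str]] = []
    per_chrom = [
        config.n_protogenes // config.n_protochromosomes
        + (1 if i < config.n_protogenes % config.n_protochromosomes else 0)
        for i in range(config.n_protochromosomes)
    ]
    fam = 0
    for p, n_genes in enumerate(per_chrom, start=1):
        n_seg = min(config.segments_per_protochromosome, max(1, n_genes))
        sizes = [
            n_genes // n_seg + (1 if s < n_genes % n_seg else 0)
            for s in range(n_seg)
        ]
        colors = []
        for s, size in enumerate(sizes, start=1):
            color = f"P{p}.{s}"
            seg_genes[color] = [f"f{fam + i:05d}" for i in range(size)]
            fam += size
            colors.append(color)
        chroms.append(colors)
    return sc.karyotype_from_colors(chroms, name="ancestor"), seg_genes


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def simulate(config: SimConfig, seed: Optional[int] = None) -> SimResult:
    """Run the generator; fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ancestor, seg_genes = build_ancestor(config)

    lineages = sorted(config.lineage_events) or ["g1", "g2"]
    shared = list(config.shared_events)
    shared_wgd = any(e.kind == "WGD" for e in shared)

    # ancestral per-family attributes
    families = sorted({f for genes in seg_genes.values() for f in genes})
    fam_cds = {
        f: int(max(300, rng.normal(config.mean_cds, config.sd_cds)))
        for f in families
    }
    fam_strand = {f: int(rng.choice((1, -1))) for f in families}

    # evolve each lineage
    base, _ = sc.replay(ancestor, shared)
    genomes: dict[str, list[GeneRecord]] = {}
    gene_index: dict[str, GeneRecord] = {}
    fam_of: dict[str, str] = {}
    copy_of: dict[str, int] = {}
    chrom_lengths: dict[tuple[str, str], int] = {}
    true_scenario: dict[str, list[sc.Event]] = {}
    chromosome_counts: dict[str, int] = {}

    for genome in lineages:
        events = config.lineage_events.get(genome, [])
        kary, _ = sc.replay(base, events)
        true_scenario[genome] = shared + list(events)
        chromosome_counts[genome] = kary.n

        # lay out genes chromosome by chromosome
        raw: list[tuple[str, str, int, int, int, int, str, int]] = []
        # (gene_id, chrom, start, end, strand, cds, family, copy)
        lost: set[tuple[str, int]] = _sample_gene_loss(
            rng, kary, seg_genes, config.gene_loss_rate
        )
        for ci, chrom in enumerate(kary.chromosomes, start=1):
            chrom_id = f"{genome}_chr{ci}"
            pos = 1
            for seg in chrom.segments:
                fams = seg_genes[seg.color]
                ordered = fams if seg.orient == 1 else fams[::-1]
                for f in ordered:
                    if (f, seg.copy) in lost:
                        continue
                    cds = fam_cds[f]
                    gap = int(rng.exponential(config.mean_intergenic)) + 200
                    start = pos + gap
                    end = start + cds - 1
                    strand = fam_strand[f] * seg.orient
                    gid = f"{genome}_{f}_c{seg.copy}"
                    raw.append(
                        (gid, chrom_id, start, end, strand, cds, f, seg.copy)
                    )
                    pos = end
            chrom_lengths[(genome, chrom_id)] = pos + int(config.mean_intergenic)

        # ranks by start (starts are strictly increasing per chromosome)
        by_chrom: dict[str, list] = {}
        for row in raw:
            by_chrom.setdefault(row[1], []).append(row)
        records = []
        for chrom_id in sorted(by_chrom):
            rows = sorted(by_chrom[chrom_id], key=lambda r: r[2])
            for rank, (gid, cid, start, end, strand, cds, f, copy) in enumerate(rows):
                rec = GeneRecord(
                    gene_id=gid, genome_id=genome, chromosome_id=cid,
                    rank=rank, start=start, end=end, strand=strand,
                    cds_length=cds,
                )
                records.append(rec)
                gene_index[gid] = rec
                fam_of[gid] = f
                copy_of[gid] = copy
        genomes[genome] = records

    divergence = _divergence_table(config, lineages, shared_wgd)
    hsps, query_lengths = _emit_hsps(
        rng, config, genomes, gene_index, fam_of, copy_of, divergence,
        shared_wgd,
    )
    tes, realized = _emit_tes(rng, config, chrom_lengths)

    ground_truth = GroundTruth(
        families=fam_of,
        copy_of=copy_of,
        true_scenario=true_scenario,
        chromosome_counts=chromosome_counts,
        realized_te_coverage=realized,
        ancestor_n=ancestor.n,
        ancestor_karyotype=ancestor,
    )
    return SimResult(
        genomes=genomes,
        gene_index=gene_index,
        hsps=hsps,
        query_lengths=query_lengths,
        tes=tes,
        chrom_lengths=chrom_lengths,
        divergence_classes=divergence,
        ground_truth=ground_truth,
    )


def _sample_gene_loss(
    rng: np.random.Generator,
    kary: sc.Karyotype,
    seg_genes: Mapping[str, list[str]],
    loss_rate: float,
) -> set[tuple[str, int]]:
    """Post-WGD diploidization: per family, drop surplus copies.

    For each duplicate beyond the first copy of a family, one uniformly
    chosen copy is removed with probability ``loss_rate``; a family always
    keeps at least one copy.
    """
    if loss_rate <= 0:
        return set()
    fam_copies: dict[str, list[tuple[str, int]]] = {}
    for chrom in kary.chromosomes:
        for seg in chrom.segments:
            for f in seg_genes[seg.color]:
                fam_copies.setdefault(f, []).append((f, seg.copy))
    lost: set[tuple[str, int]] = set()
    for f in sorted(fam_copies):
        copies = fam_copies[f]
        surplus = len(copies) - 1
        for _ in range(surplus):
            alive = [c for c in copies if c not in lost]
            if len(alive) <= 1:
                break
            if rng.random() < loss_rate:
                lost.add(alive[int(rng.integers(len(alive)))])
    return lost


def _divergence_table(
    config: SimConfig, lineages: Sequence[str], shared_wgd: bool
) -> dict[tuple[str, str], str]:
    table: dict[tuple[str, str], str] = {}
    for i, ga in enumerate(lineages):
        for gb in lineages[i:]:
            if ga == gb:
                # within-genome duplicates: age of the separating WGD
                has_own_wgd = any(
                    e.kind == "WGD"
                    for e in config.lineage_events.get(ga, [])
                )
                table[(ga, gb)] = (
                    "distant" if shared_wgd and not has_own_wgd else "close"
                )
            else:
                table[(ga, gb)] = config.divergence_classes.get(
                    (ga, gb),
                    config.divergence_classes.get((gb, ga), "close"),
                )
    return table


def _pair_identity_class(
    ga: str, gb: str, copy_a: int, copy_b: int,
    divergence: Mapping[tuple[str, str], str], shared_wgd: bool,
) -> str:
    """Divergence class governing a gene pair's sequence identity.

    Copy-mismatched cross-genome pairs under a shared (pre-speciation) WGD
    split at the WGD, which predates the speciation: they draw from the
    distant model regardless of the genome pair's class.
    """
    if ga == gb:
        return divergence[(ga, gb)]
    cls = divergence.get((ga, gb), divergence.get((gb, ga), "close"))
    if copy_a != copy_b and shared_wgd:
        return "distant"
    return cls


def _emit_hsps(
    rng: np.random.Generator,
    config: SimConfig,
    genomes: Mapping[str, list[GeneRecord]],
    gene_index: Mapping[str, GeneRecord],
    fam_of: Mapping[str, str],
    copy_of: Mapping[str, int],
    divergence: Mapping[tuple[str, str], str],
    shared_wgd: bool,
) -> tuple[list[HspRecord], dict[str, int]]:
    query_lengths = {g: rec.cds_length for g, rec in gene_index.items()}
    by_family: dict[str, list[str]] = {}
    for gid, f in fam_of.items():
        by_family.setdefault(f, []).append(gid)

    hsps: list[HspRecord] = []
    n_true_pairs = 0
    for f in sorted(by_family):
        members = sorted(by_family[f])
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                ga, gb = gene_index[a].genome_id, gene_index[b].genome_id
                cls = _pair_identity_class(
                    ga, gb, copy_of[a], copy_of[b], divergence, shared_wgd
                )
                mean, sd = config.identity_model[cls]
                ident = _truncnorm(rng, mean, sd, 5.0, 100.0)
                n_true_pairs += 1
                for q, s in ((a, b), (b, a)):
                    hsps.extend(
                        _fragment_pair(
                            rng, q, s, query_lengths[q], ident,
                            config.hsp_fragmentation,
                        )
                    )

    # decoys: sub-threshold alignments between unrelated genes
    n_decoys = int(round(config.decoy_rate * n_true_pairs))
    all_genes = sorted(gene_index)
    for _ in range(n_decoys):
        a, b = (all_genes[i] for i in rng.integers(len(all_genes), size=2))
        if a == b or fam_of[a] == fam_of[b]:
            continue
        ident = _truncnorm(rng, config.decoy_identity, 3.0, 5.0, 100.0)
        cov = rng.uniform(0.5, 0.9)
        qlen = query_lengths[a]
        length = max(30, int(cov * qlen))
        hsps.append(
            HspRecord(
                query_id=a, subject_id=b, hsp_length=length,
                identities=int(round(ident / 100.0 * length)),
                query_start=1, query_end=length,
                e_value=1e-5, bit_score=50.0,
            )
        )
    return hsps, query_lengths


def _fragment_pair(
    rng: np.random.Generator,
    query: str,
    subject: str,
    query_length: int,
    identity_pct: float,
    frag_mean: float,
) -> list[HspRecord]:
    """Split one pairwise alignment into HSP fragments covering the query."""
    n_frag = 1 + int(rng.poisson(max(0.0, frag_mean - 1.0)))
    coverage = rng.uniform(0.88, 1.0)
    covered = max(n_frag * 30, int(coverage * query_length))
    covered = min(covered, query_length)
    # split covered length into n_frag chunks, separated by small gaps
    cuts = np.sort(rng.integers(1, covered, size=n_frag - 1)) if n_frag > 1 else []
    bounds = [0, *[int(c) for c in cuts], covered]
    sizes = [max(15, bounds[i + 1] - bounds[i]) for i in range(n_frag)]
    gap_total = query_length - sum(sizes)
    gaps = (
        rng.multinomial(max(0, gap_total), [1.0 / (n_frag + 1)] * (n_frag + 1))
        if gap_total > 0
        else [0] * (n_frag + 1)
    )
    out = []
    pos = 1 + int(gaps[0])
    for i, size in enumerate(sizes):
        ident_i = float(np.clip(identity_pct + rng.normal(0, 1.5), 1, 100))
        start = min(pos, query_length)
        end = min(start + size - 1, query_length)
        size_eff = end - start + 1
        out.append(
            HspRecord(
                query_id=query, subject_id=subject,
                hsp_length=size_eff,
                identities=int(round(ident_i / 100.0 * size_eff)),
                query_start=start, query_end=end,
                e_value=1e-30, bit_score=200.0,
            )
        )
        pos = end + 1 + int(gaps[i + 1])
        if pos > query_length:
            break
    return out


def _emit_tes(
    rng: np.random.Generator,
    config: SimConfig,
    chrom_lengths: Mapping[tuple[str, str], int],
) -> tuple[list[TeRecord], dict[str, dict[str, dict[str, float]]]]:
    """Place TE annotations window by window to hit coverage targets.

    Plant mode concentrates class I LTR elements into periodic hot-spot
    windows (nested insertions on top); animal mode spreads all classes
    homogeneously.  Realized per-window coverage is returned as a ledger:
    genome -> class -> {mean_pct, max_pct}.
    """
    targets = TE_TARGETS[config.te_model or config.profile]
    mean_len = {"classI_LTR": 8000, "classI_nonLTR": 1500, "classII": 2000}
    tes: list[TeRecord] = []
    window_pct: dict[str, dict[str, list[float]]] = {}

    global_window = 0
    for (genome, chrom_id), length in sorted(chrom_lengths.items()):
        n_windows = (length + config.window_bp - 1) // config.window_bp
        for w in range(n_windows):
            lo = w * config.window_bp + 1
            hi = min((w + 1) * config.window_bp, length)
            wlen = hi - lo + 1
            hot = (
                config.te_model == "plant"
                and global_window % PLANT_HOTSPOT_PERIOD == 2
            )
            global_window += 1
            for te_class, (bg, hot_pct) in targets.items():
                pct = hot_pct if (hot and te_class == "classI_LTR") else bg
                if config.te_model == "animal":
                    pct *= rng.uniform(0.85, 1.15)  # mild jitter, max < 1.5x mean
                placed = _fill_window(
                    rng, lo, hi, pct / 100.0, mean_len[te_class]
                )
                covered = sum(e - s + 1 for s, e in placed)
                for s, e in placed:
                    tes.append(
                        TeRecord(
                            genome_id=genome, chromosome_id=chrom_id,
                            start=s, end=e, te_class=te_class,
                        )
                    )
                # nested insertions: contained copies, union unchanged
                if config.te_model == "plant" and hot and te_class == "classI_LTR":
                    for s, e in placed:
                        if e - s > 2000 and rng.random() < 0.5:
                            ns = int(rng.integers(s, e - 1000))
                            ne = min(e, ns + int(rng.integers(500, 2000)))
                            tes.append(
                                TeRecord(
                                    genome_id=genome, chromosome_id=chrom_id,
                                    start=ns, end=ne, te_class=te_class,
                                )
                            )
                window_pct.setdefault(genome, {}).setdefault(
                    te_class, []
                ).append(100.0 * covered / wlen)

    realized: dict[str, dict[str, dict[str, float]]] = {}
    for genome, classes in window_pct.items():
        realized[genome] = {}
        for te_class, pcts in classes.items():
            realized[genome][te_class] = {
                "mean_pct": float(np.mean(pcts)),
                "max_pct": float(np.max(pcts)),
            }
    return tes, realized


def _fill_window(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    frac: float,
    mean_len: int,
) -> list[tuple[int, int]]:
    """Non-overlapping intervals covering ~``frac`` of [lo, hi]."""
    wlen = hi - lo + 1
    needed = int(frac * wlen)
    if needed <= 0:
        return []
    lengths: list[int] = []
    while sum(lengths) < needed:
        lengths.append(max(200, int(rng.exponential(mean_len))))
    lengths[-1] = max(100, needed - sum(lengths[:-1]))
    free = wlen - sum(lengths)
    if free < 0:  # target larger than window: single covering interval
        return [(lo, hi)]
    gaps = rng.multinomial(free, [1.0 / (len(lengths) + 1)] * (len(lengths) + 1))
    out = []
    pos = lo + int(gaps[0])
    for i, ln in enumerate(lengths):
        out.append((pos, pos + ln - 1))
        pos += ln + int(gaps[i + 1])
    return out


# --------------------------------------------------------------------------
# Random parsimony instances (oracle fodder)
# --------------------------------------------------------------------------

def random_scenario_instance(
    seed: int,
    max_events: int = 4,
    max_chromosomes: int = 6,
    max_segments: int = 3,
) -> tuple[sc.Karyotype, sc.Karyotype, list[sc.Event]]:
    """A random (start, target, generating events) parsimony instance.

    The start karyotype has up to ``max_chromosomes`` chromosomes of 1 to
    ``max_segments`` uniquely coloured segments; the target is produced by
    applying up to ``max_events`` random fissions, fusions (both modes) and
    inversions.
    """
    rng = np.random.default_rng(seed)
    n_chrom = int(rng.integers(2, max_chromosomes + 1))
    color = 0
    chroms = []
    for _ in range(n_chrom):
        n_seg = int(rng.integers(1, max_segments + 1))
        chroms.append([f"s{color + i}" for i in range(n_seg)])
        color += n_seg
    start = sc.karyotype_from_colors(chroms, name="start")

    k = start
    events: list[sc.Event] = []
    n_events = int(rng.integers(0, max_events + 1))
    for _ in range(n_events):
        moves = []
        for i, chrom in enumerate(k.chromosomes):
            for pos in range(1, len(chrom)):
                moves.append(sc.Event("Cfis", {"chrom": i, "pos": pos}))
            for s in range(len(chrom)):
                for e in range(s + 1, len(chrom) + 1):
                    if s == 0 and e == len(chrom):
                        continue
                    moves.append(
                        sc.Event("inversion", {"chrom": i, "start": s, "end": e})
                    )
        if k.n >= 2:
            for ia in range(k.n):
                for ib in range(k.n):
                    if ia == ib:
                        continue
                    moves.append(
                        sc.Event(
                            "Cfus_TCF",
                            {"chrom_a": ia, "chrom_b": ib, "flip_b": False},
                        )
                    )
                    for pos in range(1, len(k.chromosomes[ia])):
                        moves.append(
                            sc.Event(
                                "Cfus_CCF",
                                {
                                    "chrom_a": ia, "chrom_b": ib,
                                    "pos": pos, "flip_b": False,
                                },
                            )
                        )
        if not moves:
            break
        ev = moves[int(rng.integers(len(moves)))]
        k = sc.apply_event(k, ev)
        events.append(ev)
    target = sc.Karyotype(k.chromosomes, name="target")
    return start, target, events
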