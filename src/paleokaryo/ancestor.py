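"""Contiguous ancestral region (CAR) assembly and ancestral karyotypes.

Validated cross-genome blocks are projected onto a reference genome and cut
into atomic conserved segments (the common refinement of all block
boundaries).  Each modern genome then induces an ordering of these segments
along its chromosomes.  Segment adjacencies observed in at least two
genomes are taken as ancestral — duplications or other shuffling events
found at orthologous positions between modern species are attributed to the
ancestor — and the resulting adjacency graph is resolved into maximal
simple paths: the CARs, each representing part of an ancestral
protochromosome.

Protogene content is derived from gene families (connected components of
the homolog graph restricted to validated blocks); the ancestral gene-space
size is the cumulative conserved CDS size, taking the minimum CDS length in
each family as its conserved representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import pvariance
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .formats import GeneRecord
from .homology import HomologPair
from .synteny import SyntenyBlock

MIN_ADJACENCY_SUPPORT = 2


@dataclass
class CAR:
    """A contiguous ancestral region: an ordered run of conserved segments."""

    car_id: str
    segments: list[tuple[str, int]]  # (segment_id, orientation)
    supports: list[int] = field(default_factory=list)  # per internal adjacency
    member_genomes: set[str] = field(default_factory=set)
    protogene_count: int = 0
    gene_space_bp: int = 0

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class AncestralKaryotype:
    name: str
    n_protochromosomes: int
    cars: list[CAR]
    total_protogenes: int
    total_gene_space_bp: int


# --------------------------------------------------------------------------
# Segment projection
# --------------------------------------------------------------------------

def project_to_segment_orders(
    blocks: Sequence[SyntenyBlock],
    genes: Mapping[str, GeneRecord],
    reference: str,
) -> dict[str, list[list[str]]]:
    """Project blocks onto reference-genome atomic segments and order them.

    Only orthologous blocks touching the reference genome are used.  The
    reference's chromosomes are cut at every block boundary; each block then
    carries its covered atomic segments onto the partner genome, ordered by
    the block's position and orientation there.

    Returns, per genome (reference included), a list of chromosomes, each
    an ordered list of segment ids.
    """
    ref_blocks = [
        b
        for b in blocks
        if b.kind == "orthologous" and reference in (b.genome_a, b.genome_b)
    ]
    if not ref_blocks:
        return {}

    def ref_side(b: SyntenyBlock) -> tuple[str, tuple[int, int], str, bool]:
        """(ref chromosome, ref rank span, partner genome, ref_is_a)."""
        if b.genome_a == reference:
            return b.chromosome_a, b.rank_span_a, b.genome_b, True
        return b.chromosome_b, b.rank_span_b, b.genome_a, False

    # cut reference chromosomes at all block boundaries
    boundaries: dict[str, set[int]] = {}
    for b in ref_blocks:
        chrom, (lo, hi), _, _ = ref_side(b)
        boundaries.setdefault(chrom, set()).update((lo, hi + 1))
    atoms: dict[str, list[tuple[int, int]]] = {}
    for chrom, cuts in boundaries.items():
        pts = sorted(cuts)
        atoms[chrom] = [
            (pts[i], pts[i + 1] - 1) for i in range(len(pts) - 1)
        ]

    def seg_id(chrom: str, atom: tuple[int, int]) -> str:
        return f"{chrom}:{atom[0]}-{atom[1]}"

    def covered_atoms(chrom: str, span: tuple[int, int]) -> list[tuple[int, int]]:
        return [
            a
            for a in atoms[chrom]
            if a[0] >= span[0] and a[1] <= span[1]
        ]

    orders: dict[str, list[list[str]]] = {}

    # reference order: atoms in rank order per chromosome, only those
    # covered by at least one block
    used: dict[str, set[tuple[int, int]]] = {c: set() for c in atoms}
    for b in ref_blocks:
        chrom, span, _, _ = ref_side(b)
        used[chrom].update(covered_atoms(chrom, span))
    orders[reference] = [
        [seg_id(chrom, a) for a in atoms[chrom] if a in used[chrom]]
        for chrom in sorted(atoms)
        if used[chrom]
    ]

    # partner genomes: order blocks along their chromosomes, expand each
    # into its atoms (reversed when the block is inverted)
    partners = sorted({ref_side(b)[2] for b in ref_blocks})
    for genome in partners:
        placed: dict[str, list[tuple[int, list[str]]]] = {}
        for b in ref_blocks:
            chrom, span, partner, ref_is_a = ref_side(b)
            if partner != genome:
                continue
            block_atoms = [seg_id(chrom, a) for a in covered_atoms(chrom, span)]
            if b.orientation == "inverted":
                block_atoms = block_atoms[::-1]
            if ref_is_a:
                p_chrom, p_span = b.chromosome_b, b.rank_span_b
            else:
                p_chrom, p_span = b.chromosome_a, b.rank_span_a
            placed.setdefault(p_chrom, []).append((p_span[0], block_atoms))
        chrom_orders = []
        for p_chrom in sorted(placed):
            entries = sorted(placed[p_chrom], key=lambda e: e[0])
            chrom_orders.append([s for _, segs in entries for s in segs])
        orders[genome] = chrom_orders
    return orders


# --------------------------------------------------------------------------
# Common intervals -> adjacency graph
# --------------------------------------------------------------------------

def common_intervals(
    segment_orders: Mapping[str, Sequence[Sequence[str]]],
    min_support: int = MIN_ADJACENCY_SUPPORT,
) -> nx.Graph:
    """Build the ancestral adjacency graph from per-genome segment orders.

    Nodes are conserved segments; an edge joins two segments adjacent
    (consecutive on the same chromosome) in at least ``min_support``
    genomes, with the supporting-genome count as edge weight.
    """
    if len(segment_orders) < 2:
        raise ValueError("common intervals need at least two genomes")
    support: dict[frozenset, set[str]] = {}
    nodes: set[str] = set()
    for genome, chromosomes in segment_orders.items():
        for chrom in chromosomes:
            nodes.update(chrom)
            for u, v in zip(chrom, chrom[1:]):
                if u == v:
                    continue
                support.setdefault(frozenset((u, v)), set()).add(genome)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(nodes))
    for pair, genomes in support.items():
        if len(genomes) >= min_support:
            u, v = sorted(pair)
            graph.add_edge(u, v, weight=len(genomes), genomes=sorted(genomes))
    return graph


# --------------------------------------------------------------------------
# CAR assembly
# --------------------------------------------------------------------------

def _drop_candidate(graph: nx.Graph, edges: list[tuple[str, str]]) -> tuple[str, str]:
    """Pick which of several lowest-weight edges to drop.

    Ties are broken by the removal that minimises the variance of the
    resulting component sizes, then lexicographically.
    """
    if len(edges) == 1:
        return edges[0]
    scored = []
    for u, v in sorted(tuple(sorted(e)) for e in edges):
        trial = graph.copy()
        trial.remove_edge(u, v)
        sizes = [len(c) for c in nx.connected_components(trial)]
        scored.append((pvariance(sizes) if len(sizes) > 1 else 0.0, (u, v)))
    scored.sort()
    return scored[0][1]


def assemble_cars(graph: nx.Graph) -> list[CAR]:
    """Resolve the adjacency graph into maximal simple paths (CARs).

    Branch nodes are resolved by repeatedly dropping their lowest-weight
    incident edge; cycles are opened at their lowest-weight edge.  Every
    node ends up in exactly one CAR; isolated nodes become singleton CARs.
    """
    g = graph.copy()

    # resolve branches
    while True:
        branch_nodes = sorted(n for n in g.nodes if g.degree(n) > 2)
        if not branch_nodes:
            break
        node = branch_nodes[0]
        incident = list(g.edges(node, data="weight"))
        min_w = min(w for _, _, w in incident)
        candidates = [(u, v) for u, v, w in incident if w == min_w]
        g.remove_edge(*_drop_candidate(g, candidates))

    # open cycles
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        min_w = min(g.edges[u, v]["weight"] for u, v in cycle)
        candidates = [
            (u, v) for u, v in cycle if g.edges[u, v]["weight"] == min_w
        ]
        g.remove_edge(*_drop_candidate(g, candidates))

    cars: list[CAR] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            path = list(comp)
        else:
            ends = sorted(n for n in sub.nodes if sub.degree(n) == 1)
            start = ends[0]
            path = [start]
            prev = None
            while True:
                nxts = [n for n in sub.neighbors(path[-1]) if n != prev]
                if not nxts:
                    break
                prev = path[-1]
                path.append(nxts[0])
        supports = [
            g.edges[u, v]["weight"] for u, v in zip(path, path[1:])
        ]
        member_genomes: set[str] = set()
        for u, v in zip(path, path[1:]):
            member_genomes.update(g.edges[u, v].get("genomes", []))
        cars.append(
            CAR(
                car_id="",
                segments=[(s, 1) for s in path],
                supports=supports,
                member_genomes=member_genomes,
            )
        )
    cars.sort(key=lambda c: c.segments[0][0])
    for i, car in enumerate(cars, start=1):
        car.car_id = f"CAR{i:03d}"
    return cars


# --------------------------------------------------------------------------
# Gene families and karyotype statistics
# --------------------------------------------------------------------------

class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def gene_families(
    pairs: Iterable[HomologPair],
    restrict_to: Optional[set[str]] = None,
) -> dict[str, str]:
    """Map gene id -> family id (connected components of the homolog graph).

    With ``restrict_to`` given, only pairs with both genes in the set
    contribute (used to restrict families to validated blocks).  Family ids
    are the lexicographically smallest member gene id.
    """
    uf = _UnionFind()
    for p in pairs:
        if restrict_to is not None and (
            p.gene_a not in restrict_to or p.gene_b not in restrict_to
        ):
            continue
        uf.union(p.gene_a, p.gene_b)
    return {g: uf.find(g) for g in list(uf.parent)}


def annotate_cars(
    cars: Sequence[CAR],
    segment_families: Mapping[str, set[str]],
    family_min_cds: Mapping[str, int],
) -> None:
    """Fill protogene counts and conserved gene-space size per CAR.

    ``segment_families`` maps segment id -> family ids anchoring it;
    ``family_min_cds`` maps family id -> minimal CDS length across members
    (the conserved representative).
    """
    for car in cars:
        fams: set[str] = set()
        for seg_id, _ in car.segments:
            fams.update(segment_families.get(seg_id, set()))
        car.protogene_count = len(fams)
        car.gene_space_bp = sum(family_min_cds.get(f, 0) for f in fams)


def karyotype_stats(
    cars: Sequence[CAR],
    name: str = "ancestor",
    n_protochromosomes: Optional[int] = None,
) -> AncestralKaryotype:
    """Summarise assembled CARs into an ancestral karyotype.

    Unless stated otherwise each CAR is counted as one reconstructed
    protochromosome (fragmentary reconstructions may group several CARs
    per protochromosome; pass ``n_protochromosomes`` in that case).
    """
    return AncestralKaryotype(
        name=name,
        n_protochromosomes=(
            n_protochromosomes if n_protochromosomes is not None else len(cars)
        ),
        cars=list(cars),
        total_protogenes=sum(c.protogene_count for c in cars),
        total_gene_space_bp=sum(c.gene_space_bp for c in cars),
    )


# --------------------------------------------------------------------------
# High-level reconstruction
# --------------------------------------------------------------------------

def reconstruct_ancestor(
    blocks: Sequence[SyntenyBlock],
    genes: Mapping[str, GeneRecord],
    pairs: Sequence[HomologPair],
    reference: str,
    name: str = "ancestor",
    min_support: int = MIN_ADJACENCY_SUPPORT,
) -> tuple[AncestralKaryotype, nx.Graph]:
    """Blocks -> segment orders -> adjacency graph -> annotated CARs."""
    orders = project_to_segment_orders(blocks, genes, reference)
    if len(orders) < 2:
        raise ValueError("ancestral reconstruction needs >= 2 genomes")
    graph = common_intervals(orders, min_support=min_support)
    cars = assemble_cars(graph)

    # families restricted to genes inside validated blocks
    block_genes = {
        g
        for b in blocks
        for a in b.anchors
        for g in (a.gene_a, a.gene_b)
    }
    fam = gene_families(pairs, restrict_to=block_genes)
    family_min_cds: dict[str, int] = {}
    for gene_id, fam_id in fam.items():
        cds = genes[gene_id].cds_length
        cur = family_min_cds.get(fam_id)
        if cur is None or (0 < cds < cur) or cur == 0:
            family_min_cds[fam_id] = cds

    # map atomic segments to the families of the reference genes they span
    ref_gene_by_rank: dict[tuple[str, int], GeneRecord] = {
        (g.chromosome_id, g.rank): g
        for g in genes.values()
        if g.genome_id == reference
    }
    segment_families: dict[str, set[str]] = {}
    for car in cars:
        for seg_id, _ in car.segments:
            chrom, span = seg_id.rsplit(":", 1)
            lo, hi = (int(x) for x in span.split("-"))
            fams = set()
            for rank in range(lo, hi + 1):
                g = ref_gene_by_rank.get((chrom, rank))
                if g is not None and g.gene_id in fam:
                    fams.add(fam[g.gene_id])
            segment_families[seg_id] = fams
    annotate_cars(cars, segment_families, family_min_cds)
    return karyotype_stats(cars, name=name), graph
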