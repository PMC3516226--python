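"""Collinear block detection and statistical validation.

Homologous gene pairs are turned into anchors (rank coordinates on their
two chromosomes) and chained into candidate collinear blocks: maximal runs
of anchors that are strictly monotone on both sides, with consecutive
anchors separated by at most ``max_gap`` gene ranks, assigned greedily
longest-chain-first so that each anchor belongs to at most one block per
chromosome pair.

Candidate blocks are then accepted only when they pass a cluster test in
the style of a CloseUp analysis: at least ``min_match`` anchors (default
5), a local anchor density at least ``density_ratio_min`` (default 2) times
the genome-pair background density, and a Monte-Carlo p-value below alpha
(default 0.05) under random permutation of gene orders within chromosomes.
The cluster length defaults to the gene-rank span of the block (maximum of
the two sides).

Within-genome (paralogous) blocks flag ancient duplications; those found
at orthologous positions in a second genome are classified as shared
pre-speciation (ancestral) duplications, the rest as lineage-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .formats import GeneRecord
from .homology import HomologPair

DEFAULT_MIN_MATCH = 5
DEFAULT_DENSITY_RATIO = 2.0
DEFAULT_MAX_GAP = 20
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    sign: int = 1  # product of member gene strands


@dataclass
class SyntenyBlock:
    block_id: str
    kind: str  # "orthologous" | "paralogous"
    genome_a: str
    chromosome_a: str
    genome_b: str
    chromosome_b: str
    anchors: list[Anchor]
    orientation: str = "direct"  # "direct" | "inverted"
    density_ratio: Optional[float] = None
    p_value: Optional[float] = None
    valid: Optional[bool] = None
    bp_span_a: tuple[int, int] = (0, 0)
    bp_span_b: tuple[int, int] = (0, 0)

    @property
    def match_number(self) -> int:
        return len(self.anchors)

    @property
    def rank_span_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def rank_span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def cluster_length(self) -> int:
        """Gene-rank span of the block: max of the two sides."""
        sa, sb = self.rank_span_a, self.rank_span_b
        return max(sa[1] - sa[0] + 1, sb[1] - sb[0] + 1)


@dataclass
class DuplicationCall:
    block: SyntenyBlock
    status: str  # "ancestral" | "lineage_specific"
    evidence: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# Anchor construction
# --------------------------------------------------------------------------

def build_anchors(
    pairs: Iterable[HomologPair],
    genes: Mapping[str, GeneRecord],
) -> dict[tuple[str, str, str, str], list[Anchor]]:
    """Group homolog pairs into per-chromosome-pair anchor lists.

    Keys are (genome_a, chromosome_a, genome_b, chromosome_b); the pair is
    oriented so that (genome_a, chromosome_a) <= (genome_b, chromosome_b),
    keeping within-genome comparisons canonical.
    """
    out: dict[tuple[str, str, str, str], list[Anchor]] = {}
    seen: set[tuple[str, str]] = set()
    for p in pairs:
        ga, gb = genes[p.gene_a], genes[p.gene_b]
        a, b = ga, gb
        if (b.genome_id, b.chromosome_id, b.gene_id) < (
            a.genome_id, a.chromosome_id, a.gene_id
        ):
            a, b = b, a
        if (a.gene_id, b.gene_id) in seen:  # both search directions reported
            continue
        seen.add((a.gene_id, b.gene_id))
        key = (a.genome_id, a.chromosome_id, b.genome_id, b.chromosome_id)
        out.setdefault(key, []).append(
            Anchor(
                gene_a=a.gene_id,
                gene_b=b.gene_id,
                rank_a=a.rank,
                rank_b=b.rank,
                sign=a.strand * b.strand,
            )
        )
    for anchors in out.values():
        anchors.sort(key=lambda x: (x.rank_a, x.rank_b, x.gene_a, x.gene_b))
    return out


# --------------------------------------------------------------------------
# Chaining
# --------------------------------------------------------------------------

def _compatible(a: Anchor, b: Anchor, direction: int, max_gap: int) -> bool:
    """Can chain step a -> b in the given rank_b direction (+1/-1)?"""
    da = b.rank_a - a.rank_a
    db = (b.rank_b - a.rank_b) * direction
    return 1 <= da <= max_gap and 1 <= db <= max_gap


def _best_chain(anchors: Sequence[Anchor], max_gap: int) -> list[int]:
    """Longest monotone chain (indices into ``anchors``).

    Anchors must be sorted by (rank_a, rank_b).  Among maximum-length
    chains over both directions the lexicographically smallest index
    sequence is returned, direct (increasing rank_b) direction preferred on
    equal length, so the choice is deterministic.
    """
    n = len(anchors)
    if n == 0:
        return []
    candidates: list[tuple[int, list[int], int]] = []
    for direction in (1, -1):
        # f[i] = longest chain starting at i in this direction
        f = [1] * n
        for i in range(n - 1, -1, -1):
            for j in range(i + 1, n):
                if _compatible(anchors[i], anchors[j], direction, max_gap):
                    f[i] = max(f[i], 1 + f[j])
        target = max(f)
        # reconstruct the lexicographically smallest max-length chain
        start = min(i for i in range(n) if f[i] == target)
        seq = [start]
        cur, remaining = start, target - 1
        while remaining:
            nxt = min(
                j
                for j in range(cur + 1, n)
                if f[j] == remaining
                and _compatible(anchors[cur], anchors[j], direction, max_gap)
            )
            seq.append(nxt)
            cur, remaining = nxt, remaining - 1
        candidates.append((len(seq), seq, direction))
    # longest wins; ties by lex-smaller index sequence, then direct first
    candidates.sort(key=lambda c: (-c[0], c[1], -c[2]))
    return candidates[0][1]


def chain_anchors(
    anchors: Sequence[Anchor], max_gap: int = DEFAULT_MAX_GAP
) -> list[list[Anchor]]:
    """Partition a chromosome pair's anchors into monotone chains.

    Greedy longest-chain-first: the best chain (see :func:`_best_chain`) is
    extracted, its anchors removed, and the process repeats, so every
    anchor ends up in exactly one chain (possibly a singleton).
    """
    pool = sorted(anchors, key=lambda x: (x.rank_a, x.rank_b, x.gene_a, x.gene_b))
    chains: list[list[Anchor]] = []
    while pool:
        idx = _best_chain(pool, max_gap)
        if not idx:
            break
        chain = [pool[i] for i in idx]
        chains.append(chain)
        picked = set(idx)
        pool = [a for i, a in enumerate(pool) if i not in picked]
    return chains


def _orientation(chain: Sequence[Anchor]) -> str:
    if len(chain) >= 2 and chain[-1].rank_b < chain[0].rank_b:
        return "inverted"
    return "direct"


def make_block(
    block_id: str,
    kind: str,
    key: tuple[str, str, str, str],
    chain: Sequence[Anchor],
    genes: Optional[Mapping[str, GeneRecord]] = None,
) -> SyntenyBlock:
    block = SyntenyBlock(
        block_id=block_id,
        kind=kind,
        genome_a=key[0],
        chromosome_a=key[1],
        genome_b=key[2],
        chromosome_b=key[3],
        anchors=list(chain),
        orientation=_orientation(chain),
    )
    if genes is not None:
        ga = [genes[a.gene_a] for a in chain]
        gb = [genes[a.gene_b] for a in chain]
        block.bp_span_a = (min(g.start for g in ga), max(g.end for g in ga))
        block.bp_span_b = (min(g.start for g in gb), max(g.end for g in gb))
    return block


# --------------------------------------------------------------------------
# Statistical validation
# --------------------------------------------------------------------------

def scan_pvalue(
    n_anchors: int, n_genes: int, window: int, min_hits: int
) -> float:
    """Closed-form probability that any length-``window`` tile holds
    >= ``min_hits`` of ``n_anchors`` uniformly placed anchors.

    Disjoint tiling windows with a binomial per-window hit count and an
    independence approximation across windows; accurate in the sparse
    (uniform-background) limit.
    """
    n_windows = max(1, n_genes // window)
    p_win = stats.binom.sf(min_hits - 1, n_anchors, window / n_genes)
    return float(1.0 - (1.0 - p_win) ** n_windows)


def montecarlo_pvalue(
    n_anchors: int,
    n_genes: int,
    window: int,
    min_hits: int,
    n_shuffles: int,
    seed: int,
) -> float:
    """Monte-Carlo permutation p-value for the cluster test.

    Each shuffle permutes the gene order of the chromosome, dropping the
    pair's ``n_anchors`` anchors onto distinct uniform gene ranks; the
    shuffle is a success when some disjoint tiling window of ``window``
    consecutive ranks contains at least ``min_hits`` anchors.
    """
    if n_shuffles < 100:
        raise ValueError("need >= 100 shuffles for a stable p-value")
    if n_anchors < min_hits:
        return 1.0 / (n_shuffles + 1)  # pseudocount floor; cannot succeed
    rng = np.random.default_rng(seed)
    k, N = n_anchors, n_genes
    n_windows = max(1, N // window)
    hits = 0
    batch = max(1, int(5e6 / max(N, 1)))
    done = 0
    while done < n_shuffles:
        b = min(batch, n_shuffles - done)
        # k distinct uniform positions per shuffle
        pos = np.argpartition(rng.random((b, N)), k - 1, axis=1)[:, :k]
        w = pos // window
        for row in w:
            if np.bincount(row, minlength=n_windows).max() >= min_hits:
                hits += 1
        done += b
    return (hits + 1) / (n_shuffles + 1)


def validate_block(
    block: SyntenyBlock,
    background: float,
    n_shuffles: int = 1000,
    seed: int = 0,
    *,
    n_genes_a: int,
    n_null_anchors: Optional[int] = None,
    min_match: int = DEFAULT_MIN_MATCH,
    density_ratio_min: float = DEFAULT_DENSITY_RATIO,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[float, float, bool]:
    """Apply the CloseUp-style acceptance test to one candidate block.

    ``background`` is the genome-wide mean anchor density (anchors per
    gene) expected between side a and the block's partner chromosome under
    random scattering; the density ratio is the block's local density
    (match number over cluster length) divided by it.  The Monte-Carlo
    permutation null shuffles gene order genome-wide on side a:
    ``n_null_anchors`` anchors (those linking the partner chromosome;
    defaults to the block's own count) fall on distinct uniform ranks among
    ``n_genes_a`` genes, and the p-value is the fraction of shuffles
    producing >= match_number anchors within any cluster-length window.

    Returns (density_ratio, p_value, verdict) and annotates the block.
    """
    m = block.match_number
    length = block.cluster_length
    local_density = m / length
    ratio = local_density / background if background > 0 else float("inf")

    verdict = m >= min_match and ratio >= density_ratio_min
    p_value = 1.0
    if verdict:
        p_value = montecarlo_pvalue(
            n_anchors=n_null_anchors or m,
            n_genes=max(n_genes_a, length),
            window=length,
            min_hits=m,
            n_shuffles=n_shuffles,
            seed=seed,
        )
        verdict = p_value < alpha

    block.density_ratio = ratio
    block.p_value = p_value
    block.valid = verdict
    return ratio, p_value, verdict


# --------------------------------------------------------------------------
# High-level detection
# --------------------------------------------------------------------------

@dataclass
class SyntenyParams:
    max_gap: int = DEFAULT_MAX_GAP
    min_match: int = DEFAULT_MIN_MATCH
    density_ratio_min: float = DEFAULT_DENSITY_RATIO
    alpha: float = DEFAULT_ALPHA
    n_shuffles: int = 1000
    seed: int = 0


def detect_blocks(
    pairs: Sequence[HomologPair],
    genes: Mapping[str, GeneRecord],
    params: Optional[SyntenyParams] = None,
    keep_invalid: bool = False,
) -> list[SyntenyBlock]:
    """Chain homolog pairs into blocks and validate them.

    The background density for a block between genome a and partner
    chromosome cb is the count of anchors linking any part of genome a to
    cb, divided by genome a's gene count — the density expected if those
    anchors were scattered over the whole genome, which is also the
    Monte-Carlo null.
    """
    params = params or SyntenyParams()
    grouped = build_anchors(pairs, genes)

    genome_genes: dict[str, int] = {}
    for g in genes.values():
        genome_genes[g.genome_id] = genome_genes.get(g.genome_id, 0) + 1

    # anchors linking genome a to each partner chromosome cb
    scatter_totals: dict[tuple[str, str, str], int] = {}
    for (ga, _, gb, cb), anchors in grouped.items():
        sk = (ga, gb, cb)
        scatter_totals[sk] = scatter_totals.get(sk, 0) + len(anchors)

    blocks: list[SyntenyBlock] = []
    counter = 0
    for key in sorted(grouped):
        ga, ca, gb, cb = key
        kind = "paralogous" if ga == gb else "orthologous"
        n_null = scatter_totals[(ga, gb, cb)]
        background = n_null / genome_genes[ga]
        anchors = grouped[key]
        for chain in chain_anchors(anchors, params.max_gap):
            counter += 1
            block = make_block(f"b{counter:05d}", kind, key, chain, genes)
            if block.match_number >= params.min_match:
                validate_block(
                    block,
                    background,
                    n_shuffles=params.n_shuffles,
                    seed=params.seed + counter,
                    n_genes_a=genome_genes[ga],
                    n_null_anchors=n_null,
                    min_match=params.min_match,
                    density_ratio_min=params.density_ratio_min,
                    alpha=params.alpha,
                )
            else:
                block.valid = False
            if block.valid or keep_invalid:
                blocks.append(block)
    return blocks


# --------------------------------------------------------------------------
# Duplication classification
# --------------------------------------------------------------------------

def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _copy_regions(
    block: SyntenyBlock,
) -> list[tuple[str, tuple[int, int]]]:
    """The two chromosome regions covered by a paralogous block."""
    return [
        (block.chromosome_a, block.rank_span_a),
        (block.chromosome_b, block.rank_span_b),
    ]


def _orthologous_images(
    genome: str,
    chrom: str,
    span: tuple[int, int],
    ortholog_blocks: Sequence[SyntenyBlock],
    target_genome: str,
) -> list[tuple[str, tuple[int, int], str]]:
    """Regions of ``target_genome`` orthologous to (genome, chrom, span).

    A region qualifies when an orthologous block between the two genomes
    has at least one anchor inside the span.
    """
    images = []
    for ob in ortholog_blocks:
        if {ob.genome_a, ob.genome_b} != {genome, target_genome}:
            continue
        if ob.genome_a == genome:
            here_chrom, here_ranks = ob.chromosome_a, [a.rank_a for a in ob.anchors]
            there_chrom, there_span = ob.chromosome_b, ob.rank_span_b
        else:
            here_chrom, here_ranks = ob.chromosome_b, [a.rank_b for a in ob.anchors]
            there_chrom, there_span = ob.chromosome_a, ob.rank_span_a
        if here_chrom != chrom:
            continue
        if any(span[0] <= r <= span[1] for r in here_ranks):
            images.append((there_chrom, there_span, ob.block_id))
    return images


def classify_duplications(
    paralog_blocks: Sequence[SyntenyBlock],
    ortholog_blocks: Sequence[SyntenyBlock],
) -> list[DuplicationCall]:
    """Split duplicated blocks into shared-ancestral vs lineage-specific.

    A duplicated (paralogous) block in genome A descends from a
    pre-speciation duplication when both of its copies lie at positions
    orthologous to the two copies of some duplicated block in another
    genome B; otherwise it is called a post-speciation, lineage-specific
    duplication.
    """
    calls: list[DuplicationCall] = []
    genomes = sorted(
        {b.genome_a for b in paralog_blocks}
        | {b.genome_a for b in ortholog_blocks}
        | {b.genome_b for b in ortholog_blocks}
    )
    for pb in paralog_blocks:
        a_genome = pb.genome_a
        copies = _copy_regions(pb)
        evidence: list[str] = []
        for b_genome in genomes:
            if b_genome == a_genome:
                continue
            images = [
                _orthologous_images(
                    a_genome, chrom, span, ortholog_blocks, b_genome
                )
                for chrom, span in copies
            ]
            if not images[0] or not images[1]:
                continue
            for qb in paralog_blocks:
                if qb.genome_a != b_genome:
                    continue
                q_copies = _copy_regions(qb)
                direct = _match_copies(images[0], q_copies[0]) and _match_copies(
                    images[1], q_copies[1]
                )
                crossed = _match_copies(images[0], q_copies[1]) and _match_copies(
                    images[1], q_copies[0]
                )
                if direct or crossed:
                    evidence.append(qb.block_id)
        status = "ancestral" if evidence else "lineage_specific"
        calls.append(DuplicationCall(block=pb, status=status, evidence=evidence))
    return calls


def _match_copies(
    images: list[tuple[str, tuple[int, int], str]],
    copy_region: tuple[str, tuple[int, int]],
) -> bool:
    chrom, span = copy_region
    return any(
        ichrom == chrom and _spans_overlap(ispan, span)
        for ichrom, ispan, _ in images
    )


# --------------------------------------------------------------------------
# Coverage summaries
# --------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def coverage_summary(
    blocks: Sequence[SyntenyBlock],
    genome: str,
    genome_bp_length: int,
) -> tuple[int, int, int]:
    """(n_anchors, n_blocks, pct genome covered) for one genome.

    Coverage is the per-chromosome union of block bp spans on the genome's
    side(s), divided by the genome's bp length, x100, rounded to integer —
    the orthologs–blocks–%coverage triplet convention.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    n_anchors = 0
    n_blocks = 0
    for b in blocks:
        involved = False
        if b.genome_a == genome:
            by_chrom.setdefault(b.chromosome_a, []).append(b.bp_span_a)
            involved = True
        if b.genome_b == genome:
            by_chrom.setdefault(b.chromosome_b, []).append(b.bp_span_b)
            involved = True
        if involved:
            n_blocks += 1
            n_anchors += b.match_number
    covered = sum(_union_length(iv) for iv in by_chrom.values())
    pct = round(100.0 * covered / genome_bp_length)
    return n_anchors, n_blocks, int(pct)
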