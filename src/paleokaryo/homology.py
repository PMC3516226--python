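"""CIP/CALP alignment filtering and ortholog/paralog calling.

For each gene pair, all HSPs of the pairwise comparison are pooled and
summarised by three quantities:

- AL, the aligned length: the sum of HSP lengths after merging HSPs that
  overlap on the query;
- CIP, the cumulative identity percentage: summed identities over AL, x100;
- CALP, the cumulative aligned-length percentage: AL over the query length,
  x100 (capped at 100).

A pair passes the divergence-dependent filter when both CIP and CALP reach
the threshold for its divergence class: 70% for genomes whose common
ancestor is younger than 50 Myr ("close"), 50% for older splits
("distant").  Among passing candidates, the highest cumulative identity
over the longest cumulative length wins: per query gene and target genome
the best pair is retained, maximising (CIP, CALP) with a deterministic
lexicographic tie-break on the subject id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .formats import HspRecord

DEFAULT_THRESHOLDS = {"close": 70.0, "distant": 50.0}


@dataclass(frozen=True)
class PairAlignment:
    """Pooled alignment summary for one (query, subject) gene pair."""

    query_id: str
    subject_id: str
    query_length: int
    al: float
    cip: float
    calp: float
    n_hsps: int


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    relation: str  # "ortholog" | "paralog"
    cip: float
    calp: float
    divergence_class: str


def merge_hsps(hsps: Sequence[HspRecord]) -> tuple[float, float]:
    """Resolve query-overlapping HSPs and return (AL, summed identities).

    HSPs are consumed in decreasing identity-fraction order; each HSP
    contributes only the part of its query span not already claimed by a
    better HSP, with its aligned length and identity count scaled by the
    surviving fraction of the span.  Disjoint HSPs therefore contribute
    their full length and identities, reproducing the plain AL = sum of HSP
    lengths; a fully shadowed HSP contributes nothing, which keeps CALP
    within 100.
    """
    if not hsps:
        raise ValueError("merge_hsps needs at least one HSP")
    order = sorted(
        hsps,
        key=lambda h: (-h.identities / h.hsp_length, h.query_start, h.query_end),
    )
    claimed: list[tuple[int, int]] = []  # disjoint, sorted query intervals
    al = 0.0
    ids = 0.0
    for h in order:
        span = h.query_end - h.query_start + 1
        uncovered = _uncovered_length(h.query_start, h.query_end, claimed)
        frac = uncovered / span
        al += frac * h.hsp_length
        ids += frac * h.identities
        claimed = _add_interval(claimed, h.query_start, h.query_end)
    return al, ids


def _uncovered_length(start: int, end: int, claimed: list[tuple[int, int]]) -> int:
    length = end - start + 1
    for s, e in claimed:
        lo, hi = max(start, s), min(end, e)
        if lo <= hi:
            length -= hi - lo + 1
    return length


def _add_interval(
    claimed: list[tuple[int, int]], start: int, end: int
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in claimed:
        if e < start - 1 or s > end + 1:
            merged.append((s, e))
        else:
            start, end = min(start, s), max(end, e)
    merged.append((start, end))
    merged.sort()
    return merged


def compute_cip(hsps: Sequence[HspRecord]) -> float:
    """Cumulative identity percentage: 100 x sum(identities) / AL."""
    al, ids = merge_hsps(hsps)
    if al <= 0:
        raise ValueError("zero total aligned length")
    return 100.0 * ids / al


def compute_calp(hsps: Sequence[HspRecord], query_length: int) -> float:
    """Cumulative aligned-length percentage: 100 x AL / query length."""
    if query_length < 1:
        raise ValueError(f"query_length must be >= 1, got {query_length}")
    al, _ = merge_hsps(hsps)
    return min(100.0, 100.0 * al / query_length)


def summarize_pair(
    query_id: str,
    subject_id: str,
    hsps: Sequence[HspRecord],
    query_length: int,
) -> PairAlignment:
    al, ids = merge_hsps(hsps)
    if al <= 0:
        raise ValueError("zero total aligned length")
    return PairAlignment(
        query_id=query_id,
        subject_id=subject_id,
        query_length=query_length,
        al=al,
        cip=100.0 * ids / al,
        calp=min(100.0, 100.0 * al / query_length),
        n_hsps=len(hsps),
    )


def classify_pair(
    cip: float,
    calp: float,
    divergence_class: str,
    thresholds: Optional[Mapping[str, float]] = None,
) -> bool:
    """Apply the divergence-dependent CIP/CALP filter (inclusive bounds)."""
    thresholds = thresholds or DEFAULT_THRESHOLDS
    if divergence_class not in thresholds:
        raise ValueError(f"unknown divergence class {divergence_class!r}")
    if not (0 <= cip <= 100 and 0 <= calp <= 100):
        raise ValueError("CIP/CALP must lie in [0, 100]")
    t = thresholds[divergence_class]
    return cip >= t and calp >= t


def call_homologs(
    pair_alignments: Iterable[PairAlignment],
    genome_map: Mapping[str, str],
    divergence_table: Mapping[tuple[str, str], str],
    thresholds: Optional[Mapping[str, float]] = None,
    reciprocal: bool = False,
) -> list[HomologPair]:
    """Filter pooled alignments and retain best hits per (query, genome).

    ``genome_map`` maps gene id -> genome id; ``divergence_table`` maps an
    unordered genome pair (also (g, g) for within-genome paralog search) to
    a divergence class.  Self-hits are discarded, paralog pairs are
    deduplicated as unordered pairs, and with ``reciprocal=True`` only
    pairs that are each other's best hit survive.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS

    def genome_of(gene: str) -> str:
        if gene not in genome_map:
            raise KeyError(f"gene {gene!r} absent from genome map")
        return genome_map[gene]

    def div_class(ga: str, gb: str) -> str:
        for key in ((ga, gb), (gb, ga)):
            if key in divergence_table:
                return divergence_table[key]
        raise KeyError(f"no divergence class for genome pair ({ga}, {gb})")

    # best passing candidate per (query gene, subject genome)
    best: dict[tuple[str, str], PairAlignment] = {}
    for pa in pair_alignments:
        if pa.query_id == pa.subject_id:
            continue
        ga, gb = genome_of(pa.query_id), genome_of(pa.subject_id)
        dclass = div_class(ga, gb)
        if not classify_pair(pa.cip, pa.calp, dclass, thresholds):
            continue
        key = (pa.query_id, gb)
        cur = best.get(key)
        if cur is None or _better(pa, cur):
            best[key] = pa

    if reciprocal:
        best = {
            key: pa
            for key, pa in best.items()
            if _is_reciprocal(pa, best, genome_map)
        }

    out: list[HomologPair] = []
    seen_paralog: set[tuple[str, str]] = set()
    for (query, _), pa in sorted(best.items()):
        ga, gb = genome_of(pa.query_id), genome_of(pa.subject_id)
        relation = "paralog" if ga == gb else "ortholog"
        if relation == "paralog":
            pair_key = tuple(sorted((pa.query_id, pa.subject_id)))
            if pair_key in seen_paralog:
                continue
            seen_paralog.add(pair_key)
        out.append(
            HomologPair(
                gene_a=pa.query_id,
                gene_b=pa.subject_id,
                relation=relation,
                cip=pa.cip,
                calp=pa.calp,
                divergence_class=div_class(ga, gb),
            )
        )
    return out


def _better(a: PairAlignment, b: PairAlignment) -> bool:
    """Selection order: highest CIP, then highest CALP, then smallest id."""
    return (-a.cip, -a.calp, a.subject_id) < (-b.cip, -b.calp, b.subject_id)


def _is_reciprocal(
    pa: PairAlignment,
    best: Mapping[tuple[str, str], PairAlignment],
    genome_map: Mapping[str, str],
) -> bool:
    back = best.get((pa.subject_id, genome_map[pa.query_id]))
    return back is not None and back.subject_id == pa.query_id
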