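"""Karyotype event calculus.

Chromosomes are modelled as signed sequences of ancestral segments.  Each
segment carries the colour of the founder protochromosome it descends from,
a copy index distinguishing the products of whole-genome duplications, and
an orientation.  Events (whole-genome duplication, fission, fusion,
inversion, translocation, deletion) transform karyotypes while obeying a
strict chromosome-count law:

    n_final = n_0 + #fissions - #fusions,

with every WGD doubling the running count at the point where it occurs.
Fusions come in two modes: telomeric (TCF, end-to-end joining, the dominant
mode in vertebrates) and centromeric/nested (CCF, insertion of one
chromosome into the body of another, the dominant mode in plants).  A
nested fusion is accounting-equivalent to one fission plus two telomeric
fusions.

The module also provides an exact breadth-first parsimony search for the
smallest event scenario transforming one karyotype into another, and a
greedy heuristic that yields a valid (replayable) upper-bound scenario.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence


# --------------------------------------------------------------------------
# Core types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One ancestral-colour segment: (colour, copy index, orientation)."""

    color: str
    copy: int = 0
    orient: int = 1

    def flipped(self) -> "Segment":
        return replace(self, orient=-self.orient)


@dataclass(frozen=True)
class Chromosome:
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a chromosome needs at least one segment")

    def reversed(self) -> "Chromosome":
        return Chromosome(tuple(s.flipped() for s in reversed(self.segments)))

    def colors(self) -> tuple[str, ...]:
        return tuple(s.color for s in self.segments)

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class Karyotype:
    chromosomes: tuple[Chromosome, ...]
    name: str = ""

    @property
    def n(self) -> int:
        return len(self.chromosomes)

    def segment_multiset(self) -> dict[tuple[str, int], int]:
        out: dict[tuple[str, int], int] = {}
        for chrom in self.chromosomes:
            for seg in chrom.segments:
                key = (seg.color, seg.copy)
                out[key] = out.get(key, 0) + 1
        return out

    def canonical(self) -> tuple[tuple[tuple[str, int, int], ...], ...]:
        """Order-free canonical form used for BFS state hashing.

        Each chromosome is normalised so that the lexicographically smaller
        of its two reading directions is kept; chromosomes are then sorted.
        """
        chroms = []
        for chrom in self.chromosomes:
            fwd = tuple((s.color, s.copy, s.orient) for s in chrom.segments)
            rev = tuple(
                (s.color, s.copy, s.orient) for s in chrom.reversed().segments
            )
            chroms.append(min(fwd, rev))
        return tuple(sorted(chroms))


def karyotype_from_colors(
    chromosomes: Sequence[Sequence[str]], name: str = ""
) -> Karyotype:
    """Build a karyotype from plain colour lists (copy 0, forward strand)."""
    return Karyotype(
        tuple(
            Chromosome(tuple(Segment(c) for c in chrom))
            for chrom in chromosomes
        ),
        name=name,
    )


# --------------------------------------------------------------------------
# Events
# --------------------------------------------------------------------------

EVENT_KINDS = {
    "WGD",
    "Cfis",
    "Cfus_TCF",
    "Cfus_CCF",
    "inversion",
    "translocation",
    "deletion",
}


@dataclass(frozen=True)
class Event:
    """A single karyotype operation.

    Operand semantics (chromosome indices refer to the karyotype at
    application time; breakpoints are between-segment positions):

    - ``WGD``: no operands.
    - ``Cfis``: ``chrom``, ``pos`` (1..len-1) — split into [:pos] and [pos:].
    - ``Cfus_TCF``: ``chrom_a``, ``chrom_b``, optional ``flip_a``/``flip_b``
      — end-to-end joining; the joined chromosome is a (optionally reversed)
      followed by b (optionally reversed).
    - ``Cfus_CCF``: ``chrom_a``, ``chrom_b``, ``pos`` (1..len(a)-1),
      optional ``flip_b`` — insertion of b into the body of a at ``pos``.
    - ``inversion``: ``chrom``, ``start``, ``end`` (segment slice, end
      exclusive) — reverse and flip the span.
    - ``translocation``: ``chrom_a``, ``chrom_b``, ``pos_a``, ``pos_b`` —
      reciprocal tail exchange (count-neutral).
    - ``deletion``: ``chrom``, ``start``, ``end`` — drop the span (the
      chromosome must keep at least one segment); count-neutral.
    """

    kind: str
    operands: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")

    # frozen dataclass with a dict field: hash on the sorted item tuple
    def __hash__(self) -> int:  # pragma: no cover - trivial
        return hash((self.kind, tuple(sorted(self.operands.items()))))


class EventError(ValueError):
    """Raised when an event's operands are invalid for the karyotype."""


def _check_chrom(k: Karyotype, idx: int) -> Chromosome:
    if not 0 <= idx < k.n:
        raise EventError(f"chromosome index {idx} out of range (n={k.n})")
    return k.chromosomes[idx]


def apply_event(karyotype: Karyotype, event: Event) -> Karyotype:
    """Apply one event, enforcing the chromosome-count law.

    WGD: n -> 2n; Cfis: n -> n+1; either fusion mode: n -> n-1;
    inversion / translocation / deletion leave n unchanged.
    """
    ops = event.operands
    chroms = list(karyotype.chromosomes)

    if event.kind == "WGD":
        offset = 1 + max(
            (s.copy for c in chroms for s in c.segments), default=0
        )
        dups = [
            Chromosome(tuple(replace(s, copy=s.copy + offset) for s in c.segments))
            for c in chroms
        ]
        return Karyotype(tuple(chroms + dups), name=karyotype.name)

    if event.kind == "Cfis":
        chrom = _check_chrom(karyotype, ops["chrom"])
        pos = ops["pos"]
        if not 1 <= pos <= len(chrom) - 1:
            raise EventError(
                f"fission breakpoint {pos} outside chromosome of {len(chrom)} segments"
            )
        chroms[ops["chrom"]] = Chromosome(chrom.segments[:pos])
        chroms.append(Chromosome(chrom.segments[pos:]))
        return Karyotype(tuple(chroms), name=karyotype.name)

    if event.kind == "Cfus_TCF":
        ia, ib = ops["chrom_a"], ops["chrom_b"]
        if ia == ib:
            raise EventError("cannot fuse a chromosome with itself")
        a, b = _check_chrom(karyotype, ia), _check_chrom(karyotype, ib)
        if ops.get("flip_a"):
            a = a.reversed()
        if ops.get("flip_b"):
            b = b.reversed()
        fused = Chromosome(a.segments + b.segments)
        return Karyotype(
            tuple(
                c for i, c in enumerate(chroms) if i not in (ia, ib)
            ) + (fused,),
            name=karyotype.name,
        )

    if event.kind == "Cfus_CCF":
        ia, ib = ops["chrom_a"], ops["chrom_b"]
        if ia == ib:
            raise EventError("cannot fuse a chromosome with itself")
        a, b = _check_chrom(karyotype, ia), _check_chrom(karyotype, ib)
        pos = ops["pos"]
        if not 1 <= pos <= len(a) - 1:
            raise EventError(
                f"insertion point {pos} not interior to chromosome of {len(a)} segments"
            )
        if ops.get("flip_b"):
            b = b.reversed()
        fused = Chromosome(a.segments[:pos] + b.segments + a.segments[pos:])
        return Karyotype(
            tuple(
                c for i, c in enumerate(chroms) if i not in (ia, ib)
            ) + (fused,),
            name=karyotype.name,
        )

    if event.kind == "inversion":
        chrom = _check_chrom(karyotype, ops["chrom"])
        start, end = ops["start"], ops["end"]
        if not (0 <= start < end <= len(chrom)):
            raise EventError(f"inversion span [{start}, {end}) invalid")
        inner = tuple(s.flipped() for s in reversed(chrom.segments[start:end]))
        chroms[ops["chrom"]] = Chromosome(
            chrom.segments[:start] + inner + chrom.segments[end:]
        )
        return Karyotype(tuple(chroms), name=karyotype.name)

    if event.kind == "translocation":
        ia, ib = ops["chrom_a"], ops["chrom_b"]
        if ia == ib:
            raise EventError("translocation needs two distinct chromosomes")
        a, b = _check_chrom(karyotype, ia), _check_chrom(karyotype, ib)
        pa, pb = ops["pos_a"], ops["pos_b"]
        if not (1 <= pa <= len(a) - 1) or not (1 <= pb <= len(b) - 1):
            raise EventError("translocation breakpoints must be interior")
        chroms[ia] = Chromosome(a.segments[:pa] + b.segments[pb:])
        chroms[ib] = Chromosome(b.segments[:pb] + a.segments[pa:])
        return Karyotype(tuple(chroms), name=karyotype.name)

    if event.kind == "deletion":
        chrom = _check_chrom(karyotype, ops["chrom"])
        start, end = ops["start"], ops["end"]
        if not (0 <= start < end <= len(chrom)):
            raise EventError(f"deletion span [{start}, {end}) invalid")
        kept = chrom.segments[:start] + chrom.segments[end:]
        if not kept:
            raise EventError("deletion would remove the whole chromosome")
        chroms[ops["chrom"]] = Chromosome(kept)
        return Karyotype(tuple(chroms), name=karyotype.name)

    raise EventError(f"unhandled event kind {event.kind!r}")


def replay(
    start: Karyotype, events: Iterable[Event]
) -> tuple[Karyotype, list[int]]:
    """Left-fold of :func:`apply_event`; returns (final karyotype, n trace).

    The trace includes the starting count, so ``trace[0] == start.n`` and
    ``trace[-1] == final.n``.
    """
    k = start
    trace = [k.n]
    for i, ev in enumerate(events):
        try:
            k = apply_event(k, ev)
        except EventError as exc:
            raise EventError(f"event {i} ({ev.kind}): {exc}") from exc
        trace.append(k.n)
    return k, trace


# --------------------------------------------------------------------------
# Pure count arithmetic
# --------------------------------------------------------------------------

def count_trace(
    n0: int, steps: Iterable[tuple[str, int] | str]
) -> tuple[int, list[int]]:
    """Chromosome-count arithmetic without segment tracking.

    ``steps`` is a list of ``"WGD"`` or ``("fis", k)`` / ``("fus", k)``
    entries.  A WGD doubles the running count, k fissions add k, k fusions
    subtract k.  Raises if the count ever drops to zero.

    Returns (final count, full trace including n0).
    """
    n = n0
    if n < 1:
        raise ValueError("starting chromosome number must be >= 1")
    trace = [n]
    for step in steps:
        if step == "WGD" or step == ("WGD",):
            n *= 2
        else:
            kind, k = step  # type: ignore[misc]
            if kind == "fis":
                n += k
            elif kind == "fus":
                n -= k
            else:
                raise ValueError(f"unknown count step {step!r}")
        if n < 1:
            raise ValueError(f"chromosome count fell to {n} after {step!r}")
        trace.append(n)
    return n, trace


# --------------------------------------------------------------------------
# Fusion-mode classification
# --------------------------------------------------------------------------

#: Elementary-operation accounting of one nested (centromeric) fusion.
CCF_ELEMENTARY_STEPS = {"Cfis": 1, "Cfus": 2}


def classify_fusion(
    pre_chromosomes: Sequence[Chromosome], post_chromosome: Chromosome
) -> str:
    """Classify a fusion product as ``"TCF"``, ``"CCF"`` or ``"complex"``.

    Membership of each post-fusion segment is traced back to the two parent
    chromosomes.  An A+B+ (or B+A+) run pattern is an end-to-end telomeric
    fusion; A+B+A+ (one parent split around a nested intact parent) is a
    centromeric/nested fusion; anything else is reported as complex.
    """
    if len(pre_chromosomes) != 2:
        raise ValueError("fusion classification needs exactly two parents")

    pools: list[list[Segment]] = [
        list(c.segments) for c in pre_chromosomes
    ]
    membership: list[int] = []
    for seg in post_chromosome.segments:
        assigned = False
        for which, pool in enumerate(pools):
            for cand in pool:
                if cand.color == seg.color and cand.copy == seg.copy:
                    pool.remove(cand)
                    membership.append(which)
                    assigned = True
                    break
            if assigned:
                break
        if not assigned:
            return "complex"
    if any(pools[0]) or any(pools[1]):
        return "complex"

    runs = [m for m, _ in itertools.groupby(membership)]
    if len(runs) == 2:
        return "TCF"
    if len(runs) == 3 and runs[0] == runs[2]:
        return "CCF"
    return "complex"


# --------------------------------------------------------------------------
# Parsimony search
# --------------------------------------------------------------------------

@dataclass
class Scenario:
    start: Karyotype
    events: list[Event]
    end: Karyotype
    mode: str = "exact"  # "exact" | "heuristic"

    @property
    def n_events(self) -> int:
        return len(self.events)

    def verify(self) -> bool:
        final, _ = replay(self.start, self.events)
        return final.canonical() == self.end.canonical()


def _neighbour_moves(k: Karyotype) -> Iterator[tuple[Event, Karyotype]]:
    """All single-event successors used by the exact search.

    The move set is fissions at every breakpoint, telomeric fusions of every
    ordered chromosome pair in both orientations of the second partner,
    nested fusions at every interior insertion point, and inversions of
    every contiguous span.
    """
    for i, chrom in enumerate(k.chromosomes):
        for pos in range(1, len(chrom)):
            ev = Event("Cfis", {"chrom": i, "pos": pos})
            yield ev, apply_event(k, ev)
        for start in range(len(chrom)):
            for end in range(start + 1, len(chrom) + 1):
                if start == 0 and end == len(chrom):
                    continue  # whole-chromosome flip is a no-op under canonicalisation
                ev = Event("inversion", {"chrom": i, "start": start, "end": end})
                yield ev, apply_event(k, ev)
    for ia, ib in itertools.permutations(range(k.n), 2):
        for flip_b in (False, True):
            ev = Event(
                "Cfus_TCF", {"chrom_a": ia, "chrom_b": ib, "flip_b": flip_b}
            )
            yield ev, apply_event(k, ev)
        a = k.chromosomes[ia]
        for pos in range(1, len(a)):
            for flip_b in (False, True):
                ev = Event(
                    "Cfus_CCF",
                    {"chrom_a": ia, "chrom_b": ib, "pos": pos, "flip_b": flip_b},
                )
                yield ev, apply_event(k, ev)


def _adjacency_multiset(k: Karyotype) -> dict[tuple, int]:
    """Multiset of internal segment adjacencies, orientation-normalised.

    An adjacency between consecutive segments is identified with its
    reverse-complement reading, so it is invariant under whole-chromosome
    flips.
    """
    out: dict[tuple, int] = {}
    for chrom in k.chromosomes:
        for a, b in zip(chrom.segments, chrom.segments[1:]):
            fwd = ((a.color, a.copy, a.orient), (b.color, b.copy, b.orient))
            rev = (
                (b.color, b.copy, -b.orient),
                (a.color, a.copy, -a.orient),
            )
            key = min(fwd, rev)
            out[key] = out.get(key, 0) + 1
    return out


def _parsimony_lower_bound(
    current: Karyotype,
    cur_adj: dict[tuple, int],
    target_n: int,
    tgt_adj: dict[tuple, int],
) -> int:
    """Admissible lower bound on the remaining event count.

    Every event changes the chromosome number by at most one, creates at
    most two target adjacencies (a nested fusion or an inversion), and
    destroys at most two non-target adjacencies.
    """
    missing = sum(
        max(0, c - cur_adj.get(adj, 0)) for adj, c in tgt_adj.items()
    )
    excess = sum(
        max(0, c - tgt_adj.get(adj, 0)) for adj, c in cur_adj.items()
    )
    return max(
        abs(current.n - target_n),
        (missing + 1) // 2,
        (excess + 1) // 2,
    )


def infer_min_events(
    start: Karyotype,
    target: Karyotype,
    budget: int = 6,
    mode: str = "exact",
) -> Optional[Scenario]:
    """Find a smallest event scenario from ``start`` to ``target``.

    Exact mode runs a best-first search (A*) over canonicalised karyotypes
    with an admissible adjacency/chromosome-count lower bound, so the
    returned scenario is provably minimal; it returns ``None`` when the
    target is unreachable within ``budget`` events.  Heuristic mode returns
    a valid upper-bound scenario (never shorter than the exact minimum): it
    cuts every chromosome into single ancestral segments, fixes
    orientations, and reassembles the target chromosomes end-to-end.
    """
    import heapq

    start_ms = start.segment_multiset()
    if start_ms != target.segment_multiset():
        raise ValueError(
            "start and target karyotypes carry different segment multisets"
        )
    if mode == "heuristic":
        return _heuristic_scenario(start, target)
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")

    goal = target.canonical()
    tgt_adj = _adjacency_multiset(target)

    def h(k: Karyotype) -> int:
        return _parsimony_lower_bound(k, _adjacency_multiset(k), target.n, tgt_adj)

    if start.canonical() == goal:
        return Scenario(start, [], target, mode="exact")

    counter = itertools.count()
    open_heap: list = [(h(start), 0, next(counter), start, [])]
    best_g: dict = {start.canonical(): 0}
    while open_heap:
        f, g, _, k, path = heapq.heappop(open_heap)
        canon = k.canonical()
        if canon == goal:
            return Scenario(start, path, target, mode="exact")
        if f > budget:
            return None
        if g > best_g.get(canon, g):
            continue  # stale queue entry
        for ev, nxt in _neighbour_moves(k):
            nc = nxt.canonical()
            ng = g + 1
            if ng >= best_g.get(nc, budget + 2):
                continue
            best_g[nc] = ng
            nf = ng + h(nxt)
            if nf <= budget:
                heapq.heappush(
                    open_heap, (nf, ng, next(counter), nxt, path + [ev])
                )
    return None


def _heuristic_scenario(start: Karyotype, target: Karyotype) -> Scenario:
    """Cut-and-reassemble upper bound.

    Fission every multi-segment chromosome down to singletons, flip
    reversed singletons, then fuse singletons left-to-right into each
    target chromosome.  Always valid, rarely minimal.
    """
    events: list[Event] = []
    k = start
    # 1. cut everything to singletons
    changed = True
    while changed:
        changed = False
        for i, chrom in enumerate(k.chromosomes):
            if len(chrom) > 1:
                ev = Event("Cfis", {"chrom": i, "pos": 1})
                events.append(ev)
                k = apply_event(k, ev)
                changed = True
                break
    # 2. orient singletons forward
    for i, chrom in enumerate(k.chromosomes):
        if chrom.segments[0].orient == -1:
            ev = Event("inversion", {"chrom": i, "start": 0, "end": 1})
            events.append(ev)
            k = apply_event(k, ev)

    # 3. reassemble each target chromosome
    def find_singleton(kary: Karyotype, color: str, copy: int) -> int:
        for i, chrom in enumerate(kary.chromosomes):
            if (
                len(chrom) == 1
                and chrom.segments[0].color == color
                and chrom.segments[0].copy == copy
            ):
                return i
        raise RuntimeError("singleton bookkeeping error in heuristic")

    for tchrom in target.chromosomes:
        segs = list(tchrom.segments)
        # growing chromosome is rebuilt by fusing the next singleton on
        first = segs[0]
        cur = find_singleton(k, first.color, first.copy)
        if k.chromosomes[cur].segments[0].orient != first.orient:
            ev = Event("inversion", {"chrom": cur, "start": 0, "end": 1})
            events.append(ev)
            k = apply_event(k, ev)
        for seg in segs[1:]:
            nxt = find_singleton(k, seg.color, seg.copy)
            flip = k.chromosomes[nxt].segments[0].orient != seg.orient
            ev = Event(
                "Cfus_TCF", {"chrom_a": cur, "chrom_b": nxt, "flip_b": flip}
            )
            events.append(ev)
            k = apply_event(k, ev)
            cur = k.n - 1  # fusion product is appended last
    return Scenario(start, events, target, mode="heuristic")
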