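"""Readers and writers for the external representations the pipeline touches.

Supported formats:

- BLAST tabular alignments (outfmt-6-like, one row per HSP), in the plain
  12-column dialect with a percent-identity column, or an extended dialect
  with an explicit ``nident`` identity-count column appended.
- Gene-order tables (TSV: genome, chromosome, gene_id, start, end, strand,
  optional cds_length) and GFF3 with ``gene`` features.
- GFF3 transposable-element annotations (``te_class=`` attribute).
- Synteny-block and contiguous-ancestral-region (CAR) TSV tables, plus BED
  export of blocks.

All coordinates are 1-based inclusive base pairs internally, following the
GFF3 convention.  Gene ranks are 0-based indices in the gene order along a
chromosome, assigned by ascending start coordinate (ties broken by gene id).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

TE_CLASSES = ("classI_LTR", "classI_nonLTR", "classII")


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HspRecord:
    """One local alignment fragment (high-scoring pair)."""

    query_id: str
    subject_id: str
    hsp_length: int
    identities: int
    query_start: int
    query_end: int
    bit_score: float = 0.0
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if self.hsp_length < 1:
            raise ValueError(
                f"HSP {self.query_id}/{self.subject_id}: length must be >= 1"
            )
        if not 0 <= self.identities <= self.hsp_length:
            raise ValueError(
                f"HSP {self.query_id}/{self.subject_id}: identities "
                f"{self.identities} outside [0, {self.hsp_length}]"
            )
        if self.query_start > self.query_end:
            raise ValueError(
                f"HSP {self.query_id}/{self.subject_id}: query_start > query_end"
            )


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    genome_id: str
    chromosome_id: str
    rank: int
    start: int
    end: int
    strand: int
    cds_length: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in (1, -1):
            raise ValueError(f"gene {self.gene_id}: strand must be +1/-1")


@dataclass(frozen=True)
class TeRecord:
    genome_id: str
    chromosome_id: str
    start: int
    end: int
    te_class: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("TE record: start > end")
        if self.te_class not in TE_CLASSES:
            raise ValueError(
                f"TE class {self.te_class!r} not in {TE_CLASSES}"
            )


class FormatError(ValueError):
    pass


# --------------------------------------------------------------------------
# HSP tables
# --------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    # percent-identity -> identity count; reversible to 1 decimal for
    # lengths <= 5000
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def read_hsp_table(path: str | Path, dialect: str = "pct") -> list[HspRecord]:
    """Read a BLAST tabular file into HSP records.

    ``dialect="pct"`` is the standard 12-column layout (qseqid sseqid pident
    length mismatch gapopen qstart qend sstart send evalue bitscore); the
    identity count is reconstructed as ``round(pident/100 * length)``.
    ``dialect="nident"`` expects a 13th column holding the identity count.
    """
    if dialect not in ("pct", "nident"):
        raise FormatError(f"unknown HSP dialect {dialect!r}")
    min_cols = 12 if dialect == "pct" else 13
    records: list[HspRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= {min_cols} columns, "
                    f"got {len(parts)}"
                )
            try:
                length = int(parts[3])
                if dialect == "pct":
                    identities = _round_half_away(float(parts[2]) / 100.0 * length)
                else:
                    identities = int(parts[12])
                rec = HspRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    hsp_length=length,
                    identities=identities,
                    query_start=int(parts[6]),
                    query_end=int(parts[7]),
                    e_value=float(parts[10]),
                    bit_score=float(parts[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_hsp_table(
    records: Iterable[HspRecord], path: str | Path, dialect: str = "nident"
) -> None:
    """Write HSP records in the tabular dialect read by :func:`read_hsp_table`.

    Subject coordinates are not tracked by :class:`HspRecord`; placeholder
    columns equal to the query coordinates are emitted to keep the column
    count canonical.
    """
    with open(path, "w") as fh:
        for r in records:
            pident = 100.0 * r.identities / r.hsp_length
            row = [
                r.query_id, r.subject_id, f"{pident:.2f}", str(r.hsp_length),
                str(r.hsp_length - r.identities), "0",
                str(r.query_start), str(r.query_end),
                str(r.query_start), str(r.query_end),
                f"{r.e_value:.3g}", f"{r.bit_score:.1f}",
            ]
            if dialect == "nident":
                row.append(str(r.identities))
            fh.write("\t".join(row) + "\n")


def group_hsps(
    records: Iterable[HspRecord],
) -> dict[tuple[str, str], list[HspRecord]]:
    """Group HSP rows by (query_id, subject_id) pair, preserving order."""
    groups: dict[tuple[str, str], list[HspRecord]] = {}
    for rec in records:
        groups.setdefault((rec.query_id, rec.subject_id), []).append(rec)
    return groups


# --------------------------------------------------------------------------
# Gene orders
# --------------------------------------------------------------------------

GENE_ORDER_COLUMNS = [
    "genome_id", "chromosome_id", "gene_id", "start", "end", "strand",
    "cds_length",
]


def _assign_ranks(genes: list[dict]) -> list[GeneRecord]:
    by_chrom: dict[tuple[str, str], list[dict]] = {}
    seen: dict[str, set[str]] = {}
    for g in genes:
        key = (g["genome_id"], g["chromosome_id"])
        by_chrom.setdefault(key, []).append(g)
        ids = seen.setdefault(g["genome_id"], set())
        if g["gene_id"] in ids:
            raise FormatError(
                f"duplicate gene id {g['gene_id']!r} in genome {g['genome_id']!r}"
            )
        ids.add(g["gene_id"])
    out: list[GeneRecord] = []
    for key in sorted(by_chrom):
        rows = sorted(by_chrom[key], key=lambda g: (g["start"], g["gene_id"]))
        for rank, g in enumerate(rows):
            out.append(GeneRecord(rank=rank, **g))
    return out


def read_gene_order(path: str | Path) -> dict[str, list[GeneRecord]]:
    """Read a gene-order TSV into per-genome rank-ordered gene tables.

    Columns: genome_id, chromosome_id, gene_id, start, end, strand
    (``+``/``-`` or ``1``/``-1``), optional cds_length.  Ranks are assigned
    by ascending start per chromosome, ties broken by gene id.
    """
    raw: list[dict] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "gene_id" not in reader.fieldnames:
            raise FormatError(f"{path}: missing gene-order header")
        for row in reader:
            strand_raw = row["strand"]
            strand = 1 if strand_raw in ("+", "1", "+1") else -1
            raw.append(
                dict(
                    genome_id=row["genome_id"],
                    chromosome_id=row["chromosome_id"],
                    gene_id=row["gene_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=strand,
                    cds_length=int(row.get("cds_length") or 0),
                )
            )
    records = _assign_ranks(raw)
    out: dict[str, list[GeneRecord]] = {}
    for rec in records:
        out.setdefault(rec.genome_id, []).append(rec)
    return out


def write_gene_order(
    genes: Mapping[str, Sequence[GeneRecord]] | Sequence[GeneRecord],
    path: str | Path,
) -> None:
    if isinstance(genes, Mapping):
        flat = [g for gs in genes.values() for g in gs]
    else:
        flat = list(genes)
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_ORDER_COLUMNS) + "\n")
        for g in flat:
            strand = "+" if g.strand == 1 else "-"
            fh.write(
                f"{g.genome_id}\t{g.chromosome_id}\t{g.gene_id}\t"
                f"{g.start}\t{g.end}\t{strand}\t{g.cds_length}\n"
            )


# --------------------------------------------------------------------------
# GFF3 (genes + TEs)
# --------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(
    path: str | Path, genome_id: Optional[str] = None
) -> tuple[dict[str, list[GeneRecord]], list[TeRecord]]:
    """Read gene and TE features from a GFF3 file.

    Gene features (type ``gene``) need an ``ID=`` attribute; TE features
    (type ``transposable_element``) need a ``te_class=`` attribute from
    {classI_LTR, classI_nonLTR, classII}.  The genome id is taken from the
    ``genome=`` attribute when present, else from the ``genome_id``
    argument.
    """
    raw_genes: list[dict] = []
    tes: list[TeRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 GFF3 columns"
                )
            seqid, _, ftype, start, end, _, strand, _, attr_text = parts
            attrs = _parse_attributes(attr_text)
            gid = attrs.get("genome", genome_id)
            if gid is None:
                raise FormatError(
                    f"{path}: line {lineno}: no genome id (pass genome_id= "
                    "or add a genome= attribute)"
                )
            if ftype == "gene":
                if "ID" not in attrs:
                    raise FormatError(
                        f"{path}: line {lineno}: gene feature without ID="
                    )
                raw_genes.append(
                    dict(
                        genome_id=gid,
                        chromosome_id=seqid,
                        gene_id=attrs["ID"],
                        start=int(start),
                        end=int(end),
                        strand=1 if strand != "-" else -1,
                        cds_length=int(attrs.get("cds_length", 0) or 0),
                    )
                )
            elif ftype == "transposable_element":
                if "te_class" not in attrs:
                    raise FormatError(
                        f"{path}: line {lineno}: TE feature without te_class="
                    )
                tes.append(
                    TeRecord(
                        genome_id=gid,
                        chromosome_id=seqid,
                        start=int(start),
                        end=int(end),
                        te_class=attrs["te_class"],
                    )
                )
    genes: dict[str, list[GeneRecord]] = {}
    for rec in _assign_ranks(raw_genes):
        genes.setdefault(rec.genome_id, []).append(rec)
    return genes, tes


def write_gff3(
    genes: Sequence[GeneRecord],
    tes: Sequence[TeRecord],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = "+" if g.strand == 1 else "-"
            fh.write(
                f"{g.chromosome_id}\tpaleokaryo\tgene\t{g.start}\t{g.end}\t.\t"
                f"{strand}\t.\tID={g.gene_id};genome={g.genome_id};"
                f"cds_length={g.cds_length}\n"
            )
        for t in tes:
            fh.write(
                f"{t.chromosome_id}\tpaleokaryo\ttransposable_element\t"
                f"{t.start}\t{t.end}\t.\t+\t.\tgenome={t.genome_id};"
                f"te_class={t.te_class}\n"
            )


# --------------------------------------------------------------------------
# Block / CAR tables
# --------------------------------------------------------------------------

BLOCK_COLUMNS = [
    "block_id", "kind", "genome_a", "chromosome_a", "genome_b",
    "chromosome_b", "rank_start_a", "rank_end_a", "rank_start_b",
    "rank_end_b", "bp_start_a", "bp_end_a", "bp_start_b", "bp_end_b",
    "n_anchors", "orientation", "density_ratio", "p_value",
]


def write_block_table(
    blocks: Sequence,
    path: str | Path,
    summaries: Optional[Mapping[tuple[str, str], tuple[int, int, int]]] = None,
) -> None:
    """Write blocks as TSV, one row per block.

    Summary rows (``# summary  genome_a  genome_b  n_anchors-n_blocks-pct``)
    mirror the orthologs–blocks–%coverage triplet reporting convention.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(BLOCK_COLUMNS) + "\n")
        for b in blocks:
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        b.block_id, b.kind, b.genome_a, b.chromosome_a,
                        b.genome_b, b.chromosome_b,
                        b.rank_span_a[0], b.rank_span_a[1],
                        b.rank_span_b[0], b.rank_span_b[1],
                        b.bp_span_a[0], b.bp_span_a[1],
                        b.bp_span_b[0], b.bp_span_b[1],
                        b.match_number, b.orientation,
                        f"{b.density_ratio:.4g}" if b.density_ratio is not None else "NA",
                        f"{b.p_value:.4g}" if b.p_value is not None else "NA",
                    ]
                )
                + "\n"
            )
        if summaries is not None:
            for (ga, gb), (n_anchors, n_blocks, pct) in sorted(summaries.items()):
                fh.write(
                    f"# summary\t{ga}\t{gb}\t{n_anchors}-{n_blocks}-{pct}\n"
                )


def read_block_table(path: str | Path) -> pd.DataFrame:
    """Read a block TSV back into a DataFrame (summary rows skipped)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(BLOCK_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing block columns {sorted(missing)}")
    return df


def write_block_bed(blocks: Sequence, path: str | Path, side: str = "a") -> None:
    """Export block spans on one genome side as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for b in blocks:
            chrom = b.chromosome_a if side == "a" else b.chromosome_b
            bp = b.bp_span_a if side == "a" else b.bp_span_b
            fh.write(f"{chrom}\t{bp[0] - 1}\t{bp[1]}\t{b.block_id}\n")


CAR_COLUMNS = ["car_id", "position", "segment_id", "orientation", "support"]


def write_car_table(cars: Sequence, path: str | Path) -> None:
    """Write contiguous ancestral regions, one row per ordered segment."""
    with open(path, "w") as fh:
        fh.write("\t".join(CAR_COLUMNS) + "\n")
        for car in cars:
            for pos, (seg_id, orient) in enumerate(car.segments):
                support = car.supports[pos] if pos < len(car.supports) else 0
                fh.write(
                    f"{car.car_id}\t{pos}\t{seg_id}\t{orient}\t{support}\n"
                )


def read_car_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CAR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing CAR columns {sorted(missing)}")
    return df
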