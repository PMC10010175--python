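"""Genomic domain types, interval arithmetic and annotation/alignment I/O.

Coordinates are 0-based, half-open everywhere inside the package (BED
convention).  GTF input (1-based, end-inclusive) is converted on read.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: reserved bucket key for reads that overlap no annotated gene span
INTERGENIC = "__intergenic__"

_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 when on different chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class AlignedRead:
    """A uniquely mapped read reduced to its genomic interval."""

    interval: GenomicInterval
    read_id: str
    sample_id: str
    replicate_id: int


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: Optional[GenomicInterval] = None  # genomic span of the coding region

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons disagree on chrom/strand"
            )
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
                )
        if self.cds is not None:
            if self.cds.chrom != self.chrom:
                raise ValueError(f"transcript {self.transcript_id}: CDS on wrong chrom")
            if self.cds.start < self.span.start or self.cds.end > self.span.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS outside exon span"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        out = []
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start > prev.end:
                out.append(GenomicInterval(self.chrom, prev.end, cur.start, self.strand))
        return out

    @property
    def is_coding(self) -> bool:
        return self.cds is not None


@dataclass
class GeneModel:
    gene_id: str
    biotype: str  # protein_coding | lncRNA | other
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand


class AnnotationSet:
    """Gene models indexed for ≥1 bp span-overlap lookup by chrom (and strand)."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {gene.gene_id}")
            self.genes[gene.gene_id] = gene
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            span = gene.span
            tree[span.start:span.end] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def lookup(
        self, interval: GenomicInterval, ignore_strand: bool = False
    ) -> list[GeneModel]:
        """Genes whose span overlaps ``interval`` by at least one base."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree[interval.start:interval.end]]
        if not ignore_strand and interval.strand != ".":
            hits = [g for g in hits if g.strand in (interval.strand, ".")]
        return sorted(hits, key=lambda g: g.gene_id)


def _parse_gtf_line(raw: str, lineno: int):
    fields = raw.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise ValueError(
            f"GTF parse error at line {lineno}: expected 9 tab-separated fields, "
            f"got {len(fields)}"
        )
    try:
        start_1 = int(fields[3])
        end = int(fields[4])
    except ValueError as exc:
        raise ValueError(f"GTF parse error at line {lineno}: non-numeric coordinates") from exc
    if start_1 < 1 or end < start_1:
        raise ValueError(
            f"GTF parse error at line {lineno}: invalid coordinates {start_1}-{end}"
        )
    try:
        feature = gffutils.feature.feature_from_line(raw)
    except Exception as exc:  # pragma: no cover - gffutils is lenient
        raise ValueError(f"GTF parse error at line {lineno}: {exc}") from exc
    return fields, feature


_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
}


def read_annotation(path: str | os.PathLike) -> AnnotationSet:
    """Parse a GTF/GFF2-style file into an :class:`AnnotationSet`.

    Exon and CDS records are grouped by ``transcript_id``.  The gene biotype
    is taken from the ``gene_biotype``/``gene_type`` attribute when present;
    otherwise a gene is called ``protein_coding`` when any transcript carries
    a CDS and ``lncRNA`` when none does.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds_parts: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    declared_biotype: dict[str, str] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields, feature = _parse_gtf_line(raw, lineno)
            ftype = fields[2]
            if ftype not in ("exon", "CDS"):
                continue
            attrs = feature.attributes
            gene_ids = attrs.get("gene_id", [])
            tx_ids = attrs.get("transcript_id", [])
            if not tx_ids or not gene_ids:
                raise ValueError(
                    f"GTF parse error at line {lineno}: {ftype} record lacks "
                    "gene_id/transcript_id"
                )
            gene_id, tx_id = gene_ids[0], tx_ids[0]
            tx_gene.setdefault(tx_id, gene_id)
            strand = fields[6] if fields[6] in ("+", "-") else "."
            iv = GenomicInterval(fields[0], int(fields[3]) - 1, int(fields[4]), strand)
            if ftype == "exon":
                exons.setdefault(tx_id, []).append(iv)
            else:
                cds_parts.setdefault(tx_id, []).append(iv)
            for key in ("gene_biotype", "gene_type"):
                if key in attrs:
                    declared_biotype.setdefault(gene_id, attrs[key][0])

    transcripts_by_gene: dict[str, list[Transcript]] = {}
    for tx_id, tx_exons in exons.items():
        cds = None
        if tx_id in cds_parts:
            parts = cds_parts[tx_id]
            cds = GenomicInterval(
                parts[0].chrom,
                min(p.start for p in parts),
                max(p.end for p in parts),
                parts[0].strand,
            )
        tx = Transcript(tx_id, tx_gene[tx_id], tx_exons, cds)
        transcripts_by_gene.setdefault(tx_gene[tx_id], []).append(tx)

    genes = []
    for gene_id, txs in transcripts_by_gene.items():
        txs.sort(key=lambda t: t.transcript_id)
        if gene_id in declared_biotype:
            biotype = _BIOTYPE_MAP.get(declared_biotype[gene_id], "other")
        else:
            biotype = "protein_coding" if any(t.is_coding for t in txs) else "lncRNA"
        genes.append(GeneModel(gene_id, biotype, txs))
    genes.sort(key=lambda g: g.gene_id)
    return AnnotationSet(genes)


def _reads_from_bed(path, sample_id, replicate_id, known_chroms):
    reads, skipped = [], 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"BED parse error at line {lineno}: fewer than 3 fields"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if known_chroms is not None and chrom not in known_chroms:
                skipped += 1
                continue
            name = fields[3] if len(fields) > 3 else f"read{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            reads.append(
                AlignedRead(
                    GenomicInterval(chrom, start, end, strand),
                    name,
                    sample_id,
                    replicate_id,
                )
            )
    return reads, skipped


def _reads_from_sam(path, sample_id, replicate_id, known_chroms):
    reads, skipped = [], 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name
            if known_chroms is not None and chrom not in known_chroms:
                skipped += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            reads.append(
                AlignedRead(
                    GenomicInterval(chrom, rec.reference_start, rec.reference_end, strand),
                    rec.query_name,
                    sample_id,
                    replicate_id,
                )
            )
    return reads, skipped


def read_alignments(
    path: str | os.PathLike,
    sample_id: str,
    replicate_id: int,
    known_chroms: Optional[set[str]] = None,
) -> list[AlignedRead]:
    """Read aligned reads from BED6 or SAM/BAM.

    SAM/BAM records flagged unmapped, secondary or supplementary are skipped.
    When ``known_chroms`` is given, records on unknown chromosomes are skipped
    with a logged count instead of raising.
    """
    suffix = str(path).lower()
    if suffix.endswith((".sam", ".bam")):
        reads, skipped = _reads_from_sam(path, sample_id, replicate_id, known_chroms)
    else:
        reads, skipped = _reads_from_bed(path, sample_id, replicate_id, known_chroms)
    if skipped:
        logger.warning("%s: skipped %d records on unknown chromosomes", path, skipped)
    if not reads:
        logger.warning("%s: no alignments read", path)
    return reads


def write_bed(reads: Sequence[AlignedRead], path: str | os.PathLike) -> None:
    """Write reads as BED6 with deterministic (chrom, start, end, id) order."""
    rows = sorted(
        reads, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.read_id)
    )
    with open(path, "w") as fh:
        for r in rows:
            iv = r.interval
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.read_id}\t0\t{strand}\n")


def assign_reads_to_genes(
    reads: Sequence[AlignedRead],
    annotation: AnnotationSet,
    ignore_strand: bool = False,
) -> dict[str, list[AlignedRead]]:
    """Partition reads over genes by maximal span overlap.

    Each read goes to the single overlapping gene (same strand unless
    ``ignore_strand``) with the largest base overlap; ties break to the
    lexicographically smallest gene_id.  Reads hitting no gene land in the
    :data:`INTERGENIC` bucket.
    """
    buckets: dict[str, list[AlignedRead]] = {}
    for read in reads:
        candidates = annotation.lookup(read.interval, ignore_strand=ignore_strand)
        if not candidates:
            buckets.setdefault(INTERGENIC, []).append(read)
            continue
        best = min(
            candidates,
            key=lambda g: (-interval_overlap(read.interval, g.span), g.gene_id),
        )
        buckets.setdefault(best.gene_id, []).append(read)
    return buckets
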