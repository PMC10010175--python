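"""Permutation-based peak calling for RIP-seq style IP/input experiments.

The strategy: reads with >= 1 bp mutual overlap are merged into candidate
peaks; for every gene the observed reads are re-placed uniformly at random
across the gene span (introns included) many times to build an empirical
null of the maximum peak height; observed peaks are kept when their height
is improbable under that null; peaks also called in the input control are
discarded whole; finally, peaks from independent replicates are intersected.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome_model import (
    INTERGENIC,
    AlignedRead,
    AnnotationSet,
    GenomicInterval,
    interval_overlap,
)

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 500
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class Peak:
    """A candidate binding site: merged read cluster with its max depth."""

    interval: GenomicInterval
    gene_id: str
    height: int
    n_reads: int
    p_value: Optional[float] = None
    sample_id: Optional[str] = None
    replicate_id: Optional[int] = None
    parents: tuple[str, ...] = ()
    summit: Optional[int] = None  # leftmost position of maximum depth

    def __post_init__(self) -> None:
        if not (1 <= self.height <= self.n_reads):
            raise ValueError(
                f"peak height {self.height} outside [1, n_reads={self.n_reads}]"
            )
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")

    @property
    def name(self) -> str:
        return f"{self.gene_id}:{self.interval.start}-{self.interval.end}"


@dataclass
class NullDistribution:
    """Per-gene empirical null of the maximum peak height."""

    gene_id: str
    n_iter: int
    max_heights: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.max_heights = np.asarray(self.max_heights, dtype=np.int64)
        if len(self.max_heights) != self.n_iter:
            raise ValueError("max_heights length != n_iter")


def depth_profile(
    intervals: Sequence[GenomicInterval | AlignedRead], span: GenomicInterval
) -> np.ndarray:
    """Per-base read depth across ``span`` (clipped to span boundaries)."""
    L = span.length
    delta = np.zeros(L + 1, dtype=np.int64)
    for item in intervals:
        iv = item.interval if isinstance(item, AlignedRead) else iv_of(item)
        lo = max(iv.start, span.start) - span.start
        hi = min(iv.end, span.end) - span.start
        if hi > lo:
            delta[lo] += 1
            delta[hi] -= 1
    return np.cumsum(delta[:-1])


def iv_of(item) -> GenomicInterval:
    return item.interval if hasattr(item, "interval") else item


def build_peaks(
    reads: Sequence[AlignedRead],
    gene_id: str,
    sample_id: Optional[str] = None,
    replicate_id: Optional[int] = None,
) -> list[Peak]:
    """Merge reads into maximal single-linkage clusters under >=1 bp overlap.

    Returns pairwise non-overlapping peaks whose interval is the union span
    of member reads and whose height is the maximum per-base depth.
    """
    if not reads:
        return []
    order = sorted(reads, key=lambda r: (r.interval.start, r.interval.end))
    chroms = {r.interval.chrom for r in order}
    if len(chroms) > 1:
        raise ValueError(f"reads for {gene_id} span multiple chromosomes: {chroms}")
    peaks: list[Peak] = []
    cluster: list[AlignedRead] = [order[0]]
    cluster_end = order[0].interval.end
    strand = order[0].interval.strand

    def flush(members: list[AlignedRead], end: int) -> None:
        start = members[0].interval.start
        span = GenomicInterval(members[0].interval.chrom, start, end, strand)
        depth = depth_profile(members, span)
        height = int(depth.max())
        summit = start + int(depth.argmax())
        peaks.append(
            Peak(span, gene_id, height, len(members), None, sample_id, replicate_id,
                 summit=summit)
        )

    for read in order[1:]:
        if read.interval.start < cluster_end:  # half-open: touching != overlap
            cluster.append(read)
            cluster_end = max(cluster_end, read.interval.end)
        else:
            flush(cluster, cluster_end)
            cluster = [read]
            cluster_end = read.interval.end
    flush(cluster, cluster_end)
    return peaks


def _random_max_heights(
    span_len: int, read_lengths: np.ndarray, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised max per-base depth of ``n_iter`` random read placements."""
    m = len(read_lengths)
    W = span_len + 1
    # start ~ Uniform{0 .. span_len - length}, one column per read
    high = span_len - read_lengths + 1
    starts = (rng.random((n_iter, m)) * high).astype(np.int64)
    rows = np.repeat(np.arange(n_iter, dtype=np.int64) * W, m)
    flat_start = rows + starts.ravel()
    flat_end = rows + (starts + read_lengths).ravel()
    delta = np.bincount(flat_start, minlength=n_iter * W) - np.bincount(
        flat_end, minlength=n_iter * W
    )
    depth = np.cumsum(delta.reshape(n_iter, W)[:, :-1], axis=1)
    return depth.max(axis=1)


def permutation_null(
    gene_span: GenomicInterval,
    read_lengths: Sequence[int],
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    gene_id: Optional[str] = None,
) -> NullDistribution:
    """Empirical null of the max peak height for one gene.

    Each iteration re-places reads of the observed lengths uniformly at
    random inside the gene span and records the maximum per-base depth of
    the placement (equivalently, the height of the tallest merged peak).
    """
    if len(read_lengths) == 0:
        raise ValueError(f"no reads for gene {gene_span.chrom}: null undefined")
    L = gene_span.length
    lengths = np.asarray(read_lengths, dtype=np.int64)
    if (lengths > L).any():
        logger.warning(
            "gene span %s:%d-%d: %d read length(s) exceed span, clamped",
            gene_span.chrom,
            gene_span.start,
            gene_span.end,
            int((lengths > L).sum()),
        )
        lengths = np.minimum(lengths, L)
    rng = np.random.default_rng(seed)
    max_heights = _random_max_heights(L, lengths, n_iter, rng)
    return NullDistribution(gene_id or gene_span.chrom, n_iter, max_heights, seed)


def peak_pvalue(height: int, null: NullDistribution) -> float:
    """Add-one empirical upper-tail probability of ``height`` under the null."""
    tail = int((null.max_heights >= height).sum())
    return (1 + tail) / (1 + null.n_iter)


def gene_subseed(master_seed: int, gene_id: str) -> int:
    """Stable per-gene seed: CRC32 of the gene id folded with the master seed."""
    return (int(master_seed) * 0x9E3779B1 + zlib.crc32(gene_id.encode())) % (2**31)


def call_peaks(
    reads_by_gene: Mapping[str, Sequence[AlignedRead]],
    annotation: AnnotationSet,
    n_iter: int = DEFAULT_N_ITER,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    sample_id: Optional[str] = None,
    replicate_id: Optional[int] = None,
) -> list[Peak]:
    """Call significant peaks per gene against the permutation null.

    Genes are processed in sorted order with deterministic per-gene
    sub-seeds, so results are reproducible and order-independent.  Reads in
    the intergenic bucket have no gene territory to permute over and are
    dropped with a log message.
    """
    results: list[Peak] = []
    n_intergenic = len(reads_by_gene.get(INTERGENIC, ()))
    if n_intergenic:
        logger.info("dropping %d intergenic reads (no permutation territory)", n_intergenic)
    for gene_id in sorted(k for k in reads_by_gene if k != INTERGENIC):
        reads = reads_by_gene[gene_id]
        if not reads:
            continue
        span = annotation[gene_id].span
        peaks = build_peaks(reads, gene_id, sample_id, replicate_id)
        lengths = [r.interval.length for r in reads]
        null = permutation_null(
            span, lengths, n_iter, gene_subseed(seed, gene_id), gene_id=gene_id
        )
        for peak in peaks:
            p = peak_pvalue(peak.height, null)
            if p <= alpha:
                results.append(replace(peak, p_value=p))
    return results


def subtract_input(ip_peaks: Sequence[Peak], input_peaks: Sequence[Peak]) -> list[Peak]:
    """Drop (whole) IP peaks that overlap any input peak by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for peak in input_peaks:
        iv = peak.interval
        trees.setdefault(iv.chrom, IntervalTree())[iv.start:iv.end] = True
    kept = []
    for peak in ip_peaks:
        tree = trees.get(peak.interval.chrom)
        if tree is not None and tree.overlaps(peak.interval.start, peak.interval.end):
            continue
        kept.append(peak)
    return kept


def replicate_overlap(peaks_rep1: Sequence[Peak], peaks_rep2: Sequence[Peak]) -> list[Peak]:
    """Intersect peaks across replicates.

    Every rep1 x rep2 pair overlapping >= 1 bp yields the intersection
    interval; height is the min, p-value the max of the parents, whose names
    are recorded as provenance.
    """
    tree_by_chrom: dict[str, IntervalTree] = {}
    for peak in peaks_rep2:
        iv = peak.interval
        tree_by_chrom.setdefault(iv.chrom, IntervalTree())[iv.start:iv.end] = peak
    out: list[Peak] = []
    for p1 in sorted(peaks_rep1, key=lambda p: (p.interval.chrom, p.interval.start)):
        tree = tree_by_chrom.get(p1.interval.chrom)
        if tree is None:
            continue
        for hit in sorted(tree[p1.interval.start:p1.interval.end]):
            p2: Peak = hit.data
            if p1.interval.strand != p2.interval.strand and "." not in (
                p1.interval.strand,
                p2.interval.strand,
            ):
                continue
            start = max(p1.interval.start, p2.interval.start)
            end = min(p1.interval.end, p2.interval.end)
            pvals = [p for p in (p1.p_value, p2.p_value) if p is not None]
            summit = next(
                (s for s in (p1.summit, p2.summit) if s is not None and start <= s < end),
                None,
            )
            out.append(
                Peak(
                    GenomicInterval(p1.interval.chrom, start, end, p1.interval.strand),
                    p1.gene_id,
                    min(p1.height, p2.height),
                    min(p1.n_reads, p2.n_reads),
                    max(pvals) if pvals else None,
                    p1.sample_id,
                    None,
                    parents=(p1.name, p2.name),
                    summit=summit,
                )
            )
    return out


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    """BED6+3 peak writer (name, score=height, then n_reads, p_value, summit)."""
    rows = sorted(
        peaks,
        key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end, p.gene_id),
    )
    with open(path, "w") as fh:
        for i, p in enumerate(rows):
            iv = p.interval
            strand = iv.strand if iv.strand in ("+", "-") else "."
            pv = f"{p.p_value:.6g}" if p.p_value is not None else "NA"
            summit = p.summit if p.summit is not None else "NA"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.gene_id}:{i}\t{p.height}\t{strand}"
                f"\t{p.n_reads}\t{pv}\t{summit}\n"
            )
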