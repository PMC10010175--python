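"""Region classification, target biotypes, RPKM, correlations, coverage.

An interval (read or peak) gets exactly one region label, the
highest-priority label among all transcript features it touches:
CDS > 5'UTR > 3'UTR > noncoding exon > intron > intergenic.  UTRs are the
exonic parts of a coding transcript outside the CDS span, oriented by
strand; exons of transcripts without a CDS are noncoding exons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import (
    INTERGENIC,
    AlignedRead,
    AnnotationSet,
    GenomicInterval,
    interval_overlap,
)
from .peak_calling import Peak, depth_profile

logger = logging.getLogger(__name__)


class RegionLabel(str, Enum):
    CDS = "cds"
    FIVE_PRIME_UTR = "five_prime_utr"
    THREE_PRIME_UTR = "three_prime_utr"
    NONCODING_EXON = "noncoding_exon"
    INTRON = "intron"
    INTERGENIC = "intergenic"


#: priority used when an interval touches several feature classes
_PRIORITY = [
    RegionLabel.CDS,
    RegionLabel.FIVE_PRIME_UTR,
    RegionLabel.THREE_PRIME_UTR,
    RegionLabel.NONCODING_EXON,
    RegionLabel.INTRON,
]


def _iv(item) -> GenomicInterval:
    return item.interval if hasattr(item, "interval") else item


def classify_interval(
    interval: GenomicInterval | AlignedRead | Peak,
    annotation: AnnotationSet,
    ignore_strand: bool = False,
) -> RegionLabel:
    """Single region label for an interval under the fixed priority."""
    iv = _iv(interval)
    touched: set[RegionLabel] = set()
    for gene in annotation.lookup(iv, ignore_strand=ignore_strand):
        for tx in gene.transcripts:
            if tx.cds is not None:
                cds = tx.cds
                for exon in tx.exons:
                    lo, hi = max(exon.start, cds.start), min(exon.end, cds.end)
                    if hi > lo and _olap(iv, exon.chrom, lo, hi):
                        touched.add(RegionLabel.CDS)
                    if exon.start < cds.start and _olap(iv, exon.chrom, exon.start, min(exon.end, cds.start)):
                        touched.add(
                            RegionLabel.FIVE_PRIME_UTR
                            if tx.strand != "-"
                            else RegionLabel.THREE_PRIME_UTR
                        )
                    if exon.end > cds.end and _olap(iv, exon.chrom, max(exon.start, cds.end), exon.end):
                        touched.add(
                            RegionLabel.THREE_PRIME_UTR
                            if tx.strand != "-"
                            else RegionLabel.FIVE_PRIME_UTR
                        )
            else:
                for exon in tx.exons:
                    if _olap(iv, exon.chrom, exon.start, exon.end):
                        touched.add(RegionLabel.NONCODING_EXON)
            for intron in tx.introns():
                if _olap(iv, intron.chrom, intron.start, intron.end):
                    touched.add(RegionLabel.INTRON)
    for label in _PRIORITY:
        if label in touched:
            return label
    return RegionLabel.INTERGENIC


def _olap(iv: GenomicInterval, chrom: str, start: int, end: int) -> bool:
    return chrom == iv.chrom and min(iv.end, end) > max(iv.start, start)


def classify_peak(
    peak: Peak, annotation: AnnotationSet, ignore_strand: bool = False
) -> RegionLabel:
    """Region label of a peak, annotated at its summit when known.

    Merged read clusters can stretch far beyond the bound site once coverage
    is appreciable; the summit (maximum-depth position) localises the
    binding evidence, so the peak is annotated there, falling back to the
    whole-interval rule when no summit is recorded.
    """
    if peak.summit is not None:
        iv = peak.interval
        point = GenomicInterval(iv.chrom, peak.summit, peak.summit + 1, iv.strand)
        return classify_interval(point, annotation, ignore_strand)
    return classify_interval(peak, annotation, ignore_strand)


def region_counts(
    items_by_sample: Mapping[str, Sequence],
    annotation: AnnotationSet,
    ignore_strand: bool = False,
) -> pd.DataFrame:
    """Item counts per region label, one row per sample.

    Reads and plain intervals take the whole-interval priority label; peaks
    are annotated at their summit (see :func:`classify_peak`).
    """
    if not items_by_sample or all(len(v) == 0 for v in items_by_sample.values()):
        raise ValueError("region_counts: no items supplied")
    labels = [l.value for l in RegionLabel]
    rows = {}
    for sample, items in items_by_sample.items():
        if len(items) == 0:
            raise ValueError(f"region_counts: sample {sample} is empty")
        counts = dict.fromkeys(labels, 0)
        for item in items:
            if isinstance(item, Peak):
                label = classify_peak(item, annotation, ignore_strand)
            else:
                label = classify_interval(item, annotation, ignore_strand)
            counts[label.value] += 1
        rows[sample] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels).astype(int)


def region_distribution(
    items_by_sample: Mapping[str, Sequence],
    annotation: AnnotationSet,
    ignore_strand: bool = False,
) -> pd.DataFrame:
    """Fraction of items per region label, one row per sample.

    Returns a DataFrame indexed by sample with one column per
    :class:`RegionLabel` value; each row sums to 1.
    """
    counts = region_counts(items_by_sample, annotation, ignore_strand)
    return counts.div(counts.sum(axis=1), axis=0)


def compare_region_distributions(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> pd.DataFrame:
    """Per-category two-proportion z-test between two pooled samples, BH-adjusted.

    A pragmatic test for IP-vs-input region shifts on pooled read counts;
    the replication unit is the read, not the replicate.
    """
    from statsmodels.stats.multitest import multipletests
    from statsmodels.stats.proportion import proportions_ztest

    n_a, n_b = sum(counts_a.values()), sum(counts_b.values())
    cats = sorted(set(counts_a) | set(counts_b))
    recs = []
    for cat in cats:
        ca, cb = counts_a.get(cat, 0), counts_b.get(cat, 0)
        if ca + cb == 0 or ca + cb == n_a + n_b:
            p = 1.0
            stat = 0.0
        else:
            stat, p = proportions_ztest([ca, cb], [n_a, n_b])
        recs.append((cat, ca / n_a, cb / n_b, stat, p))
    df = pd.DataFrame(recs, columns=["region", "frac_a", "frac_b", "z", "p_value"])
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


@dataclass
class CountTable:
    """Gene x sample read counts with per-sample library sizes and gene lengths."""

    counts: pd.DataFrame  # genes x samples
    library_sizes: pd.Series  # per sample, total reads assigned to genes
    gene_lengths: pd.Series  # genomic span length per gene, bp

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        for sample in self.counts.columns:
            if self.counts[sample].sum() > self.library_sizes[sample]:
                raise ValueError(f"counts exceed library size for {sample}")


def gene_counts(
    assignments_by_sample: Mapping[str, Mapping[str, Sequence[AlignedRead]]],
    annotation: AnnotationSet,
) -> CountTable:
    """Build a :class:`CountTable` from per-sample gene read buckets.

    The intergenic bucket is excluded from gene rows; library size is the
    number of reads assigned to genes.
    """
    genes = sorted(annotation.genes)
    data = {}
    for sample, buckets in assignments_by_sample.items():
        col = {g: len(buckets.get(g, ())) for g in genes}
        data[sample] = col
    counts = pd.DataFrame(data, index=genes).astype(int)
    lib = counts.sum(axis=0).astype(int)
    lengths = pd.Series({g: annotation[g].span.length for g in genes})
    return CountTable(counts, lib, lengths)


def rpkm(table: CountTable) -> pd.DataFrame:
    """Reads per kilobase of gene per million assigned reads: 1e9*C/(N*L)."""
    if (table.library_sizes <= 0).any():
        bad = table.library_sizes[table.library_sizes <= 0].index.tolist()
        raise ValueError(f"zero library size for samples {bad}")
    L = table.gene_lengths.values[:, None].astype(float)
    N = table.library_sizes.values[None, :].astype(float)
    return pd.DataFrame(
        1e9 * table.counts.values / (N * L),
        index=table.counts.index,
        columns=table.counts.columns,
    )


def sample_correlation(
    rpkm_table: pd.DataFrame, sample_a: str, sample_b: str
) -> float:
    """Pearson r between two samples on log2(RPKM + 1) over shared genes."""
    a = np.log2(rpkm_table[sample_a].astype(float) + 1.0)
    b = np.log2(rpkm_table[sample_b].astype(float) + 1.0)
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError("need >= 3 genes with finite values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def classify_targets(
    peaks: Sequence[Peak], annotation: AnnotationSet
) -> pd.DataFrame:
    """Counts and fractions of peak target genes by biotype class.

    Biotypes map to the reported classes mRNA (protein_coding), lncRNA and
    other; peaks in the intergenic bucket are excluded with a logged count.
    """
    class_of = {"protein_coding": "mRNA", "lncRNA": "lncRNA"}
    counts = {"mRNA": 0, "lncRNA": 0, "other": 0}
    skipped = 0
    for peak in peaks:
        if peak.gene_id == INTERGENIC or peak.gene_id not in annotation.genes:
            skipped += 1
            continue
        biotype = annotation[peak.gene_id].biotype
        counts[class_of.get(biotype, "other")] += 1
    if skipped:
        logger.info("classify_targets: excluded %d intergenic peaks", skipped)
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "count": pd.Series(counts),
            "fraction": pd.Series(
                {k: (v / total if total else 0.0) for k, v in counts.items()}
            ),
        }
    )


def coverage_track(
    reads: Sequence[AlignedRead], track_name: Optional[str] = None
) -> str:
    """bedGraph text of per-base read depth (zero-depth runs omitted).

    Depth values agree with :func:`ripcall.peak_calling.depth_profile`
    everywhere.
    """
    lines = []
    if track_name:
        lines.append(f'track type=bedGraph name="{track_name}"')
    by_chrom: dict[str, list[AlignedRead]] = {}
    for read in reads:
        by_chrom.setdefault(read.interval.chrom, []).append(read)
    for chrom in sorted(by_chrom):
        chrom_reads = by_chrom[chrom]
        lo = min(r.interval.start for r in chrom_reads)
        hi = max(r.interval.end for r in chrom_reads)
        span = GenomicInterval(chrom, lo, hi)
        depth = depth_profile(chrom_reads, span)
        # run-length encode
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(depth)]])
        for s, e in zip(starts, ends):
            d = int(depth[s])
            if d > 0:
                lines.append(f"{chrom}\t{lo + int(s)}\t{lo + int(e)}\t{d}")
    return "\n".join(lines) + ("\n" if lines else "")
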