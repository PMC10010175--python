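"""Synthetic genome, gene models and IP/input read sets with ground truth.

The generator emulates a two-replicate RIP-seq experiment: a toy genome of
non-overlapping genes with exon/intron structure, heterogeneous expression,
an input sample of background reads drawn uniformly over each gene's
genomic span, and IP samples in which a subset of genes carries narrow
binding sites where read density is locally elevated by a configurable
fold.  A short recognition motif (AAGG by default) is written into the
genome at each planted site, so both the peak caller and the k-mer motif
test can be scored against machine-readable ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .genome_model import (
    AlignedRead,
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    Transcript,
    interval_overlap,
)

# sub-stream tags so adding replicates never perturbs earlier streams
_STREAM_GENOME = 0
_STREAM_SAMPLE = {"input": 1, "IP": 2}

#: fraction of planted sites placed inside introns (the remainder in exons);
#: intronic placement dominates because the binding under study is
#: co-transcriptional, on pre-mRNA.
INTRON_SITE_BIAS = 0.65

_MIN_INTRON = 150
_INTERGENIC_GAP = (300, 1500)
_GENES_PER_CHROM = 50
_CODING_FRACTION = 0.85


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults describe the reference scenario used throughout the test
    suite: 200 genes, 20% of them carrying a single 60 bp site with 8-fold
    local enrichment, two IP replicates of 100,000 single-end 50 nt reads
    plus one matched input, and the motif AAGG planted at every site.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (2000, 8000)
    exons_per_gene_range: tuple[int, int] = (3, 6)
    exon_length_range: tuple[int, int] = (400, 700)
    gc_content: float = 0.5
    expression_lognormal: tuple[float, float] = (0.0, 0.5)
    read_length: int = 50
    library_size: int = 100_000
    n_replicates: int = 2
    binding_fraction: float = 0.2
    sites_per_bound_gene: int = 1
    site_width: int = 60
    enrichment_fold: float = 8.0
    motif: str = "AAGG"
    motif_insertion_prob: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_genes=self.n_genes,
            read_length=self.read_length,
            library_size=self.library_size,
            n_replicates=self.n_replicates,
            sites_per_bound_gene=self.sites_per_bound_gene,
            site_width=self.site_width,
        )
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        for name, value in (
            ("binding_fraction", self.binding_fraction),
            ("motif_insertion_prob", self.motif_insertion_prob),
            ("gc_content", self.gc_content),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.enrichment_fold < 0:
            raise ValueError("enrichment_fold must be >= 0")
        for name, rng in (
            ("gene_length_range", self.gene_length_range),
            ("exons_per_gene_range", self.exons_per_gene_range),
            ("exon_length_range", self.exon_length_range),
        ):
            if rng[0] < 1 or rng[1] < rng[0]:
                raise ValueError(f"{name} must be an increasing pair >= 1, got {rng}")
        if self.site_width > self.gene_length_range[0]:
            raise ValueError("site_width exceeds the minimum gene length")
        if self.read_length > self.gene_length_range[0]:
            raise ValueError("read_length exceeds the minimum gene length")
        if not self.motif or set(self.motif.upper()) - set("ACGT"):
            raise ValueError(f"motif must be a non-empty ACGT string, got {self.motif!r}")


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    interval: GenomicInterval
    motif_present: bool
    in_intron: bool


@dataclass
class GroundTruth:
    """Machine-readable truth for scoring: sites, motif, per-gene expression."""

    planted_sites: list[PlantedSite]
    motif: str
    expression: dict[str, float]

    def sites_by_gene(self) -> dict[str, list[PlantedSite]]:
        out: dict[str, list[PlantedSite]] = {}
        for site in self.planted_sites:
            out.setdefault(site.gene_id, []).append(site)
        return out


def _make_gene_structure(gene_len: int, cfg: SimulationConfig, rng) -> list[tuple[int, int]]:
    """Relative exon coordinates inside a gene of ``gene_len`` bases."""
    lo_n, hi_n = cfg.exons_per_gene_range
    n_exons = int(rng.integers(lo_n, hi_n + 1))
    lo_e, hi_e = cfg.exon_length_range
    while n_exons > 1:
        need = n_exons * lo_e + (n_exons - 1) * _MIN_INTRON
        if need <= gene_len:
            break
        n_exons -= 1
    if n_exons == 1:
        return [(0, gene_len)]
    lengths = rng.integers(lo_e, hi_e + 1, size=n_exons)
    budget = gene_len - (n_exons - 1) * _MIN_INTRON
    if lengths.sum() > budget:
        lengths = np.full(n_exons, budget // n_exons, dtype=np.int64)  # >= lo_e by construction
    spare = gene_len - lengths.sum() - (n_exons - 1) * _MIN_INTRON
    # distribute spare intronic bases over the gaps at random
    gaps = np.full(n_exons - 1, _MIN_INTRON, dtype=np.int64)
    if spare > 0:
        gaps += rng.multinomial(spare, np.full(n_exons - 1, 1.0 / (n_exons - 1)))
    exons = []
    pos = 0
    for i, length in enumerate(lengths):
        exons.append((pos, pos + int(length)))
        pos += int(length)
        if i < n_exons - 1:
            pos += int(gaps[i])
    # first exon starts at 0; stretch the last exon to end exactly at gene_len
    start, _ = exons[-1]
    exons[-1] = (start, gene_len)
    return exons


def _place_site(gene: GeneModel, cfg: SimulationConfig, existing, rng) -> Optional[PlantedSite]:
    tx = gene.transcripts[0]
    introns = [iv for iv in tx.introns() if iv.length >= cfg.site_width]
    exons = [iv for iv in tx.exons if iv.length >= cfg.site_width]
    for _ in range(50):
        use_intron = introns and (not exons or rng.random() < INTRON_SITE_BIAS)
        pool = introns if use_intron else exons
        if not pool:
            return None
        region = pool[int(rng.integers(len(pool)))]
        start = int(rng.integers(region.start, region.end - cfg.site_width + 1))
        iv = GenomicInterval(gene.chrom, start, start + cfg.site_width, gene.strand)
        if all(interval_overlap(iv, s.interval) == 0 for s in existing):
            present = bool(rng.random() < cfg.motif_insertion_prob)
            return PlantedSite(gene.gene_id, iv, present, bool(use_intron))
    return None


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], AnnotationSet, GroundTruth]:
    """Build the toy genome, annotation and ground truth.

    Genes are packed without span overlap onto synthetic chromosomes of 50
    genes each, separated by random intergenic gaps.  Binding sites are
    placed inside randomly chosen bound genes, biased toward introns, and
    the motif is written into the sequence at a random offset inside each
    site with probability ``motif_insertion_prob``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_GENOME]))
    bases = np.array(list("ACGT"))
    probs = np.array(
        [
            (1 - config.gc_content) / 2,
            config.gc_content / 2,
            config.gc_content / 2,
            (1 - config.gc_content) / 2,
        ]
    )

    genes: list[GeneModel] = []
    chrom_seqs: dict[str, np.ndarray] = {}
    n_chroms = (config.n_genes + _GENES_PER_CHROM - 1) // _GENES_PER_CHROM
    gene_idx = 0
    id_width = max(4, len(str(config.n_genes)))
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        pos = int(rng.integers(*_INTERGENIC_GAP))
        n_here = min(_GENES_PER_CHROM, config.n_genes - gene_idx)
        for _ in range(n_here):
            gene_len = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"G{gene_idx + 1:0{id_width}d}"
            rel_exons = _make_gene_structure(gene_len, config, rng)
            exons = [
                GenomicInterval(chrom, pos + s, pos + e, strand) for s, e in rel_exons
            ]
            coding = rng.random() < _CODING_FRACTION and len(exons) >= 1
            cds = None
            if coding:
                # CDS from the middle of the first exon to the middle of the
                # last exon, leaving UTR stubs on both ends
                first, last = exons[0], exons[-1]
                cds_start = first.start + max(1, first.length // 3)
                cds_end = last.end - max(1, last.length // 3)
                if cds_end > cds_start:
                    cds = GenomicInterval(chrom, cds_start, cds_end, strand)
            tx = Transcript(f"{gene_id}.t1", gene_id, exons, cds)
            biotype = "protein_coding" if cds is not None else "lncRNA"
            genes.append(GeneModel(gene_id, biotype, [tx]))
            pos += gene_len + int(rng.integers(*_INTERGENIC_GAP))
            gene_idx += 1
        chrom_len = pos
        seq = rng.choice(bases, size=chrom_len, p=probs)
        chrom_seqs[chrom] = seq

    annotation = AnnotationSet(genes)

    # expression heterogeneity
    mu, sigma = config.expression_lognormal
    expr_vals = rng.lognormal(mu, sigma, size=len(genes))
    expression = {g.gene_id: float(v) for g, v in zip(genes, expr_vals)}

    # choose bound genes and plant sites
    n_bound = int(round(config.binding_fraction * config.n_genes))
    bound_ids = sorted(
        rng.choice([g.gene_id for g in genes], size=n_bound, replace=False)
    ) if n_bound else []
    sites: list[PlantedSite] = []
    for gene_id in bound_ids:
        gene = annotation[gene_id]
        gene_sites: list[PlantedSite] = []
        for _ in range(config.sites_per_bound_gene):
            site = _place_site(gene, config, gene_sites, rng)
            if site is None:
                raise RuntimeError(
                    f"could not place a {config.site_width} bp site in gene {gene_id}"
                )
            gene_sites.append(site)
        sites.extend(gene_sites)

    # the motif is a sense-strand (RNA) motif: on minus-strand genes its
    # reverse complement is written into the genomic plus strand
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    motif_fwd = np.array(list(config.motif.upper()))
    motif_rev = np.array([comp[b] for b in reversed(config.motif.upper())])
    for site in sites:
        if site.motif_present:
            lo = site.interval.start
            hi = site.interval.end - len(config.motif)
            offset = int(rng.integers(lo, hi + 1))
            motif_arr = motif_rev if site.interval.strand == "-" else motif_fwd
            chrom_seqs[site.interval.chrom][offset : offset + len(motif_arr)] = motif_arr

    genome = {chrom: "".join(arr) for chrom, arr in sorted(chrom_seqs.items())}
    truth = GroundTruth(sites, config.motif.upper(), expression)
    return genome, annotation, truth


def _site_windows(gene: GeneModel, sites: Sequence[PlantedSite], read_length: int) -> np.ndarray:
    """All start positions from which a read would overlap >= 1 site base."""
    span = gene.span
    positions: list[np.ndarray] = []
    for site in sites:
        lo = max(span.start, site.interval.start - read_length + 1)
        hi = min(span.end - read_length, site.interval.end - 1)
        if hi >= lo:
            positions.append(np.arange(lo, hi + 1))
    if not positions:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(positions))


def site_probability(
    enrichment_fold: float, n_window: int, n_valid_starts: int
) -> float:
    """Mixture weight of the site component of IP read starts.

    Chosen so the expected per-base depth at sites is ``enrichment_fold``
    times the background depth: p = (f-1)W / (G + (f-1)W), where W is the
    number of starts overlapping a site and G the number of valid starts.
    Folds <= 1 give a pure background sample.
    """
    if enrichment_fold <= 1 or n_window == 0:
        return 0.0
    excess = (enrichment_fold - 1) * n_window
    return excess / (n_valid_starts + excess)


def simulate_reads(
    config: SimulationConfig,
    annotation: AnnotationSet,
    truth: GroundTruth,
) -> dict[tuple[str, int], list[AlignedRead]]:
    """Draw the input and IP read sets for every replicate.

    Genes receive reads in proportion to their expression; input starts are
    uniform over valid starts of the gene span; IP starts fall inside a
    planted-site window with the probability given by
    :func:`site_probability`, otherwise they follow the background law.
    Every sample contains exactly ``library_size`` reads.  Replicates share
    the genome and truth and differ only in their random stream.
    """
    config.validate()
    gene_ids = sorted(truth.expression)
    weights = np.array([truth.expression[g] for g in gene_ids])
    weights = weights / weights.sum()
    sites_by_gene = truth.sites_by_gene()
    rl = config.read_length

    for gene_id in gene_ids:
        if annotation[gene_id].span.length < rl:
            raise ValueError(
                f"read_length {rl} exceeds span of gene {gene_id}"
            )

    out: dict[tuple[str, int], list[AlignedRead]] = {}
    for sample_id, stream in _STREAM_SAMPLE.items():
        for rep in range(1, config.n_replicates + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, stream, rep])
            )
            counts = rng.multinomial(config.library_size, weights)
            reads: list[AlignedRead] = []
            for gene_id, n in zip(gene_ids, counts):
                if n == 0:
                    continue
                gene = annotation[gene_id]
                span = gene.span
                n_valid = span.length - rl + 1
                gene_sites = sites_by_gene.get(gene_id, [])
                if sample_id == "IP" and gene_sites:
                    window = _site_windows(gene, gene_sites, rl)
                    p_site = site_probability(
                        config.enrichment_fold, len(window), n_valid
                    )
                else:
                    window = np.empty(0, dtype=np.int64)
                    p_site = 0.0
                n_site = int(rng.binomial(n, p_site)) if p_site > 0 else 0
                starts = np.concatenate(
                    [
                        window[rng.integers(0, len(window), size=n_site)]
                        if n_site
                        else np.empty(0, dtype=np.int64),
                        span.start + rng.integers(0, n_valid, size=n - n_site),
                    ]
                )
                for j, s in enumerate(starts):
                    reads.append(
                        AlignedRead(
                            GenomicInterval(span.chrom, int(s), int(s) + rl, span.strand),
                            f"{sample_id}{rep}_{gene_id}_{j}",
                            sample_id,
                            rep,
                        )
                    )
            out[(sample_id, rep)] = reads
    return out


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(annotation: AnnotationSet, path: str | os.PathLike, source: str = "ripcall_sim") -> None:
    """Write the annotation as GTF (1-based, end-inclusive on output)."""
    lines = []
    for gene in sorted(annotation, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
        for tx in gene.transcripts:
            attrs = (
                f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_biotype "{gene.biotype}";'
            )
            for exon in tx.exons:
                lines.append(
                    f"{exon.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t."
                    f"\t{exon.strand}\t.\t{attrs}"
                )
            if tx.cds is not None:
                lines.append(
                    f"{tx.cds.chrom}\t{source}\tCDS\t{tx.cds.start + 1}\t{tx.cds.end}\t."
                    f"\t{tx.cds.strand}\t.\t{attrs}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def write_ground_truth(truth: GroundTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tsite_start\tsite_end\tstrand\tmotif_present\tin_intron\n")
        for s in sorted(truth.planted_sites, key=lambda s: (s.interval.chrom, s.interval.start)):
            fh.write(
                f"{s.gene_id}\t{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                f"\t{s.interval.strand}\t{int(s.motif_present)}\t{int(s.in_intron)}\n"
            )
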