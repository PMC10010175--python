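"""Shared fixtures: a toy annotation built in memory and a session-scoped
run of the reference synthetic study (5 seeds) reused by the slower tests."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pytest

from ripcall.annotation_metrics import region_distribution
from ripcall.enrichment import extract_peak_sequences, kmer_enrichment
from ripcall.genome_model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    Transcript,
    assign_reads_to_genes,
    interval_overlap,
)
from ripcall.peak_calling import call_peaks, replicate_overlap, subtract_input
from ripcall.synthetic_data import SimulationConfig, simulate_genome, simulate_reads

STUDY_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture
def toy_annotation() -> AnnotationSet:
    """Two genes on chr1: a coding two-exon gene (+) and a one-exon lncRNA (-).

    geneA: exons [100,300) and [500,800), CDS [200,700), so
    5'UTR=[100,200), 3'UTR=[700,800), intron=[300,500).
    geneB: exon [1000,1400), no CDS.
    """
    tx_a = Transcript(
        "tA.1",
        "geneA",
        [GenomicInterval("chr1", 100, 300, "+"), GenomicInterval("chr1", 500, 800, "+")],
        cds=GenomicInterval("chr1", 200, 700, "+"),
    )
    tx_b = Transcript("tB.1", "geneB", [GenomicInterval("chr1", 1000, 1400, "-")])
    return AnnotationSet(
        [GeneModel("geneA", "protein_coding", [tx_a]), GeneModel("geneB", "lncRNA", [tx_b])]
    )


@dataclass
class StudyResult:
    seed: int
    recall: float
    precision: float
    n_overlap: int
    top_kmer: str
    peak_label_counts: Counter
    ip_intron_fracs: list[float]
    input_intron_fracs: list[float]
    overlapped_peaks: list
    input_peaks_rep1: list
    final_rep1: list
    annotation: object
    truth: object


def _run_study(seed: int) -> StudyResult:
    cfg = SimulationConfig(seed=seed)
    genome, annotation, truth = simulate_genome(cfg)
    reads = simulate_reads(cfg, annotation, truth)
    finals = {}
    input_peaks = {}
    for rep in (1, 2):
        ip = assign_reads_to_genes(reads[("IP", rep)], annotation)
        inp = assign_reads_to_genes(reads[("input", rep)], annotation)
        ip_peaks = call_peaks(ip, annotation, seed=seed, sample_id="IP", replicate_id=rep)
        input_peaks[rep] = call_peaks(
            inp, annotation, seed=seed, sample_id="input", replicate_id=rep
        )
        finals[rep] = subtract_input(ip_peaks, input_peaks[rep])
    overlapped = replicate_overlap(finals[1], finals[2])

    sites = truth.planted_sites
    recall = sum(
        any(interval_overlap(s.interval, p.interval) > 0 for p in overlapped)
        for s in sites
    ) / len(sites)
    precision = sum(
        any(interval_overlap(s.interval, p.interval) > 0 for s in sites)
        for p in overlapped
    ) / max(1, len(overlapped))

    seqs = extract_peak_sequences(
        [p for p in overlapped if p.interval.length >= 4], genome, window=100
    )
    top_kmer = kmer_enrichment(seqs, k=4, seed=seed)[0].kmer if seqs else ""

    peak_rd = region_distribution({"peaks": overlapped}, annotation)
    labels = Counter()
    for col in peak_rd.columns:
        labels[col] = round(peak_rd.loc["peaks", col] * len(overlapped))
    read_rd = region_distribution(
        {f"{s}{r}": reads[(s, r)] for s in ("IP", "input") for r in (1, 2)}, annotation
    )
    return StudyResult(
        seed=seed,
        recall=recall,
        precision=precision,
        n_overlap=len(overlapped),
        top_kmer=top_kmer,
        peak_label_counts=labels,
        ip_intron_fracs=[read_rd.loc["IP1", "intron"], read_rd.loc["IP2", "intron"]],
        input_intron_fracs=[read_rd.loc["input1", "intron"], read_rd.loc["input2", "intron"]],
        overlapped_peaks=overlapped,
        input_peaks_rep1=input_peaks[1],
        final_rep1=finals[1],
        annotation=annotation,
        truth=truth,
    )


@pytest.fixture(scope="session")
def study_runs() -> dict[int, StudyResult]:
    """The reference synthetic study (default config) across five seeds."""
    return {seed: _run_study(seed) for seed in STUDY_SEEDS}
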