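"""Statistical enrichment analyses downstream of peak calling.

Covers gene-level IP-vs-input enrichment (per-gene one-sided Fisher exact
test on assigned-read counts), k-mer motif over-representation against a
shuffled or user-supplied background, hypergeometric term enrichment with
Benjamini-Hochberg adjustment, gene-set overlaps, and relative qPCR
quantification by the 2^-ddCt method.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_metrics import CountTable
from .peak_calling import Peak

_DNA = "ACGT"


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class GeneEnrichmentResult:
    gene_id: str
    ip_count: int
    input_count: int
    log2fc: float
    p_value: float
    q_value: float
    status: str  # enriched | not_enriched


def gene_enrichment(
    table: CountTable,
    ip_sample: str,
    input_sample: str,
    alpha: float = 0.05,
    min_lfc: float = 1.0,
) -> list[GeneEnrichmentResult]:
    """Per-gene one-sided Fisher exact test of IP over input.

    For each gene the 2x2 table [C_ip, N_ip - C_ip; C_in, N_in - C_in] is
    tested for IP excess (hypergeometric upper tail); q-values are BH over
    all genes; log2 fold change uses library-size-normalised counts with a
    pseudocount of 1.  A gene is ``enriched`` when q <= alpha and
    log2fc >= min_lfc.
    """
    n_ip = int(table.library_sizes[ip_sample])
    n_in = int(table.library_sizes[input_sample])
    if n_ip == 0 or n_in == 0:
        raise ValueError("zero library size")
    c_ip = table.counts[ip_sample].astype(int)
    c_in = table.counts[input_sample].astype(int)
    # one-sided Fisher == hypergeometric upper tail on the 2x2 margins
    p = stats.hypergeom.sf(
        c_ip.values - 1, n_ip + n_in, c_ip.values + c_in.values, n_ip
    )
    p = np.clip(p, 0.0, 1.0)
    q = bh_fdr(p)
    lfc = np.log2(((c_ip.values + 1) / n_ip) / ((c_in.values + 1) / n_in))
    out = []
    for gene, ci, cn, l, pv, qv in zip(c_ip.index, c_ip.values, c_in.values, lfc, p, q):
        status = "enriched" if (qv <= alpha and l >= min_lfc) else "not_enriched"
        out.append(
            GeneEnrichmentResult(gene, int(ci), int(cn), float(l), float(pv), float(qv), status)
        )
    return out


def extract_peak_sequences(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    window: Optional[int] = None,
) -> list[str]:
    """Genomic sequence under each peak; minus-strand peaks reverse-complemented.

    ``genome`` is any mapping chrom -> sequence (a dict or a pyfaidx.Fasta).
    With ``window`` set, a fixed-size window centred on the peak summit (or
    the interval midpoint when no summit is recorded) is extracted instead
    of the full peak — the usual practice for motif analysis, which keeps
    broad clusters from swamping the bound site.  Windows are clipped to the
    contig.
    """
    seqs = []
    for peak in peaks:
        iv = peak.interval
        if iv.chrom not in genome:
            raise ValueError(f"peak {peak.name}: unknown chromosome {iv.chrom}")
        contig = genome[iv.chrom]
        if iv.end > len(contig):
            raise ValueError(
                f"peak {peak.name}: end {iv.end} beyond contig {iv.chrom} "
                f"length {len(contig)}"
            )
        if window is None:
            start, end = iv.start, iv.end
        else:
            centre = peak.summit if peak.summit is not None else (iv.start + iv.end) // 2
            start = max(0, centre - window // 2)
            end = min(len(contig), start + window)
        seq = str(contig[start:end]).upper()
        if iv.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        seqs.append(seq)
    return seqs


@dataclass(frozen=True)
class MotifResult:
    kmer: str
    fg_count: int
    bg_count: int
    fold: float
    p_value: float
    q_value: float


def _count_kmers(sequences: Iterable[str], k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    n_positions = 0
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if set(kmer) - set(_DNA):
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
            n_positions += 1
    return counts, n_positions


def _mononucleotide_shuffle(sequences: Sequence[str], rng: np.random.Generator) -> list[str]:
    out = []
    for seq in sequences:
        arr = np.array(list(seq.upper()))
        rng.shuffle(arr)
        out.append("".join(arr))
    return out


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 500) -> str:
    """Dinucleotide-preserving shuffle via a random Eulerian walk.

    Edge orders are resampled until a full Eulerian walk from the original
    start base exists (rejection sampling over the dinucleotide multigraph;
    acceptance is high for 4-letter alphabets).
    """
    s = seq.upper()
    if len(s) < 3:
        return s
    base_edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        base_edges.setdefault(a, []).append(b)
    n_edges = len(s) - 1
    for _ in range(max_tries):
        edges = {a: list(targets) for a, targets in base_edges.items()}
        for a in edges:
            rng.shuffle(edges[a])
        out = [s[0]]
        pos = {a: 0 for a in edges}
        cur = s[0]
        for _ in range(n_edges):
            lst = edges.get(cur)
            if lst is None or pos[cur] >= len(lst):
                break
            nxt = lst[pos[cur]]
            pos[cur] += 1
            out.append(nxt)
            cur = nxt
        if len(out) == len(s):
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian walk")


def kmer_enrichment(
    fg_sequences: Sequence[str],
    k: int = 4,
    bg: Sequence[str] | str = "shuffle",
    seed: int = 0,
    dinucleotide: bool = False,
) -> list[MotifResult]:
    """Exhaustive k-mer over-representation test of foreground vs background.

    Counts every k-mer occurrence on the given strand of the foreground
    sequences and compares each k-mer's count against its frequency in the
    background (user-supplied sequences, or a seeded per-sequence shuffle of
    the foreground) with a one-sided binomial test; BH over all 4^k k-mers;
    ranked by q-value, then descending fold, then k-mer.
    """
    if not 2 <= k <= 8:
        raise ValueError(f"k must be in [2, 8], got {k}")
    if any(len(s) < k for s in fg_sequences):
        raise ValueError("every foreground sequence must be at least k long")
    if isinstance(bg, str):
        if bg != "shuffle":
            raise ValueError("bg must be 'shuffle' or a list of sequences")
        rng = np.random.default_rng(seed)
        if dinucleotide:
            bg_sequences = [_dinucleotide_shuffle(s, rng) for s in fg_sequences]
        else:
            bg_sequences = _mononucleotide_shuffle(fg_sequences, rng)
    else:
        bg_sequences = list(bg)
    fg_counts, n_fg = _count_kmers(fg_sequences, k)
    bg_counts, n_bg = _count_kmers(bg_sequences, k)
    n_kmers = 4**k
    results = []
    for kmer_tuple in itertools.product(_DNA, repeat=k):
        kmer = "".join(kmer_tuple)
        fg_c = fg_counts.get(kmer, 0)
        bg_c = bg_counts.get(kmer, 0)
        # half-count pseudocounts keep the background probability in (0, 1)
        # and make fold exactly 1 when fg and bg coincide
        bg_freq = (bg_c + 0.5) / (n_bg + 1)
        fg_freq = (fg_c + 0.5) / (n_fg + 1)
        fold = fg_freq / bg_freq
        p = float(stats.binom.sf(fg_c - 1, n_fg, bg_freq))
        results.append((kmer, fg_c, bg_c, fold, min(1.0, max(p, 0.0))))
    q = bh_fdr([r[4] for r in results])
    out = [
        MotifResult(kmer, fg_c, bg_c, fold, p, float(qv))
        for (kmer, fg_c, bg_c, fold, p), qv in zip(results, q)
    ]
    out.sort(key=lambda m: (m.q_value, -m.fold, m.kmer))
    return out


@dataclass(frozen=True)
class TermEnrichmentResult:
    term_id: str
    universe_size: int  # N
    term_size: int  # K genes in universe with the term
    query_size: int  # n
    overlap: int  # k query genes with the term
    p_value: float
    q_value: float


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) -> mapping term -> gene set."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"term map parse error at line {lineno}")
            gene, term = fields[0], fields[1]
            terms.setdefault(term, set()).add(gene)
    return terms


def term_enrichment(
    query_genes: Iterable[str],
    term_map: Mapping[str, set[str]],
    universe_genes: Iterable[str],
) -> list[TermEnrichmentResult]:
    """Hypergeometric upper-tail term over-representation with BH adjustment.

    Only terms with at least one query gene are tested and reported; results
    are sorted by q-value, then p, then term id.
    """
    universe = set(universe_genes)
    query = set(query_genes)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for term in sorted(term_map):
        members = term_map[term] & universe
        K = len(members)
        k = len(members & query)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, K, k, min(1.0, max(p, 0.0))))
    q = bh_fdr([r[3] for r in rows])
    out = [
        TermEnrichmentResult(term, N, K, n, k, p, float(qv))
        for (term, K, k, p), qv in zip(rows, q)
    ]
    out.sort(key=lambda t: (t.q_value, t.p_value, t.term_id))
    return out


@dataclass(frozen=True)
class SetOverlap:
    only_a: tuple[str, ...]
    common: tuple[str, ...]
    only_b: tuple[str, ...]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.only_a), len(self.common), len(self.only_b))


def gene_set_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> SetOverlap:
    """Exact three-way partition of two gene sets (Venn counts + members)."""
    a, b = set(set_a), set(set_b)
    return SetOverlap(
        tuple(sorted(a - b)), tuple(sorted(a & b)), tuple(sorted(b - a))
    )


@dataclass(frozen=True)
class QpcrMeasurement:
    """One relative-quantification measurement (target and reference Ct values)."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_control: float
    ct_ref_control: float

    @property
    def ddct(self) -> float:
        return (self.ct_target_test - self.ct_ref_test) - (
            self.ct_target_control - self.ct_ref_control
        )

    @property
    def fold(self) -> float:
        return 2.0 ** (-self.ddct)


def ddct_fold_change(measurement: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method."""
    for name, v in measurement.__dict__.items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite Ct value {name}={v}")
    return measurement.fold


def read_ct_table(path) -> pd.DataFrame:
    """TSV of Ct values with columns sample, ct_target_test, ct_ref_test,
    ct_target_control, ct_ref_control; returns the table with a fold column."""
    df = pd.read_csv(path, sep="\t")
    required = ["ct_target_test", "ct_ref_test", "ct_target_control", "ct_ref_control"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    df["ddct"] = (df.ct_target_test - df.ct_ref_test) - (
        df.ct_target_control - df.ct_ref_control
    )
    df["fold"] = 2.0 ** (-df["ddct"])
    return df


def motif_results_frame(results: Sequence[MotifResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def term_results_frame(results: Sequence[TermEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def gene_results_frame(results: Sequence[GeneEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
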