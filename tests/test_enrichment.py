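"""Multiple testing, gene/k-mer/term enrichment and qPCR quantification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ripcall.annotation_metrics import CountTable
from ripcall.enrichment import (
    QpcrMeasurement,
    bh_fdr,
    ddct_fold_change,
    extract_peak_sequences,
    gene_enrichment,
    gene_set_overlap,
    kmer_enrichment,
    term_enrichment,
)
from ripcall.genome_model import GenomicInterval
from ripcall.peak_calling import Peak


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.2]).tolist() == [0.2]

    def test_step_up_hand_case(self):
        # ranks 1..4: m*p/rank = 0.04 for every entry
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_q_dominates_p_and_is_monotone_on_sorted_p(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


def _table(c_ip, c_in, n_ip, n_in, genes=None):
    genes = genes or [f"g{i}" for i in range(len(c_ip))]
    return CountTable(
        counts=pd.DataFrame({"IP": c_ip, "input": c_in}, index=genes),
        library_sizes=pd.Series({"IP": n_ip, "input": n_in}),
        gene_lengths=pd.Series({g: 1000 for g in genes}),
    )


class TestGeneEnrichment:
    def test_equal_counts_not_enriched(self):
        table = _table([50], [50], 10_000, 10_000)
        (res,) = gene_enrichment(table, "IP", "input")
        assert res.log2fc == pytest.approx(0.0)
        assert res.status == "not_enriched"

    def test_matches_fisher_exact_tail(self):
        table = _table([100], [10], 10_000, 10_000)
        (res,) = gene_enrichment(table, "IP", "input")
        _, p_fisher = stats.fisher_exact(
            [[100, 10_000 - 100], [10, 10_000 - 10]], alternative="greater"
        )
        assert res.p_value == pytest.approx(p_fisher, rel=1e-9)
        assert res.status == "enriched"

    def test_zero_counts_both_sides(self):
        table = _table([0, 200], [0, 20], 10_000, 10_000)
        res = {r.gene_id: r for r in gene_enrichment(table, "IP", "input")}
        assert res["g0"].log2fc == pytest.approx(0.0)
        assert res["g0"].p_value == pytest.approx(1.0)

    def test_zero_library_rejected(self):
        table = _table([0], [0], 0, 10)
        with pytest.raises(ValueError):
            gene_enrichment(table, "IP", "input")

    def test_null_false_positive_rate_controlled(self):
        # IP and input drawn from the same multinomial: few q <= 0.05 calls
        n_genes, lib = 400, 200_000
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            probs = rng.dirichlet(np.full(n_genes, 5.0))
            c_ip = rng.multinomial(lib, probs)
            c_in = rng.multinomial(lib, probs)
            table = _table(list(c_ip), list(c_in), lib, lib)
            res = gene_enrichment(table, "IP", "input")
            frac = np.mean([r.q_value <= 0.05 for r in res])
            assert frac <= 0.08


class TestExtractPeakSequences:
    GENOME = {"c": "ACGTACGTAAGGTTTT"}

    def _peak(self, start, end, strand="+", summit=None):
        return Peak(GenomicInterval("c", start, end, strand), "g", 1, 1, summit=summit)

    def test_plus_strand(self):
        assert extract_peak_sequences([self._peak(0, 4)], self.GENOME) == ["ACGT"]

    def test_minus_strand_reverse_complement(self):
        assert extract_peak_sequences([self._peak(8, 12, "-")], self.GENOME) == ["CCTT"]

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="beyond contig"):
            extract_peak_sequences([self._peak(10, 20)], self.GENOME)

    def test_summit_window_clipped(self):
        (seq,) = extract_peak_sequences(
            [self._peak(0, 16, summit=2)], self.GENOME, window=8
        )
        assert seq == "ACGTACGT"


class TestKmerEnrichment:
    def test_identical_fg_bg_fold_one(self):
        seqs = ["ACGTACGTAACC", "GGTTACGTACGT"]
        results = kmer_enrichment(seqs, k=4, bg=list(seqs))
        assert all(r.fold == pytest.approx(1.0) for r in results)
        assert all(r.p_value > 0.05 for r in results)

    def test_count_conservation(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(20)]
        results = kmer_enrichment(seqs, k=4, seed=0)
        assert sum(r.fg_count for r in results) == sum(len(s) - 3 for s in seqs)

    def test_planted_motif_ranks_first(self):
        rng = np.random.default_rng(7)
        seqs = []
        for _ in range(200):
            s = list(rng.choice(list("ACGT"), 60))
            pos = int(rng.integers(0, 57))
            s[pos : pos + 4] = "AAGG"
            seqs.append("".join(s))
        results = kmer_enrichment(seqs, k=4, seed=0)
        assert results[0].kmer == "AAGG"

    def test_single_sequence_single_kmer(self):
        results = kmer_enrichment(["AAAA"], k=4, bg=["AAAA"])
        by_kmer = {r.kmer: r for r in results}
        assert by_kmer["AAAA"].fg_count == 1
        assert len(results) == 4**4

    @pytest.mark.parametrize("k", [1, 9])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            kmer_enrichment(["ACGTACGT"], k=k)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            kmer_enrichment(["ACG"], k=4)

    def test_dinucleotide_shuffle_preserves_dinucleotide_counts(self):
        from collections import Counter

        from ripcall.enrichment import _dinucleotide_shuffle

        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 200))
        shuf = _dinucleotide_shuffle(seq, rng)
        assert Counter(zip(shuf, shuf[1:])) == Counter(zip(seq, seq[1:]))


class TestTermEnrichment:
    def test_exact_hypergeometric_value(self):
        # N=10 genes, K=5 with the term, query n=4 all carrying it
        universe = [f"g{i}" for i in range(10)]
        term_map = {"T": set(universe[:5])}
        query = universe[:4]
        (res,) = term_enrichment(query, term_map, universe)
        assert res.p_value == pytest.approx(5 / 210)

    def test_saturated_term_p_one(self):
        universe = ["a", "b", "c"]
        (res,) = term_enrichment(universe, {"T": set(universe)}, universe)
        assert res.p_value == pytest.approx(1.0)

    def test_terms_without_query_hits_not_reported(self):
        universe = ["a", "b", "c", "d"]
        res = term_enrichment(["a"], {"T1": {"a"}, "T2": {"b"}}, universe)
        assert [r.term_id for r in res] == ["T1"]

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment(["x"], {"T": {"x"}}, ["a", "b"])

    def test_matches_exhaustive_enumeration_small_universe(self):
        # brute-force over all query subsets of the universe, N <= 12
        universe = [f"g{i}" for i in range(9)]
        term_genes = set(universe[:4])
        term_map = {"T": term_genes}
        n = 4
        for query in itertools.combinations(universe, n):
            k = len(term_genes & set(query))
            if k == 0:
                continue
            # oracle: exact tail by enumerating all C(N, n) draws
            total = math.comb(9, n)
            tail = sum(
                1
                for draw in itertools.combinations(universe, n)
                if len(term_genes & set(draw)) >= k
            )
            (res,) = term_enrichment(list(query), term_map, universe)
            assert res.p_value == pytest.approx(tail / total, rel=1e-9)


class TestGeneSetOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, (1, 2, 1)),
            ({"a", "b"}, {"a", "b"}, (0, 2, 0)),
            ({"a", "b"}, {"c"}, (2, 0, 1)),
        ],
    )
    def test_partition_counts(self, a, b, expected):
        assert gene_set_overlap(a, b).counts == expected


class TestDdct:
    def test_all_equal_fold_one(self):
        m = QpcrMeasurement(20, 20, 20, 20)
        assert ddct_fold_change(m) == pytest.approx(1.0)

    def test_ddct_minus_one_doubles(self):
        m = QpcrMeasurement(19, 20, 20, 20)
        assert ddct_fold_change(m) == pytest.approx(2.0)

    def test_worked_example(self):
        m = QpcrMeasurement(20, 18, 24, 18)
        assert m.ddct == pytest.approx(-4.0)
        assert ddct_fold_change(m) == pytest.approx(16.0)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(QpcrMeasurement(float("nan"), 20, 20, 20))

    @given(st.floats(-5, 5))
    @settings(max_examples=50, derandomize=True)
    def test_reciprocal_symmetry(self, x):
        fold_pos = QpcrMeasurement(20 + x, 20, 20, 20).fold
        fold_neg = QpcrMeasurement(20 - x, 20, 20, 20).fold
        assert fold_pos * fold_neg == pytest.approx(1.0)
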