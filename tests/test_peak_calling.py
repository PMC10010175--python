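"""Peak construction, permutation null, significance and set operations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripcall.genome_model import (
    AlignedRead,
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    Transcript,
)
from ripcall.peak_calling import (
    NullDistribution,
    Peak,
    build_peaks,
    call_peaks,
    depth_profile,
    gene_subseed,
    peak_pvalue,
    permutation_null,
    replicate_overlap,
    subtract_input,
    write_peaks_bed,
)


def _read(start, end, rid="r", chrom="chr1", strand="+"):
    return AlignedRead(GenomicInterval(chrom, start, end, strand), rid, "IP", 1)


def naive_depth(reads, span):
    """Independent per-base counting loop used as the depth oracle."""
    depth = [0] * span.length
    for r in reads:
        for i in range(r.interval.start, r.interval.end):
            if span.start <= i < span.end:
                depth[i - span.start] += 1
    return depth


class TestDepthProfile:
    def test_no_reads_all_zero(self):
        span = GenomicInterval("chr1", 0, 20)
        assert depth_profile([], span).tolist() == [0] * 20

    def test_two_identical_reads(self):
        span = GenomicInterval("chr1", 100, 110)
        reads = [_read(100, 110, "a"), _read(100, 110, "b")]
        assert depth_profile(reads, span).tolist() == [2] * 10

    def test_staggered_reads_match_naive_loop(self):
        span = GenomicInterval("chr1", 0, 50)
        rng = np.random.default_rng(0)
        reads = [
            _read(int(s), int(s) + int(l), f"r{i}")
            for i, (s, l) in enumerate(zip(rng.integers(0, 40, 30), rng.integers(1, 11, 30)))
        ]
        assert depth_profile(reads, span).tolist() == naive_depth(reads, span)


class TestBuildPeaks:
    def test_single_read_single_peak(self):
        (peak,) = build_peaks([_read(100, 150)], "g")
        assert (peak.interval.start, peak.interval.end) == (100, 150)
        assert peak.height == 1 and peak.n_reads == 1

    def test_one_bp_overlap_merges(self):
        (peak,) = build_peaks([_read(100, 150, "a"), _read(149, 200, "b")], "g")
        assert (peak.interval.start, peak.interval.end) == (100, 200)
        assert peak.height == 2  # depth 2 on [149,150)
        assert peak.summit == 149

    def test_touching_reads_stay_separate(self):
        peaks = build_peaks([_read(100, 150, "a"), _read(150, 200, "b")], "g")
        assert len(peaks) == 2

    def test_empty_input(self):
        assert build_peaks([], "g") == []

    @given(st.lists(st.tuples(st.integers(0, 200), st.integers(1, 30)), min_size=1, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_peaks_disjoint_and_partition_reads(self, raw):
        reads = [_read(s, s + l, f"r{i}") for i, (s, l) in enumerate(raw)]
        peaks = build_peaks(reads, "g")
        assert sum(p.n_reads for p in peaks) == len(reads)
        spans = sorted((p.interval.start, p.interval.end) for p in peaks)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # pairwise non-overlapping
        for p in peaks:
            assert 1 <= p.height <= p.n_reads


class TestPermutationNull:
    def test_read_filling_span_forces_height_one(self):
        null = permutation_null(GenomicInterval("chr1", 0, 50), [50], n_iter=200, seed=1)
        assert set(null.max_heights.tolist()) == {1}

    def test_span4_two_len3_reads_always_overlap(self):
        # any two placements of length-3 reads in a 4 bp span share >= 2 bp
        null = permutation_null(GenomicInterval("chr1", 0, 4), [3, 3], n_iter=500, seed=2)
        assert set(null.max_heights.tolist()) == {2}

    def test_span10_two_len2_reads_matches_enumeration(self):
        # starts 0..8 each; max height 2 iff |s1-s2| <= 1: 25 of 81 pairs
        null = permutation_null(GenomicInterval("chr1", 0, 10), [2, 2], n_iter=10_000, seed=3)
        frac = float((null.max_heights == 2).mean())
        p = 25 / 81
        se = (p * (1 - p) / 10_000) ** 0.5
        assert abs(frac - p) <= 3 * se

    def test_empty_read_lengths_rejected(self):
        with pytest.raises(ValueError):
            permutation_null(GenomicInterval("chr1", 0, 10), [], n_iter=10, seed=0)

    def test_overlong_reads_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            null = permutation_null(GenomicInterval("chr1", 0, 10), [25], n_iter=50, seed=0)
        assert set(null.max_heights.tolist()) == {1}
        assert "clamped" in caplog.text

    def test_deterministic_given_seed(self):
        span = GenomicInterval("chr1", 0, 100)
        a = permutation_null(span, [10, 10, 5], n_iter=300, seed=42)
        b = permutation_null(span, [10, 10, 5], n_iter=300, seed=42)
        assert np.array_equal(a.max_heights, b.max_heights)


class TestPeakPvalue:
    def _null(self, heights):
        return NullDistribution("g", len(heights), np.array(heights), 0)

    def test_height_above_all_maxima(self):
        null = self._null([1] * 500)
        assert peak_pvalue(2, null) == pytest.approx(1 / 501)

    def test_height_below_all_maxima(self):
        null = self._null([5] * 500)
        assert peak_pvalue(3, null) == 1.0

    def test_partial_tail_count(self):
        # 450 maxima strictly below, 50 at-or-above the height
        null = self._null([1] * 450 + [7] * 50)
        assert peak_pvalue(5, null) == pytest.approx(51 / 501)

    def test_monotone_non_increasing_in_height(self):
        rng = np.random.default_rng(5)
        null = self._null(rng.integers(1, 20, 1000).tolist())
        ps = [peak_pvalue(h, null) for h in range(1, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def _one_gene_annotation(length=2000, gene_id="g1"):
    tx = Transcript(f"{gene_id}.t", gene_id, [GenomicInterval("chr1", 0, length, "+")])
    return AnnotationSet([GeneModel(gene_id, "protein_coding", [tx])])


class TestCallPeaks:
    def test_pileup_retained_singletons_rejected(self):
        ann = _one_gene_annotation()
        pile = [_read(500, 550, f"p{i}") for i in range(20)]
        scattered = [_read(1000 + 100 * i, 1000 + 100 * i + 10, f"s{i}") for i in range(10)]
        peaks = call_peaks({"g1": pile + scattered}, ann, n_iter=500, alpha=0.05, seed=0)
        assert len(peaks) == 1
        assert peaks[0].height == 20
        assert 500 <= peaks[0].summit < 550

    def test_alpha_zero_empty(self):
        ann = _one_gene_annotation()
        peaks = call_peaks(
            {"g1": [_read(500, 550, f"p{i}") for i in range(20)]},
            ann, n_iter=100, alpha=0.0, seed=0,
        )
        assert peaks == []

    def test_per_gene_seed_stable(self):
        assert gene_subseed(7, "geneA") == gene_subseed(7, "geneA")
        assert gene_subseed(7, "geneA") != gene_subseed(8, "geneA")
        assert gene_subseed(7, "geneA") != gene_subseed(7, "geneB")

    def test_output_bed_byte_deterministic(self, tmp_path):
        ann = _one_gene_annotation()
        reads = {"g1": [_read(500, 550, f"p{i}") for i in range(15)]}
        paths = []
        for run in (1, 2):
            peaks = call_peaks(reads, ann, n_iter=200, alpha=0.05, seed=9)
            path = tmp_path / f"peaks{run}.bed"
            write_peaks_bed(peaks, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]


class TestSubtractInput:
    def _peak(self, start, end, gene="g", height=3, n=5):
        return Peak(GenomicInterval("chr1", start, end, "+"), gene, height, n)

    def test_overlapping_ip_peak_removed_whole(self):
        ip = [self._peak(100, 200)]
        assert subtract_input(ip, [self._peak(150, 160)]) == []

    def test_disjoint_sets_unchanged(self):
        ip = [self._peak(100, 200)]
        assert subtract_input(ip, [self._peak(300, 400)]) == ip

    def test_empty_input_is_identity(self):
        ip = [self._peak(100, 200), self._peak(500, 600)]
        assert subtract_input(ip, []) == ip

    def test_zero_residual_overlap(self):
        rng = np.random.default_rng(11)
        ip = [self._peak(int(s), int(s) + 50) for s in rng.integers(0, 5000, 40)]
        inp = [self._peak(int(s), int(s) + 30) for s in rng.integers(0, 5000, 20)]
        from ripcall.genome_model import interval_overlap

        kept = subtract_input(ip, inp)
        assert all(
            interval_overlap(k.interval, i.interval) == 0 for k in kept for i in inp
        )


class TestReplicateOverlap:
    def _peak(self, start, end, gene="g", height=3, p=0.01):
        return Peak(GenomicInterval("chr1", start, end, "+"), gene, height, height, p)

    def test_intersection_interval(self):
        (out,) = replicate_overlap([self._peak(0, 100)], [self._peak(50, 150)])
        assert (out.interval.start, out.interval.end) == (50, 100)

    def test_disjoint_gives_empty(self):
        assert replicate_overlap([self._peak(0, 100)], [self._peak(200, 300)]) == []

    def test_peak_spanning_two_partners_yields_two(self):
        wide = self._peak(0, 300, height=5)
        narrow = [self._peak(10, 50, height=2, p=0.02), self._peak(200, 260, height=9, p=0.001)]
        out = replicate_overlap([wide], narrow)
        assert [(p.interval.start, p.interval.end) for p in out] == [(10, 50), (200, 260)]
        # height = min, p = max of the parents; parents recorded
        assert [p.height for p in out] == [2, 5]
        assert out[0].p_value == pytest.approx(0.02)
        assert all(len(p.parents) == 2 for p in out)
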