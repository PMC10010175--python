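# Methods

## The binding model and the permutation test

A RIP-seq IP library is modelled as a mixture: most reads reflect the
abundance of each transcript (background), while a minority pile up where
the protein binds. The detection statistic is the maximum per-base depth
(*peak height*) of each merged read cluster within one gene, compared with
the distribution of the same statistic when the gene's reads are placed
uniformly at random over the gene's genomic span.

Key properties of this test:

- It conditions on the per-gene read count, so expression level alone
  cannot produce significance: a highly expressed gene gets a proportionally
  taller null.
- Randomisation is over the *genomic* span, introns included. Binding in a
  RIP experiment is substantially co-transcriptional (pre-mRNA), and
  intronic sites are first-class citizens. A spliced-transcript null is a
  possible future mode, not implemented.
- The empirical p-value uses the add-one estimator
  p = (1 + #{null ≥ h}) / (1 + B), so p ∈ (0, 1] always; ties count against
  the peak. With the default B = 500, the floor is 1/501 ≈ 0.002 and the
  default threshold α = 0.05 is comfortably above it.
- The null re-places *all* reads assigned to the gene (the observed read
  lengths, not a parametric length model). Reads longer than the gene span
  are clamped with a warning.
- Each gene draws its permutation stream from a sub-seed derived from the
  master seed and a CRC32 of the gene id, so results are independent of
  processing order and reproducible under parallelism.

The max-height sampler is vectorised (one bincount/cumsum per gene over a
B × span matrix); the unit suite verifies it against exhaustive enumeration
of every placement for spans ≤ 12 bp and ≤ 3 reads.

### Input subtraction and replicates

Input libraries (whole-lysate, no IP) are analysed by the identical
procedure and any IP peak overlapping an input peak by ≥ 1 bp is removed
whole — no trimming — because a shared pile-up is evidence of an artefact
(mappability, local amplification) rather than binding. Subtraction
ignores strand, as the input is not strand-selected evidence of binding.
Final sites are the pairwise intersections of the surviving peaks across
replicates; the intersection inherits the weaker height and the weaker
(larger) p-value of its parents.

### Peak summits and annotation

Once mean background depth approaches 1, single-linkage clusters chain far
beyond the bound site (at the package's reference scale — 100,000 reads of
50 nt over ~1 Mb of gene territory — mean depth is ≈ 5 and clusters span
kilobases). Each peak therefore records its *summit*, the leftmost
position of maximum depth, which is where the binding evidence is
concentrated. Region classification of a peak uses its summit, mirroring
how peak-annotation tools annotate peak centres; motif analysis likewise
uses fixed 100 bp summit-centred windows rather than full cluster
sequences. Reads and summit-less intervals are classified by the
whole-interval rule: the highest-priority label among all touched features,
with priority CDS > 5′UTR > 3′UTR > noncoding exon > intron > intergenic.
UTRs are the exonic parts of a coding transcript outside the CDS span,
oriented by strand; exons of transcripts without a CDS count as noncoding
exons.

## The synthetic experiment

`synthetic_data` generates the study the tests score against:

- **Genome and genes.** Random sequence at a configurable GC content
  (default 0.5). Genes of 2–8 kb are packed without overlap, 50 per
  synthetic chromosome, with random strands and intergenic gaps of
  0.3–1.5 kb. Each gene carries one transcript of 3–6 exons of 400–700 bp
  (introns ≥ 150 bp fill the remainder); 85% of genes receive a CDS
  spanning from inside the first to inside the last exon (leaving UTR
  stubs), the rest are annotated lncRNA. This architecture makes gene
  territory roughly half exonic — wide enough introns for intronic sites
  to sit clear of exons, yet exon-rich enough that a 0.65-intron-biased
  site set visibly shifts the IP read distribution toward introns relative
  to a genomically uniform input.
- **Expression.** Per-gene lognormal weights (μ = 0, σ = 0.5); libraries
  are multinomial draws over genes. σ = 0.5 gives an ~8-fold central 95%
  expression range — heterogeneous, but such that a typical bound gene
  still receives enough reads for an 8-fold 60 bp site to be resolvable at
  the reference library size; stronger heterogeneity starves the weakest
  bound genes of reads and no height-based test can recover their sites.
- **Sites and motif.** A configurable fraction of genes (default 20%)
  receives one 60 bp site, placed inside an intron with probability 0.65
  (else an exon), uniformly where it fits. The recognition motif (default
  AAGG) is written into the site in the gene's *sense* orientation — its
  reverse complement on minus-strand genes — with probability
  `motif_insertion_prob` (default 1).
- **Reads.** Single-end, fixed 50 nt. Input read starts are uniform over
  the valid starts of the gene span. IP reads fall in a planted-site
  window with probability p = (f−1)W / (G + (f−1)W) (W = starts
  overlapping a site, G = all valid starts), which makes the expected
  per-base depth at sites exactly f (`enrichment_fold`, default 8) times
  background; folds ≤ 1 collapse to pure background. Every library has
  exactly `library_size` reads (default 100,000). Each (sample, replicate)
  draws from its own fixed-offset stream of the master seed, so adding
  replicates never perturbs existing ones and the genome/truth never
  depend on the replicate count.

What the generator does *not* emulate: sequencing errors and base
qualities, paired-end fragments, splicing (reads are genomic), mappability
structure, PCR duplication, and the mature-mRNA composition of a real
input library (the real input is exon-dominated; ours is uniform over the
gene span). Passing tests therefore demonstrate the statistical machinery
under a clean mixture model, not robustness to those artefacts.

## Downstream statistics

- **RPKM** = 10⁹·C/(N·L) with N the reads assigned to genes in that
  sample and L the genomic span length. Sample correlations are Pearson on
  log2(RPKM+1) (the transform stabilises the heavy right tail).
- **Gene-level enrichment** (a deliberately simple stand-in for count-model
  differential tests): per gene, a one-sided Fisher exact test of
  [C_ip, N_ip−C_ip; C_in, N_in−C_in], computed as the hypergeometric upper
  tail; BH across genes; log2 fold change on library-normalised counts
  with pseudocount 1; "enriched" requires q ≤ 0.05 and log2FC ≥ 1 (both
  configurable). With whole-library margins the test is anti-conservative
  toward overdispersion, which is why the null false-call rate is checked
  empirically in the suite.
- **k-mer motif enrichment** (a deliberately simple stand-in for degenerate
  motif optimisers): exact counts of all 4^k k-mers (default k = 4, DNA
  alphabet, given strand only) in summit-window sequences versus a
  per-sequence mononucleotide shuffle (dinucleotide-preserving shuffle via
  a random Eulerian walk is available by flag); one-sided binomial tail
  with half-count pseudocounts on both frequencies (fold is exactly 1 when
  foreground equals background); BH over all 4^k k-mers; ranked by q, then
  fold. RNA-side motifs read with U→T (AAGG is reported in DNA letters).
- **Term enrichment**: hypergeometric upper tail per term restricted to
  terms with ≥ 1 query gene, BH across tested terms. Term maps are plain
  two-column TSV (gene, term); no ontology database is bundled.
- **Region-shift testing**: per-category two-proportion z-tests on pooled
  IP versus input read counts with BH correction. The replication unit is
  the read, a pragmatic choice; with replicate-level variance in real data
  this overstates confidence and should be read as descriptive.
- **qPCR**: ΔΔCt = (Ct_target − Ct_ref)_test − (Ct_target − Ct_ref)_control,
  fold = 2^−ΔΔCt. No primer-efficiency correction.

All BH adjustments are applied within one analysis family at a time, never
pooled across families.

## Numerical and interface conventions

- Coordinates are 0-based half-open everywhere internally; GTF (1-based
  inclusive) is converted on read and write. Half-open logic means
  touching intervals do not overlap — two reads sharing only a boundary
  stay in separate peaks.
- Gene assignment is strand-aware by default (`--ignore-strand` switches
  it off), by maximal span overlap with lexicographic tie-break; reads
  overlapping no gene go to a reserved intergenic bucket, which receives
  no permutation null (no territory to permute over) and is dropped from
  peak calling with a log message.
- Writers emit records in deterministic (chrom, start, end, id) order;
  the pipeline writes a SHA-256 manifest of every output, and a rerun with
  the same config and seed is byte-identical (logs and timing excluded).
- Degenerate inputs fail loudly: empty read-length lists for a null,
  malformed GTF lines (with line number), alpha outside (0, 1], zero
  library sizes, out-of-bounds peaks, queries outside the term universe.

## Problem sizes used in the test suite

The reference study the suite (and the acceptance script) scores is
200 genes × 100,000 reads × 2 replicates with 500-iteration nulls —
roughly a hundredth of a mammalian transcriptome — chosen so a full
five-seed replication of simulation, calling, subtraction and overlap
completes in a few minutes while every per-gene quantity (depth, null
resolution, site contrast) matches the reference conditions. Enumeration
oracles run on spans ≤ 12 bp where the placement space is exactly
computable.

## Known limitations

- Single-linkage peaks have no width refinement or deconvolution of
  adjacent sites; two sites chained by background coverage merge.
- The permutation null assumes uniform placement within the gene span;
  real coverage has composition and mappability structure the null does
  not model (the input subtraction absorbs part of this in practice).
- The Fisher gene-level test ignores biological replicate variance.
- Crosslink-site resolution (truncation/mutation signatures) is out of
  scope; resolution is peak-level.
- Published RIP-seq studies operate on tens of millions of reads against
  a full genome annotation; at that scale the figures they report are
  beyond desk-scale reproduction, so the package validates the algorithms
  on ground-truthed synthetic data instead.
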