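# ripcall

Permutation-based peak calling and downstream enrichment analysis for
RIP-seq / iRIP-seq experiments — identifying where an RNA-binding protein
sits on the transcriptome from immunoprecipitated (IP) sequencing libraries
and a matched input control.

## Who this is for

Groups analysing RIP-seq-style data (an IP library enriched for
protein-bound RNA plus a whole-lysate input, usually in replicates) who
want a transparent, fully reproducible implementation of the classic
per-gene permutation strategy for binding-site detection, together with the
standard downstream readouts: genomic region distributions, target biotype
classes, RPKM correlations, coverage tracks, k-mer motif enrichment,
gene-level IP-vs-input enrichment, term over-representation, and
2^-ΔΔCt qPCR quantification. A synthetic-data generator with machine-readable
ground truth is a first-class part of the package, so every statistical
claim the pipeline makes can be scored against planted binding sites.

## The method

**Peak formation.** Uniquely mapped reads are assigned to the gene whose
genomic span (introns included) they overlap most. Within a gene, reads
with ≥ 1 bp of mutual overlap are merged single-linkage into candidate
peaks; a peak's *height* is its maximum per-base read depth, and its
*summit* the (leftmost) position attaining that depth.

**Permutation null.** For each gene, reads of the observed number and
lengths are re-placed uniformly at random across the gene span, and the
maximum peak height of the random placement is recorded. With *B*
iterations (default 500) the empirical tail probability of an observed
peak of height *h* is

&nbsp;&nbsp;&nbsp;&nbsp;p = (1 + #{b : max-height_b ≥ h}) / (1 + B)

and peaks with p ≤ α (default 0.05) are retained. Ties count against the
peak, and the add-one correction keeps p > 0, so with B = 500 the smallest
attainable p is 1/501 ≈ 0.002.

**Input subtraction and replicate overlap.** The input library is analysed
by the identical procedure; IP peaks overlapping any input peak by ≥ 1 bp
are removed whole. Peaks surviving in both replicates are intersected
(height = min, p = max of the parents), giving the final binding-site set.

**Downstream.** Final peaks are annotated at their summit into
CDS / 5′UTR / 3′UTR / noncoding-exon / intron / intergenic classes and by
target biotype (mRNA / lncRNA / other); summit-centred windows feed an
exhaustive k-mer binomial test against a shuffled background; per-gene
IP-vs-input enrichment uses a one-sided Fisher exact test; term
over-representation uses the hypergeometric upper tail; all families of
p-values are Benjamini–Hochberg adjusted separately.

## Worked example

Simulate the reference two-replicate experiment (200 genes, 20% carrying a
single 60 bp site with 8-fold local enrichment, 100,000 reads per library,
the motif AAGG planted at every site) and run the full analysis:

```python
from ripcall import validate_config, run_pipeline

config = validate_config({
    "output_dir": "demo_run",
    "simulation": {"n_genes": 200, "library_size": 100_000, "seed": 1},
    "parameters": {"n_iter": 500, "alpha": 0.05, "seed": 1},
})
report = run_pipeline(config)
s = report["stages"]
print("peaks per replicate:", s["call_peaks"]["peaks"])
print("after input subtraction:", s["subtract_input"]["peaks"])
print("replicate-overlapped peaks:", s["replicate_overlap"]["peaks"])
print("IP1 x IP2 correlation:", s["annotate"]["correlations"]["IP_rep1|IP_rep2"])
print("target classes:", s["annotate"]["target_classes"])
print("top k-mer:", s["motifs"]["top_kmer"])
```

which prints:

```
peaks per replicate: {'IP_rep1': 46, 'IP_rep2': 47, 'input_rep1': 6, 'input_rep2': 9}
after input subtraction: {'rep1': 44, 'rep2': 47}
replicate-overlapped peaks: 38
IP1 x IP2 correlation: 0.9944
target classes: {'mRNA': 31, 'lncRNA': 7, 'other': 0}
top k-mer: AAGG
```

Forty sites were planted: the IP libraries yield ~46 significant peaks each
(a handful of them background), input subtraction and the replicate
intersection prune them to 38 high-confidence sites, the two IP replicates
correlate at r ≈ 0.99 on log2(RPKM+1), the bound genes split into mRNA and
lncRNA targets, and the planted AAGG motif is the top-ranked 4-mer. The
output directory contains the peak BEDs, bedGraph coverage tracks, RPKM
and region-distribution tables, enrichment TSVs and a checksummed manifest;
re-running with the same seeds reproduces every file byte for byte.

The same analysis is available from the shell:

```bash
ripcall simulate --out sim --seed 1
ripcall peaks --ip sim/reads_IP_rep1.bed --ip sim/reads_IP_rep2.bed \
    --input sim/reads_input_rep1.bed --input sim/reads_input_rep2.bed \
    --gtf sim/annotation.gtf --out peaks --iterations 500 --alpha 0.05 --seed 1
ripcall motifs --peaks peaks/peaks_overlap.bed --fasta sim/genome.fa --out motifs.tsv
```

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its defaults, numerical conventions, and known limitations.
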