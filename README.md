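# clipmotif

Analysis toolkit for discovering and quantifying short 3'UTR cis-regulatory
elements from PAR-CLIP and RNA-seq data — cluster calling, k-mer enrichment,
motif scanning, and motif-conditioned fold-change binning — plus a
synthetic-data generator with full ground truth so every stage is testable
at desk scale.

It is aimed at computational RNA biologists who want a transparent,
reproducible reimplementation of the standard PAR-CLIP + RNA-seq analysis
chain for RNA-binding-protein (RBP) target discovery: from SAM alignments
with MD tags to ranked binding-site clusters, enriched sequence motifs, and
per-gene repression estimates conditioned on motif content.

## The models

**Cluster calling.** PAR-CLIP's 4SU chemistry leaves T→C conversions in
reads crosslinked to an RBP. The background per-base mismatch rate is
estimated from non-T→C mismatches library-wide,

    r_bg = (n_nonT→C / aligned_bases) · 12/11,

and each candidate cluster (a maximal union of overlapping reads with ≥ 3
reads) is tested with a Poisson upper tail,

    p = P( X ≥ count_T2C ),   X ~ Poisson(r_bg · covered_T_bases),

followed by Benjamini–Hochberg correction (q ≤ 0.05), a filter on distinct
conversion positions (loc_T2C ≥ 2), and ranking by total conversions
(count_T2C).

**K-mer enrichment.** Against ≤ 200-nt flanking background regions, each
5-mer is scored

    Z = (X − μ) / σ,

with X the pooled proportion of 5-mer windows in cluster sequences and μ, σ
the mean and sd of per-background-region proportions.

**Motif binning.** Genes are scanned for the canonical heptamer `ATGAATT`
(AUGAAUU in RNA) and its 21 single-nucleotide variants; per-gene log2 fold
changes (built-in median-of-ratios estimator, or an ingested DESeq2-style
table) are binned by motif count, motif region, or variant identity, each
bin summarized by its empirical CDF and median log2FC.

See `docs/methods.md` for the full model description, parameter defaults,
and the generator's scope and limitations.

## Worked example

The `demo` subcommand runs the whole pipeline on one seed: simulate a
300-transcript transcriptome with a canonical motif planted in every tenth
3'UTR, write SAM/FASTA/GTF/counts, then call clusters, scan k-mers and
motifs, bin fold changes, and emit QC profiles:

```
clipmotif demo --seed 7 --outdir demo/
```

Top of `demo/clusters.bed` (BED6+; score = count_T2C):

```
#reference_name start end  name     score ... count_T2C loc_T2C expected_T2C p_value     q_value     region gene_id
tx0180          572   652  cluster1 52    ... 52        6       0.8339       4.3e-73     1.3e-71     utr3   gene0180
tx0160          911   964  cluster2 48    ... 48        3       0.6034       1.3e-72     2.0e-71     utr3   gene0160
```

Every retained cluster sits in a 3'UTR at a planted site: 52 observed
conversions against a Poisson expectation of 0.83 gives a vanishing
q-value. The run log reports the background estimate (`r_bg=0.0016`,
matching the simulated 0.002 per-base error rate) and 30/30 planted sites
recovered.

Top of `demo/kmers.tsv`:

```
kmer   x_cluster  mu_bg     sigma_bg  z      au_rich atg_containing
GAATT  0.02177    0.000567  0.00194   10.93  False   False
ATGAA  0.02041    0.000722  0.00183   10.78  True    True
TGAAT  0.02041    0.000629  0.00194   10.18  False   False
```

The three constituent 5-mers of the planted heptamer take the top three
Z-scores of all 1024, exactly the signature used to nominate the motif.

`demo/bins.tsv` (region-binned fold changes, baseMean ≥ 10):

```
label     n    median_lfc
utr3_1    30   -0.956
none      270   0.073
```

Genes with one 3'UTR motif are suppressed ~2-fold (median log2FC −0.96
against a planted per-copy effect of −1), while motif-free genes sit near
zero.

The same stages are available separately (`simulate`, `callclusters`,
`kmerscan`, `motifscan`, `diffbin`, `qc`) for real data: point
`callclusters` at any ungapped transcript-space SAM with MD tags plus its
FASTA/GTF, or feed `diffbin` an external differential-expression table with
`--de-table`.

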