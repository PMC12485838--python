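# Methods

## Overview

`clipmotif` reimplements, at desk scale, the computational chain used to
discover and characterize a short 3'UTR cis-regulatory element from PAR-CLIP
and RNA-seq data: (1) calling T->C conversion clusters against a Poisson
background, (2) ranking 5-mers by proportion Z-score against flanking
background sequence, (3) scanning transcripts for a canonical heptamer
(`ATGAATT` in DNA space) and its 21 single-nucleotide variants, and
(4) binning per-gene log2 fold changes by motif content. A synthetic-data
generator with known ground truth drives every stage, so the pipeline's
statistical behaviour (recall, precision, type-I error, effect recovery) is
testable without any external download.

All coordinates are 0-based half-open in memory; 1-based inclusive GTF
coordinates are converted at the file boundary. RNA motifs are represented
with T in place of U throughout, because every file format touched is
DNA-space.

## Cluster calling

PAR-CLIP crosslinking chemistry converts reference T to read C at crosslink
sites, so an excess of T->C mismatches over the sequencing-error background
marks binding sites. The model:

* **Background rate.** Let `n_non` be the number of non-T->C mismatch events
  library-wide and `B` the total aligned reference bases. The per-base
  background mismatch probability is estimated as
  `r_bg = (n_non / B) * 12/11`, where the 12/11 factor restores the T->C
  share excluded from the numerator under a uniform-substitution background
  (T->C is 1 of the 12 ordered substitution types).
* **Candidates.** Maximal intervals of contiguous coverage >= 1 (the union
  of overlapping or abutting reads), dropped when fewer than `min_depth`
  (default 3) reads support them.
* **Test.** For a candidate, the opportunity set for conversions is
  `covered_T_bases` — the sum over member reads of reference-T positions
  each covers — because T->C can only occur at a T. With
  `mu = r_bg * covered_T_bases`, the p-value is the Poisson upper tail
  `P(X >= count_T2C)`. Benjamini–Hochberg q-values are computed across all
  candidates; retained clusters satisfy `q <= alpha` (default 0.05) and
  `loc_T2C >= 2` (at least two distinct converted positions, suppressing
  single-position sequencing-error artifacts), and are ranked by `count_T2C`
  descending.

The estimator deliberately errs conservative: under a uniform-substitution
null, a covered T converts to C with probability `p_bg/3`, while `mu` uses
the full per-base rate `r_bg ~ p_bg`. The null simulation in the test suite
shows the realized type-I fraction at uncorrected p < 0.05 is well below
0.05; power at realistic conversion rates (0.2–0.5 per covered T) is
unaffected because planted signals exceed `mu` by orders of magnitude.
`mu = 0` with `count_T2C >= 1` yields p = 0 (reported as exactly 0.0, below
machine epsilon).

Region annotation uses majority overlap with the transcript's 5'UTR/CDS/3'UTR
intervals; ties break by precedence 3'UTR > CDS > 5'UTR > intron. Each
library is called independently; replicate merging is out of scope.

## 5-mer Z-score enrichment

For the top clusters (default: top 2000 after requiring >= 10 reads, ranked
by `count_T2C`), the <= 200-nt slices upstream and downstream of each
cluster — clipped at transcript bounds and with any overlap with another
cluster cut out — form the background regions. For each of the 1024 5-mers:

    X     = pooled proportion of 5-mer windows in cluster sequences
    mu    = mean of per-background-region proportions
    sigma = sample (n-1) standard deviation of those proportions
    Z     = (X - mu) / sigma

The standard deviation is taken *across* background regions, not from a
pooled background, because pooling destroys the between-region variance the
statistic standardizes against. A binomial standard error
(`sqrt(mu(1-mu)/W)` over the pooled window count `W`) is available via
`sigma_mode="binomial"` for sensitivity checks.

When `sigma == 0` (the background proportion is constant across regions,
typically because the 5-mer never occurs there), the Z-score is taken as
+inf or -inf according to the sign of `X - mu` — a 5-mer present in clusters
but absent from every background region is enriched with certainty — and NaN
when `X == mu`, in which case the 5-mer is flagged and left unranked. This
keeps a motif wholly absent from background (the interesting case) at the
top of the ranking instead of discarding it.

Classification flags follow the field's convention for AU-rich scatter
plots: `au_rich` iff the 5-mer has >= 3 A's or >= 3 T's; `atg_containing`
iff `ATG` occurs as a substring.

## Motif scanning and gene summaries

`enumerate_variants` produces the 21 Hamming-distance-1 variants of the
heptamer. Scanning is exact and overlap-permitting (step 1), restricted so
the full 7-nt window lies inside the queried region. Genes with multiple
transcripts are represented by the transcript with the longest annotated
3'UTR.

Variant presence in a gene's 3'UTR is **exclusive** by default: a gene
counts for variant v only if it has >= 1 occurrence of v and 0 occurrences
of the canonical motif in its 3'UTR. Without exclusivity a gene carrying
both would attribute the canonical motif's repression to the variant,
making the single-substitution tolerance tile uninterpretable. The
`--no-exclusive` flag disables the rule.

## Fold changes and binning

The built-in estimator is intentionally minimal: DESeq-style
median-of-ratios size factors (geometric-mean reference over genes with
all-positive counts), `baseMean` = mean normalized count over all samples,
and `log2FC = log2((mean_ind + 0.5) / (mean_ctl + 0.5))` with a 0.5
pseudocount. No dispersion estimation, shrinkage or Wald testing — the
binning analyses need only `baseMean` and `log2FC`, and an externally
computed differential-expression table (columns `gene_id`, `baseMean`,
`log2FoldChange`, optional `padj`) can be ingested instead; the significance
filter on ingested tables is `padj <= 0.05` and `|log2FC| > 1`.

Genes below `baseMean >= 10` (configurable; 100 is a common stricter
variant) are excluded before binning. Bin layouts:

* **site count:** {>= 2 motifs, 1 motif, bound-without-motif, unbound},
  counting motifs in the 3'UTR (`region` mode) or inside called clusters
  (`sites` mode);
* **region:** {3'UTR >= 2, 3'UTR 1, CDS, 5'UTR, none} with priority
  3'UTR > CDS > 5'UTR for multi-region genes;
* **variant tile:** 21 cells (position 1–7 x substituted base), each the
  median log2FC of genes carrying that variant exclusively, plus a canonical
  reference cell.

Each bin reports its gene list, size, median log2FC (even-sized bins use
the mean of the two central values) and an empirical CDF (right-continuous,
ties share a step). Note that the median of log2 fold changes equals the
log2 of the median fold change whenever the median is a single order
statistic, since log2 is strictly monotone; the test suite asserts this
commutation.

## QC profiles

* **XRPM** — crosslinked reads (>= 1 T->C) per million library crosslinked
  reads, per gene. By default a read must overlap one of the gene's retained
  clusters (`--xrpm-universe sites`); `all` counts any crosslinked read on
  the gene's transcript. XRPM sums to 10^6 whenever any crosslinked read
  exists.
* **Spearman matrix** — pairwise rank correlation of per-gene XRPM over the
  union gene universe, absent genes imputed as 0; constant vectors yield
  NaN for their pairs.
* **Metagene profile** — each cluster contributes its `count_T2C` at its
  midpoint's normalized position within its region; regions are
  concatenated with fixed widths of 10/30/30 bins (5'UTR/CDS/3'UTR) and the
  profile normalized to sum 1. Fixed widths were chosen over data-scaled
  ones so profiles are comparable across libraries.
* **Region composition** — fraction of clusters per region label.

## Synthetic-data generator

The generator emulates the two data modalities the analyses consume.

**Transcriptomes.** `n_transcripts` transcripts with region lengths drawn
uniformly from configurable ranges (defaults 50–150 nt 5'UTR, 300–900 nt
CDS, 200–600 nt 3'UTR). Background sequence is rejection-sampled (capped at
1000 attempts per region) so that no occurrence of the canonical heptamer or
any of its 21 variants exists anywhere except where `plant_motifs` writes
one; planting redraws offsets until a rescan finds exactly the planted
occurrences, so junction artifacts cannot arise. This exclusivity is what
makes planted-motif recovery tests exact.

**PAR-CLIP reads.** For each placement, `read_depth` reads (default 50)
start uniformly over the window in which the read fully covers the
placement. Each reference T inside a placement converts to C with `p_conv`
(default 0.3, a typical 4SU conversion efficiency); every aligned base
additionally mismatches with `p_bg` (default 0.002, a short-read error
rate), the substitute uniform over the three alternatives — so background
T->C occurs at share 1/3 at T positions, giving the caller a realistic null.
Background reads are Poisson(`bg_read_rate`, default 2) per transcript,
uniformly placed. Output is coordinate-sorted SAM with MD/NM tags computed
against the reference.

**Counts.** Control means are log-normal (default log-mean 6.0, log-sd 1.0,
i.e. a median of ~400 counts); the induced mean of gene g is
`mu_g * 2^(-delta * k_g)` with `k_g` the number of canonical 3'UTR
placements and `delta` the per-copy suppression (default 1.0, i.e. 2-fold
per site — the order of magnitude reported for single-site targets of
deadenylation-recruiting RBPs). Counts are negative-binomial with dispersion
0.05 (typical for technical-replicate cell-line RNA-seq), 4 replicates per
condition. Variant or custom placements contribute no suppression unless a
per-variant delta map is supplied.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spliced genome-space alignments, PCR duplicates
and adapter artifacts, non-uniform crosslinking efficiency across sites,
transcript-abundance-coupled read depth, antisense (A->G) libraries, and
between-replicate biological variance beyond the NB dispersion. Insert-size
and depth distributions of real libraries are unknown; the read-model
parameters are free knobs, not estimates.

Determinism: every stochastic routine takes its seed from `SimConfig.seed`
(sub-streams offset by +1 for reads, +2 for counts), so identical configs
reproduce byte-identical files.

## Problem sizes and numerical choices

Simulation-backed tests use 300–1000 transcripts with shortened regions
where only count statistics matter, 2–3 fixed seeds per property, and the
read model at its default depth; these sizes put every recovery statistic
(recall/precision >= 0.9, type-I <= 0.07 over >= 500 candidates,
median-lfc windows of +/- 0.3) comfortably inside their acceptance bands
while keeping the full suite under a minute. Known estimator caveats:

* Median-of-ratios normalization assumes most genes are non-DE; when a
  large fraction of genes is suppressed, size factors absorb part of the
  effect and log2FC estimates shift toward zero by the compositional
  offset. At the default planting fraction (~10–15% of genes) the shift is
  < 0.15 log2 units.
* The 0.5 pseudocount biases |log2FC| downward for genes with mean
  normalized counts below ~20; at the default expression scale the bias on
  bin medians is negligible.
* BH q-values use the standard step-up procedure; the paper-side analysis
  names Poisson significance without a correction rule, so the FDR level is
  a package choice (alpha = 0.05, configurable).
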