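# Methods

`tssbind` implements the positional analysis used to characterize
transcription factors — such as the ZFX family — that bind CpG-island
promoters *downstream* of the transcription start site and act as
activators there. This note describes the models, estimators, and design
choices, and what the synthetic data generator does and does not emulate.

## Coordinate model

All intervals are 0-based half-open (BED convention); GTF input is
converted on read (start − 1). Distances to a TSS are signed in the
transcription direction: for a summit *s* and a transcript with TSS *t*,

    d = s − t   on the + strand
    d = t − s   on the − strand

so *d* > 0 always means "inside the transcribed region". The TSS of a
minus-strand transcript is `interval.end − 1` (the last base of the
half-open interval). Nearest-TSS assignment minimizes |d|; ties go to the
lexicographically smallest transcript id so annotation is deterministic.
A peak is a *promoter* peak when −upstream ≤ d ≤ +downstream with an
inclusive boundary; the default window is (1000, 1000) bp. This window is
a parameter, not a published value: it encloses the ±240 bp near modes
while excluding the ±2 kb far modes. A promoter is CGI-class when the
window overlaps ≥ 1 bp of a CpG-island interval (half-open overlap
algebra). Genes with several transcripts are reduced to gene level by
"bound if any transcript's promoter window contains a summit"; a
multiply-bound gene takes the cluster label of its highest-scoring
promoter peak.

Summit positions are classified against gene structure with priority
5′UTR > first coding exon > first intron > other transcribed; positions
5′ of the TSS are `upstream`, positions beyond the transcript are
`intergenic`. Transcripts without CDS collapse the first two categories
into `5'-exonic`.

## Synthetic data generator

The generator produces every input the analysis consumes, with a planted
truth manifest, so each stage can be tested without downloads.

**Genome.** `n_chroms` × `chrom_length` chromosomes (default 4 × 20 Mb)
with `n_genes` (default 10,000) evenly spaced, non-overlapping genes of
fixed anatomy: 200 nt 5′UTR, CDS exons of 300/400/700 nt, introns of
800/600 nt (3 kb body), random strand. A configurable fraction of
promoters (default 0.7) carries a CpG island spanning [−500, +1500)
around the TSS. Background sequence is i.i.d. at GC = 0.40. Island
sequence uses a first-order Markov chain constructed so that the
stationary base distribution is *exactly* the configured composition
(GC = 0.65) and the CpG dinucleotide frequency is exactly
`oe · πC · πG` (default o/e = 0.75): the independent joint dinucleotide
law is reweighted at (C,G) with compensating mass shifted along the C row
and G column, keeping both marginals fixed. The known 8-mer motif
AGGCCTAG is planted once per island (it contains GGCCT, so both survey
motifs are planted together).

**Peaks.** Each peak picks a transcript anchor (without replacement when
`n_peaks` ≤ transcript count, emulating an IDR-deduplicated list) and a
latent component from the five-part TSS-relative mixture

| component  | law                | weight |
|------------|--------------------|--------|
| down_near  | N(+240, 120)       | 0.25   |
| up_near    | N(−240, 120)       | 0.15   |
| down_far   | N(+2000, 300)      | 0.10   |
| up_far     | N(−2000, 300)      | 0.10   |
| diffuse    | U(−3000, +3000)    | 0.40   |

mapped through the anchor's strand. Peak widths are log-normal with
median 1800 bp (σ = 0.25) in ChIP-seq mode and 300 bp in ChIP-exo mode,
matching the ~6× width contraction exonuclease trimming produces. Scores
are gamma (shape 4) with component-specific scale, the downstream-near
component strongest, so amplitude ordering is part of the planted truth.
Coverage is the sum of score-scaled triangular kernels of each peak's
width centered on its summit, binned at 20 bp — cheap, deterministic, and
shape-preserving.

**Expression.** Negative-binomial counts (Gamma–Poisson, dispersion 0.05)
for control, two single-KO clones, and three DKO clones, 3 replicates
each. Gene baselines are log-normal around 500 (log2 sd 0.8). Direct
targets (genes with a downstream-bound promoter) are scaled by
2^(−2) = 4-fold down in the DKO clones; a disjoint unbound indirect set
is scaled 2-fold up. Single-KO clones are generated exchangeable with
control — a simplification of the weaker single-knockout phenotype; the
consensus machinery only needs the DKO contrast.

**Methylation.** Probes are placed uniformly in promoter windows
([−1500, end of first coding exon], transcription direction). For probe
beta β and array intensity I = 1000, M = round(I·β·e) and
U = round(I·(1−β)·e′) with independent log-normal multiplicative noise
(sd 0.02); a configurable fraction of entries gets detection p > 0.05.
A planted set of probes has Δβ = −0.3 in the knockout condition.

**What the generator does not emulate:** mappability and copy-number
structure, read-level artifacts, realistic gene-length/isoform diversity,
correlated probe noise, batch effects, and open-vs-closed chromatin
context. Passing tests therefore demonstrate that the *analysis logic*
recovers planted structure under the stated statistical model, not that
it is robust to every artifact of real data.

## Signal matrices, profiles, and clustering

A signal matrix has one row per anchor (transcript or annotated peak),
covering ±3000 bp of the TSS in 20-bp bins, read upstream→downstream on
both strands (minus-strand rows use a mirrored bin-index map so that an
impulse at +d lands in the same column regardless of strand; the
left-edge convention makes coordinate-reversal invariance exact at bin
resolution). The ±3 kb window is chosen to contain the ±2 kb far modes.

**Mode detection.** Tag-density and summit-frequency profiles are
smoothed with a Gaussian kernel (σ = 3 bins = 60 bp, roughly
σ·n^(−1/5) for the planted 120-bp spread at the default peak count) and
the primary mode is the argmax bin center, ties broken toward positive
(downstream) offsets. A three-point parabolic interpolation around the
argmax gives a sub-bin refined estimate (`primary_mode_refined`); in
repeated simulations at default scale the refined estimate stays within
one 20-bp bin of the planted +240 mode. The shoulder is the largest
local maximum of a 5-bin moving-average-smoothed profile on the opposite
side of the TSS from the primary mode.

**Clustering.** Rows are divided by their maximum (all-zero rows dropped
and counted) so K-means clusters by shape and position, not depth;
scikit-learn's k-means++ with a fixed seed and `n_init=10` provides the
iterations. Labels are renumbered 1..k by descending mean total *raw*
signal, so "cluster 1" is the strongest class, as in the usual naming of
TF peak classes. Sub-clustering re-runs K-means on the member rows of
one cluster (or the union of several — the far/diffuse "combination"
material is typically split across two clusters whose centroid modes lie
beyond ±1 kb) and names sub-centroids by mode location and amplitude:
upstream-far (< −1 kb), downstream-far (> +1 kb), over-TSS, and weak
(centroid max < 25% of the global centroid max).

**Clustering evaluation.** The planted mixture contains a 40% diffuse
component whose rows are, at any given offset, distributionally identical
to localized rows at that offset; no clustering can recover their labels,
and k = 4 cannot represent 5 classes. Recovery is therefore scored as the
adjusted Rand index over the rows from the four *localized* components
(ARI ≈ 0.94 at default scale); the diffuse rows are excluded from the
truth comparison, not from the clustering itself.

**Correlation and group signal.** Genome-wide sample correlation is the
Pearson correlation of log(1 + signal) over 10-kb bins (bin size
configurable; zero-variance tracks yield NaN and are flagged). Group
comparisons (e.g. H3K36me3-like signal at bound vs unbound promoters)
report per-group mean profiles and the ratio of overall means, with an
infinite ratio flagged rather than masked.

## Motif null

Scanning is exact/IUPAC, both strands by default (a TF motif is
orientation-free on double-stranded DNA), implemented as a compiled
regular expression with lookahead so overlapping occurrences all count;
`N` in the sequence never matches. The randomized background samples
width-matched regions uniformly (with replacement across source regions)
from CpG-island promoter intervals; the width curve (20 / 200 / 2000 nt)
uses *nested* sampling — each narrower region drawn inside the previous
sample — so coverage is non-decreasing in width by construction. Peak
coverage uses the full called interval in seq/exo modes and summit ± 10
nt in ChExMix mode. On GC-rich islands a 5-mer like GGCCT has
per-position hit probability ≈ 2·(GC/2)⁵ ≈ 0.007, so 2-kb windows are
covered with probability ≈ 1 − (1−p)^2000 ≈ 1: apparent motif
"enrichment" in wide peaks is a width artifact, which is exactly what
the null makes visible.

## Differential expression and consensus

The DE caller is plumbing for synthetic counts, not an edgeR
reimplementation: median-of-ratios size factors, log2(normalized + 0.5),
and a two-sample t with empirical-Bayes variance moderation — per-gene
pooled variances squeezed toward the median gene variance with 10 prior
degrees of freedom, p-values on the augmented df, Benjamini–Hochberg
adjustment. Moderation is essential at 3 replicates: a raw Welch test's
variance estimate at ~4 df is so noisy that all-clone recovery of planted
4-fold targets drops to ~36%, while the moderated test reaches ~100% at
~2% empirical FDR in the same Monte-Carlo. A gene is a DEG when adjusted
p < 0.05 *and* fold change (ratio of normalized means, no shrinkage) is
strictly beyond 1.5. Consensus sets are exact set operations over
per-clone DEG lists ("all clones" and "≥ 2 clones"); when published
per-clone tables are supplied through the tolerant reader
(`read_deg_table`, column names configurable), the caller is bypassed and
consensus reproduces printed counts as pure set algebra. Responding
promoters are the exact intersection of (bound ∧ down in all clones) with
(up upon re-expression).

## Methylation

β = M/(M+U), with M+U = 0 masked (NaN), never coerced to 0; no intensity
offset is added (configurable choice, documented rather than hidden).
Entries with detection p strictly above 0.05 are masked per sample.
Promoter probes lie in [TSS − 1500, end of first coding exon] measured in
the transcription direction, against any transcript (the all-transcripts
option; longest-transcript reduction is a caller-side filter). Condition
β for replicated samples is the mean of unmasked betas. A probe is
hypo-/hypermethylated when the signed delta (KO − control) strictly
exceeds ±0.2.

## Numerical and degenerate-input conventions

Seeded determinism everywhere: every generator and the pipeline derive
per-stage sub-seeds from one master seed (Knuth multiplicative hash mixed
with a CRC of the stage name, kept below 2³¹); identical config + seed
gives byte-identical outputs. Degenerate cases are flagged, not silently
absorbed: all-zero profiles (undefined modes), duplicate-row K-means
(fewer effective centroids), zero-variance tracks (NaN correlation),
zero-library samples (dropped with a warning), truncated summit windows
at sequence boundaries (counted). Boundary rules are strict and tested:
promoter windows inclusive, DEG fold-change threshold exclusive,
detection-p exclusive, delta-beta cutoff exclusive.

## Problem sizes

The default synthetic study uses 4 × 20 Mb chromosomes, 10,000 genes,
10,000 ChIP-seq and 10,000 ChIP-exo peaks, 5,000 randomized background
regions per width, 18 RNA-seq samples over 10,000 genes, and 2,000
methylation probes — large enough for the clustering and mode-recovery
statistics to be stable across seeds while the full pipeline completes in
well under a minute on one CPU.

## Known limitations

* The DE statistic is not edgeR; printed DEG counts from a real study are
  reproduced only through the supplied-table path, by design.
* Cluster naming by centroid mode/amplitude codifies what is usually done
  by visual inspection; the ±1 kb far cutoff and 25% weak-amplitude
  threshold are conventions, exposed as parameters.
* The CGI Markov model controls composition and CpG o/e only; it does not
  reproduce higher-order sequence structure, so motif-null baselines on
  real promoters will differ quantitatively from the synthetic ones.
* bigWig output is not written (bedGraph only); IDAT parsing and array
  normalization are out of scope — pre-processed intensities are the
  input contract.
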