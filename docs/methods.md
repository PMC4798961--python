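# Methods

clipscan implements the statistical core of a CLIP-seq analysis for an
RNA-binding protein (RBP) with U-rich specificity, of the kind studied in
human brain: where does the protein bind (peak calling), how strongly per
transcript (binding quantification), what changes between conditions
(differential counts), which cassette exons respond (splicing GLM), and
whether binding is redistributed onto Y RNAs under stress (sequestration).
This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Tag preprocessing

Raw CLIP reads carry a degenerate 5' barcode marking independent ligation
events. Quality filtering requires every barcode base to score >= 20 and
the remaining bases to average >= 20. PCR duplicates are exact full-sequence
duplicates (barcode included); reads differing only in the barcode are
independent captures and are kept. After mapping, tags within a sample
collapse to one per (chromosome, strand, 5'-most position): the crosslink
site fixes the 5' end, so equal-start tags of different lengths are
digestion variants of one event. The 5'-most position of a minus-strand
tag is its half-open interval end. Collapsing is idempotent and never
crosses samples — cross-sample collapsing would destroy the biological
complexity statistic below.

## Peak calling

Unique tags from all samples are pooled per gene and clustered into maximal
runs of positions covered by at least one tag. The PeakHeight (PH) of a
cluster is its maximum coverage; the peak interval is the leftmost maximal
run attaining PH (a deterministic tie-break), which equals the number of
tags over the summit when all tags share one length.

Significance is assessed against a uniform null: the gene's n unique tag
starts are iid uniform on its unspliced span (TSS to TES, length L) — the
span rather than the mature transcript because intronic binding is dense
and real for this protein family. The p-value is

    p = P( max over t of #{starts in [t, t+w)} >= PH ),

with window w equal to the sample-median tag length, which makes the
coverage-based PH and the start-count null commensurable. Two regimes:

* **n <= 10 and w/L >= 0.04 — exact.** The no-hit event is the convex
  polytope {0 <= x_(1) <= ... <= x_(n) <= 1, x_(i+k-1) - x_(i) >= w/L};
  its volume, scaled by n!, is computed with Qhull. This reproduces the
  classical closed forms (1 - ((L-w)/L)^2 for n = k = 2; the spacings
  formula 1 - (1 - (n-1)w/L)^n for k = 2 is special-cased for all n) and
  matches 10^5-replicate Monte Carlo within 3 MC standard errors across
  the grid n <= 10, L/w <= 20. Near-degenerate polytopes retry with
  triangulated, wide-merge Qhull options; thin windows (w/L < 0.04) skip
  the geometric path entirely because Qhull's precision model breaks
  there while the approximation below is already excellent.

* **general n — product approximation.** p = 1 - Q2 (Q3/Q2)^(L/w - 2),
  where Q2 (no hit within two adjacent windows) is computed exactly via a
  ballot-path reflection identity — the number of up/down orderings in
  which a lattice path from a to b touches level k is C(a+b, k)/C(a+b, a)
  of all orderings — summed over the trinomial cell counts; Q3 uses the
  same identity with a factorized-interleaving approximation whose error
  involves three points falling in three adjacent windows and vanishes for
  w << L. Assembly is in log space, so deep-tail p-values (10^-100 and
  below) retain full relative precision. The approximation deliberately
  trades accuracy at moderate p for speed at genome scale; at coarse L/w
  and mid-range p its absolute error can reach a few percent, which is
  irrelevant downstream of a Bonferroni threshold of 0.01 over ~10^4
  clusters.

Bonferroni multiplicity is the number of clusters tested transcriptome-wide.
A peak is retained if the adjusted p is below alpha (default 0.01) and its
biological complexity (BC) — the number of samples with at least one tag
overlapping the peak interval — reaches min_bc (default 5 of 8).
On pure-null simulations the family-wise false-peak rate is at or below
alpha; planted windows of tag-length width with 10-fold enrichment and
>= 20 expected pooled tags are recovered with sensitivity >= 0.9.

## Binding quantification

cpm = count * 1e6 / library size; rpkm additionally divides by the gene's
constitutive-exon length in kb (exon regions shared by all annotated
transcripts — the stable part of the gene model). A gene is *expressed*
when cpm exceeds 1 in at least min_samples samples. Peak heights become
comparable across experiments as PH_cpm = PH * 1e6 / pooled CLIP library
size, and normalized PH divides by the gene's mean rpkm so abundant
transcripts do not dominate: norm_PH is undefined (and the peak excluded
from rankings) when rpkm is 0. Per-gene binding is the sum of PH over
peaks; normalized binding sums norm_PH; 3'UTR and intronic binding restrict
to peaks whose summit (leftmost maximal-coverage position) falls in that
region, with annotation precedence 3'UTR > 5'UTR > CDS > noncoding exon >
intron — peaks can span boundaries and the summit is the binding-relevant
point; the precedence avoids double counting and reflects the 3'UTR-heavy
biology of this protein. Top targets are the N = 1000 genes with the
highest normalized binding. Genomic distributions come in raw (fraction of
peaks per category) and per-nucleotide (divided by total category length,
rescaled to sum 1) modes. The meta-exon map aggregates norm_PH by summit
distance (transcript orientation, +-2.5 kb, 50-nt bins) from the
boundaries of regulated exons, separately for inclusion- and
exclusion-associated exon sets.

## Differential counts

Both gene counts and peak-height counts run through the same engine:
TMM normalization (M-values trimmed 30% per tail, A-values 5%, zero
features excluded, delta-method precision weights, factors rescaled to
geometric mean 1, reference = sample with the most typical upper-quartile
cpm), a common NB dispersion phi maximizing the Cox–Reid adjusted profile
likelihood (golden-section on log10 phi; a boundary optimum reports
phi = 0), and per-feature NB GLMs with log link and log effective library
size offsets, fitted by IRLS vectorized across features. The condition
effect is tested by likelihood ratio against the nested model without
condition (chi-square, df = number of condition coefficients), with batch
as a fixed covariate in both models. FDR uses Storey q-values (lambda grid
0.05–0.95 step 0.05, cubic-smoothed pi0 evaluated at lambda = 0.95,
falling back to pi0 = 1 for small inputs); q-values are never above
Benjamini–Hochberg when pi0 < 1. A pseudo-count (0.5 cpm) enters only the
*reported* log2 fold change of features with an all-zero group, never the
fit. This is a deliberate simplification of the edgeR-style analysis — one
common dispersion, no empirical-Bayes tagwise shrinkage, no
quasi-likelihood — validated by calibration: null LRT p-values are uniform
(KS), phi = 0.1 is recovered within 20% at 10^4 genes, and planted 2-fold
changes at mean 100 are detected with sensitivity >= 0.8 at FDR < 0.05.
The log2FC estimator's error floor is ~sqrt((1/mu + phi)/2)/ln2 per 4v4
contrast, so recovery tests run at low dispersion where that floor is
below the asserted tolerance.

## Cassette-exon splicing

Each exon has two inclusion junctions and one skipping junction per
sample. Per sample, inc = (J_up + J_dn)/2 — averaging keeps the binomial
denominator on the read scale without double-counting an inclusion read's
two junctions. The inclusion fraction of a condition pools counts:
I = sum(inc)/sum(inc + J_skip); dI = I(cond1) - I(cond2) is reported from
pooled counts, not fitted coefficients. Exons are testable when the
library-size-normalized pooled reads of *each* isoform reach 5 in *each*
condition (the stricter per-isoform-and-condition reading; a config switch
relaxes it). The test is a binomial GLM with logit link on
(round-half-even inc, J_skip) with intercept + condition + batch, LRT
against the no-condition model, chi-square with 1 df. Completely separated
exons refit with a small ridge penalty (1e-4) and carry a ``penalized``
flag. High-confidence events require q < 0.05 and |dI| >= 0.1 (inclusive
threshold, direction retained). Calibration: type-I error at p < 0.05
within [0.035, 0.065] on 2000 null exons at depth 200, 4v4; a planted
|dI| = 0.4 is estimated within +-0.05 and detected with sensitivity >= 0.9.
Exons are associated with intronic peaks whose summit lies within
+-2.5 kb of the exon body, labeled upstream/downstream in transcript
orientation.

## Y RNA analysis

Tags count toward a Y RNA when their interval overlaps its locus; tags
overlapping more than one Y RNA are discarded under the default
unique-only policy (a best-match policy assigns them to the
highest-count locus, ties to the lexicographically first — emulating the
permissive-alignment strategy). A Y RNA is *bound* when it has tags in at
least two samples, counted across all samples regardless of condition.
Motif enrichment among bound Y RNAs uses a one-sided Fisher test on the
bound/unbound x motif+/motif- table. The condition comparison normalizes
counts by *whole-library* sizes (never by Y-panel totals, which would
absorb a genuine binding shift), averages within condition and applies a
paired one-sided Wilcoxon signed-rank test across Y RNAs. The
"paired rank-sum" wording that sometimes accompanies such analyses is read
as the signed-rank test — a rank-sum test cannot be paired. Subject
grouping into high/low Y-binding uses deterministic 1-d 2-means on log10
totals, initialized at the extremes.

## Statistics toolbox

The hypergeometric upper tail P(X >= k) is an explicit log-space sum of
log-pmf terms (logsumexp), exact for all population sizes and stable to
p < 10^-300; it matches full enumeration for N <= 30 and reproduces
published overlap p-values of order 10^-287 within 10% relative error in
log10. One-sided Fisher equals the hypergeometric tail; the two-sided
version sums tables at least as improbable as observed (scipy). The
Wilcoxon signed-rank test drops zero differences, midranks ties, and uses
an exact sign-flip convolution (ranks doubled to integers) up to 25
informative pairs — scipy's exact method refuses ties, but the all-ties
case (every difference equal) is exactly the textbook example with
p = 1/2^n — and a tie-corrected normal approximation above. The one-sided
two-sample KS statistic is D+ = sup[ECDF_b - ECDF_a], rejecting when b is
stochastically smaller. The motif scanner accepts windows equal to a base
symbol repeated (default T6) with at most one substitution by an allowed
symbol (default G): exactly 7 accepted hexamers; N never matches; 5-mer
and A/C-substitution variants are explicit modes, not defaults.

## Synthetic data

The generators produce exactly the structure the estimators assume, which
is what makes their tests sharp and also bounds what they show. Gene
models: non-overlapping genes on one synthetic chromosome, 2+ exons,
terminal 3'UTR (default 25% of exonic length), 5'UTR fixed at 5%. CLIP
tags: starts uniform on the gene span except in rectangular enrichment
windows (a window of width W and enrichment e receives start mass eW
against background L - W, so its expected start fraction is
eW/(L - W + eW)); tag length fixed at 50 nt per sample. Junction counts:
per exon/sample Poisson total depth, inclusion ~ binomial with
logit-linear predictor baseline + condition effect + per-(exon, batch)
Gaussian offsets; batches are assigned imbalanced across conditions (3:1
at 4v4) because balanced batches cancel exactly out of the condition
contrast and would make the covariate vacuous. Gene counts: gamma-Poisson
with lognormal relative abundances and controlled log2 fold changes.
Y RNA panel: 100-nt sequences with a controlled motif-positive fraction
(motif-negative sequences rejection-sampled to carry none) and a
multiplicative condition-2 Poisson rate shift on motif-positive Y RNAs.
All generators are byte-deterministic under their seed and emit truth
tables.

What passing these tests does *not* show: robustness to mappability and
crosslink-site biases, overdispersed or autocorrelated tag backgrounds
within genes, annotation errors, tagwise dispersion variation, or junction
mis-assignment — real-data phenomena the generators intentionally omit.

## Problem sizes and defaults

The validation suite runs at desk scale: 500-gene genomes and ~10^4 tags
for null peak calling (100 replicates), 2000 exons at depth 200 for
splicing calibration, 10^4 genes and 8 samples for the count engine, 100
Y RNAs at base rate 10 with a 4-fold shift. Thresholds default to the
analysis constants of the study design: scan alpha 0.01 after Bonferroni,
BC >= 5 of 8, cpm > 1 for expression, FDR < 0.05, |dI| >= 0.1, 2.5-kb
exon flanks, top 1000 targets, 50-nt tags. All are config keys.
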