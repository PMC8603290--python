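# Methods

`melpipe` re-implements the computational core of a tumor/normal melanoma
characterization study as a tested pipeline: somatic-variant consensus
filtering with tumor mutation burden (TMB), a GC-adjusted log-R-ratio (LRR)
copy-number caller, variance-stabilized expression analysis with
variable-gene PCA and signature scoring, and CD8×CD155 cohort stratification
with survival statistics. Because the underlying sequencing and clinical
data are access-restricted, a synthetic-data module generates every input
with known ground truth; all quantitative claims in the test suite are made
about this synthetic data, under the model below.

## Somatic filtering and TMB

Candidate mutations from three callers are merged on (chrom, pos, ref, alt);
read-count evidence comes from a fixed caller-precedence order and the
source is recorded in a provenance column. A variant is discarded if any of
the following hold, with strict inequalities exactly as stated:

- tumor total read number < 20,
- tumor variant allele frequency (VAF = alt/total) < 0.05,
- mutant reads in the germline control > 2,
- alt reads on only one strand (zero on one strand, ≥ 1 on the other),
- presence in a population SNP database or an in-house blacklist,
- support from fewer than `min_callers` callers (default 2 of 3; 1 gives
  the union, 3 the intersection).

So depth 20, VAF 0.05 and 2 germline alt reads all pass. The consensus rule
is majority voting — the conventional reading of a three-caller pipeline —
and is configurable because other combination logics are defensible. "Total
read number" is interpreted as tumor depth. TMB is the count of kept
non-synonymous mutations; synonymous kept variants remain in the output
tables. Consequence labels are consumed as input (annotation is out of
scope here).

## Copy number from paired depths

1. **Informative sites.** Database SNP positions whose normal-sample VAF is
   ≤ 0.05 or ≥ 0.95 (homozygous) or in [0.4, 0.6] (heterozygous) are kept;
   everything in between is excluded.
2. **GC adjustment.** Depths are corrected per sample by binned
   median-ratio normalization on the 100 bp flanking-window GC fraction:
   bins of width 0.01 GC, adjusted depth = raw × (global median / bin
   median), bins with fewer than 20 sites merged with their nearest
   neighbor (by count-weighted GC-center distance, ties toward lower GC).
   The estimator is binned medians rather than a fitted curve because it is
   robust and assumption-light; a loess fit would also serve.
3. **LRR.** `lrr = log2(t_adj / n_adj)` per site; sites with a zero
   adjusted depth are dropped with a logged count. By default a constant is
   subtracted so the genome-wide median is 0, standing in for tumor/normal
   throughput normalization. Caveat: on a heavily aneuploid genome the
   median no longer sits at the diploid level, so the baseline shifts; with
   the default synthetic genome (70 % diploid) the shift is ≲ 0.05 LRR and
   is the dominant contribution to segment-mean error.
4. **Smoothing.** The representative LRR at site *i* is the median of raw
   LRR over sites within ±500 kb on the same chromosome (1 Mb window,
   bp-based). Windows truncate at chromosome ends and never cross
   chromosome boundaries; the median uses the standard midpoint rule on
   ties. An O(n²) per-site re-scan serves as the oracle in tests.

Gene-level calls average the representative LRR over a gene interval
(BED input converted from 0-based half-open to the package's 1-based
inclusive coordinates exactly): mean ≤ −1.0 → homozygous loss, ≤ −0.3 →
loss, ≥ +0.3 → gain, else neutral; no call with fewer than 5 sites. These
thresholds are conventional defaults, exposed in `LossThresholds`. Formal
segmentation (CBS/HMM), B-allele modelling and purity/ploidy estimation are
out of scope.

## Expression

Counts are normalized by median-of-ratios size factors (reference: genewise
geometric mean across samples, genes containing zeros excluded from the
median) and transformed as `log2(count/size_factor + 1)`. This `vst_like`
transform is a surrogate for a fitted variance-stabilizing transform: the
downstream uses — standard-deviation ranking and PCA — need variance
stabilization in spirit, not bit-compatibility with a particular fitted
dispersion trend. A subtle property of this estimator worth knowing:
doubling one sample's counts multiplies its size factor by 2^((m−1)/m)
(m = number of samples), not exactly 2, because the geometric-mean
reference moves too.

Variable genes are the top 10,000 by across-sample SD (deterministic tie
break by gene identifier). PCA centers genes but does not scale them to
unit variance — SD ranking has already selected for variance and scaling
would undo it — and uses the full SVD for determinism. The signature score
is the per-sample mean of genewise z-scores over the genes of a set; it
replaces a weighted Kolmogorov–Smirnov enrichment statistic as a
deliberately simple, monotone summary. It is a simplification: it ignores
gene ranks and correlation structure within the set.

## Cohort statistics

Marker cut-offs are chosen from the ROC curve against a 6-month
progression-free-survival landmark: candidates are the observed marker
values, the criterion is Youden's J = sensitivity + specificity − 1, ties
break toward the smaller cutoff. Patients censored before 6 months without
progression carry no information about the landmark and are excluded by
default (`censored_policy="non_progressor"` treats them as non-progressors
instead). Stratification: CD8-high ⇔ count ≥ cutoff (82.8 cells per
0.25 mm² field in the motivating cohort), CD155-high ⇔ ordinal score in
{2, 3}.

Fisher's exact test uses the minimum-likelihood two-sided convention (sum
of hypergeometric probabilities of tables no more probable than observed),
the convention of R's `fisher.test` and scipy; a zero margin yields p = 1.
Kaplan–Meier estimation and the log-rank test are delegated to lifelines
behind the module surface, with hand-computed product-limit and O−E oracles
in the tests; pairwise follow-up of a >2-group comparison applies a
Bonferroni correction. Paired baseline/resistance score shifts use a paired
t test; a zero-variance difference vector returns the limiting p (1 for a
zero mean shift, 0 otherwise, with a warning). Cox modelling is
deliberately not implemented.

## Synthetic data model

One `SimulationConfig` drives four generators; a single global seed spawns
independent child streams per generator, so re-running one never perturbs
another and equal seeds give byte-identical outputs.

- **Depths.** Sites are allocated to piecewise-constant copy-number
  segments in proportion to length; the default genome is 100 Mb across
  three chromosomes, 70 % diploid, with one segment per copy state 0–4.
  Window GC is uniform on [0.3, 0.7], independent of position. Depths are
  negative binomial (overdispersion is universal in capture sequencing):
  normal mean `D·g(gc)` and tumor mean `D·g(gc)·max(purity·c/2 +
  (1−purity), 0.05)` with `g(gc) = 1 + A·sin(2π·gc)`. Defaults: D = 100×,
  dispersion (NB size) 10, A = 0.3, purity 1 (established cell lines are
  clonal). The 0.05 floor models the residual mapped coverage real
  homozygous deletions retain; without it a c = 0 segment would have no
  evaluable sites at the log step. Normal VAFs are Beta(100,100) for
  heterozygous sites (50 % by default) and Beta(1,100)/Beta(100,1) for
  homozygous ones, with binomial read sampling on top.
- **Variant calls.** Planted true somatics satisfy every keep-rule with
  ≥ 2 callers; for each of the five discard rules a configurable number of
  artifacts violates exactly that rule and no other, so the filter's
  confusion matrix against truth must be diagonal. Non-synonymous fraction
  defaults to 0.6.
- **Expression.** NB counts with log-normal gene means; a chosen subset of
  genes is shifted between two groups by a log2 fold change, planting
  separable structure for PCA and signature scoring.
- **Cohort.** 144 patients; CD8 counts Gamma(2, 50) so roughly half lie
  above the 82.8 cutoff; ordinal CD155 with ~44 % high. PFS/OS are
  exponential with stratum hazards (default: CD8-high/CD155-low protective
  at HR 0.4, CD155-high strata mildly adverse), medians 6/18 months at the
  reference; censoring is independent exponential calibrated to the target
  censoring fraction (25 %). Twenty-five patients carry paired
  baseline/resistance CD155 scores, shifted upward when the
  resistance-state CD8 count is high.

What the generators do **not** emulate: read-level artifacts and alignment
error, subclonal copy number, tumor-in-normal contamination,
position-dependent GC (GC is independent of copy state by construction,
so the GC correction is tested in the easiest fair regime), gene–gene
correlation in expression, and non-proportional hazards. Passing tests
therefore demonstrate correctness of the algorithms under a clean
generative model, not robustness to every failure mode of real sequencing
data.

## Problem sizes and numerics

Simulation-backed tests use 10,000 SNP sites for copy number, 2,000 × 10
count matrices (100 replicates of 300 × 10 for the signature check), and
500 replicates of 100-per-arm cohorts for log-rank calibration; these sizes
keep Monte-Carlo error well below the asserted tolerances while the full
suite runs in about a minute. Known numerical choices: LRR never contains
infinities (zero-depth sites are dropped first), degenerate GC bins fall
back to a unit factor with a logged warning, PCA sign is not pinned (tests
align signs before comparing), and all boundary comparisons (VAF 0.05/0.4/
0.6/0.95, depth 20, germline 2, CD8 cutoff, CD155 score 2) are inclusive
exactly as documented above.

## Known limitations

- The LRR baseline assumes a mostly diploid genome; whole-genome
  duplication would re-center the track.
- The ROC cutoff is optimism-biased like any maximized statistic; the
  package reports the curve so users can inspect stability.
- The `vst_like` transform under-stabilizes very low counts relative to a
  fitted dispersion trend.
- The signature score is not an enrichment test and carries no null
  distribution; it is a descriptive summary.
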