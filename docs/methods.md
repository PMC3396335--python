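# Methods

This package reimplements, as one tested pipeline, the called
array-CGH analysis used to compare matched early- and advanced-stage
ovarian carcinomas: preprocessing, circular binary segmentation,
mixture-model calling, region reduction, group-level tests, weighted
clustering of call profiles, and the survival statistics of the
32-patient clinical table.  This note records the models, the defaults
and why, and what the synthetic validation does and does not show.

## Preprocessing

**Median normalization.** Each array's log2 ratios are centred at their
median; copy-neutral DNA is assumed to dominate every genome.

**De-waving.** aCGH profiles carry a slowly oscillating,
position-dependent bias ("waves").  The published analysis cites an
external calibration method whose formulas are not available here, so
the package uses its own two-scale decomposition, per sample and per
chromosome:

1. a running-median *trend* over a wide window (`span`, default 0.3 of
   the chromosome's probes; full windows only, flat-extended into the
   half-window edges).  A median is edge-preserving, so true
   copy-number plateaus longer than about half the window pass into the
   trend unchanged while any oscillation shorter than the window
   averages out;
2. the *wave* is estimated from the trend residual by a quadratic
   Savitzky-Golay smooth over a narrow window (`wave_span`, default
   `span`/10, floor 15 probes).  Residuals more than `signal_mask_sd`
   (default 2.0) robust SDs from the residual median — short
   aberrations the trend missed — are masked, the mask is closed and
   dilated so flagged stretches are contiguous, and the wave is fitted
   through the unmasked probes only;
3. the wave estimate alone is subtracted.  Noise is essentially
   untouched, which matters because the segmentation p-values assume
   exchangeable residuals.

Trade-off: on a sinusoid of amplitude 0.3 the residual SD after
de-waving is ~0.001 and an isolated unit step survives in full, but on
dense aberration landscapes the wave fit can smear some segment edges
by a few probes.  De-waving is therefore a pipeline stage, while
segmentation accuracy is assessed on its stated input (normalized
profiles).

**MAD quality control.** Array noise is summarized by the unscaled
median absolute deviation of a chromosome arm chosen to be
breakpoint-free (default 2q, split at a configurable centromere table).
Arrays above the threshold are excluded together with their matched
partner.  The cohort that motivated this rule had passing arms between
0.17 and 0.43 and one failure at 0.70; no cutoff is stated anywhere, so
the default 0.50 is the midpoint of that gap and is exposed in the
configuration.

## Segmentation (CBS)

Each sample x chromosome series is joined into a circle.  For an arc
(i..j] the statistic is the pooled-variance two-sample t comparing the
arc against its complement; the maximizing arc (first, i.e. leftmost
and shortest, on ties) is the candidate change.  Significance is
assessed by permutation of the values within the current segment:
default `alpha` 0.01 and `n_perm` 10,000 with two-sided sequential
early stopping (stop once a +/-2*sqrt binomial bound separates the
exceedance fraction from alpha; the reported p is exceedances over
permutations run).  Accepted splits recurse.  Isolated single-probe
spikes further than 3 robust SDs from both neighbours are clamped to
their median-of-three before detection (segment means always come from
the original values); a blanket smoother would correlate neighbours and
invalidate the permutation null.  Afterwards adjacent segments merge
while the residual-sum-of-squares increase of the merge is below
`prune_sd`^2 (default 1.5^2) times the robust noise variance estimated
from successive differences.  Minimum arc width is 2 probes.  A
sequence with zero within-arc variance on both sides of a split is a
perfect split (infinite statistic); a constant sequence scores 0.

Degenerate inputs: n = 1 returns the single value as one segment;
sequences shorter than 4 probes are never split.

## Mode normalization and calling

The probe-level segmented values are shifted so the most common level
sits at zero: the mode is located by a Gaussian kernel density
(normal-reference bandwidth, floor 1e-3) evaluated at the distinct
segment levels, ties broken toward the smallest absolute shift.

Calling pools all segment means of the cohort, each weighted by its
probe count, and fits a four-component Gaussian mixture — loss, normal,
gain, amplification — by EM with:

* means initialized at (−0.45, 0, 0.3, 0.9), typical log2 levels for
  65-95% tumor cell fractions;
* a quadratic prior worth `anchor_weight` = 5 probes shrinking the
  normal component's mean to 0;
* strict mean ordering enforced in the M step by a precision-weighted
  isotonic (pool-adjacent-violators) projection;
* one pooled SD shared by all components (floor 0.01).  With free SDs
  the gain component inflates into a wide catch-all for the stray
  intermediate segment means segmentation leaves behind and absorbs
  genuinely normal segments; sharing the SD removed that failure mode
  (hard-call accuracy 0.79 -> 0.92 on the default synthetic cohort);
* convergence when the penalized objective gains < 1e-8 relative, cap
  500 iterations; the objective is asserted non-decreasing every
  iteration.

Cohorts with fewer than four distinct segment means degrade to that
many components (flagged `degraded`), each mapped to the canonical
state nearest its mean with the component nearest zero forced to
"normal".

Per segment, the posterior over the four states follows from the fitted
mixture; amplification is folded into gain for the three-state view,
and the hard call is the merged argmax only when it exceeds 0.5 —
otherwise the probe stays uncalled (sentinel −9).  Uncalled entries are
treated as carrying no information downstream: they agree with
anything during region reduction and are excluded from frequency
denominators.

## Region reduction

Within each chromosome, a greedy left-to-right merge grows a region
while the candidate region's information loss stays within the budget
(default threshold 0.01, i.e. at most 1% of probe-sample hard calls may
disagree with their region's per-sample majority call; majority ties
resolve to the first probe's call).  The per-region guarantee implies
the same bound genome-wide, which the implementation also asserts.
Representative per-sample probabilities are the probe means.  Region
weights are probe counts normalized to sum to 1.  Whether the loss
budget should be measured on hard calls or on probabilities was an open
choice; hard calls were chosen because the budget is stated in calls.

## Group comparison

**Frequencies and per-region tests.** Gain and loss frequencies per
region and group are computed over called samples.  Differential
occurrence of aberration (call != 0) is tested per region with the
Pearson chi-square on the 2x2 table without continuity correction;
regions with a zero margin get p = 1 and a flag.  Benjamini-Hochberg
(via statsmodels) controls the FDR across regions, default level 0.15.

**Genome-wide odds test.** The published claim that aberration odds are
genome-wide higher in advanced stage came with a supplement whose
formulas are not available (it is an image); the test here is the
package's own fully specified reconstruction of the stated hypothesis
and matched design.  Each sample's aberration burden is the
region-weight-weighted fraction of its called genome that is aberrant,
continuity-corrected by half a region's mass so the logit is finite.
The statistic is the difference in mean logit burden (advanced minus
early).  With a perfect matching the null distribution comes from
swapping labels within pairs — exhaustive over all 2^m sign assignments
for m <= 20 pairs, otherwise Monte-Carlo — and without a matching from
free label permutations; the one-sided p is the fraction of null
statistics at or above the observed one, the identity assignment
included.  This is *not* claimed to be the original supplement's
statistic, and the original study's p = 0.012 on the real arrays is
out of scope by design.

## Weighted clustering

Two samples' similarity is the region-weight-weighted probability of
being in the same merged state, `sum_r w_r sum_s P_ir(s) P_jr(s)`,
rescaled by `1/sqrt(sim_ii sim_jj)` so identical hard-called profiles
score exactly 1.  Agglomerative clustering runs on 1 − similarity with
average linkage by default (complete available); ties merge the
lexicographically smallest pair, making the dendrogram deterministic.
The two-cluster cut labels the larger cluster "A".  The published
study's own concordance measure and linkage are not specified in the
text; this probability-overlap similarity is the declared stand-in.

## Survival statistics

Product-limit (Kaplan-Meier) estimation with Greenwood variance;
censoring tied with a death counts as occurring after it.  The
restricted mean survival is the area under the KM curve up to the
group's largest observed time — event or censored — with the
Greenwood-based restricted-mean SE (no small-sample inflation factor)
and a normal 95% CI.  This is the convention of the reporting software
used for the original cohort (SPSS), verified equivalent to R
`survival`'s `survmean` on the packaged table.  The log-rank test is
Mantel-Cox with the hypergeometric variance at each distinct event
time; the 2x2 chi-square is Pearson without continuity correction.
Two-sided p-values throughout.  The grade comparison (1 vs 2-3
combined) uses the same Mantel-Cox test as the cluster comparison; the
original text states the test only for clusters.

Recomputing the published statistics from the printed patient table
reproduces the cluster-by-stage chi-square (p = 0.0012), the
early-vs-advanced log-rank (p < 0.001), the cluster sizes and rounded
mean ages exactly, but gives cluster log-rank p = 0.0013 (printed
0.002), restricted means 141.5/41.5 months (printed 142.0/43.0) and
grade log-rank p = 0.042 (printed 0.044).  Independent oracles (R
`survival`, lifelines) agree with this package to machine precision on
the same inputs, and the printed CI half-widths match the computed SEs,
so the printed values evidently derive from unrounded survival times
whereas the table prints whole months.  The acceptance tests assert the
printed values at their stated tolerances and those four assertions
fail; they are kept failing rather than loosened.

## Synthetic cohorts

The generator emulates the study design, not the platform: two matched
groups share one library of candidate aberration intervals (uniform
length between 5 probes and half a chromosome, so both focal and
arm-level events occur); each early sample carries aberration k with
probability p (default 0.25), each advanced sample with odds multiplied
by `odds_ratio_advanced` (default 3).  Later intervals overwrite
earlier ones, so truth states tile each chromosome.  The probe signal
is state amplitude x tumor fraction + sinusoidal wave + Gaussian noise,
with defaults: loss −1, gain log2(3/2) ~ 0.585, amplification 1 (two
extra copies), tumor fraction 0.778 (the real cohort's mean tumor
percentage), noise SD 0.15, wave amplitude 0.1 with period 50 probes
and a random phase per sample.  The scaled-down grid is 8 chromosomes
x 150 probes; problem sizes in the tests and the acceptance script are
chosen at this scale.  Survival is exponential with the hazard coupled
to the true group only (median 120 months for the low-risk group,
hazard ratio 3), administratively censored at 150 months; ages,
histology and grade follow the real cohort's marginals with
histology/grade shared within each matched pair.  All draws derive
from one master seed through counter-keyed child streams, so reruns
are byte-identical.  `disjoint_aberrations` gives each group its own
half of the candidate library; two-cluster recovery of the groups is
only a meaningful target under that option, since with one shared
landscape the groups differ in aberration frequency, not pattern.

What passing synthetic tests do **not** show: real aCGH noise is
heteroscedastic and autocorrelated beyond a single sinusoid; real
tumor fractions vary per sample; real aberration landscapes are not
uniform intervals; and PFS here simply mirrors OS.  The synthetic
results validate the algorithms' contracts, not platform-specific
performance.

## Numerical and degenerate-input choices

Probabilities are renormalized on file round-trip; posterior rows must
sum to 1 within 1e-9.  Probes missing in more than 20% of samples are
dropped pipeline-wide; missing values are excluded from medians and
smooths.  The KM variance at S(t) = 0 is reported as 0.  Regions whose
2x2 table is degenerate get p = 1.  All TSV coordinates are 1-based
inclusive (docs/formats.md).
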