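# acghcall

Called array-CGH copy-number analysis for two-group tumor cohorts:
preprocessing, circular binary segmentation, mixture-model calling of
losses/gains/amplifications, region dimension reduction, group
frequency and genome-wide aberration-odds tests, weighted clustering of
call profiles, and survival statistics.

## The problem

Array comparative genomic hybridization (aCGH) measures DNA copy number
as a per-probe log2 ratio of tumor versus normal reference.  A classic
question for ovarian carcinoma is whether early (FIGO stage I) and
advanced (stage III–IV) disease are distinct molecular entities or one
continuum: if advanced tumors carry the *same* aberrations as early
tumors, only more of them, a common origin is the parsimonious reading.
Answering it takes a pipeline, not a single tool — noisy FFPE-derived
log2 ratios must be normalized, de-waved and QC'd; segmented into
constant copy-number stretches; classified into discrete calls with
confidence; reduced to non-redundant regions; and only then compared
between groups, clustered, and correlated with survival.

This package implements that pipeline as a library (`src/acghcall`),
a CLI (`acghcall`), and a set of analysis drivers (`analysis/`).  It
ships two data sources so every stage is testable without downloads:

* the published 32-patient clinical table of a matched early/advanced
  ovarian carcinoma cohort (16 + 16; `load_table1_fixture()`), and
* a synthetic-cohort generator with known ground truth
  (`simulate_cohort`): two matched groups share one aberration
  landscape, with the advanced group carrying every aberration at
  odds ratio θ; signal = state amplitude × tumor fraction + wave +
  Gaussian noise; exponential survival with group-dependent hazard.

## The statistics at the core

* **CBS** — on the circularly joined sequence, the arc (i..j]
  maximizing the pooled-variance two-sample t statistic
  t = (x̄_arc − x̄_comp) / (s_p √(1/k + 1/(n−k)))
  is a candidate change point, kept when its permutation p < α and
  recursed; weak splits are pruned against the residual noise.
* **Calling** — a 4-component Gaussian mixture (loss < normal < gain <
  amplification) fitted by EM to probe-weighted segment means, ordered
  means, pooled SD, normal anchored at 0; hard calls require a merged
  posterior > 0.5, amplification is folded into gain.
* **Region reduction** — greedy merge of adjacent probes while ≤ 1% of
  probe-sample calls disagree with their region's majority call.
* **Genome-wide odds test** — per sample the region-size-weighted
  aberrant fraction b_i, statistic T = mean logit(b) difference between
  groups, null by within-pair label swaps (exhaustive over 2^16
  assignments for 16 pairs).
* **Survival** — Kaplan–Meier with Greenwood variance; restricted mean
  survival = area under the curve to the largest observed time (the
  SPSS reporting convention, equivalent to R `survival::survmean`);
  Mantel–Cox log-rank; Pearson 2×2 chi-square.

## Worked example

```sh
python analysis/01_table1_survival.py
```

prints, recomputed from the packaged patient table:

```
cluster x stage: table [[14, 5], [2, 11]], chi2=10.49, p=0.001198
log-rank by cluster: chi2=10.35, p=0.001296
log-rank by stage: chi2=15.83, p=6.926e-05
log-rank by grade: chi2=4.14, p=0.04199
restricted mean survival: cluster A 141.5 months (95% CI 112.4-170.7),
                          cluster B 41.5 months (95% CI 25.1-57.9)
```

Reading: the two clusters found by weighted clustering of the called
copy-number profiles separate early from advanced stage almost
perfectly (chi-square p ≈ 0.001) and differ sharply in overall
survival — patients in cluster A live on average 141.5 months
(restricted mean), those in cluster B 41.5 months, log-rank p ≈ 0.0013.
Grade 1 versus grade 2–3 also separates survival (p ≈ 0.042), but far
less than the genomic clusters do.

The synthetic end-to-end run:

```sh
python analysis/02_simulate_cohort.py   # writes the cohort TSVs
python analysis/03_run_pipeline.py      # full pipeline + truth scoring
python analysis/04_operating_characteristics.py
```

On the default cohort (32 samples, 8×150 probes, σ = 0.15, wave 0.1)
the full pipeline reaches hard-call accuracy 0.963 against the
generator truth with 0.6% region information loss, and the paired
genome-wide odds test detects the simulated odds ratio 3 at
p = 7.6e-5; its type-I error over 200 null cohorts is 0.060 at
α = 0.05 and its power at odds ratio 3 is 1.00.

The same stages are available from the shell:

```sh
acghcall simulate --seed 1 --out sim/
acghcall run --matrix sim/matrix.tsv --clinical sim/clinical.tsv --out out/
acghcall survival --by cluster --out surv.json   # packaged table by default
```

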