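# Methods

## The problem

Healthy ageing leaves a reproducible imprint on the transcriptome. Given
log-intensity expression profiles of healthy young and healthy old tissue,
we want (i) a fixed list of probes, each with a direction of change with
age, that classifies the age group of new samples — including samples from
other tissues and array platforms — and (ii) a per-subject *gene score*
that places any individual on a young-like ↔ healthy-old-like axis within
their cohort. The package implements the full procedure and ships a
synthetic-cohort generator so every stage can be exercised and calibrated
without external data.

## Signature discovery: nested hold-out LOOCV

The discovery cohort is a two-group (young/old) matrix. For every ordered
pair of distinct samples *(i, j)* both samples are set aside; an
empirical-Bayes moderated t-statistic ranks all probes on the remaining
n−2 samples, the top `n_inner` probes define a feature space, and sample
*i* is classified by k-nearest-neighbour majority vote (Euclidean distance
on per-probe z-scores fitted on the retained samples only). The decision's
correctness is credited to each of the `n_inner` contributing probes.
With n samples this visits exactly n·(n−1) decisions and n·(n−1)·`n_inner`
probe-evaluation events; every quantity is deterministic given the input.

The exact topology of a double hold-out loop is a design choice: we hold
out one array to be classified and one further array excluded from the
probe ranking, over all ordered pairs. Any scheme in which the ranking
never sees the classified sample is unbiased; the ordered-pair scheme is
the simplest one in which both held-out roles are exercised symmetrically.

Per-probe **performance** is the fraction of a probe's decisions that were
correct. Probes flagged as mapping to multiple genomic loci are removed,
probes seen in fewer than `min_appearance_frac` (default 10 %) of all
decisions are removed (a probe selected a handful of times can reach any
performance by luck), survivors at or above `perf_threshold` (default
0.90) are ranked by (performance, appearances, |moderated t| on the full
training data) and the top `top_n` (default 150) are kept. A relaxed list
(default 0.70) is emitted alongside. Each retained probe's direction is
fixed once, on the full training cohort: *down* if the old-group mean is
below the young-group mean. If fewer than `top_n` probes survive, the
survivors are returned as-is — the signature is never padded.

Performance is read as *per-probe accuracy* (correct/appearances), not as
a share of all correct decisions; the appearance floor makes that reading
stable.

### Moderated t

Per probe, the pooled two-sample variance s²_g with d_g = n₁+n₂−2 degrees
of freedom is shrunk toward a prior: s̃²_g = (d₀·s₀² + d_g·s²_g)/(d₀+d_g),
and t_g = Δmean / (s̃_g·√(1/n₁+1/n₂)). The hyperparameters (d₀, s₀²) are
estimated by moment-matching the distribution of log s²_g via the
digamma/trigamma equations of the standard empirical-Bayes variance model
(trigamma inverted by Newton iteration). When the excess variance of
log s² is non-positive the moment equations have no solution and the
statistic falls back to the ordinary pooled t (d₀ = 0); the event is
logged. The implementation reproduces limma's `eBayes` hyperparameters
and moderated t to ~10 significant digits on a frozen fixture (see
`tests/test_selection.py`).

### Choice of `n_inner` for the synthetic studies

The default `n_inner = 200` reflects the original discovery design, where
200 probes were drawn per inner loop from a ~54,000-probe array (≈0.4 % of
the universe). The synthetic studies use a 2,000-probe universe; keeping
200 there would hand 10 % of all probes a slot in every fold, so the same
couple of hundred probes — mostly noise — recur in every decision, pass
the appearance floor, and share the cohort-level accuracy as their
performance. Selection pressure, not the absolute count, is what the
design needs, so the synthetic analyses scale the inner list to 1 % of
the universe (`n_inner = 20`). At the planted effect of 1 sd this yields
signatures of ~25–35 probes dominated by planted probes (precision
0.84–1.0 across seeds in our runs).

## External validation and classification

A reference cohort of known samples defines the expression space: test
samples are z-scored per probe with the *reference* mean and standard
deviation and classified by k-nearest-neighbour vote among the reference
samples (the reference is never re-fit). Within a single cohort,
leave-one-out classification re-fits the z-scoring on each fold's n−1
retained samples. Reference/per-fold z-scoring is the package's
harmonisation step between cohorts; it deliberately replaces heavier
cross-study normalisation and is documented as such.

ROC curves rank samples by the vote score (fraction of k neighbours
carrying the old/case label; at most k+1 distinct values) and the AUC is
computed by the rank formula AUC = U/(n₊·n₋) with ties counting ½ — the
vote fraction is our choice of ranking variable. Distance ties break by
the lowest sample index; an even-k vote tie falls to the nearest
neighbour's label (k defaults to 5, odd, so vote ties cannot occur).

## The healthy-ageing gene score

For each signature gene present in a cohort, samples are ranked within
the cohort: for a gene *down*-regulated with healthy age the sample with
the highest expression gets rank 1 and the lowest rank n; for an
up-regulated gene the opposite. Ties receive average ranks. A sample's
raw score is the **median** of its per-gene ranks — the median gives every
gene equal weight regardless of dynamic range — and the scaled score is
raw/n ∈ (0, 1]. Higher score = closer to the healthy-old profile. A
sum-of-ranks variant (`method="sum"`) is exposed for sensitivity analysis;
the median is the default. Scores are cohort-relative by construction:
adding or removing samples changes every score.

Group comparisons are rank-based throughout: two-sided Wilcoxon rank-sum
(exact null for combined n ≤ 20 without ties, otherwise the tie-corrected
normal approximation), Kruskal–Wallis with tie correction for ≥2 groups,
post hoc pairwise Mann–Whitney with Holm step-down adjustment, and OLS for
score-vs-covariate regressions.

## Enrichment against a resampling null

A signature's gene-set profile is tested term-by-term with upper-tail
hypergeometric tests (population = the full platform annotation, the
background population). To ask whether the *profile as a whole* differs
from chance, the same battery runs on `n_draws` (default 10,000) random
gene sets of the signature's size drawn uniformly without replacement
from the universe, each with per-draw Benjamini–Hochberg adjustment. The
observed p-value vector is compared with the pooled null p-values by a
two-sample Kolmogorov–Smirnov test; KS is an artifact choice for
summarising what is naturally a density comparison, and kernel-density
summaries of both samples are emitted for plotting. Under-representation
is out of scope. Correlated term memberships make the KS test on the
observed vector anti-conservative, so the KS p-value is a summary, not a
calibrated test.

## The synthetic-data generator

`simulate_training_cohort` plants a directional signature in Gaussian
log-intensity data: probe g in sample s is baseline_g + 1[old]·effect_g +
ε with ε ~ N(0, noise_sd) and baseline_g ~ N(baseline_mean, 1). Defaults
mirror the discovery design: 15 v 15 samples, 2,000 probes, 100 signal
probes of which 85 % are down-regulated (allocated exactly, by rounding),
effect 1 sd, baseline mean 8 (a typical log2 intensity), and 5 % of probes
flagged multi-locus so the removal rule is exercised.
`simulate_validation_cohort` keeps the truth but redraws baselines and
noise, scaling effects by (1 − tissue_attenuation).
`simulate_case_control` builds an older-age cohort on a second platform
(fresh probe ids joined by gene symbol) in which cases carry the
old-direction shift scaled by (1 − δ); attenuation acts multiplicatively
because a single parameter then interpolates control → case. Optional
extra case groups (e.g. a milder prodromal group) live in the same cohort
so rank scores are comparable. `platform_dropout` removes a fraction of
signature genes from the emitted annotation, reproducing cross-platform
attrition. `simulate_gmt` draws random gene sets, optionally planting one
term, for enrichment calibration.

All randomness flows from a single integer seed per call; there is no
global state. The generator does **not** emulate correlated probe blocks,
batch structure, intensity-dependent variance, or count-based RNA-seq
noise — passing tests demonstrate the procedures' statistical behaviour
under the stated model, not robustness to real microarray artefacts.

## Null behaviour of the hold-out loop

Two properties of the nested loop matter when checking that no signal is
reported on null data. First, the n·(n−1) decisions are far from
independent: the n−1 decisions about one sample are nearly duplicates,
and the recurring inner feature lists couple decisions across samples. In
our null simulations the cohort-level accuracy has a standard deviation
about eight times the binomial value at n·(n−1) trials. Calibration
checks therefore use the number of classified *samples* as the effective
trial count. Second, holding out a second array from the same group as
the classified sample leaves the training fold imbalanced by two, biasing
the majority vote against the held-out sample's group; the expected null
accuracy sits slightly *below* 0.5 (≈0.47 at 15 v 15, k=5). Both effects
are inherent to the published design, not artefacts of this
implementation.

## Numerical and degenerate-input choices

* Quantile normalisation maps each sample onto the mean of the per-rank
  values; tied entries receive the mean of the reference values at the
  ranks they occupy (the common dialect), so ranks are preserved exactly
  and column totals are conserved under ties.
* Scaling/centering is per-probe with the n−1 denominator; zero-variance
  probes are dropped with a logged warning. The direction of scaling
  ("scaled and centered") is ambiguous in general; per-probe is the
  default and per-sample is available behind `axis="samples"`.
* Cross-platform signature mapping joins on gene symbols; a gene measured
  by several destination probes contributes all of them with the same
  direction, and multiple probes per gene are averaged (not max-picked)
  when collapsing to gene level — symmetric and deterministic without
  external "best probe" metadata.
* Expression files must be complete; missing cells are rejected by
  default, with optional per-probe median imputation. Orientation
  (probes-in-rows vs samples-in-rows) is an explicit flag, never guessed.
  Identifiers are opaque, case-sensitive strings.
* File parsing uses correctly-rounded float conversion so write/read
  round-trips are bit-exact.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the discovery loop on the
default 15 v 15 × 2,000-probe cohort (870 decisions), a 30-sample ×
250-probe cohort with `n_inner = 200` for the counting identities (870
decisions, 174,000 probe-evaluation events), 20 v 20 validation cohorts,
50 case–control replicates at δ = 0.5 (70 controls v 45 cases), 200 null
case–control replicates for p-value uniformity, and a 500-draw resampling
null over 50 synthetic terms (the analysis driver uses the full 10,000
draws). The complete suite runs in well under a minute on one CPU.

## Known limitations

* The gene score is cohort-relative; scores are not comparable across
  cohorts without re-ranking, and the package deliberately offers no
  cross-cohort score calibration.
* Survival and multi-factor clinical modelling (Cox, logistic regression,
  Kaplan–Meier) are out of scope; `regress_score` covers only the
  single-covariate linear screens.
* The classifier assumes two groups; multi-class classification and
  probability calibration are not implemented.
* Array pre-summarisation (RMA/fRMA from raw CEL files) and array QC are
  upstream of this package's contract, which starts at the summarised
  log-intensity matrix.
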