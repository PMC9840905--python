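# Methods

This note documents the statistical models behind `septimark`, the defaults
and why they were chosen, what the synthetic cohorts do and do not emulate,
and the design decisions taken where the procedure being re-implemented left
the choice open.

## Cohort structure and data model

Three groups are carried throughout: healthy controls (`C`, sampled at
day 0) and severely burned patients who did (`S`) or did not (`NS`)
subsequently develop sepsis, sampled on post-burn days 1, 3, 5 and 7.
Sample metadata is a `(sample_id, group, day)` table; subjects appear once
at day 0 (the enrollment draw used for genomics and plasma miRNA) and once
per follow-up day for plasma proteomics (`NS001_D3` etc.).

Abundance matrices (features × samples, NaN = missing) carry an explicit
processing state — `raw → normalized → log2 → imputed` — and each operation
checks the state of its input, so the documented order (missingness filter →
quantile normalization → log2 → minimum imputation → testing) cannot be
silently violated.

## Variant susceptibility screen

Carrier status is presence-based: a sample carries a gene if it harbours at
least one variant of pathogenicity category ≥3 (or ≥4 for the stricter
screen); variant dosage is ignored, matching how per-patient mutated-gene
counts are usually reported.  The screen selects genes with
|f_S − f_NS| > δ, strict inequality, with δ = 0.18 by default.  The
difference is taken as an absolute difference of fractions (not a ratio),
and direction is reported but does not affect selection.  Carrier fractions
use the enrollment (day-0) sample set as denominator so that longitudinal
plasma samples of the same subject cannot inflate group sizes.

At the study's exome group sizes (24 NS vs 16 S) the screen's operating
characteristics are fully binomial: a gene planted at carrier frequencies
(0.6, 0.2) exceeds the 0.18 cut with probability 0.932 per cohort draw
(exact sum over the two binomials), and a background gene at (0.05, 0.05)
does so with probability 0.018.  The acceptance suite measures both; the
planted-recovery rate observed over 50 simulated cohorts (~0.93) is the
binomial ceiling, not an implementation loss.

## Quantile normalization with missing values

On complete data the implementation is the textbook algorithm: each
sample's sorted values are replaced by the across-sample means of sorted
values, making every column share one empirical distribution; the operation
is then idempotent.  With missing values, each sample's observed values are
ranked, the reference distribution is the across-sample mean of per-sample
quantile curves evaluated on a common grid (size = the largest observed
count), and observed values map onto the reference by linear interpolation
of their quantile position.  Missing cells stay missing (normalization
precedes imputation), and tied observations receive the mean of their tied
reference slots.

## log2 and minimum imputation

After log2 transformation, missing cells are filled with the **global**
minimum of observed log2 values.  A per-feature minimum was rejected
because a feature entirely missing in one group would leave the fill
undefined; the global minimum also encodes the left-censoring reading of
intensity-dependent missingness.  The cost of this convention is real and
is quantified below (see *Trend analysis*).

## Empirical-Bayes moderated test

"Linear model fitting plus Bayesian testing" is implemented as standard
empirical-Bayes variance moderation.  For feature *g*, the two-group model
gives Δ̄_g (difference of group means of log2 intensities, reported as
`log2fc` with `fold_change = 2^log2fc`) and a pooled residual variance
s²_g on d = n_A + n_B − 2 df.  The variance ensemble is modelled as
s²_g ~ s₀²·F(d, d₀); the prior (d₀, s₀²) is estimated by matching the mean
and variance of log s²_g through digamma/trigamma identities, inverting the
trigamma function by Newton iteration.  When the ensemble is no more
dispersed than sampling alone implies, d₀ = +∞ (all variances collapse to
s₀²; exactly equal variances short-circuit to the common value so that
shrinkage is a no-op).  The moderated statistic uses the posterior variance
s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) and is referred to t(d₀ + d) (normal when
d₀ = ∞).  With d₀ = 0 the statistic reduces *exactly* to the classical
pooled two-sample t, which the tests verify on random matrices; the full
moderated fit is cross-checked against the Bioconductor reference
implementation (limma, driven through Rscript) to ~1e-8 relative agreement
on a shared matrix.

Calls require fold change > 1.2 in either direction **and** p < 0.05.
P-values are reported raw with BH-adjusted values alongside; calling uses
raw p by default (`use_adjusted` switches), since the original procedure
states no multiple-testing correction.  The miRNA screen uses the fold
criterion alone (|fold| > 2, no p gate).

On plant-free synthetic cohorts (2000 proteins, log2 noise SD 0.5, 24 vs 16
samples) the p < 0.05 rate of the moderated test averaged over 20 cohorts
sits within three binomial standard errors of 5%.  This calibration check
runs on complete matrices: constant-minimum imputation of MNAR cells makes
the nominal level conservative by construction (imputed cells are identical
in both groups), which is a property of the imputation convention, not of
the test.

## Trend analysis

Each protein's path over (C, day 1, day 3) — the anchor C mean is shared by
the NS and S paths — is reduced to step signs: +1/−1 when the between-mean
change exceeds ±log2(threshold), else 0 (strict).  The 8 non-flat sign
pairs map to profile ids 0–7 in lexicographic order of (s₁, s₂) with
−1 < 0 < +1; the flat pair has no profile.  A configurable class map
partitions ids into up/down trends.  Two contradictory orientations of the
id→class key are in circulation for this profile-numbering family; both are
shipped (`results-text`, the default: 0,1,3,5 = down; `figure-caption`: the
inverse) and the trend-differential rule — opposite classes, or a trend on
exactly one path — is provably invariant under swapping them.

Two calibration-driven choices differ from a naive reuse of the DE
parameters:

* **Step threshold 1.5, not 1.2.**  Step significance is a fold threshold,
  not a test, because per-day group sizes are small (6 C / 6 NS / 4 S in
  the discovery proteomes).  At those sizes with log2 noise SD 0.3, a flat
  step crosses log2(1.2) with probability ≈0.13, so a truly flat protein
  would be called trend-differential ≈42% of the time and the stage would
  be useless; at log2(1.5) the flat-step crossing rate is ≤0.6% per step
  while a 1-log2-unit step is still detected with ≥93% per sign.  The
  threshold is a parameter (`step_fc_threshold`); 1.2 remains available.
* **Observed-value means, not imputed values.**  Group means for step
  computation use observed log2 intensities (features with <2 observations
  in any group-day cell are dropped), because constant-minimum imputation
  moves small-group means of low-abundance features by several log2 units
  and floods the step threshold: in an end-to-end experiment at 10% MNAR
  missingness the imputed-mean variant produced ~180 false
  trend-differential calls out of 400 features versus ~9 for observed
  means, with identical sensitivity on the planted features.

Recovery at the stated conditions (planted profile pairs with 1.0-log2
steps, noise SD 0.3, DIA group sizes, 50 cohorts; an ensemble mixing 12
differential pairs, 6 same-class pairs and 22 flat proteins) is measured at
sensitivity ≈0.99 and FDR ≈0.04.  The recovery simulation feeds the trend
caller log2 intensities directly rather than quantile-normalizing first:
with nearly half the features planted, the equal-distribution assumption
behind quantile normalization is deliberately violated by the design, and
normalizing such a matrix leaks the plants into null features (measured
FDR ≈0.18 from that leakage alone).  In the end-to-end pipeline, where
plants are sparse, the trend stage does run on normalized values.

## Enrichment

Over-representation only: p = P(X ≥ k) for X ~ Hypergeometric(N, K, n),
i.e. the one-sided Fisher exact probability, BH-adjusted across terms.  The
background universe defaults to the union of all annotation-set genes, since
no background is prescribed; predicted-target consensus keeps genes present
in every database (relaxable to ≥ min_dbs).  Target and annotation sets are
consumed as GMT files — the named prediction databases are unversioned web
resources, so set retrieval is out of scope.

## ROC / AUC validation

The ROC curve places one point per distinct score threshold (descending,
ties grouped) plus the (0,0) endpoint; the AUC is the trapezoidal area and
equals the pair-counting (Mann–Whitney) probability with ties half-counted,
which the tests verify exactly on random instances.  The positive class is
S throughout, so AUC > 0.5 means higher abundance in sepsis.  The
two-group test is Student's pooled t or the Mann–Whitney U with normal
approximation and tie correction; `auto` selection runs a Shapiro–Wilk
screen at α = 0.05 per group (groups of <3 values cannot be screened and
default to t).  Confidence intervals (DeLong, bootstrap) are deliberately
out of scope.

## Synthetic cohorts

The generator plants effects into an otherwise exchangeable background:

| parameter | default | meaning |
|---|---|---|
| `n_control / n_ns / n_s` | 10 / 24 / 16 | group sizes (study-sized) |
| `days` | (0, 1, 3, 5, 7) | day 0 = healthy controls |
| `baseline_mean/sd` | 20 / 2 | per-feature log2 baseline ~ N(20, 2), DIA-like |
| `noise_sigma` | 0.5 | per-sample log2 noise SD |
| `background_carrier_freq` | 0.05 | carrier frequency of non-planted genes |
| `missing_rate_base` | 0.1 | protein missingness rate at the median intensity |
| `missing_intensity_slope` | 1.0 | slope of the logistic missingness curve |

Qualifying-variant carrier status is an independent Bernoulli per
(gene, subject) at the group's frequency; carriers receive one category-3–5
record (70/20/10%), and benign category-1–2 records are sprinkled at 5% per
gene-subject to exercise the category filter.  Intensities are log-normal;
planted miRNA folds shift one group additively in log2; planted trend
profiles add ±step offsets at day 1 and day 3 (held flat afterwards);
planted markers shift the S group at day 1 by d·σ so the day-1 AUC is
Φ(d/√2) by the binormal identity — the generator's own calibration is
verified against that closed form.  Protein missingness is
Bernoulli with probability 2·base·logistic(−slope·(log2 x − median)),
clipped to [0, 1]: monotone decreasing in intensity with rate ≈ base at the
median.  One integer seed feeds a `SeedSequence`; each table draws from its
own spawned stream, so resizing one table never perturbs the others.

What the generator does **not** emulate: clinical covariates (age, burn
area, inhalation injury), correlation between features, batch effects,
subject-level longitudinal correlation (each day is an independent draw
around the planted path), peptide-level structure, and linkage between the
omics layers.  Passing recovery tests therefore demonstrate correctness of
the statistical machinery under the stated model, not performance on real
plasma data.

Targeted recovery simulations (null calibration, AUC calibration, trend
recovery) run with `missing_rate_base = 0`: they isolate the operation
under test, while the missingness mechanism is validated by its own
monotonicity property and exercised in the end-to-end default run.

## Numerical notes and degenerate inputs

* Ties in sorting are always broken deterministically (mergesort, feature
  id ascending); reruns are byte-identical, and the run report omits wall
  times (logged instead) for that reason.
* `estimate_eb_prior` requires ≥10 positive variances; an all-equal
  ensemble returns (∞, common variance).  Features with zero variance are
  excluded from estimation but still moderated.
* A zero mean difference yields t = 0, p = 1 even when the posterior
  variance is 0 (identical groups).
* `step_sign` and the fold screens use strict inequalities at their
  thresholds; a difference of exactly log2(threshold) is not a step.
* Problem sizes in the test and acceptance suites (cohort counts, seed
  counts, feature counts) are chosen to keep each check's Monte-Carlo error
  well inside its asserted band — e.g. 100 seeds give the mean AUC a
  standard error of ~0.008 against a ±0.03 band.

## Known limitations

* The trend stage's step thresholding has no inferential error control; the
  FDR figures above hold under the generator's model at the stated sizes.
* Global-minimum imputation biases low-abundance fold changes toward zero
  difference when missingness is group-balanced and away from it when not;
  alternatives (per-feature minimum, model-based imputation) are not
  implemented because the re-implemented procedure specifies the global
  minimum.
* The enrichment background is configurable but defaults to the annotation
  union, which can overstate significance relative to a whole-genome
  background.
* `auto` test selection pre-tests normality, which is known to distort
  nominal levels slightly; the explicit `t`/`rank` methods are available.
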