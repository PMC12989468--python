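# Methods

This note documents the models, parameter choices and numerical
conventions behind `liftbiome`, and what the synthetic-data validation
does and does not establish about real data.

## Study design being modeled

An 8-week supervised resistance intervention in sedentary adults: 205
enrolled, 43 drop out, 6 excluded for data quality, 6 reserved for
workflow validation, leaving 150 analyzed participants.  Training happens
on 7 strength machines (leg press, leg curl, back trainer, abdominal
trainer, chest press, seated row, lat pull) under one of two programs —
regular resistance training (RRT) or muscle building (MBRT) — each a
sequence of four 2-week phases with program-specific repetitions and
percent-of-maximum loads (e.g. RRT phase 1: 2 sets × 7 machines × 20
repetitions at 45 % of maximum).  Stool is sampled at weeks 0, 4 and 8
for 16S profiling; metabolites at weeks 0 and 8; diet surveys at all
three fitness tests.

## Synthetic study generator

### Cohort

Counts follow the funnel exactly (conservation is asserted, not hoped
for).  Ages are truncated normal on [24, 61] with mean 41.7, sd 11.6; BMI
normal 24.5 ± 3.5 clipped to the plausible screening range; height is
sex-specific so body weight = BMI·height² is coherent.  Exclusion flags
are assigned by a seeded permutation; dropouts receive a dropout week in
1–7 and contribute a W0 stool sample only, which exercises the cohort
filtering of every downstream stage.

### Training logs

Each participant draws a total percent gain G ~ N(24, 16²) (truncated at
−90 %), converted to log₂ units.  Baseline leg-press strength is
N(154, 54²) kg (truncated at 40 kg) with a sex factor normalized to leave
the cohort mean unchanged, and the other machines scale from it by fixed
fractions with 0.15 log-normal spread.  Baseline and gain share a
Gaussian copula with correlation −0.35: weaker participants improve
relatively more, a well-known feature of resistance training that the
responder-prediction benchmark must be able to rediscover.  Strength at
week w follows the piecewise-linear log₂ trajectory through (0, 0),
(4, 0.7·G), (8, G) — most of the gain arrives in the first half — plus a
per-machine deviation of sd 0.05 log₂.  Sessions run 2–3 times per week
(Mon/Wed/Fri pool); per-set repetition deficits are binomial with a
per-participant miss propensity ~ Beta(2, 38) (mean 5 %), so compliance
averages ≈ 95 %.

### ASV counts

A hierarchical log-normal composition → multinomial read model:

* per-ASV baseline log-abundance ~ N(0, 1.5²) (natural log),
* per-participant, per-ASV random intercept with variance set by the
  within-subject correlation ρ = 0.5,
* per-sample noise sd `within_sd` = 0.5,
* softmax to a composition; read depth ~ negative binomial with mean
  69,000 and size 25 (CV ≈ 0.2); counts multinomial.

27 "planted" ASVs (16 up, 11 down) shift at W4 (log₂FC 1.25) and W8
(log₂FC 2.5), scaled per participant by `coupling_strength` (0.8) times
the participant's strength-gain percentile.  Two deliberate choices:

* **Coupling form** — scale = c·percentile rather than a mean-one form.
  This concentrates the planted effect in high responders, which is the
  regime the permutation-subset robustness analysis is about: with a
  mean-one scaling, mid-percentile participants carry ≥ 1-log₂ effects
  and random non-HR subsets detect nearly as many ASVs as the HR subset.
* **Planting among abundant ASVs** — planted ASVs are drawn from the
  upper half of baseline abundance.  Rare planted ASVs are perfectly
  detectable by the paired per-ASV test but contribute nothing to
  Bray–Curtis, making the community-level coupling unobservable; abundant
  planting mirrors the fact that exercise-responsive taxa reported in
  this literature are common gut genera.

`within_sd` is the generator's main free parameter (no public estimate of
the within-subject noise of real profiles exists to condition on).  At
0.5 the within-subject Bray–Curtis noise floor is ≈ 0.3 and the planted
coupling yields Pearson r ≈ 0.25–0.6 at n = 150 — comfortably in the
"modest but significant" regime — while the global-null configuration
stays clean.  At 0.7 the noise-floor heterogeneity between participants
swallows the coupling signal entirely; this sensitivity is worth knowing
when reasoning about real cohorts.

A ground-truth sidecar (`truth.json`: planted ids, per-participant gains
and effect scales) is always written so recovery tests never read
analysis outputs.

### Metabolites and diet

The 34-compound panel (SCFAs, amino acids, bile-acid derivates, choline
metabolites, indoles, phenolics, polyamines, vitamins) is log-normal with
a participant intercept and *no* time effect — null by construction — so
a correct analysis must find nothing (the type-I rate of a paired test on
it is checked to sit at the nominal 5 %).  Diet profiles are stable per
participant: 8 ordinal food frequencies (0–7 per week, an encoding
assumption — the survey scale is not standardized) plus 4 drink volumes
(ml), with small survey noise.

## Strength metrics

* **Average strength gain**: mean over machines of
  log₂(S_follow/S_base); the percent form is 2^mean − 1, *not* the mean
  of per-machine percents (the two differ under machine heterogeneity;
  the log-mean form is additive over composed intervals, which tests
  exploit).
* **Leg-press maximum** (kg) per fitness test; when a test value is
  missing the maximum session `max_strength` within ±3 days substitutes.
* **BioAge (strength age-equivalent)**: the commercial model is
  proprietary, so a transparent exponential surrogate is used:
  R(age) = peak·sex_factor·machine_factor·exp(−k(age−peak_age)) with
  peak_age 25, k = 0.01/yr, sex factors 1.15/0.90, machine factors equal
  to the generator's strength fractions.  The observed relative strength
  (max strength / body weight) is inverted analytically per machine —
  extending the exponential above the peak so above-reference strength
  maps to ages below 25 — averaged over machines, then clamped to the
  21-year floor.  Clamping after averaging is a convention choice; its
  visible consequence is a tie mass at exactly 21 (and hence zero change)
  for the strongest participants, which the strict-quantile responder
  rule sends to the middle class — the LR tail of the BioAge metric can
  be small or empty in small cohorts.
* **Compliance**: 100·Σdone/Σtarget over all sessions, not clamped above
  100.  **Training days**: distinct calendar dates with ≥ 1 session.

## Diversity

Rarefaction is an exact multivariate-hypergeometric subsample (without
replacement) to a common depth — default 90 % of the minimum sample depth
— with shallower samples dropped and logged.  Shannon entropy is reported
in natural-log units (the unit is stated in the output header); Pielou
evenness is H/ln(observed), undefined for single-ASV samples.
Within-subject trajectories use Bray–Curtis on rarefied counts for the
three pairs W0–W4, W4–W8, W0–W8.

## Rank-test toolkit

All tests use mid-ranks and tie-corrected variances (survey data are
heavily tied).  Friedman's chi-square uses the Conover tie-corrected
form; when significant, Conover–Iman all-pairs t statistics on rank sums
((n−1)(k−1) df) follow, BH-adjusted, with a greedy insert-absorb compact
letter display at α = 0.05.  Kruskal–Wallis pairs with Dunn z tests
(BH-adjusted).  The Wilcoxon rank-sum uses the normal approximation with
0.5 continuity correction.  The chi-square test defaults to no Yates
correction.  Degenerate inputs (fully tied blocks, identical groups)
return statistic 0, p 1 rather than NaN.

Known approximation behavior, quantified against brute-force oracles in
the test suite: at 4 blocks × 3 conditions the Friedman chi-square p can
deviate from the exact permutation p by up to ~0.15 for weak signals
(≤ 0.02 at moderate/strong signal); Dunn's z p deviates by up to ~0.04 at
mid-range p with 5 observations per group (≤ 0.013 in the detectable
regime).  These are properties of the classical approximations, not of
the implementation — the statistics match scipy exactly where scipy
covers them.

The group × time interaction of the two-group repeated-measures design is
a permutation surrogate (not the ANOVA-type statistic of the dedicated
nonparametric longitudinal literature): global mid-ranks, participant
means removed, statistic = Σ over timepoints of squared group mean-rank
differences, null = permuting group labels across participants, p with
the add-one convention (never exactly 0).

## Differential abundance

The paired design replaces a random-intercept model fit: for complete
pairs, the within-participant difference *is* the exact subject-level
contrast.  Steps, per analyzed subset:

1. Prevalence filter: ASV nonzero in ≥ 25 % of the subset's samples
   (needed for stable t-tests; structural-zero handling of full
   compositional frameworks is out of scope).
2. log₂((count + 0.5)/depth) differences vs W0, depths taken over all
   ASVs.
3. Bias correction: subtract the per-participant-contrast *median* across
   ASVs.  A shift common to all ASVs in a sample pair is a
   compositional/depth artifact (the analogue of a sampling-fraction
   term); the median is robust to ≤ ~10 % genuinely shifted ASVs.
4. One-sample t per ASV per contrast; Holm across the two baseline
   contrasts within each ASV (the two-contrast Dunnett family);
   significance requires Holm-p ≤ 0.05 and |mean log₂FC| ≥ 1.
   Zero-variance ASVs get p = 1 with a warning.

The permutation-subset robustness procedure reruns the identical DAA on
`n_subsets` = 100 seeded, size-matched draws from the non-HR pool
(participants not HR under *any* strength metric).  The empirical p is
k/N — the fraction of subsets with at least as many significant ASVs —
deliberately without the add-one term, so "99 of 100 below" reads exactly
0.01; a zero count is reported as "< 1/N" rather than 0.  Per-ASV chance
frequencies count significance in either direction; q-values are BH over
the chance frequencies of the HR-significant ASVs only (the rows of the
result table), matching the annotation semantics of a per-row "found by
chance" measure.  Note the empirical p of a count statistic is valid but
*not* uniform under the null: the count is almost always 0 there, so the
p has a large atom at 1; tests assert validity (P(p ≤ α) ≲ α), not
uniformity.

## Responder stratification and prediction

Quantiles are linear-interpolation (type 7) with strict inequalities;
ties at a cut go to MR.  For the BioAge metric the sign is inverted
(larger decrease = HR).  The prediction benchmark is a 500-tree random
forest, stratified 5-fold cross-validated ROC-AUC on baseline-only
features, with a label-permutation p ((1 + #perm ≥ obs)/(1 + n_perm),
default 1000 permutations) and fold-averaged, normalized Gini
importances.  Cross-validated AUC (rather than training AUC) is this
package's convention.

## Diet analysis

Variables are centered by their overall mean and scaled by the RMS of the
centered values (making distances invariant to raw units); constant
variables are dropped with a warning.  Sammon mapping minimizes
E = (1/Σδ)Σ(δ−d)²/δ by the diagonal pseudo-Newton update with step
halving, initialized from classical scaling (deterministic; a seed
matters only for the optional random init).  Convergence: relative stress
change < 1e−7 or 500 iterations; exact duplicate records get a 1e−9
jitter because the objective divides by δ.

## Pipeline

`run_all` executes simulate → strength → responders → diversity →
coupling → daa → permtest → diet → predict → report.  Every stage derives
its seed as (global_seed + CRC32(stage name)) mod 2³¹, so stages are
reproducible independently of execution order; two runs with the same
config produce byte-identical bundles (fixed float formatting, no
timestamps).  Disabling a stage skips its dependents with an explicit
message; a missing upstream file fails fast with the stage name.
Analysis stages restrict to the final cohort via the participant table.

## Problem sizes used in validation

The test suite runs the full default-size study (150 analyzed
participants, 300 ASVs, 69k mean depth, 100 permutation subsets) for the
recovery and coupling properties, 10 seeds for recovery and 200 reduced
simulations (30 participants, 200 ASVs, 5k depth) for the DAA type-I
property; end-to-end determinism and orchestration tests use a reduced
study (40 analyzed participants, 60 ASVs) so the whole suite stays in the
minutes range on one core.

## Limitations

* The generator's log-normal/multinomial model has no phylogenetic
  structure, no zero inflation beyond sampling zeros, and exchangeable
  non-planted ASVs; passing recovery tests shows the *procedures* behave
  correctly under a controlled truth, not that real effect sizes are
  detectable.
* Strong planted shifts leave a small footprint in alpha diversity (the
  cohort Friedman p can approach 0.05 under defaults); the alpha-null of
  real data is not part of the generator's contract.
* The BioAge surrogate is calibrated for plausibility (baseline ≈ 46 y,
  ≈ 16-y improvement), not to any proprietary model's outputs.
* The W4 planted effect (log₂FC 1.25, further scaled by coupling) sits
  near the |log₂FC| ≥ 1 call threshold, so week-4 detection counts are
  small and seed-dependent by design — the time progression (few at W4,
  all 27 at W8) is the modeled behavior.
* The 2-group longitudinal interaction test is a permutation surrogate;
  it does not reproduce the ANOVA-type statistic's small-sample
  distribution theory.
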