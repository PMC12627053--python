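# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Expression model and classification

A coded face image is an AU intensity vector over the FACS Action Units
(integers 0–5 for the human coder, reals in [0, 5] for the automated
coder; after ingestion an absent AU is identical to a zero one).  Each
basic emotion has a prototypical AU set; happiness is AU6+AU12+AU25 and
the remaining entries follow EMFACS conventions (sadness {1,4,15}, fear
{1,2,4,5,20,26}, anger {4,5,7,23}, surprise {1,2,5,26}, disgust
{9,15,16}).  The table is user-overridable from a plain-text file.

Human coders do not label emotions by an explicit formula, so the
classifier here is a deliberately simple, auditable stand-in: score each
emotion by prototype coverage minus an off-template penalty
(`β = 0.5`), call the expression neutral when no AU except the blink
(AU45) reaches the activation threshold `τ_active = 1` (FACS counts any
trace as present) or when the best score is below `s_min = 0.5`, and
break ties by mean prototype intensity, then by a fixed emotion order.
The rule reduces to exact matching on clean prototypes: a pure prototype
at any intensity always classifies back to its emotion, since every rival
either misses coverage or takes an off-template penalty.

Three intensity indices summarise an expression over its emotion's
prototype AUs: the mean over all of them, the mean over the active
(non-zero) ones — the headline index, since zero-padding the mean
conflates weak activation with absent AUs — and the maximum.  For neutral,
which has an empty prototype, the indices run over the rater's full AU
set.

## Blood pressure

Four automated readings per day on two days; the first of each day is
discarded (first readings are systematically elevated) and the remaining
six averaged.  JNC-7 bands are applied top-down — out-of-range (SBP ≥ 160
or DBP ≥ 100), then stage 1 (SBP ≥ 140 and/or DBP ≥ 90), then
prehypertension (SBP ≥ 120 and/or DBP ≥ 80), else normotension — so a
mixed profile lands in its higher band and the category is monotone in
both pressures.  Because the study design recruits only up to stage 1,
means at stage-2 levels are flagged `out_of_range` and excluded with a
logged count rather than silently absorbed.

## Agreement panel

Machine intensities are binned (round half away from zero, clamp to 0–5)
before the categorical indices; ICC consumes the raw continuous values by
default since it is not a categorical statistic.  The comparison set
defaults to the 17 AUs for which the automated coder emits intensities.

* **Cohen's κ** uses each rater's observed marginals.  It is undefined
  (not zero) when expected agreement is 1.
* **Gwet's AC1** uses mean marginals over the full 6-category scale
  whether or not all categories were observed, per its definition.
* **Krippendorff's α** is computed from the coincidence matrix with the
  ordinal squared-rank metric; with only two observed categories the
  metric is constant and α reduces to its nominal form.
* **ICC(3,1)** comes from the two-way (units × 2 raters) mean-square
  decomposition.  The literature is ambiguous about whether a fixed-rater
  "absolute agreement" reading is intended for this design, so both
  variants are implemented; the pipeline default is the canonical
  consistency form, and the absolute variant (which penalises a constant
  rater offset) is one flag away.

Undefined index values are excluded from group means with per-cell
exclusion counts in the output — under sparse codings the degeneracies
are themselves informative, and averaging zeros in would bias the panel.
Benchmark labels follow the conventional bands (ICC: <0.5 poor / ≤0.75
moderate / ≤0.90 good / above excellent; κ and AC1: >0.60 acceptable,
>0.80 strong; α: >0.667 acceptable, >0.80 good; boundaries belong to the
lower band).

Group-cell dispersion is the SD across participants (not across AUs);
cells with a single trial report SD 0 with n = 1 visible, and empty cells
report missing values.

## Inference

The demographics ANOVA is recomputed from per-group (n, mean, SD)
summaries via the exact between/within sum-of-squares decomposition — an
algebraic identity with the raw-data F, which is what makes published
summary tables a verification surface.  The ANCOVA is the classic
additive model (group dummies + covariates, no interactions, so Type II
and III coincide for the group effect); the group F compares full versus
covariates-only SSE, partial η² = df1·F/(df1·F + df2), and adjusted means
evaluate the fit at the grand covariate means.  Accuracy enters as 0/100
per participant per emotion, reproducing the percentage scale of the
group table; gender enters as a 0/1 indicator.  Bonferroni post hoc
comparisons multiply each pairwise contrast p by the number of pairs;
homogeneous-subset letters are the maximal cliques of the
not-significantly-different graph, so the familiar a / ab / b pattern
arises when only the extremes differ.  Partial correlations residualise
both variables on the covariates and correlate the residuals
(df = n − 2 − k, two-tailed p); with no covariates this is plain Pearson.

Sample size for the group effect inverts noncentral-F power:
λ = f²·N, df = (k−1, N−k−c), N is the smallest integer whose power
reaches the target.  At f = .50, α = .05, power = .95, k = 3, c = 3 this
gives N = 66 (power 0.9530; 0.9499 at 65).  A Fisher-z routine for the
partial-correlation design is provided, but its result depends on which
exact test family a power calculator assumes, so it is reported without a
canonical reference value.

## Synthetic data generator

The generator emulates the study conditions: group sizes 33/21/20,
per-group BP sampling windows centred near the observed group means
(normotensive ≈ 103/71, prehypertensive ≈ 126/82, hypertensive ≈ 144/91),
reading noise SD 2 mmHg with the first reading of each day elevated by
8 mmHg so the discard rule is exercised, and per-group demographic models
(age means 24/30/40, the observed gender ratios, education ≈ 16 ± 2
years) so covariate adjustment has real work to do.  Targets are redrawn
until the six-reading mean classifies back into the intended group,
making group labels exact ground truth.

Expression accuracy follows a logistic model in continuous SBP,
`P(correct) = invlogit(β0_e − β1_e·(SBP−100)/10)`, so categorical and
continuous analyses share one ground truth.  The default intercepts and
slopes were back-fitted once from the observed group-level accuracy
ordering at the groups' mean SBPs (happiness near ceiling and flat;
sadness, fear and surprise steeply BP-dependent; anger and disgust mildly
so) and are not tuned thereafter.  On the correct path all prototype AUs
activate at `clamp(round(N(μ_e − d·g, σ)), 1, 5)` with dampening
d = 0.25 intensity units per group step and σ = 0.8; incidental
off-template AUs activate with probability 0.05 at intensity 1–2.  On the
incorrect path the participant produces either a sub-threshold partial
prototype or a confusable emotion's prototype (sad↔fear, anger↔disgust,
surprise→fear, happy→surprise) with equal probability; either way the
rule-based classifier cannot return the intended label, so latent
correctness and pipeline accuracy coincide.  Incidental AUs are kept off
the intended prototype, and in the rare case where they would still
outvote it on the correct path they are stripped, preserving that
identity.

The machine rater transforms the human coding per AU: a miss with
probability `0.5·exp(−h)` (automated detectors miss subthreshold
activations), otherwise `clamp(0.7·h + N(0, 0.4), 0, 5)` — gain below 1
reproduces the observed direction that human intensities exceed machine
ones.  Two percent of images fail wholesale (`success = 0`), exercising
the exclusion accounting.

What the synthetic data do **not** model: real image capture, temporal
dynamics, coder drift, demographic biases of automated detectors, or any
nonlinear (inverted-U) BP–expressivity relation.  Passing tests therefore
establish that the pipeline recovers effects of the assumed generative
form from realistically sized and structured data — not that the
published effect sizes themselves are reproduced, which is impossible
without the raw images.

## Numerical choices and edge cases

* ANCOVA with numerically zero residual variance: F = 0 when the group
  adds nothing beyond the covariates (e.g. a constant outcome), an error
  otherwise; rank-deficient designs name the collinear column.
* κ/α/ICC degeneracies return missing values, logged and excluded from
  aggregation.
* Binning rounds half away from zero (2.5 → 3), matching the intuition
  that a half-step of evidence counts up.
* Automated-coder intensities outside [0, 5] are clamped on ingestion
  with warnings and counts; rows with `success = 0` are excluded and
  counted; the pipeline asserts that input trials = analyzed +
  machine-failed + retention-removed.
* All simulation randomness flows from a single seeded generator; a
  (config, seed) pair reproduces a study byte-for-byte.

## Problem sizes

The validation suite runs the oracle sweep at 1,000 random instances, the
sparsity simulation at 1,000 replicates, parameter recovery at 200
replicates of 100 participants per group, and the type-I-error study at
1,000 simulated 74-participant studies — sizes chosen to give stable
Monte-Carlo estimates (binomial SE ≈ 0.7 percentage points at 1,000
replicates) while keeping the whole suite comfortably fast on one core.
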