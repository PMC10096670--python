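# Methods

This note documents the statistical procedures dietgxe implements, the
generating model behind its synthetic cohorts, the numerical choices made
where the design was genuinely open, and what the package's tests do and
do not establish about real data.

## Outcome: the trait-impulsivity score

Four NEO facet sum scores (impulsivity, excitement seeking,
deliberateness, self-discipline; 8 items each on a 1–5 Likert scale, so
sums lie in [8, 40]) are combined into one score.  The two
conscientiousness facets are reverse-keyed and reflected as
`48 − sum`, which maps [8, 40] onto itself.  A single principal
component is extracted from the 4×4 Pearson correlation matrix, oriented
so the impulsivity facet loads positively, and each person's score is
the standardized projection of their z-scored facets.  Because the PCA
runs on correlations, the score is invariant to per-facet location
shifts.  An optional separate estimation sample is supported, since PC
loadings are ideally estimated on the largest available sample rather
than the genotyped subset.

## Polygenic scoring

* **QC.** Duplicated variant ids are treated as multiallelic sites and
  removed entirely.  A/T and C/G pairs are strand-ambiguous and removed.
  Variants with min(freq, 1−freq) ≤ 0.01 or imputation INFO ≤ 0.8 are
  dropped, then the table is intersected with the target panel.  The
  function returns a per-filter count report so exclusion flowcharts can
  be reproduced.
* **Clumping.** Greedy: repeatedly take the remaining variant with the
  smallest p-value as an index and remove all unselected variants on the
  same chromosome within ±250 kb whose squared dosage correlation is
  ≥ 0.1 (so survivors within a window satisfy r² < 0.1, the standard
  survivor condition).  Ties on p break toward the smaller position for
  determinism.  r² uses pairwise-complete samples.  The test suite
  checks the greedy result against an independent brute-force
  implementation on randomized fixtures.
* **Scoring.** For each of 11 thresholds (5e-8 … 1), the score is
  Σ β_j · dosage_ij over variants with p ≤ t, then z-standardized.
  Alleles are harmonized by id: when the summary-stat effect allele is
  the panel's other allele the dosage is flipped (2 − d); strand flips
  cannot arise because ambiguous pairs were removed.  Missing dosages
  are mean-imputed per variant.  Thresholds with no qualifying variants
  (or zero variance) are flagged and excluded from the PCA with a
  warning.
* **PRS-PCA.** The final PRS is the first principal component of the
  correlation matrix of the standardized threshold scores, re-standardized.
  Sign convention: flipped if the mean loading is negative, so a higher
  score means higher risk at most thresholds.  This makes the output
  invariant to column order, to the eigensolver's sign, and to sign
  flips of a minority of input columns; negating *every* column can only
  negate the score — no data-driven orientation can undo a global
  negation, because the negated panel is observationally identical.
* **Variance explained.** Two-step: residualize the outcome on age,
  sex, genotyping chip, four genetic PCs and chip × PC products, then
  regress the residuals on the PRS alone; the reported quantity is the
  second model's adjusted R² × 100.  Slightly negative values under the
  null are reported as computed.

## Diet and lifestyle derivation

* **Schofield BMR** uses the weight + height equations by sex and adult
  age band (18–30, 30–60, ≥60), in kcal/day (e.g. male 18–30:
  15.4·W − 27·H + 717).  Weight is recovered from BMI × height² when
  only BMI is recorded.  Ages below 18 are out of scope (the cohort
  excludes minors).
* **Reliability.** Records with energy/BMR outside [0.79, 2.49] (±2 SD
  of required energy) are excluded; the boundaries themselves are
  retained because the published rule excludes strictly outside them.
* **Excess ratios.** KCAL = energy/BMR, FAT = fat%/30, SUGAR =
  sugar%/10 (WHO maxima).  Values below 1 denote non-excessive intake
  and are censored to 1, so only the excess varies.
* **LLDS.** Each of 9 healthy food groups (g/1000 kcal) scores its
  within-sample quintile 0–4; 3 unhealthy groups score 4–0; the sum is
  the diet score (0–48) and LLDS-I = 48 − LLDS is its inversion (the
  published description says only that the score was inverted; 48 − LLDS
  preserves the printed range and the reported score scale).  Quintiles
  and tertiles use average ranks with boundary values assigned to the
  lower bin, matching the half-open printed group ranges
  (e.g. Q3: KCAL > 1.41).
* **MVPA** is rescaled to fixed quintile scores with cuts 60/150/255/420
  min/week.  The published band edges print "150–255" followed by
  "250–420"; a single 255 boundary restores contiguity (one-character
  typo assumption) and is adopted.
* **Sleep** classes come from deciles of sleep-hour residuals on age and
  sex (lowest decile short, highest long), because sleep need varies
  with age in a sex-dependent way.  Rank-based assignment gives
  10/80/10 shares within one person at any n ≥ 20.
* **Alcohol** bands are printed to one decimal (occasional < 2.5, light
  2.5–14.9, moderate 15–29.9, heavy > 30 g/day), leaving [14.9, 15) and
  [29.9, 30) unassigned; half-open bins [2.5, 15), [15, 30), [30, ∞)
  close the gaps.  Abstinent requires exactly 0 g/day.  Smoking uses
  current > past > never precedence.

## Regression battery

All models are OLS with complete cases.  The basic model regresses the
outcome on the PRS plus age, sex, BMI, four SES indices (neighborhood
SES, household income, education dummies vs low, occupational status),
a non-communicable-disease flag, current depression and anxiety,
stressful life events and long-term difficulties, and genetic controls
(chip dummy, four genetic PCs, chip × PC products).  Step-2 models add
one moderator's main effects plus PRS × moderator products; reference
levels are the lowest tertile, SUGAR = 1, normal sleep, never-smoker
and abstinent, and MVPA enters as a single semi-continuous score with
one product term.  Interaction tests use the Bonferroni bound
0.05/4 = 0.0125, applied per step.

Numerical choices: confidence intervals use the t distribution with
residual degrees of freedom (no robust errors — nothing indicates they
were used originally); tiny p-values are reported in scientific notation
without flooring; the standardized beta for term x is
B · sd(x)/sd(outcome) on the analysis sample, dummy columns included
(the original report does not state its standardization; this choice
reproduces the printed scale pattern); rank-deficient designs raise an
error naming the implicated columns.  The SES sensitivity refit appends
moderator × SES products (constant products, e.g. an absent education
level, are dropped as uninformative) and reports the change in each
PRS × moderator coefficient.  A median/mode single imputer is provided
as plumbing for covariate missingness; the original analysis used
chained-equation imputation, which is out of scope, and complete-case
analysis is the default here.

## The synthetic cohort

The generator's defaults are the study conditions of the source
analysis: n = 33,047 adults; a discovery GWAS of 225,534 individuals;
covariate and exposure marginals calibrated to the cohort's published
descriptives (age 42.1 ± 12.35 truncated to [18, 90] with the location
shifted so the post-truncation mean hits the target; 59.8% female;
BMI 25.5 ± 4.04; education 25.5/40.8/33.7%; chip split 82/18; four
standard-normal genetic PCs).

* **Genotypes.** Variants get MAFs uniform on [0.05, 0.5] and are laid
  out in LD blocks ~5 kb apart.  Each allele copy is thresholded from a
  latent Gaussian with a per-block equicorrelation; the latent
  correlation is calibrated (via the bivariate-normal rectangle
  probability, Gauss–Legendre quadrature on the correlation integral)
  so the mean within-block *dosage* correlation matches `block_r`.
  When a block's MAF spread makes the target unattainable the maximum
  achievable correlation is used with a warning.
* **Summary statistics.** True log-odds effects are N(0, effect_sd²)
  for a causal fraction (default 0.3) and zero otherwise; observed
  effects add noise with variance 1/(gwas_n · 2·MAF·(1−MAF)).  A small
  fraction of rows is emitted allele-flipped and strand-ambiguous, and a
  few ids are duplicated, so QC and harmonization are exercised by
  construction.
* **Exposures.** Energy/BMR is normal (1.28 ± 0.30, clipped inside the
  reliability bounds), percent energy from fat normal (35.4 ± 4.45),
  free-sugar percent lognormal (median 10.6, log-SD 0.445) — chosen so
  the derived KCAL/FAT/SUGAR medians, interquartile ranges and tertile
  cuts match the published descriptives (KCAL cuts ≈ 1.14/1.41, FAT ≈
  1.12/1.25, > 33% at SUGAR = 1).  Food-group intakes are lognormal
  around plausible Dutch-FFQ magnitudes with a shared diet-healthiness
  factor (loading 0.22) that reproduces the diet score's SD of ≈ 6;
  only within-sample ranks matter for the score.  Sleep hours carry
  age and sex effects matching the published sex means; MVPA, alcohol
  and smoking follow the published class frequencies.
* **Outcome.** The linear predictor is assembled from the *derived*
  variables (tertile dummies, lifestyle classes, covariates) using the
  configured coefficient map — defaults are the published estimates —
  so recovery experiments have exact generating values while still
  exercising the derivation code.  Records drawn as energy-unreliable
  (default 2%) carry no diet-moderator signal and are excluded upstream
  of any fit; recovery experiments set this fraction to zero so the
  analysed n equals the configured n.  Residual noise defaults to
  SD = √(1 − var(linear predictor)), giving outcome variance ≈ 1.
  NEO facet sums are back-filled from the outcome with loadings matching
  the published PC structure (0.82/0.82/0.68/0.37), clipped to [8, 40]
  and rounded.
* **rGE.** A gene–environment correlation dial adds
  `γ · sd(exposure) · PRS` to each continuous diet exposure (on the log
  scale for lognormal ones, with the healthiness factor *decreasing* in
  the PRS), so cor(PRS, exposure) ≈ γ/√(1+γ²), monotone in γ.
* **Reproducibility.** All randomness flows from one seed through
  fixed-order `SeedSequence` children (genotypes, summary stats,
  covariates, exposures, outcome, facets); identical configs produce
  byte-identical fixture files.

What the simulator does **not** emulate: real human LD maps and allele
frequency spectra, Hardy–Weinberg departures, imputation-error
structure, realistic FFQ item-level measurement error, within-family
correlation (the source cohort has a three-generation design), or
non-linear covariate–outcome relations.  Passing recovery tests
therefore establishes that the pipeline's estimators are correct and
calibrated under the stated generating model — not that the published
effect estimates are themselves unbiased in the real cohort.

## Experiment sizes

The reproduction script and the acceptance tests run 50–55 replicates
at n = 33,047 per target (Monte-Carlo standard error of the mean
interaction estimate ≈ 0.0017, well inside the ±0.005 comparison band),
a 10,000-person cohort for the sleep-decile share, and 500 replicates
at n = 2,000 for confidence-interval coverage and type-I error of the
interaction test.  Recovery simulations use a small independent-variant
panel (m = 40) because the PRS entering the outcome model is the
standardized true genetic score, making coefficient recovery independent
of the panel's LD structure; LD-dependent behaviour (clumping,
harmonization, PRS-PCA) is tested separately on structured panels.

## Known limitations

* The impulsivity PC is estimated on whatever sample is supplied; the
  original loadings came from a much larger superset of the genotyped
  sample.
* Which Schofield variant (weight-only vs weight + height) the source
  cohort used is not stated; the weight + height equations are adopted
  and tabulated in `derive.SCHOFIELD_WH`.
* Whether diet-score quintiles were computed on the full cohort or the
  analysis subset is not stated; this implementation computes all
  sample-relative cuts on the analysis (post-exclusion) sample.
* Family relatedness is not modelled in either the simulator or the
  regressions (OLS assumes independent residuals).
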