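# Methods

## Scope and data model

`facepref` analyses studies with this design: raters nested in countries
judge, for each of two judgements (attractiveness, femininity) and five
fertility-cue prototype sets (conception probability in all cycles;
conception probability in "textbook" ovulatory cycles; estradiol E;
progesterone P; E/P ratio), a triplet of low/medium/high-cue composite
faces — once as a three-alternative forced choice and once as 1–7 ratings
of each composite.  Four long-format tables carry the data: participants
(demographics, self-ratings, 9-item SOI-R with composite = item mean),
choices, ratings, and a country-by-indicator table of 11 national
statistics.

## The centroid randomisation test

A 3AFC cell is the count composition (n_low, n_medium, n_high).  The
statistic is the Euclidean distance of the observed proportion point from
the centroid of the ternary simplex, computed in the unit-edge
equilateral-triangle embedding (vertices low=(0,0), medium=(1,0),
high=(1/2, √3/2)); algebraically d(p) = √(Σ(p_i − 1/3)²) / √2.  The null
distribution is simulated: n_sim (default 10,000) draws of
Multinomial(n; 1/3, 1/3, 1/3), one per simulated sample — statistically
identical to simulating n raters individually and n-fold faster.  The
p-value is the fraction of simulated distances at least as large as the
observed one.

Numerical conventions:

- **Tie rule.**  All exceedance comparisons use the integer statistic
  T = Σ(3 c_i − n)², strictly monotone in d, so ties are exact rather than
  float-equal.  The default rule counts simulated T ≥ observed T ("geq"),
  which is conservative (never understates p); strict exceedance ("gt") is
  available, and `exact p(gt) ≤ exact p(geq)` always.
- **Smoothing.**  p is reported as k/n_sim, matching the
  proportion-of-simulations definition; the add-one variant
  (k+1)/(n_sim+1) is reported alongside for users who prefer a p-value
  that cannot be exactly zero.
- **Oracles.**  `exact_multinomial_p` enumerates all O(n²) compositions
  for n ≤ 200 and sums the exact multinomial tail; `chi_square_p` uses the
  closed form exp(−X²/2) (survival function of χ²₂ at
  X² = Σ(O_i − n/3)²/(n/3), in which d is monotone).  The test suite
  checks the Monte Carlo route against both, for every composition with
  n ≤ 30 and at the study's n = 1371 respectively.
- The embedding scale is a convention; any rigid rescaling multiplies all
  magnitudes by a constant and leaves every p-value unchanged.

## Reconstituting printed tables

Published reports typically print cell percentages, not counts.
`reproduce_table1` maps a percentage row back to counts at the analysed
sample size by largest-remainder rounding (floor, then distribute the
shortfall to the largest fractional remainders; remainder ties broken by
column order low, medium, high, making the rounding deterministic).  The
per-cell sample sizes after missing-data attrition are not printed in such
reports, so the full final sample n is used for every row; plausible
attrition shifts mid-range p-values by a few hundredths, which is why the
reproduction tolerance is ±0.05.

## Preprocessing

Exclusions, in order: Kinsey 4–6 (predominantly homosexual raters; missing
Kinsey retained), sex neither female nor male, then whole countries with
fewer than 10 remaining raters.  Each removed rater is counted against the
first rule that removes them, so the report reconciles exactly, and the
operation is idempotent.  Whether the 10-per-country rule preceded or
followed the other two in the original analysis is not documented; applying
it last is this package's convention and is surfaced in the exclusion
report.

Continuous covariates are winsorised at mean ± 3 sample SDs in a single
pass (bounds from the raw values, not iterated; values exactly at a bound
untouched; zero-variance vectors returned unchanged).  Standardisation uses
the sample-SD (n−1) convention and respects the unit of analysis:
participant-level covariates are z-scored across participants, country
factors across countries (regardless of how many raters each country
contributes).  Two-level factors are effect coded female=−1/male=+1 and
low=−1/high=+1; in model design matrices unknown categories (e.g. sex
"other" before exclusions) code to missing and are removed listwise.  The
3AFC choice enters the consistency models as the numeric score −1/0/+1,
because a single printed estimate per model is incompatible with a
2-degree-of-freedom categorical coding.

## Mixed models

All linear mixed models are fitted with statsmodels `MixedLM`.
Participants are nested in countries, so the country is the grouping
factor; participant intercepts enter as variance components (participants
relabelled within country to keep the design narrow).

- **Rating model** (per judgement × cue set): rating ~ level + age_z +
  sex_ec, restricted to the low and high prototypes, with a country random
  intercept, a country random slope on level, and participant intercepts.
  Level is coded −1/2 vs +1/2 so the coefficient *is* the high-minus-low
  difference in rating points.
- **Consistency model**: the high-minus-low difference score
  (one per rater × judgement × cue set, raters missing either rating
  omitted) regressed on the −1/0/+1 choice score plus age and sex, country
  random intercept.  A positive coefficient means raters who chose the
  high-cue face also rated it relatively higher.
- **Moderation models**: the rating variant adds level × moderator
  interactions (headline terms); the choice variant is an ordinal model of
  the chosen level (below).  Two moderator batteries mirror the emulated
  analysis: individual differences (age, sex, self-rated attractiveness,
  health, financial difficulties) and SOI (age, sex, SOI composite, fitted
  on the SOI-complete subsample only, since SOI carries the most
  missingness).  Country-level moderation uses the two country factors,
  standardised across the scored countries and passed through unstandardised
  at the participant level.

"Maximal" random-effect structures cannot be reproduced exactly from a
published description, so the fitting cascade is explicit: start with the
country slope, prune slopes before intercepts whenever a fit is singular
(smallest random-effect eigenvalue below 1e−6 × residual scale) or fails to
converge under any of three optimizers, and fall back to OLS only when every
mixed structure fails (e.g. noiseless degenerate data).  Every prune is
recorded on the returned `ModelFit`; nothing is silently skipped.
Significance is read at α = .05, two-sided, without multiplicity
correction; the pipeline's model summary records how many models were run
so readers can apply their own correction.

## Ordinal choice models

No Python library provides a cumulative-link model with random effects, so
the choice moderation model offers two links:

- `link="cumulative"` (default): a population-averaged cumulative logit
  fitted by GEE (`OrdinalGEE`) with the country as the cluster and an
  exchangeable working correlation.  This matches the field's standard
  CLMM analysis in link and in its clustering correction, but estimates
  marginal rather than conditional coefficients.
- `link="adjacent"`: an adjacent-categories logit fitted by maximum
  likelihood (own implementation; analytic gradient and observed
  information).  Under this link P(level j) ∝ exp(δ·x_j) with
  x = (−1, 0, +1) — exactly the synthetic generator's choice model — so a
  slope planted in the generator is the estimand itself.  Parameter-recovery
  validation therefore uses this link; a cumulative-logit fit of
  adjacent-categories data estimates a rescaled quantity (≈1.5δ near
  δ = 0), which is a link mismatch, not an error.

Positive coefficients always mean "shifts choices toward the high-cue
prototype".  Complete separation is flagged (coefficient magnitude above
30 or singular information) and reported as non-estimable rather than
raised.

## Country factors

The 11 indicators (HDI, life expectancy, years lost to disease, fertility
rate, GII, urbanisation, historical pathogen prevalence, mortality rate,
homicide rate, Gini, GDP) are reduced by a 2-factor exploratory factor
analysis: maximum-likelihood extraction with varimax rotation
(scikit-learn `FactorAnalysis`), regression-method scores.  The named
"independent factor analysis" procedure this emulates is not publicly
specified; standard EFA reproduces its documented output (two
interpretable factors) and the extraction is configurable.  Factors are
labelled automatically from marker loadings — health/development by
HDI + life expectancy, inequality by Gini + GII + homicide — with signs
oriented so the markers load positively; labels and signs are conventions
of an otherwise rotation-indeterminate model and can be overridden.  The
model is fitted on *all* supplied countries (the emulated analysis used
121) and scores are then standardised across the scored study subset.
Missing indicator cells are mean-imputed with a warning rather than
dropping a country.  Recovery is judged by Tucker congruence after
orthogonal procrustes alignment, the standard yardstick for factor
equality (≥ 0.95).

## The synthetic generator

The generator is the pipeline's ground truth, not a convenience fixture.
Defaults emulate the published study's conditions: 12 countries × 114
raters (≈1371), age truncated-normal (mean 29.59, SD 9.72, range 18–70),
9% Kinsey-4–6 mass, sex mix ≈45/54/1% female/male/other, per-cue-set
preference strengths δ₀ implied by the published choice percentages
(e.g. textbook ≈ 0.142 = log(39.35/29.64)/2) and rating effects of the
published order (≈0.1–0.2 rating points).  Covariate scales are uniform
integers; their real-world distributions are undocumented, so these are
conventions, as are the heterogeneity SDs (participant 0.3 / country 0.1
on δ; participant 0.5 / country 0.2 / residual 1.0 on the rating latent).

Choices follow P(level j) ∝ exp(δ_i x_j), x = (−1, 0, +1), with
δ_i = δ₀(cue set) + Σ slope·z(moderator) + country effect + participant
noise.  Ratings follow a Gaussian latent y* = μ + (effect + b_i)·x_level +
participant intercept + country intercept + noise, x_level = ±1/2, rounded
and clipped to 1–7 — a round-and-clip convention rather than a full
threshold model.  The optional per-participant cue-effect slope b_i
(SD `rating_slope_sd_participant`, correlation `task_coupling` with the
participant's choice deviation) exists because without it the two tasks
share no participant-level signal: the participant intercept cancels from
high-minus-low difference scores, making cross-task consistency
untestable.  Defaults of zero reduce the model to the plain
random-intercept form.  Country indicators are loadings × latent 2-factor
scores + Gaussian noise, with the same latent scores optionally driving
choice preferences (country-factor moderation with known truth).

One integer seed drives named SeedSequence substreams (participants,
latents, choices, ratings, indicators, country factors), so identical
config + seed reproduces any table bit-for-bit, alone or together.

What the generator does *not* emulate — and hence what passing recovery
tests do not certify about real data: non-uniform covariate distributions
and covariate–preference confounding, informative missingness (its
missingness is completely at random), unequal country sizes by default,
response styles and scale-use heterogeneity in ratings, and any true
cumulative-threshold response process.

## Simulation studies

`power_study` draws choice compositions from the preference model over a
(δ₀, n) grid and reports the rejection rate of the randomisation test at
α = .05; at δ₀ = 0 this is the type-I error rate, which the acceptance
suite requires to sit in [0.035, 0.065] across 1000 simulated datasets of
n = 1371 (1000 Monte Carlo samples per test).

## Problem sizes used in validation

Recovery checks run at the scale a desk validation supports: 100 seeded
replicates of ~500 raters (rating effect 0.5) and ~750 raters (choice
moderation slope 0.4), requiring ≥90% CI coverage; oracle equivalence over
every composition with n ≤ 30 at 50,000 simulations (one shared null
sample per n, equivalent for tail counting) and six compositions at
n = 1371 against the closed form at 100,000 simulations; factor recovery
at 60 synthetic countries.  The full pipeline is exercised end-to-end on a
reduced dataset (4 countries × 30 raters).

## Known limitations

- Mixed-model p-values are Wald-normal (statsmodels convention), not
  Satterthwaite; with 12 country-level units, country-level fixed effects
  have optimistic tails.
- The cumulative-link moderation route is population-averaged (GEE), not
  conditional; its coefficients are attenuated relative to a
  random-intercept CLMM when country heterogeneity is large.
- `exact_multinomial_p` is limited to n ≤ 200 by design; beyond that the
  Monte Carlo route with the chi-square cross-check is the intended path.
- Published coefficient tables for the rating/consistency models cannot be
  reproduced without the study's raw responses; the pipeline reproduces the
  *scheme* and validates it by parameter recovery instead.
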