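# Methods

## Data model

The atomic record is a field plot. An *environment* is a location-year
crossed with a nitrogen fertilization level; a *location-year* is a
unique combination of location, year and irrigation regime (irrigation
is usually confounded with site and season, so it is part of the
location-year identity rather than a crossed factor). Within each
environment the design is a randomized complete block with (typically)
two blocks. Trait units are carried as metadata and never converted
implicitly; the only unit operation provided is the explicit maize
grain conversion 1 bu/acre = 0.0628 MT/ha (56-lb bushels at 15.5%
moisture). Growing degree days use the standard 86/50 °F maize method:
daily minimum and maximum temperatures are clamped into [10 °C, 30 °C]
before averaging and the daily value is floored at zero; the clamping
convention is stated here because base and optimum temperatures alone
do not pin it down.

Plot tables and pedigrees are plain CSV (UTF-8, comma separators,
header row, `.` decimal, blank cell = missing). Rows with unparseable
identity keys are dropped with a logged count; unparseable or empty
trait cells become missing values, never errors.

### Filtering

- `filter_min_environments(min_env)` removes hybrids observed in fewer
  than `min_env` distinct environments (default 3 in the pipeline).
  Under-observed hybrids cannot support reaction-norm estimates;
  removal is idempotent and recorded.
- `remove_extreme_values(bounds)` sets trait values outside
  user-supplied per-trait (optionally per-location-year) bounds to
  missing and reports the removed fraction. The thresholds themselves
  are deliberately configuration, not code: sensible values are
  trait- and panel-specific, and sane bounds should remove well under a
  few percent per trait. With plot-mean ear phenotypes as input,
  re-averaging individual ears after removing one extreme ear is not
  possible and the mechanism operates on the plot values as given.

## Finlay–Wilkinson regression

The estimator is the classical two-step joint regression:

1. Environment index h_j = mean of all plot values of the trait in
   environment j, over whichever hybrids are present (the population-
   level performance of the environment). Plot means rather than
   hybrid means are used; under equal replication they coincide.
2. Per hybrid, OLS of its per-environment means on h_j. The slope is
   reported directly, so the presence-weighted population slope is 1
   (on balanced data, exactly 1): this *is* the "+1 convention" —
   fitting environment-mean deviations and adding one gives the same
   number.

Hybrids with fewer than two environments for a trait are excluded from
that trait's fit only. Low-yield outlier environments (a location-year
whose population mean sits far below all others distorts the index) can
be excluded by pattern before indexing. A degenerate (constant) index
raises rather than fitting noise.

An optional alternating-least-squares refinement re-estimates h_j from
the current slopes/intercepts (the least-squares index update
h_j = Σ_i b_i(ȳ_ij − a_i) / Σ_i b_i²), refits, rescales so the
presence-weighted mean slope is 1 with the index mean unchanged, and
iterates (tolerance 1e-8 on the index, maximum 100 iterations). On
balanced data it reproduces the two-step fit; under strong
unbalancedness it can shift the index slightly. It is off by default
because the two-step fit is the method's standard, deterministic form.
A Bayesian hierarchical FW fit would shrink extreme slopes toward 1;
slopes reported here are unshrunken OLS values and can therefore have
slightly wider range than shrinkage estimators on the same data.

### Rank-change prediction

Fitted values a_i + b_i·h_j are evaluated at the lowest- and
highest-index environments for every hybrid pair; a pair "changes rank"
iff the fitted difference changes sign between the two. Differences
smaller than 1e-9 trait units at either endpoint are ties and count as
no change (float-equality artifacts cannot evidence a crossover).
Among changing pairs the report also gives the fraction whose fitted
gap in the best environment exceeds a threshold (default 0.63 MT/ha =
10 bu/acre, the conventional agronomically-meaningful yield gap).

### Percent-of-environment-mean plasticity

Each plot's response is 100 · value / (environment mean). A hybrid's
percent-basis plasticity is its OLS slope of this response on the
environment mean, plus 1. This equals fitting one linear model with
hybrid, environment-mean and hybrid × environment-mean terms and taking
interaction coefficient + shared coefficient + 1, because the
interaction model is saturated per hybrid; the per-hybrid form is used
for numerical transparency. A hybrid exactly tracking its environment
mean everywhere gets slope 1 and mean percent performance 100.

### BLUP ranking

Overall hybrid ranking uses a mixed model with environment as a fixed
effect and genotype as a random effect (REML, via statsmodels MixedLM).
Hybrids are ranked by ascending predicted genotype effect (rank 1 =
minimum BLUP), ties broken lexicographically by hybrid id for
reproducibility. On balanced data shrinkage is uniform, so the BLUP
order equals the raw-mean order; under unbalanced presence the
environment fixed effect corrects hybrids seen mainly in good or bad
environments.

## Variance components

Both decompositions are REML estimates of Gaussian random-effects
models, computed by a purpose-built engine rather than a generic mixed-
model routine, because the crossed design (genotype × environment) at
study size — hundreds of hybrids, tens of environments, thousands of
plots — is far outside what per-group mixed-model implementations
handle efficiently.

**Plot model** Y_ijk = μ + g_i + e_j + η_ij + ε_ijk. The likelihood is
factored exactly into (a) within-cell replicate contrasts, which depend
only on σ²_ε and contribute df_w·log σ²_ε + SS_w/σ²_ε, and (b) cell
means, whose covariance is D + σ²_g Z_g Z_g' + σ²_e Z_e Z_e' with
D = diag(σ²_η + σ²_ε/n_ij). Woodbury/determinant-lemma identities
reduce every solve to the (genotypes + environments)-sized inner
matrix, so a 100 × 30 × 2 fit takes well under a second. The four
variances are optimized on the log scale (L-BFGS-B, Nelder–Mead
fallback, relative tolerance 1e-8, max 200 iterations); boundary
components shrink to the lower bound and are reported as exactly zero
with a flag. Proportions divide each variance by the sum of all four
("total phenotypic variance"), so they are non-negative, sum to one,
and are invariant to affine rescaling of the trait. Verified against
closed-form balanced-design ANOVA estimators (equal to REML at interior
optima) and against lme4's REML on unbalanced fixtures; requires some
within-cell replication, since without replicates the interaction and
the plot residual are confounded.

**GCA model** B_ij = μ + ear_i + pollen_j + ε_ij on per-hybrid
plasticity values (one observation per hybrid). Ear and pollen parents
are two separate random-effect populations even when the same inbred
appears on both sides of different crosses; the reported parental GCA
proportion is the sum of the two parental proportions, which is how the
overlap is resolved. Hybrids without a resolvable pedigree (commercial
checks) are excluded with a logged count; the model refuses to fit when
there are fewer hybrids than parents + 2. The n × n covariance is
handled densely (n = hybrids, small).

## Interaction-importance scoring

Per environment: one-way ANOVA with genotype as the sole predictor
pools the within-genotype variance; all hybrid pairs are compared with
the Tukey–Kramer statistic
q = |m_a − m_b| / sqrt(MSE/2 · (1/n_a + 1/n_b)) referred to the
studentized-range distribution with k = number of genotypes and the
ANOVA residual df (scipy's distribution; at k = 2 this reduces exactly
to the pooled t-test via q = t√2). Significance is α = 0.05 by default,
configurable; no additional multiplicity correction is applied across
environments or traits. When only the α decision is needed (all-pairs
scoring) the comparison uses the single critical value
isf(α; k, df) instead of per-pair p-values — identical decisions,
since the sf is monotone in q, and orders of magnitude faster. If the
pooled variance is exactly zero, a zero mean difference is p = 1 and a
nonzero one p = 0.

Per environment pair: score 0 without a rank change of the two hybrids'
means (exact ties count as no change — conservative); otherwise the
number of the two environments with a significant difference (0, 1, 2).
Per hybrid pair: n_E counts environments where both hybrids have trait
data; all C(n_E, 2) environment pairs are scored, the raw sum is
normalized by n_E × (n_E − 1) (two points possible per environment
pair, implemented literally), and pairs with n_E < 2 carry an undefined
score and are excluded from distribution summaries. All plots in an
environment feed the ANOVA, regardless of block.

## Repeatability and nitrogen plasticity

*Split-block repeatability*: half A takes the lowest block id of every
in-scope environment, half B the rest (deterministic; a seeded random
assignment mode exists for sensitivity checks). Two FW fits on the
disjoint halves are compared by Spearman ρ (average ranks for ties)
over common hybrids; fewer than three common hybrids yields undefined ρ
rather than a spurious value.

*Nitrogen plasticity*: a location-year qualifies when its population
median (configurable to mean) of the trait increases strictly across
nitrogen levels ordered by application rate — medians because
population-level dose-response summaries conventionally use them and
they resist plot outliers. Within a qualifying location-year, nitrogen
plasticity is the FW slope over that location-year's nitrogen
environments only (hybrids in fewer than two of them are dropped). MNP
is the exact arithmetic mean of a hybrid's per-location-year slopes and
is reported only for hybrids with slopes in every qualifying
location-year (a `require_complete=False` flag averages whatever is
available). Cross-location-year Spearman correlations use hybrids with
complete observations per pair; within-location-year repeatability
stacks the (hybrid, location-year) half-slope pairs from all qualifying
location-years into one correlation — one block per nitrogen treatment
per half.

*Trend*: OLS of overall hybrid mean on FW plasticity and mean parent
release year, with sequential (type-I) ANOVA in both predictor orders,
since "the plasticity effect controlling for breeding era" and vice
versa are different questions under correlated predictors.

## The synthetic-data generator

Plot yields follow Y_ijk = μ + g_i + b_i·e_j + η_ij + β_jk + ε_ijk.
The FW slope term b_i·e_j is deliberately added to the additive G×E
model: FW regression is exactly the projection of G×E onto the
environment index, so without a slope term there would be no signal to
recover; η_ij remains the non-systematic G×E remainder.

Defaults describe one study-sized condition set, fixed once: 120
hybrids; 10 location-years (years 2022/2023) × 3 nitrogen levels
(84/168/252 kg N/ha) = 30 environments; 2 blocks; μ = 9 MT/ha;
environment effect sd 2.5 MT/ha (the realized sample sd is pinned
exactly, and includes a diminishing nitrogen dose–response of
0 / +1.5 / +2.25 MT/ha across levels); genotype intercept sd 0.6
MT/ha; FW slope sd 0.15 — chosen above the range visible in shrunken
published slope estimates for era-diverse panels, so that the
slope-recovery signal-to-noise at 30 environments sits in the intended
recovery regime; G×E remainder sd 0.25 MT/ha; plot noise sd 0.7 MT/ha
(≈ 8% CV, a realistic combine-yield replicate error); block effect sd
= plot sd / 2 unless set explicitly. Genotype intercepts and slopes are
correlated (default 0.5) with a release-year covariate built from a
simulated inbred parent pool (years uniform on 1934–2000; each hybrid's
mean parent release year is the average of its two parents), and half
of the non-era slope variance is parental-additive (GCA), so combining-
ability recovery is testable. Intercepts, slope deviations and
environment effects are exactly centered (and e exactly scaled), so the
noiseless limits recover generating values to machine precision rather
than up to sampling error. Presence is thinned per hybrid ×
environment (default 90%) with at least four environments always
retained; yields are floored at 0.1 MT/ha (real combine yields are
bounded away from zero). A single seeded RNG drives everything; equal
configs and seeds give byte-identical data.

`simulate_nitrogen_study` replaces the constant slope with
b_il = 1 + σ_slope(√f·u_i + √(1−f)·w_il) per location-year l: the
`repeatable_fraction` f interpolates between perfectly repeatable
(f = 1) and independent (f = 0) nitrogen responses, with u and w
exactly centered so each location-year's population slope is 1.
Presence is thinned wholesale per (hybrid, location-year).

What the generator does *not* emulate: spatial field trend (inputs are
assumed spatially corrected or raw-with-noise), weather-driven
environment structure, non-Gaussian trait distributions, correlated
multi-trait architecture, and heteroscedastic plot error across
environments. Passing tests therefore demonstrate estimator
correctness under the stated additive Gaussian reaction-norm model, not
robustness to field-spatial artifacts.

## Numerical choices and degenerate inputs

- Tie tolerance for rank comparisons and mean crossovers: 1e-9 trait
  units (ties are never crossovers).
- REML: log-variance parameterization bounded at 1e-8 × trait variance;
  components below 1e-6 of the total are reported as exactly 0.
- FW: per-hybrid fits require ≥ 2 environments and a non-constant
  index restricted to that hybrid.
- Spearman correlations: undefined (NaN / reported missing) below 3
  common hybrids.
- Zero residual df in a per-environment ANOVA is an error, not a
  silent skip.
- Pipeline stages fail loudly with the stage name; the split-block
  repeatability stage alone degrades to an undefined ρ when the design
  cannot be split, so minimal datasets still produce a bundle.

## Problem sizes used in the test suite

Simulation-backed checks run at 100 hybrids × 30 environments × 2
blocks for slope and variance-component recovery (single fits), 117
hybrids × 50 parents for GCA recovery with 20 pedigree permutations,
and 50 replicate simulations per repeatable-fraction level (40 hybrids,
3 location-years × 3 nitrogen levels) for the nitrogen-repeatability
monotonicity sweep. These sizes give Monte-Carlo error comfortably
inside the asserted tolerances while keeping the whole suite fast.

## Known limitations

- The FW estimator is the unshrunken classical fit; hierarchical or
  spatial FW variants will give modestly different slopes on noisy,
  unbalanced data.
- The GCA model ignores specific combining ability; with few hybrids
  per parent the parental proportions have large sampling variance
  (visible in the permutation-null spread).
- Variance-component standard errors are not reported.
- The interaction-importance procedure inherits Tukey HSD's
  equal-variance assumption within environments.
- `remove_extreme_values` needs user-supplied thresholds; it does not
  derive them.
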