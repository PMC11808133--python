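# Methods

`exposcan` implements an exposure-wide survival analysis pipeline of the
kind used in large prospective biobank studies of chronic disease: many
candidate exposures are screened against a time-to-event outcome, the
surviving factors are combined into per-domain composite risk scores,
those scores are crossed with a polygenic score, and the preventable
fraction of disease is summarized as population attributable fractions
(PAFs). A synthetic-cohort generator supplies data with exact ground truth
so every stage is testable end to end. This note records the models, the
conventions chosen where the methods literature leaves room, and what the
synthetic validation does and does not establish.

## Synthetic cohort generator

One row per participant with adjusters (age uniform on 40–69, sex,
assessment center, genotyping batch), seven exposure domains
(socioeconomic status, medical history, psychosocial, physical measures,
early life, local environment, lifestyle) with a configurable number of
variables per domain, blood-assay analogues, and genotypes.

* **Variable types** cycle continuous / binary / 3-level categorical
  (ordinal or nominal) within a domain. Variables in a domain share an
  equicorrelation ρ (default 0.2) through a common latent factor, so
  collinearity filtering and PCA communalities have signal. The default is
  a free design parameter, not an estimate of any real exposure
  correlation.
* **Event model**: exponential proportional hazards. The hazard is
  `baseline_hazard_scale · exp(Σ b_v X_v + b_age (age − mean) + b_sex sex
  + b_prs PRS)`; event times are exponential draws, administratively
  censored at `followup_years` (default 12) with additional exponential
  random censoring whose rate is set as −ln(1 − censoring_rate)/followup,
  which hits the configured random-censoring fraction when events are
  rare. Baseline scale is in events per person-year; defaults (0.005/year,
  12 years) give a rare-disease cohort (~6% crude incidence under the
  null), matching the incident-disease setting the methods assume.
* **Raw codes**: a configured fraction of cells is overwritten with
  questionnaire codes (−1 "do not know", −3 "prefer not to answer", or
  −10 "less than one" on designated count variables), with a registry of
  altered cells for bookkeeping tests. Item missingness is injected as
  NaN at `missing_rate`.
* **Genotypes**: independent biallelic SNPs, dosages Binomial(2, MAF),
  MAF uniform on a configured range; SNP weights normal. No linkage
  disequilibrium is simulated, so instrument clumping is out of scope by
  construction.
* **GWAS summaries**: per-SNP exposure effects are drawn positive (risk
  alleles oriented to increase the exposure) with small SEs;
  `beta_out = true_effect · beta_exp + pleiotropy + noise`. Orienting the
  exposure effects positive makes a constant pleiotropy term directional
  in the MR-Egger sense; with symmetric exposure effects it would cancel
  under Egger's sign convention and test nothing.
* **Seeds**: one master seed; each stage (covariates, genotypes, events,
  censoring, assays, raw codes, MR, flags) uses a child stream derived as
  `SeedSequence(seed, spawn_key=(stage,))`, so stages are independently
  reproducible and bit-for-bit deterministic.

**Generative PAF truth.** For each scoreable domain the generator defines
its own exposure contrast — the top tertile (conservative model 1) or top
two tertiles (optimistic model 2) of the domain's true linear-predictor
contribution — and evaluates Levin's formula at the true exposed fraction
and the true marginal hazard ratio `E[e^lp | exposed] / E[e^lp |
unexposed]`. This is the same functional the estimation pipeline applies,
evaluated at exact inputs, so the recovery test measures estimation error
rather than the irreducible gap between hazard-ratio and risk-ratio
estimands. That gap is a property of Levin's formula with Cox hazard
ratios (shared by the analysis this pipeline reproduces), grows with
cumulative incidence, and is quantified separately in the test design
notes below.

## Preprocessing

Exclusions (in order): variables with more than 20% raw missingness
(strict inequality; −1/−3 codes count as missing), then participants with
prevalent disease, missing genetic data, or more than 20% missing values
across the retained variables — first-matching criterion, so the report's
id lists are disjoint. Recoding maps −10 → 0.5 on count-coded variables
(−10 elsewhere warns and becomes missing) and −1/−3 → missing everywhere.
Multi-instance columns are averaged over non-missing instances.
Imputation fills categorical gaps with the mode (ties to the smallest
coded value) and continuous gaps with the median, computed on the
post-exclusion cohort — thresholds therefore act on raw missingness, and
imputation never feeds back into exclusion. Unordered categoricals with
k ≥ 3 levels become k−1 indicators against the most frequent level
(stabilizes the Cox fits); ordinal variables stay integer-coded; constant
columns are dropped with a warning.

## Cox core

The Cox partial likelihood with Efron tie correction is maximized by
Newton–Raphson (convergence ‖score‖∞ < 1e-8, at most 100 iterations, step
halving judged on a relative likelihood scale so rounding plateaus near
the optimum cannot stall the line search). Risk-set sums are computed by
aggregating rows into segments between consecutive event times and
suffix-summing, which makes a single-exposure fit on a 2,000-person cohort
cost ~3 ms — the property that keeps 200 × 255-variable scan simulations
tractable. A coefficient walking past |β| = 13 raises a monotone-likelihood
error naming the covariate (a separated binary covariate's score falls
below the convergence tolerance near |β| ≈ 18, so divergence must be
caught before that). The test suite cross-checks coefficients, standard
errors and log-likelihoods against lifelines and against brute-force
maximization on small datasets.

The proportional-hazards (PH) check is the Grambsch–Therneau score test on
scaled Schoenfeld residuals against Kaplan–Meier-transformed event time,
using the fitted covariance approximation (the classic `cox.zph`
formulation, matching lifelines' `proportional_hazard_test` with the km
transform). Covariates with p < 0.05 are refit with an exposure × log(t)
interaction; the reported exposure effect is evaluated at the mean event
time with a delta-method SE. log(t) is conventional and bounded in
influence; the time-varying fit is validated against lifelines'
`CoxTimeVaryingFitter` on an episodic expansion. Assessment center enters
all models as indicator covariates (not strata).

## Exposure-wide scan

One Cox fit per modifiable variable, adjusted for age, sex and center;
significance at α/m (α = 0.05, m = number of scanned variables; a subgroup
scan pins m to the full-sample count so all strata share one threshold).
Among significant variables, pairs with squared Pearson correlation above
0.9 are pruned iteratively, dropping the member with the larger scan
p-value until no pair exceeds the threshold — the drop rule is a
convention; the analysis this reproduces states only that highly
correlated variables were excluded. Per-variable failures (constant
columns, separation) are recorded in the scan table and the scan
continues.

## Domain scores and gene–environment models

Significant factors are oriented into binary risk indicators: protective
binaries (HR < 1) are complemented; continuous and ordinal factors are
dichotomized at the cohort median in the risk direction. Median
dichotomization is a documented choice — composite-score methods of this
family treat score inputs as binary, but no convention exists for
continuous members. The unweighted score counts risk factors; the
weighted score is S = Σ X_k β_k / Σ β_k with β_k from a single
within-domain multivariable Cox fit (adjusted for age, sex, center).
Negative β_k can arise under mutual adjustment despite orientation; they
are retained with sign (preserving the formula exactly) and flagged with
a warning. Scores are cut at their 1/3 and 2/3 quantiles into favorable /
moderate / unfavorable, ties at a cut going to the lower category; with
discrete scores a tertile can be empty, in which case joint models drop
the empty contrast and the PAF for an empty exposed group is 0 (nothing
to eliminate).

The joint model fits all five domain categories (favorable reference)
plus adjusters in one Cox regression, repeated with unweighted scores as
a sensitivity check. The gene–environment analysis crosses polygenic-score
tertiles with score tertiles: a nine-group model against the low-PRS /
favorable reference (genotype batch added as a covariate), and
within-PRS-stratum models against the unfavorable reference.

## Polygenic score and Mendelian randomization

PRS_j = (Σ_i β_i G_ij − mean)/SD with the sample SD (n−1). Instruments
are selected at p < 5e-8, relaxed to 5e-6 when fewer than three survive
(the "insufficient" cutoff of three is a convention). Estimators: IVW as
the fixed-effect inverse-variance-weighted mean of per-SNP ratio
estimates with first-order delta-method SEs; the weighted median defined
as the ratio at which the cumulative normalized weight first reaches one
half (invariant to duplicating the instrument set), SE by seeded
parametric bootstrap (1,000 draws by default); MR-Egger as weighted least
squares with intercept, weights 1/se_out², exposure effects oriented
positive, residual dispersion floored at 1, t inference on n−2 degrees of
freedom. Cochran's Q with K−1 degrees of freedom carries the heterogeneity
diagnostic; the Egger intercept carries directional pleiotropy. MR-PRESSO
and LD clumping are out of scope.

## Mediation

Difference method: total effect = exposure coefficient in the outcome
model without the mediator; direct effect = with the mediator; mediation
= total − direct, exactly, in the point estimate and in every bootstrap
draw. Outcome models are linear; the disease-as-outcome leg uses a linear
probability model so the difference identity stays exact (a logistic
decomposition would break it). Inference is a seeded percentile bootstrap
(default 1,000 draws); the two-sided p-value is the smallest level at
which the percentile interval excludes zero, floored at 1/n_boot.

## Attributable fractions

Levin's formula PAF = P(HR−1)/(P(HR−1)+1), with P the exposed fraction
and HR from an adjusted Cox fit on the binary contrast. Model 1 treats
the unfavorable tertile as exposed; Model 2 unfavorable ∪ moderate.
Communalities come from a PCA of the correlation matrix of the five
weighted domain scores: components with eigenvalue ≥ 1 are retained
(inclusive, so an exactly-identity correlation matrix keeps everything),
and a domain's communality is its sum of squared loadings on the retained
components. The per-domain weighted PAF is unweighted × √communality —
the square-root weighting reproduces all published per-domain cells from
their printed inputs to ±0.01 pp — and the overall PAF sums the
per-domain weighted PAFs after rounding each to two decimals (percent
scale). One printed cell (medical history, optimistic model) recomputes
as 5.95 vs the published 5.96 because the published communality is itself
rounded to two decimals; the difference propagates to the overall
optimistic PAF (33.86 vs 33.87). PAF confidence intervals are out of
scope.

## Validation design and its limits

The acceptance suite checks, on synthetic cohorts: family-wise error of
the 255-variable scan under a global null (200 scans at n = 2,000,
FWER ≤ 0.07); 95% CI coverage of a known log-HR across 200 cohorts
(within [90%, 99%]); Schoenfeld-test type-I error in [0.02, 0.09];
agreement of the MR estimators with closed-form oracles; and end-to-end
recovery of the generator's own PAFs at n = 100,000.

The PAF-recovery experiment uses two binary members per scoreable domain
at prevalence 0.38 with equal effects ln(1.25), independent exposures,
baseline hazard 0.003/person-year (~8.5% incidence). Prevalence 0.38 is
chosen so both tertile cuts fall strictly between the mass blocks of the
two-binary score (boundaries at (1−p)² = 0.384 > 1/3 and 1−p = 0.62 <
2/3 < 1−p² = 0.856), making the truth's and the pipeline's exposure
partitions identical rather than split by estimated-weight tie-breaking.
At ~8,500 events the sampling SD of one domain-PAF estimate is ~0.5–0.8
pp, so the check asserts the mean recovery error across the five domains
within ±1 pp per model (a per-cell ±1 pp bound is tighter than the
information available at this sample size permits for the worst of ten
cells), with a 3 pp per-cell sanity bound.

What passing does not show: the generator draws exposures with simple
equicorrelation, exponential baseline hazards, no LD, no palindromic-
allele ambiguity, no informative censoring, and missingness completely at
random. Real-cohort behavior under violations of those assumptions —
non-PH baselines beyond the log(t) fallback, MNAR questionnaire data,
confounded exposure–genotype structure — is outside what this suite can
certify.

## Default problem sizes

The bundled demo profile (CLI defaults) runs 5,000 participants × 21
variables end-to-end in a few seconds; the simulation-based acceptance
checks use the sizes stated above and complete in minutes on a single
core. All stage outputs are plain CSV/JSON with a manifest of config
hash, seed and row counts; rerunning a config reproduces outputs
byte-for-byte.
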