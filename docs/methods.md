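# Methods

## Scientific setting

White matter hyperintensities (WMH) are FLAIR-bright lesions of cerebral
white matter and a core imaging marker of small-vessel disease. Their burden
rises with age and with blood pressure (BP), but a single clinic BP reading
is a noisy proxy for the long-term ("usual") BP that plausibly drives
vascular injury, so naive regressions of WMH on one visit's BP are
attenuated by **regression dilution bias**. This package implements, as a
tested pipeline, a cohort analysis of that problem: harmonizing BP from
heterogeneous sources across two visits ~9 years apart, modelling
logit-transformed WMH load on concurrent and past BP, estimating the
population burden of severe WMH attributable to elevated BP, and correcting
the dose–response slope for regression dilution with a stratified usual-BP
design. Because the motivating cohort (the UK Biobank imaging subsample) is
access-restricted, every analysis runs against a synthetic cohort generator
whose defaults are calibrated to that cohort's published summary statistics
(`bpwmh.reference`), giving each estimator a known ground truth.

## Outcome definition

The primary outcome is **WMH load** = WMH volume / total white-matter
volume, a proportion in (0, 1); a sensitivity variant divides by total brain
volume (grey + white + CSF). The load is logit-transformed
(`wmh_logit = log(p/(1−p))`) to normalize and variance-stabilize the heavily
right-skewed distribution. Loads of exactly 0 or 1 raise an error rather
than being clamped: the generator guarantees interior values and the
published cohort minimum (1.8e-5) is interior, so a boundary value signals
an upstream fault. On loads this small, logit ≈ log, so differences on the
model scale exponentiate to multiplicative load ratios.

## BP harmonization

Each visit carries up to two readings from one of three sources, used in
the fixed preference order automated > manual > pulse-wave analysis (PWA);
readings are averaged within a visit. A visit with a single available
reading uses it as-is (the alternative — discarding the visit — loses data
for no bias advantage); such visits are counted in the ingest audit. A
`--exclude-pwa` switch supports the sensitivity analysis without PWA-based
BP. BP bands and age groups use **left-closed** intervals throughout
(DBP <70, 70–80, 80–90, ≥90; SBP <120, 120–130, 130–140, ≥140 mmHg; ages
<50/50–60/≥60 at baseline, <60/60–70/≥70 at follow-up), so a boundary value
belongs to the upper band; band edges are tested at ±1 ulp.

Eligibility filters run in a fixed, audited order: missing WMH volume →
exclusion diagnosis flag → missing follow-up BP → missing baseline BP. The
first three define the cross-sectional sample; the last only demotes a
participant from the longitudinal to the cross-sectional set. The audit
JSON makes the accounting explicit (published exclusion flows of this kind
do not always reconcile arithmetically, which is why the order is fixed and
reported rather than assumed). The follow-up interval is exact days between
visit dates / 365.25.

## Association models

Ordinary least squares of `wmh_logit` on BP with three adjustment tiers:

* **unadjusted** — each exposure alone;
* **age & sex adjusted**;
* **fully adjusted** — SBP and DBP jointly, plus age, sex, arterial
  stiffness index (ASI), smoking (two indicators: ex, active; never =
  reference), diabetes, BP source, assessment centre, and — in past-BP
  (longitudinal) models — the inter-visit interval.

Concurrent models use follow-up covariate values; past models baseline
values. **Standardized coefficients** z-score the outcome and the continuous
predictors on the fitted (complete-case) sample; binary and categorical
indicators stay on their natural scale, so e.g. the female-sex coefficient
is in outcome-SD units per level. (Whether the source analysis z-scored
binary covariates is not stated; this convention is fixed here because
z-scoring indicators changes sign conventions for table rows like "female
sex".) Categorical terms (centre, BP source) take the most frequent level
as reference — the choice affects only intercepts. Confidence intervals are
normal-theory t intervals; the bootstrap is reserved for the usual-BP
analysis. Per-unit effects are reported as multiplicative load ratios
exp(β·10) per 10 mmHg SBP and exp(β·5) per 5 mmHg DBP from the
unstandardized model, with CI endpoints transformed identically.

Stratified fits (baseline or follow-up age group to match timing, sex, and
a median split of follow-up duration) remove the stratifying variable from
the adjustment set and are otherwise independent refits; strata too small
to fit are skipped and reported. Sex interactions add an exposure × female
product term to the fully adjusted model.

## Population attributable fraction

Severe WMH is defined as a load strictly above the sample's 90th percentile
(linear-interpolation quantile, computed within each analysis sample), and
exposure as SBP > 120 mmHg or DBP > 70 mmHg (strict thresholds, tested at
the boundary). No closed-form "adjusted PAF" is standard, so the estimator
here is **logistic g-computation** (model-based standardization): fit a
logistic model of the top-decile flag on the exposure indicator plus the
full adjustment set (including the other BP measure as a continuous
covariate), then

PAF = (p̄_obs − p̄_cf) / p̄_obs,

where p̄_cf averages predicted risk with everyone set to unexposed. With an
empty adjustment set the model is saturated and this reduces algebraically
to Levin's formula p_e(RR−1)/(1+p_e(RR−1)), which the tests verify to
1e-10. A population with no exposed (or no unexposed) members raises an
error — the fraction is undefined rather than zero, since no exposure
contrast exists to standardize over. No PAF confidence intervals are
produced.

## Usual-BP analysis (regression dilution correction)

Participants in the longitudinal sample are stratified by baseline age
group × baseline BP band (SBP and DBP separately, as in the two panels of
the corresponding dose–response figure). Each stratum's **usual BP** is its
members' mean *follow-up* BP: because the follow-up measurement error is
independent of the baseline-defined grouping, this is an unbiased estimate
of the stratum's long-term BP, whereas the stratum's own baseline mean is
biased outward (regression to the mean). Each stratum's median WMH load is
expressed as a ratio to the reference stratum — the lowest band (<120 SBP
or <70 DBP) within the youngest (<50) age group — and the log-ratio is
regressed on usual BP, unweighted (an n-weighted variant sits behind a
flag, off by default). The overall fit pools all age-group strata in one
regression (rather than refitting on collapsed strata); per-age-group fits
use that group's four band strata. Medicated participants are included by
default, with an exclusion flag for sensitivity. Strata need ≥ 20 members
(configurable); an empty or undersized reference stratum is an error, since
every ratio is defined against it.

Confidence intervals are **non-parametric percentile bootstrap** (default
1000 replicates, seeded): participants are resampled with replacement and
the entire pipeline — strata, medians, reference, regression — is
recomputed per replicate; replicates whose reference stratum collapses are
redrawn and counted, and a >10% failure rate aborts the analysis as too
fragile to bootstrap. BCa was not used: the percentile interval is the
simplest estimator consistent with a plain non-parametric bootstrap, and
the coverage simulation below supports it.

## Treatment categories

Hypertension severity is the *worse* of the SBP and DBP bands (the "or"
rule: SBP <120 **and** DBP <70 = low-range normotensive; SBP 120–130 **or**
DBP 70–80 = high-range normotensive; 130–140 / 80–90 = pre-hypertensive;
≥140 / ≥90 = hypertensive — each read as "or well/very-well/controlled/
uncontrolled hypertensive" for medicated participants), crossed with the
antihypertensive flag. Mixed-band ties resolve to the maximum severity.
Every category is contrasted against unmedicated low-range normotensives in
a pooled linear model adjusted for decade of age (floor(age/10), numeric),
sex, ASI, smoking, diabetes, centre, and (for baseline BP) the inter-visit
interval; per-age-group medians and quantiles of logit load are emitted
separately as plotting data and are invariant to the model.

## Synthetic cohort generator

The generator emulates the two-visit imaging subcohort at the participant
level. Per participant: age ~ U(40, 70) at baseline; a follow-up interval
~ N(9.0, 1.6²) years truncated to [4, 13.5] (published median 9.07, range
4.28–13.49); sex, smoking, diabetes, ASI and centre with published-summary
prevalences. Latent ("usual") BP is bivariate normal (SBP SD 16, DBP SD 9,
correlation 0.7) around a mean linear in current age — the SBP slope
0.39 mmHg/yr reproduces the published baseline→follow-up mean change over
8.8 years, while the DBP change (−3.72 mmHg) is modelled as a within-person
follow-up shift because midlife cross-sectional DBP is approximately flat
in age. Follow-up latent BP correlates with baseline at the tracking
parameter (default 0.80); each visit's two readings add independent
N(0, 8²) mmHg noise. Neither the tracking correlation nor the
within-person SD has a published value for this cohort; both are
assumptions, chosen as typical of repeated clinic sphygmomanometry, and
are the knobs the regression-dilution tests turn.

WMH arises on the logit scale:
logit(load) = α + β_S·SBP_lat,fu + β_D·DBP_lat,fu + covariate effects
+ N(0, 1.2²), with default conditional effects β_S = ln(1.041)/10 and
β_D = ln(1.031)/5 per mmHg (the published fully adjusted per-unit ratios)
and α anchored so the cohort median load is 0.0052. Covariate effects
(age 0.10/yr, female 0.12, diabetes 0.45, active smoking 0.33, ex-smoking
0.11, ASI 0.01, interval 0.10 logit units) are back-calculated from the
published standardized coefficients at the cohort's dispersions. An
optional sex-specific SBP slope supports interaction-recovery experiments.

Antihypertensive medication is assigned by a logistic propensity in latent
baseline SBP (≈15% at baseline, ≈28% by follow-up) and lowers *measured*
BP by 10/5 mmHg (SBP/DBP) while WMH continues to track the untreated
latent exposure — the confounding-by-indication mechanism that makes
medicated participants carry more WMH at equal measured BP. Missingness is
injected field-wise at configured rates (defaults matching the published
attrition: 6.9% missing WMH, 2.1% missing follow-up BP, 0.05% missing
baseline BP, 1.3% exclusion diagnoses). All draws flow through named
sub-streams of one seed, so adding a generation stage never perturbs
earlier stages and cohorts are byte-reproducible.

What the generator does **not** emulate: skewed/heavy-tailed BP
distributions (latents are Gaussian), medication initiation dynamics beyond
two static flags, drug classes, ICD-10 coding, voxel-level imaging, age
acceleration of WMH variance, or informative missingness (all fields blank
at random). Passing tests therefore demonstrate estimator correctness
under a faithful but idealized data-generating law, not agreement with the
restricted real data; in particular the attributable-fraction asymmetry
between SBP and DBP is reproduced only as an ordering, not in magnitude.

## Verification design

* Exact oracles: OLS against a pseudo-inverse normal-equations computation
  (1e-8); unadjusted g-computation against Levin's formula and brute-force
  counterfactual enumeration (1e-10); noiseless log-linear strata against
  the closed-form slope (1e-10).
* Invariances: band partition at ±1 ulp around every threshold; logit
  antisymmetry/monotonicity (property-based); shift/scale invariance of the
  usual-BP slope; PAF invariance to row duplication.
* Monte-Carlo calibration, at stated sizes chosen as the package's own
  verification conditions: usual-BP recovery of a known slope
  (ln(1.126)/10 per mmHg) within the bootstrap CI in ≥93/100 cohorts of
  n = 20 000; empirical CI coverage 95% ± 4% over 200 cohorts of n = 5 000
  with 200 replicates; full-model coefficient bias over 50 replicates of
  n = 20 000 with measurement noise off.
* Directional phenomena: observed BP tracking correlation below the latent
  parameter; naive baseline-BP slope attenuated versus the usual-BP slope
  with visit noise on, exactly equal with it off.

Recovery and coverage experiments switch off the nuisance mechanisms
(covariate effects, DBP effect, age trends, treatment reductions) so the
marginal estimand equals the configured slope; the qualitative-pattern
tests use the full calibrated defaults.

## Numerical and degenerate-input conventions

Standardization uses sample SD (ddof = 1) and errors on zero variance.
Rank-deficient designs raise with the offending columns named. Quantiles
use linear interpolation; the top-decile flag is strict, so fully tied
loads flag nothing. Bootstrap seeds, generator seeds and pipeline stage
seeds are all derived deterministically from one user seed (kept below
2³¹). Categorical reference levels break frequency ties alphabetically.

## Known limitations

The adjusted-PAF estimator is one defensible choice among several
(doubly-robust or matching estimators would differ); it is isolated behind
`estimate_paf` and swappable. The usual-BP median-ratio regression treats
stratum medians as exact in the point fit — only the bootstrap propagates
their sampling error. Single-visit medication flags cannot separate
treatment effects from indication. The generator's Gaussian latent BP
understates the prevalence of extreme hypertension, which in turn damps
attributable-fraction magnitudes relative to a heavy-tailed reality.
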