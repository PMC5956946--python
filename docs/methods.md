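# Methods

This note records the models, estimators, numerical choices and known
limitations behind `metsrisk`, in the spirit of a statistical software
methods appendix.

## Synthetic cohort generator

The generator emulates the baseline structure of a large middle-aged
biracial US cohort observed at five study sites (four ARIC-style, one
JHS-style).  It is the package's study-condition definition: its defaults
are fixed calibration constants, not tuning knobs.

**Subgroups and components.**  Participants are drawn from four
sex-by-race subgroups (default mix 29.7 / 35.9 / 13.4 / 21.0 % for white
men / white women / black men / black women).  Within a subgroup, a latent
metabolic factor `f ~ N(0,1)` drives the five MetS components:

    z_k = λ_k f + ν_k ε_k,   ε_k ~ N(0,1),  ν_k = √(1 − λ_k²) by default,

mapped to natural units by the subgroup's mean and SD (defaults around
waist 96 cm (14), SBP 120 mmHg (17), HDL 53 mg/dL (17), triglycerides
119 mg/dL (74), glucose 97 mg/dL (10), age 53 y (7), with subgroup-specific
values).  Default loadings are λ = (0.72, 0.55, −0.50, 0.45, 0.50) for
(waist, trig, HDL, SBP, glucose).  Triglycerides and insulin are simulated
log-normally (moment-matched on the arithmetic scale, with the latent
structure applied on the log scale); the other components are normal with
physiologic floors (glucose ≥ 40, SBP ≥ 70, waist ≥ 50, HDL ≥ 10).  BMI is
generated from waist plus noise; total cholesterol, smoking (25 %), BP
treatment (25 %) and family history of diabetes (33 %) are independent.

**CHD outcome.**  Time to incident CHD is Weibull proportional hazards,
`S(t|x) = exp(−(t/σ)^k · e^lp)` with shape k = 1.4, scale σ = 45 y and

    lp = 0.867·z_conv + 0.14·f + 0·z_conv·f,

where `z_conv` is a standardised conventional-risk driver (fixed blend of
age, smoking, total and HDL cholesterol, SBP, treatment; standardisation
constants frozen from one large reference draw).  Follow-up is the minimum
of the event, other-cause death (exponential, 0.008/y), drop-out
(exponential, 0.0223/y ⇒ ≈20 % lost before 10 y) and a 20-year
administrative horizon; the event indicator is true only when the event is
the minimum.  σ was calibrated once so the default analytic sample shows
≈13 % observed 10-year CHD incidence, the headline condition the package
emulates; the score coefficient is log 2.38 per SD, a typical
conventional-score effect size in this literature.

**T2DM outcome.**  A 10-year diabetic status is drawn from
`P(D=1) = expit(−2.73 + 1.25·f + 0.50·z_dm)` (z_dm: age/BMI/family-history
driver; intercept calibrated once to ≈12 % incidence in the analytic
sample; 1.25 ≈ log 3.5 per SD of metabolic burden).  The status is then
*realised as visits*: follow-up visits at 3/6/9 y (ARIC protocol) or
4.5/9 y (JHS), a uniformly chosen onset visit, and post-onset labs that
satisfy the diagnostic rules (fasting glucose ≥ 126, non-fasting ≥ 200,
HbA1c ≥ 6.5, medication/self-report with fixed probabilities); pre-onset
and non-diabetic trajectories drift upward with metabolic burden but stay
below every threshold.  Detection through `t2dm_status` therefore equals
the generative status exactly — visit-interval detection is the outcome
definition, not an approximation of a latent event time.

**Exclusions.**  Baseline flags (other race 0.24 %, prevalent T2DM 12.8 %,
CHD 5.0 %, stroke 2.0 %, missing components 4.1 %, non-fasting 2.6 %, no
follow-up 15.4 %) mirror the proportions such studies report; prevalent
T2DM is also triggered by a baseline fasting glucose ≥ 126.  Filters are
applied in a fixed order and each removed participant is tallied at the
first filter that caught them.

**Randomness.**  One global seed fans out to per-participant substreams
(`SeedSequence(entropy=seed, spawn_key=(pid,))`), so a participant's record
is invariant to cohort size and generation order; identical seed + config
gives byte-identical CSV output.

**What the generator does not emulate.**  Joint distributions beyond first
and second moments plus the single-factor structure; competing-risk
mortality for T2DM; visit attendance correlated with CHD follow-up;
measurement error or assay drift.  Passing tests therefore demonstrate
correctness of the *procedure* under a faithful null/alternative structure,
not agreement with any restricted dataset's numbers.

## MetS severity score

One-factor maximum-likelihood factor analysis (EM, `lapack` SVD, tol 1e-4)
on the transformed, reference-standardised components, per subgroup, with
≥ 200 complete participants required.  Signs are normalised so glucose
loads positively; the fit is flagged *degenerate* when the second-largest
|loading| is below 0.15, because a "factor" loading on a single variable
is indistinguishable from that variable's unique variance.  The score is
the loading-weighted sum of z-scores, affinely rescaled so the reference
sample has mean 0, SD 1 (a participant at the reference means scores
exactly 0).  Published scoring equations can be supplied as YAML and are
used verbatim; provenance (`cfa-fit`, `cfa-fit-pooled`, or file) is
recorded.  In small pipelines where a subgroup cannot support its own fit,
a pooled equation is used for all subgroups and noted in the manifest.
Transformations: log for triglycerides, identity otherwise (the tag is
config-visible per component).

## Comparator risk scores

Risk equations are declarative YAML specs, never hard-coded: a term list
(covariate, identity/log transform, coefficient, optional sex or subgroup
stratum) plus family-specific constants — 10-year survival equations
return `1 − S₀^exp(lp − lp̄)`, logistic equations a probability, ordinal
specs integer points from threshold bins.  The bundled files carry
*synthetic placeholder coefficients* with realistic functional forms (the
diabetes logistic spec includes fasting glucose, which is why it
discriminates strongly); users substitute published values for real use.
Scores are Z-standardised in the analytic sample for HR/OR display
(skipped for the ordinal score); prediction statistics always use the
original scale.

## Model fitting

**Cox.**  In-repo Newton–Raphson on the partial likelihood with Efron tie
handling by default (day-resolution data are heavily tied) and Breslow by
flag.  Covariates are centered for conditioning (coefficients unchanged);
convergence requires the gradient max-norm below 1e-8 *per event* (the
gradient is a sum over events) or a Newton decrement below the float noise
of the log-likelihood (1e-13·|logL|); step-halving guards overshoot.
Rank-deficient designs, diverging coefficients (|β| > 50) and non-finite
likelihoods raise explicit errors rather than returning silently.
Model-based covariance is the inverse observed information; CIs are Wald.
Ten-year risks use the Breslow baseline cumulative hazard:
`risk = 1 − exp(−H₀(τ)·e^lp)` as a step function (no interpolation between
event times).  The implementation is validated against lifelines
(coefficients, SEs, baseline) and against a brute-force risk-set
enumeration of the Efron/Breslow likelihoods at small n.

**Logistic.**  Delegated to statsmodels (`Logit`, IRLS/Newton); separation
warnings are surfaced as flags, non-convergence raises.

**Nested ladder.**  Models A–D share one analytic sample and site
indicator columns (first site as reference).  The interaction in Model D
is the continuous score×MetS product by default; a quintile-index form is
available and labelled, since a quintile-based interaction is what the
per-quintile figure uses.  Display fits re-parametrise the score per SD;
log-likelihood and AIC are invariant to that affine change (tested).

## Performance statistics

* **Binary c**: midrank formulation (exactly the ties-½ pair count);
  DeLong structural-components variance.
* **Survival c**: usable pairs require the earlier subject to be an event
  within the horizon and strictly earlier; counting is O(n log n) via a
  Fenwick tree over risk ranks, identical to exhaustive enumeration;
  CIs by seeded percentile bootstrap (default B = 200).
* **IDI**: difference of discrimination slopes; SE by the two-sample
  variance of the per-subject risk differences.
* **Continuous NRI**: strict-inequality up/down with exact ties counted in
  neither direction; asymptotic multinomial variances.  The overall NRI is
  the literal sum of the two components, so the decomposition identity is
  exact by construction.
* **Survival IDI/NRI at τ**: each subject gets a KM-based event weight —
  1 if an event by τ, 0 if followed past τ, else the conditional
  probability `1 − S(τ)/S(c)` with S fitted *within the subject's
  reclassification group* for the NRI and on the full sample for the
  slopes.  With no censoring before τ all weights are 0/1 and the binary
  statistics are recovered exactly.  A complete-case fallback (drop
  censored-before-τ) exists for comparison; a constructed scenario in the
  tests shows its bias when censoring concentrates in one reclassification
  group, with the direction derived in closed form.
* **VIF**: 1/(1 − R²) from regressing each covariate on the rest
  (intercept included); rank deficiency reports ∞ and is flagged severe
  (> 10).

A caveat the tests quantify: all statistics are *apparent* (computed on
the sample the models were fitted to, as in the source analyses), so an
uninformative refitted marker shows O(1/n) optimism — at n = 2000, mean
IDI ≈ 0.0005 and mean continuous NRI ≈ 0.05 across replicates, both within
one replicate SD of 0 and with 95 % CIs covering 0 in > 90 % of runs.

## Quintile interaction analysis

Quintile cuts are the empirical 20/40/60/80 percentiles; values exactly on
a boundary fall to the lower quintile; duplicated boundaries (coarse
ordinal scores) flag the analysis as degenerate instead of estimating.
The per-quintile MetS effect comes from a single site-adjusted model with
quintile main effects and five MetS-by-quintile slopes; quintiles without
events are flagged.  Collapsing the five slopes to one linear-in-index
slope is a nested restriction, so the saturated model never fits worse — a
property the tests assert.  Plots draw HR/OR per SD on a log scale with
Wald whiskers; a sidecar TSV always carries the plotted numbers.

## Problem sizes and tolerances

Unit and acceptance tests run on cohorts of 2,000–20,000 participants:
oracle-equality checks at n ≤ 500 (tolerance 1e-10), null calibration on
200 cohorts of n = 2,000, parameter recovery on 100 replicates of
n = 5,000 (95 % CI coverage ≥ 93/100) and CFA recovery at n = 10,000
(±0.05), detection of a genuine metabolic effect on 100 replicates of
n = 5,000 (≥ 95 positive IDI/event-NRI/Δc).  The acceptance script runs
the full default cohort (19,467 raw → ≈12,400 analytic) with B = 100
bootstrap replicates.  These sizes were chosen to give the Monte-Carlo
checks comfortable resolution while the whole suite stays desk-scale.

## Known limitations

No proportional-hazards diagnostics, frailty or time-varying covariates;
no categorical NRI or calibration metrics (Hosmer–Lemeshow, calibration
slope); no IPCW time-dependent AUC; no competing-risk treatment of death
in the T2DM outcome; bundled risk-equation coefficients are synthetic
placeholders, so absolute risk levels from the bundled specs are
illustrative only.
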