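# Methods

## Model and estimation

The seasonal model is a single-harmonic cosinor: 25OHD concentrations
(nmol/l) are regressed by ordinary least squares onto `sin(2πm/12)` and
`cos(2πm/12)` of the calendar month `m ∈ {1,…,12}` of blood draw, with
the period fixed at 12 months. Time is the integer calendar month;
day-of-month is not modelled and no mid-month offset is applied (the
offset would only rotate the phase estimate by a constant, and the
month-resolution convention keeps fitted values directly comparable to
monthly summaries). Covariates enter as level shifts, which move the
curve up or down without changing its shape; covariate-by-sine and
covariate-by-cosine interactions let the amplitude and phase differ by
group. The coefficient covariance is the classical homoskedastic
`σ̂²(XᵀX)⁻¹`; no robust alternative is offered.

From coefficients `(β_s, β_c)` — plus the active interaction terms at a
covariate setting — the amplitude is `A = √(s² + c²)`, the peak-trough
seasonal variation is `2A`, and the peak month is `atan2(s, c)·12/2π`
reduced to `[0, 12)` with month 1 ≡ January; the trough is 6 months
away by symmetry. The two-argument arctangent handles all quadrants.
When `A` is numerically zero (< 1e-12) the phase is undefined and is
flagged rather than reported.

Standard errors of amplitude, peak-trough, peak month and
between-group amplitude contrasts are first-order Delta-method
propagations, `SE = √(gᵀΣg)` with the analytic gradient `g` evaluated
at the estimate (for `A`: `∂A/∂s = s/A`, `∂A/∂c = c/A`, chain-ruled
onto interaction coefficients; for the phase: `c/A²`, `−s/A²`, rescaled
to months). All confidence intervals are Wald intervals with the
normal multiplier 1.96 rather than a t-quantile — at the sample sizes
this package targets (thousands) the difference is negligible, and a
single convention keeps interval arithmetic reproducible from estimate
and SE alone. P-values are two-sided Wald tests; a joint chi-square
Wald test is available for multi-coefficient hypotheses. No
multiple-comparison adjustment is applied anywhere.

## Covariate contrasts

Annual-mean differences per covariate level are the level-shift
coefficients themselves. Seasonal-variation differences are
`2A(level) − 2A(reference)` from a model with that covariate's
interactions, with the Delta-method SE taken over the joint covariance
of all four trigonometric coefficients. Adjusted models add age group
(≥62 y), gender, study site, BMI group and smoking as level shifts
only; adjustment covariates deliberately do not get their own
interactions, so each covariate's effect on the seasonal swing is
assessed against a common seasonal shape. When the covariate under
study is itself part of the adjustment set it is removed from it.
Multi-level covariates (BMI: <25, 25–30, >30) yield one contrast per
non-reference level, each with its own Wald z. Every model is fitted
on its own complete cases and reports its n.

## Prediction of follow-up concentrations

All prediction methods share one anchoring construction: fit a
seasonal-curve model on the baseline cohort, shift the patient's curve
to pass through their observed baseline value, and read the prediction
off the shifted curve — `ŷ = y_base + curve(m_follow) − curve(m_base)`.
Level terms cancel in the difference, so only the seasonal component
matters, and a same-month prediction returns the baseline value
exactly. The three curve models are: the cosinor (optionally with
patient-specific interaction-modified coefficients), a step function
over the four quarters ("linear regression adjusted for season" — the
anchoring rule is applied to it too, so the methods differ only in
their curve model, which is the comparison of interest), and the flat
curve (baseline carried forward). Models are fitted on the full
baseline cohort, not refitted excluding the nested subgroup.
Accuracy is summarised per method by Pearson correlation with the
measured follow-up (Fisher-z 95% CI), MSE, RMSE, SD of predictions and
the proportion of predictions within 10 nmol/l; methods are compared
with paired t-tests on per-observation squared errors, treating a
patient's two follow-ups as independent pairs (the analysis unit is
the observation; within-patient dependence across the two visits is a
known simplification).

## Annual values and reclassification

A participant's season-adjusted annual value is the cohort annual mean
plus their deviation from the fitted curve at their month and
covariates. For the unadjusted model the annual mean is the intercept
and annualisation is exactly mean-preserving (OLS residuals sum to
zero). For covariate models the annual mean is the cohort-average
fitted value with all seasonal columns zeroed — a generalisation that
reduces to the intercept when no covariates are present; per-covariate
annual means would instead remove the covariate differences
themselves, which is not the goal of seasonal adjustment.
Sufficiency uses the 50 nmol/l threshold with the boundary value
classified sufficient (≥50). Reclassification tables cross-classify
measured against annual status for the whole year and within the dark
(October–March) and bright (April–September) periods; percentages are
kept unrounded internally and rounded to one decimal only for display.

## Preprocessing rules

Assay components (25OHD2, 25OHD3) strictly below the 6.6 nmol/l lower
limit of quantification are set absent; the total is the sum of the
present components, so a sub-LLOQ D2 contributes zero while the
patient is retained via D3. A record whose D3 is absent after
filtering carries no usable total and is excluded from analysis.
Smoking is self-report, or quitting ≤90 days ago, or plasma cotinine
>85 nmol/l; hypertension is SBP >140 and/or DBP >90 mm Hg and/or
antihypertensive treatment (both rules use strict inequalities at the
stated boundaries). Seasons are calendar quarters and the dark/bright
periods are October–March / April–September. Missing-data policy is
complete-case per fitted model, with per-column missing counts
reported on read.

## Synthetic cohort

The generator emulates the target study design: `n_baseline = 4116`
patients; a nested subgroup of 271 with follow-up visits at offsets of
1 and 12 months (months wrap modulo 12) and attendance probability
528/542, giving ~528 expected follow-up rows. The seasonal truth is a
cosine with explicit peak month (7.5, i.e. mid-July–August; trough
between January and February), equivalent to the sine+cosine form via
`β_s = A sin(2π·peak/12)`, `β_c = A cos(2π·peak/12)`.

Covariates are drawn independently (no joint distribution is known; a
hook accepts a user-supplied joint sampler): age ~ N(61.8, 10.4), BMI
~ N(26.8, 4.0), eGFR ~ N(87.8, 17.2), and Bernoulli indicators with
prevalences female 0.281, Stavanger site 0.181, smoker 0.317, activity
≥2 h/week 0.688, supplement use 0.336, diabetes 0.119, CRP >10 mg/l
0.068. Self-report items are missing completely at random (activity
24.7%, supplements 12.7%), which reproduces the varying complete-case
n of the covariate models. Annual-mean effects per level (nmol/l:
female −2.2, ≥62 y +1.9, Stavanger −5.3, smoker −3.4, BMI 25–30 −2.3,
BMI >30 −8.6, activity +4.1, supplements +8.4, diabetes −1.9) and the
older-age peak-trough effect (−6.3) are centred at the realised
baseline prevalences, so the cohort-level annual mean, amplitude and
peak equal the configured 59.6 / 7.9 / 7.5 exactly while
level-vs-reference contrasts equal the configured effects; the
reference-age (younger) peak-trough is then ~18.9 and the older-age
~12.6 nmol/l. CRP and eGFR carry no effect by default and so serve as
true nulls for type-I-error checks.

Residual variation is Gaussian with total SD 19 nmol/l (chosen between
the printed monthly SDs of ~18.5–20.3; the cohort-wide value is not
published), decomposed into a person-level intercept (SD √(19²−10²) ≈
16.2) shared across a patient's visits and within-person measurement
noise (SD 10, giving a baseline–follow-up correlation of ~0.72 from
the intercept alone, consistent with the ~0.75 correlation of
baseline-carried-forward predictions). The within-person noise of a
follow-up keeps a serial correlation of 0.3 per month of offset
(geometric decay), so 1-month repeats track baseline more closely than
12-month repeats — the feature that favours baseline-carry over
season-dummy regression when follow-ups are close. Values are
truncated at zero with a logged count.

What the generator does not emulate: the right skew of real 25OHD
distributions (noise is symmetric), assay drift and storage effects,
visit-timing spread around the nominal offsets, covariate
correlations, and any intervention effect. Passing tests therefore
demonstrate correctness of the estimators and accounting under the
assumed sinusoidal-plus-Gaussian structure, not robustness to
real-data pathologies.

One consequence of the Gaussian tail is worth recording: ~0.3% of
synthetic totals fall below the 6.6 nmol/l LLOQ and are excluded by
the preprocessing rule, which left-truncates the analysed distribution
and shifts the estimable annual mean by about +0.3 nmol/l and the
amplitude by about −0.2 relative to the nominal generator values (real
cohorts of this biomarker have essentially no sub-LLOQ totals, being
right- rather than left-tailed). The recovery tests therefore compare
estimates against the closed-form estimand of the truncated mixture
(computed independently in `tests/oracles.py` from truncated-normal
means over the covariate cells) rather than against the nominal
values; contrasts are unaffected at the tested precision.

## Numerical choices and problem sizes

Rank deficiency is detected before fitting (QR diagnostics name the
collinear columns). Degenerate inputs — empty complete-case sets,
zero amplitude, singular Wald submatrices — raise typed errors rather
than returning NaNs. The test suite exercises the pipeline at the
study's own scale: 500 replicates of n = 4116 for parameter/contrast
recovery and type-I error, 500 cohorts of n = 1000 for CI coverage
with a 2000-resample bootstrap cross-check of the Delta SE, and 200
replicates of the 271-patient follow-up design for the
prediction-method ordering; these sizes give Monte-Carlo error well
below the tolerances asserted while keeping the default test run to
about a minute.
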