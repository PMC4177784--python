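# Methods

## The problem

Serum banked over decades and assayed in a single batch confounds three time
scales: follow-up time (biology), calendar period (who gets enrolled and
treated in which era), and storage time (pre-analytical decay). Because all
samples share one analysis date, storage time is `analysis_date −
sample_date`; within a patient it is perfectly anti-collinear with follow-up
time, and the decay rate is identified only because inclusion dates differ
across patients. The analysis therefore (i) tests whether lipid trajectories
differ by enrolment period, (ii) estimates the linear storage-decay rate with
a model that handles repeated measures and confounders, (iii) inverts the
decay additively, and (iv) asks whether the correction changes anyone's
cardiovascular risk category.

## Statistical model

For lipid level `y_ij` (mmol/L) of patient `i` at occasion `j`:

    y_ij = x_ij' β + b_i + e_ij,   b_i ~ N(0, σb²),  e_ij ~ N(0, σe²)

a linear mixed model with one random intercept per patient (compound-symmetric
within-patient covariance). The decay model's fixed effects are storage time
(the coefficient of interest), follow-up time and its square (lipid
trajectories over follow-up are curved), and confounders: age, gender, BMI,
statin and glucocorticoid use at baseline for TC; age and gender suffice for
HDL-c. The period model replaces storage time with subcohort indicators and
subcohort × follow-up interactions; the period effect is the joint test of the
interaction block.

Estimation is by REML for reported coefficients and ML where likelihoods must
be compared, via `statsmodels.MixedLM`. Numerical detail: the default
L-BFGS/Powell fit is followed by a BFGS polish (`gtol = 1e-12`) started at
the first optimum, accepted only if it does not decrease the (restricted)
log-likelihood; this brings variance components to near machine precision so
they match closed-form oracles (balanced-ANOVA estimators, GLS at fixed
variance components) to 1e-8. At the boundary σb² → 0 gradient methods can
fail on a singular information matrix; the fit then falls back to
derivative-free Powell. Rank deficiency is detected by pivoted QR and
reported with the collinear column names.

Inference: joint hypotheses use the Wald chi-square `β'V⁻¹β` (not an F test
with small-sample degrees of freedom — a known mild anti-conservatism at this
cohort size, acceptable here and visible in the type-I simulations staying
just above 0.05 but inside the binomial band). Likelihood-ratio tests are
provided for ML fits and refuse REML fits with differing fixed effects.
Confidence intervals are Wald, estimate ± 1.96·SE.

**Confounder screening** uses the change-in-estimate rule: each candidate is
added alone to the base model and selected when any monitored coefficient
moves by more than 10 % relative. The monitored set is configurable because
the rule is applied twice with different targets: to the subcohort ×
follow-up effects in the period analysis, and to the storage-time coefficient
in the decay analysis. A monitored coefficient of exactly zero switches the
criterion to absolute change against a configurable scale.

## Decay correction and derived lipids

The correction is the model read backwards: `corrected = observed + δ·t`
with `δ = −`(storage-time coefficient) and `t` the storage years; it is exact
arithmetic, linear in `t`, and invertible. LDL-c is computed by Friedewald in
mmol/L units (`LDL = TC − HDL − TG/2.2`, valid for TG ≤ 4.5 mmol/L; samples
are nonfasting, so the validity guard is enforced). LDL-c is *not* corrected
for storage — no storage effect on LDL-c was found — so a "corrected" LDL, if
requested, is recomputed by Friedewald from corrected TC and HDL-c with
observed triglycerides, keeping the panel internally coherent. Triglyceride
decay is not modelled.

Because the default decay rates satisfy δ_TC/δ_HDL = 0.030/0.024 = 1.25,
correction lowers the TC:HDL ratio exactly when the observed ratio exceeds
1.25 — true for any clinically plausible profile — so corrected risk never
exceeds observed risk and reclassification can only move patients toward
lower categories.

## SCORE risk engine

Ten-year fatal-CVD risk follows the published Weibull formulation: per cause
(CHD, non-CHD CVD) with sex/region-specific `(α, p)`,
`S0(age) = exp(−exp(α)(age−20)^p)`, linear predictor
`w = Σ βk(xk − ref_k)` over the cholesterol term, systolic blood pressure
(ref 120 mmHg) and current smoking, `S = S0^exp(w)`, cause risk
`1 − S(age+10)/S(age)`, and total risk the sum over causes. Coefficients are
transcribed from the published derivation into a versioned YAML file
(`data/score_conroy2003.yaml`); nothing numeric is hard-coded in the engine.
Two cholesterol variants are selectable — total cholesterol (ref 6 mmol/L)
and TC:HDL ratio (ref 5) — with the ratio variant as default, since the ratio
is what the storage effect distorts; the region default is `low_risk`
(Dutch cohort). No RA-specific multiplier is applied. Ages outside the
calibrated range [20, 85] raise by default (`allow_out_of_range=True`
extrapolates); the pipeline clamps simulated ages to that range explicitly
when building risk profiles.

Verification scope: the engine is checked to 1e-12 against an independent
scalar re-implementation, by exhaustive monotonicity sweeps, and against
published chart cells. Chart agreement is asserted at the printed-integer
level only for corner/extreme cells transcribed with high confidence, and at
colour-band level otherwise; published charts are rounded and were tabulated
on age bands, so cell-exact agreement across the whole chart is not a
meaningful target.

Risk categories: low < 10 %, intermediate 10–20 % (read as the closed
interval, so both boundaries classify as intermediate), high > 20 %;
cut-offs are configurable.

## Reclassification summary

The 3×3 before/after table is summarised with the convention of clinical
reclassification tables: per-category percentages of the cohort for the
before/after columns, net change as a percentage of that category's *before*
count, and the overall reclassified share as a percentage of the cohort.
Percentages are whole percents, ties rounded away from zero. Note one
arithmetic caveat documented in the tests: a published high-risk row of this
shape prints −39 as an 11 % decrease of 373, but 39/373 = 10.46 % rounds to
10 % under any standard rule; `summarize` reports the computed 10.

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces the design features the analysis depends on: five
inclusion-period subcohorts (defaults 1985–2009, 30 patients each), sampling
at follow-up years {0,1,2,3,5,7,10} censored at the analysis date (the
staircase of storage times, ~1–26 years), within-patient correlation via the
random intercept, a quadratic follow-up trend, linear storage decay
(defaults 0.030/0.024 mmol/L·yr), and per-subcohort covariate distributions
with the observed calendar trends (statin use 0 % → 29 %, smoking 47 % →
29 %, rising glucocorticoid use and age). Inclusion dates are uniform within
each period; dates are decimal years. Covariate effect sizes on lipids are
set to the fitted values of the decay models (age 0.016, statin 0.888,
glucocorticoid 0.239, BMI 0.011, gender 0.023 mmol/L for TC; age 0.003,
gender 0.074 for HDL-c) so that the fitted model is correctly specified on
generated data and parameter recovery is a well-posed check.

Variance components default to σb = 0.8, σe = 0.5 mmol/L for TC. HDL-c
varies on a far narrower scale (observed SDs ≈ 0.2–0.4 vs 1.0–1.5 mmol/L),
so both HDL components are scaled by `hdl_sd_scale = 0.25`. This is not
cosmetic: with TC-scale noise on HDL-c, a large fraction of long-stored HDL
values would fall below the positivity floor and the floor handling would
bias the recovered decay. With realistic scales, floor truncation affects
<~1 % of the oldest samples and the recovery bias is negligible relative to
Monte-Carlo error. Lipids are kept positive by redrawing the residual while
below 0.1 mmol/L (at most 100 redraws, then clamped). Systolic blood
pressure, needed only for SCORE, is Normal(135, 15) mmHg per patient;
triglycerides are log-normal around 1.4 mmol/L capped at the Friedewald
validity limit. DAS28 and rheumatoid-factor status are static baseline
covariates; disease course, freeze–thaw cycles, vial type and the 2008
−20 °C → −80 °C transfer are deliberately not modelled.

Consequently, passing tests show that the *estimation machinery* is unbiased
and calibrated under the design's correlation and censoring structure — not
that real serum decays linearly, nor that real confounding is fully captured
by the covariates modelled here.

## Problem sizes and determinism

Replicated checks use 200 cohorts (seeds 1–200) for decay-rate recovery,
accepted within two Monte-Carlo standard errors of the generator truth, and
500 replicates for the period-test type-I error, accepted within the binomial
95 % band around 0.05. One seed drives each cohort through a single
`numpy.random.Generator` stream; the pipeline is bit-identical under a fixed
seed, and every output file carries the seed and a configuration hash
(output paths excluded) so mixed outputs are detectable.

## Known limitations

- Wald chi-square joint tests, no Satterthwaite/Kenward-Roger small-sample
  correction.
- Single random intercept: no random slopes or serial correlation.
- The SCORE constants file is a manual transcription; chart verification is
  band-level away from the anchored cells (see above).
- The change-in-estimate screen evaluates candidates one at a time, as in the
  original procedure; joint confounding among candidates is not assessed.
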