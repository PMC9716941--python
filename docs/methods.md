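# Methods

## The prediction problem

A pregnancy of unknown location (PUL) resolves into one of three outcomes:
a spontaneously failing PUL, an intrauterine pregnancy (IUP), or an ectopic
pregnancy (EP). The triage models considered here are multinomial logistic
regressions on two serum hCG measurements taken 24–72 h apart, with failed
PUL as the reference class. The analysis outcome is dichotomous: EP versus
non-EP, with persisting PUL (plateauing hCG, no visualised pregnancy)
analysed as EP because it is managed as one. Gestational trophoblastic
disease and lost-to-follow-up records are excluded before analysis.

Model coefficients are configuration, not code: a `ModelSpec` JSON maps
basis-function names (`intercept`, `log_hcg1`, `log_hcg1_sq`, `log_ratio`,
`log_ratio_sq`, `log_hcg1_x_log_ratio`; natural logs throughout) to
coefficients for the IUP and EP logits. Unknown keys and unknown basis
names fail at load time, guarding against silent transcription typos.
Probabilities come from a max-shifted softmax; the high-risk rule is
`P(EP) ≥ τ` (a probability that *reaches* the threshold is high risk), and
argmax outcome labels break exact ties in the fixed order
failed PUL < IUP < EP so results are deterministic.

## Validation battery

**Discrimination.** AUC is computed by the midrank Mann–Whitney identity in
O(n log n); ties count one half. Variance and the paired two-model test use
the DeLong structural components: per-positive placements V10 and
per-negative placements V01, with `var = var(V10)/m + var(V01)/n` and the
paired covariance from the same components. CIs are Wald on the AUC scale,
truncated to [0, 1] (a logit-scale CI would be an alternative; the Wald
form matches how such CIs are conventionally reported). Two degenerate
regimes are handled explicitly: identical score vectors give z = 0, p = 1,
and a zero-variance difference with unequal AUCs (e.g. a perfect versus an
anti-classifier) returns the certainty limit z = ±∞, p = 0 with a warning
rather than dividing by zero.

**Calibration.** Calibration-in-the-large is the MLE intercept of a
logistic model with logit(p) as offset and slope fixed at 1; the
calibration slope comes from the free recalibration `a + b·logit(p)`. Both
are fitted by IRLS (statsmodels GLM, 100 iterations, tolerance 1e-10, far
tighter than reporting precision) with Wald CIs; coefficients larger than
30 in absolute value are treated as separation and rejected. Predicted
probabilities are clipped at 1e-12 before the logit because softmax outputs
can underflow. When predictions are constant the offset model has the
closed form `citl = logit(observed) − logit(p)`, which the tests verify to
1e-8 against the IRLS path.

**Calibration curve.** A loess-style local linear regression of the binary
outcome on the predicted risk: tricube weights with a span-based
nearest-neighbour bandwidth (default span 0.75, degree 1 — the conventional
loess defaults, exposed as parameters since the method is usually named
without them), evaluated on a 100-point grid over the observed prediction
range. Pointwise CIs use the local fit's heteroscedasticity-robust
(sandwich) variance through the fit's influence vector; a bootstrap band
(200 resamples) is available behind a flag. Smoothed values and bands are
clipped to [0, 1]; fewer than 20 observations are refused. The curve is
written by hand because no installed smoother exposes span-based local
linear fits with pointwise CIs.

**Classification.** Sensitivity, false positive rate, negative predictive
value and percent-low-risk at thresholds 2.5/5/10% (overridable), all with
Wilson score CIs — chosen for sane behaviour at boundaries such as
sensitivities near 100%. A zero denominator yields an explicitly undefined
measure, never a silent 0. McNemar's paired test uses the exact two-sided
binomial p-value when the discordant total b + c < 25 and the
continuity-corrected chi-square otherwise (the rule is recorded in the
result); restricting to EP records compares sensitivities, to non-EP
records compares FPRs; zero discordance gives p = 1 by convention.

**Decision curve.** Net benefit `TP/n − (FP/n)·τ/(1−τ)` per patient
(unit scale), against treat-all (`prev − (1−prev)·τ/(1−τ)`, crossing zero
exactly at τ = prevalence) and treat-none (0). The default grid is 0.01 to
0.50 in steps of 0.01 — clinically relevant PUL thresholds are low — with
no smoothing: each point is the exact arithmetic at that threshold. A model
has utility at a threshold only if its net benefit exceeds both defaults.

## Synthetic cohort generator

Descriptive mode emulates a 1061-woman emergency-gynaecology validation
cohort: outcome mixture (461, 362, 238)/1061 with 46/238 of EP labelled
persisting PUL; first hCG log-normal with log-median ln 703 and log-sigma
`(ln 2312 − ln 210)/(2·z₀.₇₅) ≈ 1.778` so the theoretical quartiles match
210 and 2312 IU/L (values clipped to the observed 7–180 000 range);
class-conditional log-normal hCG ratios with medians 0.51 (failed PUL,
declining), 2.0 (IUP, doubling over ~48 h) and 0.95 (EP, near-plateau) and
log-sigmas 0.50/0.30/0.55, chosen once so the mixture median is ≈ 0.94
(attained: 0.943), truncated to the observed range 0.06–5.65; sampling
intervals drawn from the (24–39, 40–56, 57–72) h bins with weights
(13, 71, 16)% and uniform hours within a bin; covariate flag rates
(bleeding 68%, prior EP 7%, IUD 3%, inpatient 8%) and PUL-type mix from the
same descriptive table. One integer seed drives named spawned sub-streams
(one per field), so outputs are reproducible and extending one sampler does
not perturb the others. Optional contamination appends out-of-window, GTD
or lost-to-follow-up records for exercising the inclusion filter and the
sensitivity analysis.

Model-consistent mode draws the same covariates (the ratio from the
mixture marginal, not conditioned on outcome) and then samples each
record's outcome from a given model's predicted probabilities. By
construction the model is perfectly calibrated on such data — slope 1,
intercept 0, and the model AUC equals the ground-truth-probability AUC in
expectation — which is what the parameter-recovery tests assert (10 seeds
at n = 20 000: mean slope within 1 ± 0.03, mean CITL within ±0.03, loess
curve within ±0.05 of the diagonal on [0.02, 0.5]).

The persisting-PUL adjudication helper implements the plateau rule: at
least three consecutive hCG values within a 7-day window, every successive
relative change below 15%.

### Placeholder model configs

The published coefficients are in supplementary material the user must
transcribe; the shipped configs are synthetic stand-ins (and say so in
their `note` fields). The class-conditional log-normal ratios imply that
the true posterior log-odds of each class versus failed PUL are exactly
quadratic in ln r, so the "M6NP-like" placeholder uses those Bayes
coefficients — giving a realistic, well-calibrated model whose functional
form matches the published family. The "M4-like" comparator sharpens those
logits by 1.4 and shifts the EP logit down by ≈ 0.55 (partly via a small
negative first-hCG term so more of the basis registry is exercised),
producing the qualitative miscalibration pattern reported for older
comparators validated in higher-prevalence settings: average risk
under-predicted (CITL > 0) and predictions too extreme (slope < 1).

### What the generator does and does not emulate

It matches the marginal outcome mix, hCG level and ratio quartiles,
interval mix and covariate rates. It does **not** model: dependence of the
ratio on the exact interval length (a real IUP doubles per ~48 h, so its
ratio should scale with the interval); any association between hCG level or
clinical flags and outcome (hCG1 is class-independent by design, so the
ratio is the only discriminating covariate and the achievable AUC is ≈ 0.71
rather than the ≈ 0.85 reported for real cohorts where level adds signal);
correlation between ultrasound PUL type and outcome; or longitudinal
follow-up beyond the two samples. Passing tests therefore demonstrate the
correctness of the validation machinery and the internal consistency of the
generator, not the clinical performance of any real model.

## Numerical choices and edge cases

- Interval window boundaries are inclusive (24 h and 72 h retained);
  outcome-based exclusions take precedence over the interval exclusion in
  the disposition log.
- Softmax is max-shifted; probability triples must sum to 1 within 1e-12.
- AUC/DeLong ties use the midrank convention everywhere, keeping the
  Mann–Whitney identity exact.
- Exact McNemar p-values are `min(1, 2·P(Bin(b+c, ½) ≤ min(b, c)))`;
  two-sided p-values are capped at 1.
- Wilson CI bounds are snapped to bracket the point estimate (pure
  round-off can otherwise leave the estimate 1e-16 outside the interval).
- The problem sizes used by the test suite and acceptance script
  (n = 20 000 pipelines, n = 100 000 marginal checks, 10-seed recovery
  runs) were chosen as the smallest at which the asserted tolerances are
  comfortably inside Monte-Carlo noise.

## Known limitations

- The progesterone-augmented model variant is out of scope (no
  progesterone field exists); the basis registry is extensible if it is
  ever needed.
- No grouped (Hosmer–Lemeshow) calibration and no model updating; the
  recalibration fits are diagnostics only.
- Net benefit carries no CI (a bootstrap hook would be the natural
  extension).
- The loess CI is pointwise, not simultaneous.
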