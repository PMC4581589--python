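# Methods

This note documents the estimation procedure, the synthetic data-generating
mechanism, the numerical choices, and what the validation studies do and do
not establish.

## Estimand and design

The estimand is counterfactual survival `S_X(k)` — the probability of
surviving through interval `k`, conditional on surviving interval 0 — had
everyone followed switching strategy `X` with an approximately uniform
distribution of switch times over the three-interval grace period.
Identification rests on the usual assumptions of this design: no
unmeasured confounders of switching and mortality given the measured
history, positivity, and (because the two randomized monitoring arms are
pooled) no direct effect of the monitoring arm on mortality or on the
time-dependent covariates other than through switching. Randomized arm is
therefore deliberately absent from every model.

Clone–censor–weight proceeds per strategy: each person is cloned;
eligibility `Q_x` is the first interval after an observed-under-schedule
CD4 below threshold, or the interval of a qualifying WHO 3/4 event
(tie-breaker: last prior observed CD4 < 250, vacuously satisfied when the
schedule has produced no observation; events count only when strictly
before a same-interval switch); clones are censored at a pre-eligibility
switch or at `Q_x + 3` when no switch occurred in the grace period
`Q_x..Q_x+2`. Compatible person-time is reweighted by the nonstabilized
inverse-probability weights with the uniform-grace numerator; the last
grace interval of a non-switching clone receives weight 0, the limit of
the formula, consistent with its censoring one interval later.

Two structural identities are enforced by construction and verified in
tests: 12-weekly monitoring is the identity regime (schedule-filtered
observation equals the full measurement record), and an empty schedule
with the CD4 restriction disabled reduces exactly to the corresponding
event-only strategy. Weight models always see the complete measurement
record regardless of the regime's schedule — confounding control must use
the data that generated behavior, not the data the regime observes.

## Models

Both the switch model and the LTFU (retention) model are discrete-time
pooled logistic regressions sharing one covariate builder (the LTFU model
adds a prior-switch indicator and uses all person-intervals in follow-up).
Interval intercepts use restricted cubic splines (Harrell basis) with
knots at the 10th/50th/90th percentiles of the interval index over at-risk
person-intervals; current CD4 uses fixed knots 15/50/100/200 cells/mm³.
Only CD4 is splined among time-dependent covariates, limiting positivity
problems. Event histories are 5-category with the highest level dominant
(recent = `k−2..k`, distal = `k−5..k−3`), qualify only when carried-forward
CD4 at the event interval was below 250, and tuberculosis history is a
separate 5-category variable (pulmonary = stage-3-like, extrapulmonary =
stage-4-like). The cotrimoxazole term is forced to zero once 72 weeks of
ART (interval 6 after the 48-week baseline) have passed.

The outcome model regresses death in `k+1` on the interval spline plus the
strategy encoding, among clone-intervals that end `k` alive, uncensored,
and still under follow-up at `k+1`, weighted by the truncated product of
strategy, substudy and LTFU weights through `k` (a person switching during
`k` keeps the same interval-`k` mortality risk as a non-switcher). Two
encodings: `hg` (threshold linear in cells/mm³; event-only strategies as
dummies; a spline or categorical threshold encoding is a supported
sensitivity variant) and `f` (categorical monitoring frequency with the
switching rule held fixed). Each encoding column interacts with the
late-follow-up indicator `k_m = 1[interval starts > 96 weeks]` (first true
at interval 25). Encoding columns that are constant in a given fit (e.g.
single-strategy fits) are dropped together with their `k_m` interactions,
so the design degrades gracefully to the plain pooled logistic model.

### Fitting

Pooled logistic likelihoods are maximized by a Newton–Raphson solver with
step-halving, internal column standardization, and a ridge of 1e-6 (on the
standardized scale, never on the intercept). The ridge pins directions of
quasi-separation — covariate cells with zero events, common in the LTFU
model — without measurably moving identified coefficients; the intercept
score equation (predicted events = observed events) remains exact, and the
test suite verifies agreement of fitted probabilities and attained
log-likelihood with `statsmodels.GLM` as an independent oracle. Zero
events raise an informative error; the pipeline treats a cohort with no
switches analytically (`p_switch ≡ 0`), mirroring the all-weights-1 rule
for a cohort with no dropout.

Positivity guard: any required denominator (`p_A`, or `1 − p_A` at a
grace-period switch, or the LTFU retention probability) below 1e-6 raises
a logged `PositivityError` instead of silently producing extreme weights.
Truncation at 10 applies to the combined product, not per component; the
raw product is retained for untruncated sensitivity runs.

### Bootstrap

Confidence bands are percentile 2.5/97.5 over a nonparametric bootstrap of
individuals, ignoring randomized arm, re-estimating every model and weight
per replicate (B = 500 by default; smaller B in the packaged studies).
Implementation detail: resampling is carried out through person frequency
weights — a resample in which person *i* appears *mᵢ* times has exactly
the likelihood of fitting *mᵢ* duplicated copies — so design matrices,
eligibility and censoring states (all resample-invariant) are built once;
replicate fits warm-start from the point estimate, and spline knots are
held at their point-estimate values (fixed basis, re-estimated
coefficients). Replicates that fail (no events after resampling, a
substudy stratum losing its continuous-therapy arm, positivity) are logged
and skipped. Percentile intervals were chosen over normal-approximation
ones because they respect the [0, 1] range of survival.

## Synthetic cohort generator

The generator emulates a two-arm monitoring trial cohort of 2,946 adults
who completed 48 weeks of first-line ART, followed for 65 four-week
intervals. Baseline CD4 is normal on the square-root scale (mean 14.18,
SD 3.41 — median ≈ 200 cells/mm³, ≈ 11–12% below 100). A baseline-CD4-
dependent fraction (≈ 25–30%) are failing first-line therapy; their latent
sqrt-CD4 drifts down 0.12 per interval until switching, after which it
recovers at up to 0.25 per interval toward a personal target; responders
mean-revert upward. Observed CD4 adds sqrt-scale measurement noise (SD
0.8) and is rounded. WHO 3, esophageal candidiasis, non-Candida WHO 4 and
pulmonary/extrapulmonary TB have per-interval logistic hazards decreasing
in true CD4; death hazard depends on true CD4, recent WHO 4 events,
and treatment line (a modest direct second-line benefit plus the indirect
CD4-recovery benefit). Switching behavior is arm-specific: LCM clinicians
respond to low returned CD4 counts, CDM clinicians only to clinical
events, plus a small CD4-independent background rate in both arms (as in
real cohorts). LTFU is a constant small hazard; an optional substudy
enrolls ≈ 27% with stratified 1:1 allocation at a fixed entry interval,
making the continuous-therapy upweight ≈ 2 exact in expectation. Defaults
reproduce the target cohort's printed marginals (median baseline CD4,
fraction < 100, switch/death/LTFU counts) to within ~15%.

Ground truth for any strategy comes from re-simulating the same latent
mechanism under forced compliance: eligibility is evaluated on the CD4
counts the strategy's schedule would observe, the switch interval is drawn
uniformly over the grace period, and behavioral switching, LTFU and the
substudy are switched off. Truth is invariant to the behavioral switching
parameters by construction.

What the generator does **not** emulate: viral load, within-person
correlation between BMI/hemoglobin and disease progression beyond a simple
CD4-linked flag process, confirmatory (repeat) CD4 testing, clinic-level
effects, or informative LTFU beyond the modeled covariates. Passing the
validation studies therefore demonstrates internal consistency of the
estimator under a known mechanism of realistic scale and confounding
structure — not correctness of any particular real-world analysis.

## Validation studies and problem sizes

The test suite's simulation studies use sizes chosen to keep the full run
practical on a single CPU while retaining statistical meaning:

- **Weight-formula equivalence** and **rule-trace agreement** run on the
  shipped fixture configuration (200 persons, 30 intervals) against
  independent per-person enumeration oracles, at 1e-12.
- **Parameter recovery**: 20 cohorts of n = 5,000 × 65 intervals; the
  estimate of S(60) under "CD4 < 100 or WHO 4 (tie-breaker 250),
  12-weekly" must fall within ±1.5 percentage points of forced-regime
  truth (200,000 trajectories) in ≥ 90% of replicates. Observed error is
  dominated by a small (~+0.5 pp) finite-sample/truncation bias.
- **Orderings**: one n = 2,946 cohort, B = 40; S(CD4<100) ≥ S(CD4<50) ≥
  S(event-only) and S(12-weekly) ≥ S(baseline-only) ≥ S(no monitoring) at
  240 weeks, each within 1.96 bootstrap SDs of the paired difference.
- **Bootstrap coverage**: 20 cohorts of n = 1,200 × 40 intervals with the
  death hazard raised (intercept −3.3) so each scaled-down cohort retains
  a trial-scale number of deaths (~45); the test asserts coverage of true
  S(36) by the 95% percentile band (B = 99) in [88%, 99%]. At this scale
  the suite *observes sub-nominal coverage* (16/20 in the packaged run)
  and the test fails by design rather than loosening the band: the misses
  are cohorts whose estimate is biased upward (few eligible non-switchers
  die; truncation at 10 contributes) and the percentile band, centered on
  that biased estimate, excludes the truth from above. Coverage improved
  from ~73% (n = 600, B = 40) to 80% (n = 1,200, B = 99) as scale grew,
  consistent with a small-sample effect rather than a defect of the
  resampling itself; full trial-scale coverage was not run for compute
  reasons.

## Known limitations

- The threshold enters the `hg` outcome model linearly; with few
  strategies fitted, the linearity assumption is untestable (the
  categorical encoding is available as a flag).
- Weight truncation at 10 trades variance for a small bias toward the
  natural-course survival; raw weights are available.
- The tie-breaker under reduced monitoring uses the strategy-observed CD4
  series, and is vacuously satisfied when no CD4 was ever observed; both
  are modeling choices where the design admits alternatives.
- Percentile bootstrap bands undercover in small cohorts with few
  compatible deaths (see the coverage study design above).
- Confirmatory CD4 measurements cannot be part of a strategy; grace
  periods are common to all trigger types.
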