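# cloneweight

Dynamic marginal structural models for **when-to-switch** questions in HIV
care, estimated by **clone–censor–weight**: every individual in a
person-period cohort is replicated once per candidate regime, artificially
censored when their data become incompatible with it, and reweighted by
inverse probability of remaining uncensored. The package targets the
setting of African ART programs, where adults on first-line antiretroviral
therapy may be switched to second-line therapy when an (observed) CD4
count crosses a threshold and/or a WHO stage 3/4 event occurs, and where
the *frequency* of CD4 monitoring itself — 12-weekly, 24-weekly, a single
baseline test, or none — is part of the regime.

It is written for epidemiologists and biostatisticians who want a tested,
reproducible implementation of this design, together with a synthetic
cohort generator whose counterfactual ground truth is computable by forced
simulation, so that the whole estimation pipeline can be validated end to
end.

## The model

Follow-up is organized in 4-week intervals `k = 0, 1, 2, …` (interval `k`
covers days `[28k, 28k+28)`); CD4 is measured every 12 weeks. A switching
strategy `X` is defined by a CD4 threshold `x` (switch at the first
*observed* CD4 `< x`), event triggers (first non-Candida WHO 4 event,
and/or second WHO 3 / esophageal candidiasis event, subject to a CD4 `<`
250 tie-breaker on the last prior observed count), a monitoring schedule
deciding which measurements are observed, and a grace period of three
intervals (`m = 2`).

The probability of switching in interval `k` is modeled by pooled logistic
regression on person-intervals alive and on first-line ART,

```
logit P[A(k)=1 | Ā(k−1)=0, D(k)=0, V, L̄(k)] = α₀(k) + α₁′V + α₂′L̄(k),
```

with a restricted-cubic-spline interval intercept, baseline covariates `V`
(center × regimen, CD4 category, BMI ≤ 18.5, hemoglobin < 8 g/dL, early
WHO 4 history) and time-dependent covariates `L̄(k)` (current CD4 as an RCS
with knots 15/50/100/200 under last-observation-carried-forward, 5-category
WHO 3/4 and tuberculosis event histories, cotrimoxazole, missed visits and
doses, a recent-WHO4 × CD4<100 interaction). Writing
`p_A(k) = 1 − P[A(k)=1 | ·]`, each clone accumulates the nonstabilized
weight

```
W_x(k) = I[C_x(k)=0] · ∏_{j ≤ k, j < Q_x} 1/p_A(j)
         · ∏_{r=0}^{m} [(1 − 1/(m+1−r)) / p_A(Q_x+r)]^{I[no switch at Q_x+r]}
                        [(1/(m+1−r)) / (1 − p_A(Q_x+r))]^{I[switch at Q_x+r]}
```

whose numerators spread the counterfactual switch uniformly over the grace
period. Substudy weights (structured treatment interruptions censored,
continuous-therapy participants upweighted by ≈ 2 within center × arm
strata) and inverse-probability-of-remaining LTFU weights multiply in, and
the product is truncated at 10. Mortality is then fitted on the expanded
data by weighted pooled logistic regression,

```
logit P[D(k+1)=1 | D(k)=0, C_x(k)=0, X, CF(k+1)=0]
    = θ₀(k) + θ₁′h(X) + θ₂′g(X) + θ₃′h(X)·k_m + θ₄′g(X)·k_m ,
```

where `h(X)` is the CD4 threshold (linear, 0 for event-only strategies),
`g(X)` dummies the event-only strategies, `k_m` flags intervals starting
more than 96 weeks after baseline, and monitoring-frequency regimes replace
`h, g` with a categorical `f(X)`. Survival is the product of one minus the
predicted hazards; confidence bands come from a nonparametric bootstrap
over individuals.

## Worked example

```python
from cloneweight import (SimulationConfig, Strategy, generate_cohort,
                         estimate_survival, simulate_counterfactual_survival)

cfg = SimulationConfig(n_individuals=2946, n_intervals=65, seed=1)
cohort = generate_cohort(cfg)          # person-period DataFrame

strategies = [
    Strategy("cd4_100", cd4_threshold=100),   # CD4<100 or WHO4, 12-weekly CD4
    Strategy("cd4_50",  cd4_threshold=50),
    Strategy("who4_only"),                    # clinical monitoring only
]
res = estimate_survival(cohort, strategies, mode="hg", horizon=60)
for sid, curve in res.curves.items():
    print(sid, round(curve.survival[60], 4))

truth = simulate_counterfactual_survival(cfg, strategies[0], 100_000)
print("forced-regime truth", round(truth.survival[60], 4))
```

Output:

```
cd4_100 0.9854
cd4_50 0.9664
who4_only 0.9418
forced-regime truth 0.9796
```

Estimated survival 240 weeks after baseline is 0.985 under "switch at the
first CD4 < 100 or non-Candida WHO 4 event" versus 0.942 under clinical
monitoring alone — earlier, immunologically triggered switching saves
lives in this cohort — and the clone-censor-weight estimate sits within
0.6 percentage points of the forced-regime Monte-Carlo truth.

A CLI wraps the same pipeline (`cloneweight simulate`, `cloneweight run
--config analysis.yaml --out outdir`, `cloneweight truth`); see
`cloneweight --help`.

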