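# longmediate

Causal mediation analysis for longitudinal randomized trials with a
log-scale continuous outcome.

## The problem

A trial shows that an active treatment reduces the urinary
albumin-to-creatinine ratio (UACR) to a fraction of baseline compared with
placebo. How much of that reduction travels *through* the treatment's
effect on systolic blood pressure (SBP) or kidney function (eGFR), and how
much is direct? `longmediate` answers this with the counterfactual
framework's natural effects: for treatment A ∈ {0, 1}, mediator summaries
M₁..M_K and baseline covariates C it fits, by ordinary least squares on the
same analysis set,

```
Y  = θ₀ + θ_A·A + Σₖ (θ_Mk·Mₖ + θ_AMk·A·Mₖ) + θ_C'C      (outcome model)
Mₖ = β₀ₖ + β_Aₖ·A + β_Cₖ'C                                (one per mediator)
```

where Y = ln(UACR at endpoint / UACR at baseline), and evaluates the
closed-form contrasts at the covariate sample mean c̄:

```
NDE = θ_A + Σₖ θ_AMk·m̄ₖ(0)          m̄ₖ(0) = β₀ₖ + β_Cₖ'c̄
NIE = Σₖ (θ_Mk + θ_AMk)·β_Aₖ
TE  = NDE + NIE
PM  = 100·NIE/TE   (proportion mediated, on the additive log scale)
```

Exponentiating gives geometric-mean-ratio effects (TE ratio = NDE ratio ×
NIE ratio). With K ≥ 2 mediators the NIE is the *joint* indirect effect
through all of them, which needs no assumption about how the mediators
affect one another. Confidence intervals come from a patient-level
percentile bootstrap (default 1000 replications). Longitudinal scans
repeat the analysis at every endpoint week; subgroup scans repeat it within
levels of a categorical attribute.

Mediator trajectories are reduced to one number per patient by either the
**cumulative mean** change from baseline over all visits up to the endpoint
(cumulative-exposure hypothesis) or the **achieved** change just before the
endpoint (acute-effect hypothesis).

A synthetic cohort generator (`longmediate.synthetic`) draws trial-like
datasets — UACR every 4 weeks to week 52, BP/eGFR every 2 weeks to week 8
then every 4 weeks, SBP plateauing near week 30 and eGFR near week 24 —
from a linear structural model whose true NDE/NIE/TE/PM are available in
closed form, so every estimator in the package can be validated against
known ground truth.

## Worked example

Simulate a 449-patient cohort with known structure, then decompose the
treatment effect through SBP and eGFR jointly:

```sh
longmediate simulate --n-patients 449 --seed 7 --out cohort.csv --truth-out truth.yaml
longmediate analyze --input cohort.csv --mediators sbp,egfr \
    --summary cumulative_mean --bootstrap 1000 --seed 1
```

prints

```
                           analysis effect estimate         95% CI                 PM
sbp,egfr (cumulative_mean, week 52)     TE    0.389 (0.339, 0.448) 22.3% (13.4, 31.5)
sbp,egfr (cumulative_mean, week 52)    NDE    0.480 (0.428, 0.541)
sbp,egfr (cumulative_mean, week 52)    NIE    0.810 (0.730, 0.890)
```

Read: the treatment reduces UACR to 0.389 times baseline versus placebo in
total; 0.480 of that ratio flows through pathways other than SBP/eGFR and
0.810 through them (0.480 × 0.810 = 0.389), so 22.3% of the (log-scale)
total effect is mediated. The sidecar `truth.yaml` holds the generating
configuration's true values (TE ratio 0.385, NDE 0.503, NIE 0.765,
PM 28.1%) — the estimates land within their bootstrap intervals.

The same machinery drives `longmediate scan --axis week` (proportion
mediated versus treatment duration, with an optional line chart) and
`--axis subgroup` (e.g. by sex, BMI class, or SGLT2-inhibitor use), and a
Python API mirrors every command:

```python
from longmediate import AnalysisSpec, analysis_set, estimate_with_ci, generate, GeneratorConfig

ds = analysis_set(generate(GeneratorConfig(seed=7)), endpoint_week=52)
spec = AnalysisSpec(mediators=(("sbp", "cumulative_mean"), ("egfr", "cumulative_mean")))
est, boot = estimate_with_ci(ds, spec, n_replicates=1000, seed=1)
print(est.te_ratio, est.nde_ratio, est.nie_ratio, est.pm_pct)
```

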