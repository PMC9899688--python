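# Methods

## Estimand and model

The outcome is the natural logarithm of the ratio of the endpoint urinary
albumin-to-creatinine ratio (UACR, mg/g creatinine) to its baseline value,
so that additive contrasts back-transform to geometric-mean ratios versus
control. For treatment A ∈ {0 = control, 1 = active}, mediator summaries
M₁..M_K and baseline covariates C, two linear models are fitted by
ordinary least squares on one common analysis set:

- outcome: Y = θ₀ + θ_A·A + Σₖ(θ_Mk·Mₖ + θ_AMk·A·Mₖ) + θ_C′C
- mediator (one per k): Mₖ = β₀ₖ + β_Aₖ·A + β_Cₖ′C

The natural direct effect (NDE), natural indirect effect (NIE) and total
effect (TE) for the contrast a = 1 vs a* = 0 are the standard closed-form
counterfactual expressions for this model family, evaluated at the
covariate sample mean c̄:

- NDE = θ_A + Σₖ θ_AMk·m̄ₖ(a*), with m̄ₖ(a*) = β₀ₖ + β_Aₖ·a* + β_Cₖ′c̄
- NIE = Σₖ (θ_Mk + θ_AMk·a)·β_Aₖ
- TE = NDE + NIE, and proportion mediated PM = 100·NIE/TE.

Because both models are linear, evaluating at c̄ equals averaging
patient-level conditional effects, so conditional and marginal reports
coincide. With multiple mediators the NIE is the joint indirect effect
through the set, which requires no assumption about causal ordering among
the mediators and absorbs mediator–mediator confounding into the joint
block. PM is defined on the additive (log) scale; this is the only reading
under which PM, the log decomposition and the ratio decomposition
(TE ratio = NDE ratio × NIE ratio) are mutually consistent.

Identification rests on sequential ignorability: randomization covers
exposure–outcome and exposure–mediator confounding; mediator–outcome
confounding by baseline covariates is addressed by adjustment (default
covariate set: log baseline UACR plus the baseline value of every analyzed
mediator), and is otherwise an assumption, not a testable property.

### Total-effect consistency check

`total_effect_check` also reports the treatment coefficient from the
marginal regression of Y on (A, C) — the intention-to-treat effect. When
the outcome model carries **no** exposure–mediator interaction and both
models share rows and covariates, this marginal coefficient equals
NDE + NIE *exactly* (nested-OLS omitted-variable algebra); the package
verifies this to 1e−8. With interaction terms the exact reconstruction of
the marginal coefficient would require the coefficient of A in a regression
of A·Mₖ on (A, C) rather than m̄ₖ(a*) + β_Aₖ, so the decomposition TE and
the marginal TE differ by a finite-sample term of order n^(−1/2) (about
2×10⁻³ at n = 400). The decomposition sum is the headline TE; the marginal
fit is a logged diagnostic. `AnalysisSpec(interactions=False)` selects the
no-interaction model, under which NIE reduces to the product of
coefficients Σₖ θ_Mk·β_Aₖ and matches the classic difference method
exactly.

## Mediator summaries

Both conventions operate on changes from baseline:

- **cumulative_mean** — unweighted mean change over all observed
  post-baseline visits with week ≤ endpoint. Unweighted (rather than
  time-weighted) averaging is the default because visits are near-regular;
  a trapezoid time-weighted variant is available via `time_weighted=True`.
- **achieved** — change at the latest non-missing visit strictly before
  the endpoint week. "Strictly before" keeps the summary distinct from the
  endpoint-week measurement and avoids same-day reverse-causation
  ambiguity when mediator and outcome share a visit; if no earlier
  measurement exists the endpoint-week value is used and flagged
  (`fallback=True`). `strictly_before=False` selects the at-endpoint
  reading.

Mean arterial pressure is composed per visit as MAP = DBP + (SBP − DBP)/3
(the conventional one-third pulse-pressure formula) before differencing.

## Analysis sets and missing data

Inclusion is complete-case per endpoint: a patient enters the week-w
analysis if the baseline UACR, SBP and eGFR are present and the UACR at
week w is present; mediator summaries additionally require at least one
usable post-baseline measurement. No imputation is performed, so the
per-week analysis sets of a longitudinal scan differ in size. Units are
never converted; the reader validates only positivity (UACR) and
finiteness.

## Bootstrap inference

Confidence intervals are percentile bootstrap over whole patients,
resampled with replacement with arms pooled — the plain nonparametric
bootstrap for a randomized trial (`stratify_by_arm=True` switches to
within-arm resampling). Per-patient rows (outcome, summaries, covariates)
are assembled once; each replicate refits the regressions on resampled
rows. Degenerate resamples (single-arm, or rank-deficient designs) are
redrawn up to 10× the replicate count and reported in `n_failed`.
Intervals are empirical 2.5/97.5 percentiles with linear interpolation
between order statistics (numpy's default), making them bit-reproducible
given a seed. PM intervals are percentiles of the replicate PM draws
themselves, never transformed from effect intervals. Percentile (not BCa)
intervals are used: they are the transparent default meaning of bootstrap
intervals and keep replicate bookkeeping auditable.

## Synthetic cohort generator

The generator emulates a 52-week two-arm trial: UACR scheduled every
4 weeks; BP and eGFR every 2 weeks to week 8, then every 4 weeks. Each
mediator's change from baseline follows a piecewise-linear ramp
`change(t) = target·min(1, t/plateau_week)` — the simplest one-parameter
curve with the observed "decline then stable" shape, and one that keeps
the cumulative-mean and achieved summaries genuinely different during the
ramp. The plateau target is α·A + b·(baseline − μ) + e with patient-level
noise e ~ N(0, σ_m); default plateaus are week 30 (SBP) and week 24
(eGFR). The endpoint log-UACR change is
δ·A + Σₖ(γₖ + τₖA)·Mₖ + c·(log baseline UACR − μ) + ε, ε ~ N(0, σ_y),
where Mₖ is the summary the configured convention implies for the ramp —
a known multiple sₖ of the target (sₖ = mean ramp height over the schedule
for the cumulative mean; the ramp height just before the endpoint for the
achieved value). Interim UACR values follow the same ramp shape (plateau
week 24) scaled by the endpoint change, so a longitudinal scan sees a
stationary effect past the plateaus. Post-baseline visits are dropped
independently at `missing_rate`; baseline never is. Diastolic BP is a
damped copy of the SBP trajectory (coupling 0.5) with its own noise and
does not enter the outcome equation — it exists to exercise DBP/MAP
sensitivity analyses.

`true_effects` returns the exact estimands of this structural model:
NDE = δ (covariates are centered, and the default interactions are zero)
and NIE = Σₖ(γₖ + τₖ)·sₖ·αₖ, with PM flagged undefined (NaN) when TE = 0.

**Default calibration.** The shipped defaults — n = 449, allocation 0.5,
α_SBP = −4 mmHg, α_eGFR = −3 mL/min/1.73 m², γ_SBP = 0.035 per mmHg,
γ_eGFR = 0.0806 per mL/min/1.73 m², τ = 0, δ = ln(0.503), σ_m = 8,
σ_y = 0.6, missing rate 5% — are a *calibration*, chosen so a default
cumulative-mean joint analysis has true effects near a representative
published decomposition (TE ratio ≈ 0.385, NDE ≈ 0.503, NIE ≈ 0.765,
PM ≈ 28%) with interval widths of similar magnitude. They are not
estimates of any real cohort's parameters. Baseline distributions
(log-UACR N(4.8, 0.8²), SBP N(140, 12²), eGFR N(70, 15²)) and attribute
frequencies are round, field-plausible values for a microalbuminuric
type-2-diabetes population on RAS blockade.

**What the generator does not emulate:** informative dropout (missingness
is independent of everything), visit-window jitter, skewed or
heteroscedastic mediator noise, time-varying path coefficients,
mediator–mediator causal effects, and titration dynamics. Passing tests
therefore certify the estimator against its own model family — linear
structural equations with normal noise — not robustness to model
misspecification on real data.

One random stream (numpy `default_rng(seed)`) is consumed in a fixed
variable-major order — arms, baselines, attributes, mediator disturbances,
outcome noise, missingness — so generation is bit-reproducible and path
coefficient edits that do not change counts leave all other draws intact.

## Numerical conventions

- OLS via `numpy.linalg.lstsq`; rank checked with a pivoted QR, and
  rank-deficient designs are rejected naming the collinear columns (a
  deficiency can arise legitimately, e.g. a mediator that is an exact
  linear function of its own baseline when σ_m = 0).
- Decomposition identities hold to construction precision: TE = NDE + NIE
  (1e−12) and TE ratio = NDE ratio × NIE ratio (1e−10).
- Scans derive per-cell bootstrap seeds as `master_seed + cell_index`, so
  a cell's result is independent of which other cells are requested.
- Publication rendering rounds ratios to 3 decimal places and PM to 1;
  machine-readable CSV output keeps full precision.

## Validation strategy and problem sizes

The suite checks the closed-form estimator against an independent
Monte-Carlo counterfactual oracle (10⁶ draws from the fitted mediator
models pushed through the fitted outcome model, n = 400 cohort; agreement
within 3 MC standard errors), verifies unbiasedness over 200 replicate
cohorts at the default size (mean NDE/NIE/PM within 2 MC SEs of truth),
and measures 95% bootstrap-interval coverage for the NIE over 200
replicates at 400 replications each (accepted range 90–99%). These sizes
give Monte-Carlo error comfortably below the effect magnitudes being
verified while keeping the full suite in the low minutes on one core.

## Known limitations

- Continuous outcomes only; no binary/survival outcomes or rare-outcome
  approximations.
- No sensitivity analysis for unmeasured mediator–outcome confounding.
- No path-specific effects within the mediator block (the joint NIE is
  deliberately not split when mediators may affect each other).
- Exposure-induced mediator–outcome confounders are handled only by the
  joint-mediator device, not by weighting or g-methods.
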