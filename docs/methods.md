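# Methods

`bustdm` reimplements, as an open library, the computational core of a
therapeutic-drug-monitoring (TDM) workflow for IV busulfan in hematopoietic
stem-cell transplant conditioning: fit an individual patient's
concentration–time profile, judge the quality of that fit in a form a
non-pharmacologist can act on, and invert the fitted clearance into a dose
that hits a clinician-specified exposure target.

## Data model and conventions

One analysis unit is a *TDM study*: a single monitored zero-order infusion
(dose `D` mg over `T_inf` min, dosing interval `τ` min, dose number within a
planned course) plus a handful of timed plasma concentrations. Times are
minutes from infusion start; concentrations are mg/L (conversions from
ng/mL, µg/mL and µmol/L — via a configurable molar mass, default 246.3 g/mol
for busulfan — happen at parse time only). Samples carry a reversible
`excluded` flag; excluded points never enter any computation, so a clinician
can remove a suspected contaminated draw and restore it without information
loss. Analysis requires at least 3 non-excluded post-infusion samples; a
rise of more than 20% between consecutive post-infusion concentrations
raises a `non_monotone_decline` warning (advisory, not blocking).

## Compartmental models

Both disposition models assume linear kinetics with zero-order input at rate
`R0 = D/T_inf` for `t ≤ T_inf`:

- **One-compartment** (parameters CL, V; `k = CL/V`):
  `C(t) = (R0/CL)(1 − e^{−kt})` during infusion, monoexponential decline
  after.
- **Two-compartment** (micro constants `V1, k10, k12, k21`; `CL = V1·k10`):
  the biexponential unit-impulse response
  `A e^{−αt} + B e^{−βt}` convolved with the infusion input, where `α, β`
  are the roots of `s² − (k10+k12+k21)s + k10k21 = 0` and `A, B` come from
  the partial-fraction expansion. Built this way the curve is continuous at
  `T_inf` by construction and reduces to the one-compartment form as
  `k12, k21 → 0`.

The macro constants (coefficients and exponents) are always derived from the
micro parameterization; their coefficients of variation are obtained from
the micro-parameter covariance by a first-order delta method and are the
scale on which fit quality is judged. A repeated root (`α = β`) is rejected
as degenerate rather than handled with the `t·e^{−αt}` form: it is a
measure-zero configuration and the optimizer perturbs away from it.

Derived quantities follow the standard single-dose/steady-state identities
of linear kinetics: `AUC(0,∞) = D/CL`, which equals the steady-state AUC
over one interval, hence `Cavg,ss = AUC/τ`; terminal half-life `ln2/k` or
`ln2/β`; `Vss = V1(1 + k12/k21)`.

## Estimation

**Curve stripping** supplies initial values with no population prior. The
terminal window is the last 3 post-infusion points (the last half, floor,
when more than 6 are available — the floor keeps the fast phase out of the
window, which matters: on a reference biexponential with α/β = 10, a
ceil-half window inflates the terminal-slope error from ~2% to ~15%). A
log-linear regression on the window gives `(B, λ)`; residuals of the earlier
points against the terminal line, when at least two are strictly positive
and the residual slope exceeds λ, give `(A, α)`. Stripped post-infusion
coefficients are rescaled by `λT_inf/(1 − e^{−λT_inf})` to unit-bolus scale
before the standard macro→micro inversion.

**Fitting** minimizes the weighted sum of squares
`Σ w_i (C_i − Ĉ(t_i; θ))²` with Levenberg–Marquardt
(`scipy.optimize.least_squares`, method `lm`). Parameters are fitted on the
log scale, which enforces positivity without box constraints and makes the
square roots of the covariance diagonal directly interpretable as parameter
CVs. The default weighting is `1/max(Ĉ, floor)²` (predicted value,
`floor = 0.01` mg/L), refreshed over 3 outer iteratively-reweighted passes;
`1/y²`, `1/y` and unweighted schemes are available in configuration. The
covariance at the optimum is `s²(JᵀJ)⁻¹` with `s² = SS_w/(m−p)`; a
rank-deficient or extremely ill-conditioned (cond > 1e12) Jacobian yields
infinite CVs rather than misleading finite ones. Convergence tolerances:
`xtol 1e-8`, `ftol 1e-10`, evaluation budget 200·(p+1). Hitting the budget
is recorded (`converged=False`), never raised; a fit whose model evaluation
fails outright (parameter underflow during an optimizer excursion) is
treated as a non-converged fit.

**Model selection** is a nested cascade, every threshold configurable:

1. Fewer than 5 post-infusion points → one-compartment only.
2. Otherwise, if stripping found a two-exponential candidate, both orders
   are fitted. The two-compartment fit is accepted only if it converged,
   every macro CV < 50%, `α/β ≥ 2`, and the extra-sum-of-squares F test
   (computed under common observation-based weights so the two models'
   objectives are commensurable; AICc available as an alternative) gives
   p < 0.05.
3. Automatic fallback to non-compartmental analysis when: no compartmental
   fit converged; or the accepted fit carries any parameter CV ≥ 100%; or
   the profile had a non-monotone decline *and* the accepted fit's
   tachometer band is red. All satisfied triggers are recorded as reason
   codes. The clinician can also force the NCA route (`user_override`).

These fallback rules are this package's stated policy, configurable because
no published reference rule exists for this cascade.

## Goodness-of-fit tachometer

Fit quality collapses to a 0–10 score from: the weighted RMSE as a fraction
of the weighted mean observed concentration, and the CV% of each macro
coefficient and exponent. Each metric `m_j` maps through

    s_j = clamp(10 − c·log10(max(m_j, 1e-12)/ref_j), 0, 10)

with defaults `ref` = 0.10 (RMSE fraction) and 25% (CVs), slope `c = 3`
(one decade above reference costs 3 points), combined by an equally-weighted
mean. Bands: green ≥ 7.0, yellow ≥ 4.0, red below — boundaries are `≥`
cut-points hit exactly. The transform is monotone (worse metrics never raise
the score) and an infinite CV scores 0. References, slopes, weights and
cut-points are all configuration, so a site can recalibrate the display
without touching code.

## Non-compartmental analysis

λz comes from a log-linear regression over the best terminal window: all
"last k post-peak points" windows (k ≥ 3) are scored by adjusted r² and ties
within 1e-12 resolve to the larger window; a non-negative best slope is an
error (no terminal phase). AUC to the last sample uses the linear-up /
log-down trapezoid with an implicit (0, 0) anchor at infusion start —
linear on rising or zero-touching segments, `(t₂−t₁)(C₁−C₂)/ln(C₁/C₂)` on
declining ones (exact for a monoexponential through the two points).
`AUC(0,∞)` adds `C_last/λz` using the regression-predicted last
concentration (less noise-sensitive than the observed one; configurable),
and `CL = D/AUC(0,∞)`. Quality flags: extrapolated fraction > 20%
(`high_extrapolation`) and a minimal 3-point window with adjusted r² < 0.95
(`few_terminal_points`).

## Dose simulation

At steady state, linear kinetics make targeting algebraic: per-dose
`AUC = D/CL` and `Cavg,ss = D/(CL·τ)`. Three target kinds are supported —
AUC per dose, Cavg,ss, and cumulative course AUC with a dose-change number
(the remaining `n` doses must supply whatever the first `change_at − 1`
doses have not; an already-exceeded cumulative target is an explicit error).
`recommend_dose` and `exposure_for_dose` are exact inverses. Rounding
what-ifs report the floor/ceiling doses on a 5 mg grid (configurable) with
their full exposure summaries. Recommendations are absolute mg; mg/kg is
shown informatively using the dosing weight. The cumulative-AUC target kind
is an extension beyond classic per-dose targeting and is labeled as such in
reports.

## Synthetic cohorts and validation

The generator draws patients from a lognormal between-subject population:
CL/kg median 0.004 L/min/kg (CV 25%), V/kg median 0.7 L/kg (CV 20%), weight
uniform 8–60 kg, 30% of subjects with two-compartment kinetics
(`k12` ~ logU(0.005, 0.05)/min, `k21` ~ logU(0.002, 0.02)/min, central
volume 40–70% of total). The study design mirrors classic busulfan TDM:
0.8 mg/kg infused over 120 min every 6 h for 16 doses, sampled at
{135, 150, 180, 240, 360} min. Observation error is proportional (CV 10%)
plus additive (SD 0.01 mg/L), truncated at zero by resampling (flooring
available as a toggle). Optional mistimed samples are *drawn* at a perturbed
time but *recorded* at the nominal one, emulating charting errors.

What the generator does not emulate: assay-specific error structure,
covariate-driven (age/organ-function) clearance, accumulation from
preceding doses, or BLQ censoring policies. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
stated error model, not clinical performance on real profiles.

All randomness flows from one `numpy` seed sequence; cohorts are
prefix-stable (the first k profiles of a larger cohort are the k-profile
cohort). A tight-tolerance LSODA integration of the compartmental mass
balance (rtol 1e-10, dose-scaled atol) serves as the independent oracle for
the closed forms. `recovery_study` runs the entire pipeline
(validate → select → fit/NCA → GOF → exposure) over a cohort and tabulates
clearance/AUC bias, selection accuracy, route/reason/flag counts. The
shipped pathology mix (clean 1- and 2-compartment slices, a sparse-schedule
slice, a heavy-noise mistimed slice, and an additive-noise-dominated floored
slice) exercises every analysis route and every automatic reason code at
n = 1000. Validation cohorts default to desk-scale sizes (200–1000 profiles)
chosen so the full suite runs in well under a minute per study; the
generator handles larger cohorts unchanged.

## Numerical choices and limitations

- Exponential-mode responses use `expm1`, so near-zero rates do not lose
  precision; the infusion response is a product of start/stop factors,
  making continuity at `T_inf` structural.
- Closed-form/oracle agreement is asserted over concentrations ≥ 1e-6 mg/L:
  deeper tails sit below any fixed-tolerance integrator's absolute error
  floor (and four orders of magnitude below any assay's quantification
  limit).
- Replicate samples at the same time are allowed and both enter the fit.
  Below-LLOQ values are retained with a warning; exclusion is the
  clinician's decision.
- During-infusion samples, when present, join both the fit objective (same
  weighting) and the NCA trapezoid grid.
- Single-dose analysis only: the studied dose is fitted in isolation, which
  is exact for dose 1 and a deliberate approximation for later doses
  (busulfan's ~2.5 h half-life against a 6 h interval leaves modest
  accumulation; the steady-state identities used for targeting are exact
  under linearity regardless).
- No Bayesian/population estimation, no covariate models, no absorption or
  nonlinear elimination models, and no EHR connectivity — the library ends
  at the report object and its registry.
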