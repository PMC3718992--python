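# Methods

## Model structure

**Pharmacokinetics.** Each drug follows linear one- or two-compartment
disposition with optional first-order oral absorption (rate kₐ,
bioavailability F).  Because the kinetics are linear and the two drugs are
assumed not to interact pharmacokinetically, the multi-dose plasma profile is
the exact superposition of closed-form single-dose responses; profiles are
stored as sums of terms c·(t−t₀)ᵖ·e^(−r(t−t₀)) anchored at the dose times.
No ODE integration enters the PK layer, so no integration tolerance leaks into
the fits.  AUC, truncated AUC and the area under the *product* of two profiles
(AUC_{c_a c_b}, the quantity that drives the interaction term) are integrated
analytically term by term, segment by segment between dose times.  The
degenerate oral case kₐ = k uses the confluent t·e^(−kt) form, triggered when
the relative rate gap falls below 1e−8.  Units are fixed: days, μM, μmol/kg
("μM/kg"), L/kg; mg/kg doses must be converted with the molar mass before
entry — there is no unit guessing.

**Tumor growth and drug effect.** Controls follow the exponential-to-linear
growth law with parameters w₀ (g), λ₀ (day⁻¹), λ₁ (g·day⁻¹) and switch
sharpness Ψ.  Ψ is not identifiable from typical data and is fixed at 20,
which keeps the right-hand side smooth while staying within 2 % of the hard
switch limit (verified against the Ψ→∞ closed form in the tests); it is
exposed as a setting.  Each drug contributes a potency k₂ (μM⁻¹day⁻¹) acting
on proliferating cells and a transit rate k₁ (day⁻¹) through three damage
stages; k₁ is mechanism-linked and deliberately *not* shared between drugs.
The combination state space is the 4×4 grid x_ij (i = damage stage by drug A,
row index; j = by drug B; stored row-major, x_00 … x_33 — this convention is
fixed in `models.py` and used everywhere, including CSV export).  The single
interaction flow moves proliferating cells x₀₀ → x₁₁ at rate γ·c_a·c_b·x₀₀.

**Mass-balanced flow form.** All transfers are written conservatively: a hit
on x₀ⱼ by drug A removes mass from x₀ⱼ at the same rate k₂ₐ·c_a at which x₁ⱼ
receives it (and symmetrically for drug B), so total weight obeys
dw/dt = f_p(w) − k₁ₐ·Σⱼx₃ⱼ − k₁ᵦ·Σᵢx_i₃ exactly; a finite-difference check of
this identity is part of the acceptance suite.  Casual renderings of the model
that set the i = 0 / j = 0 margin equations to pure inflow terms create mass
out of nothing; the flow form here is the physically meaningful reading.

**Negative γ.** The model admits γ < 0, but once the net kill rate on
proliferating cells, k₂ₐc_a + k₂ᵦc_b + γc_ac_b, goes negative, drug exposure
would *create* cells.  Simulation then still proceeds (nothing is clamped) but
a `ModelValidityWarning` reporting the offending time span is emitted.  In
that regime transients can be violently fast; quantitative checks in the test
suite use mildly antagonistic settings that stay inside the validity region,
while sign-recovery simulations deliberately cross it, as real antagonistic
datasets may.

## Numerics

Integration uses LSODA with rtol 1e−8 / atol 1e−10 for reported trajectories
and rtol 1e−6 / atol 1e−9 inside optimization loops.  Integration restarts at
every dose time so iv-bolus concentration jumps never sit inside an adaptive
step.  Solver undershoots below zero are clipped to 0 in stored trajectories
with the maximum clipped magnitude recorded on the trajectory.  Finite
differences for optimizer Jacobians use a relative step of 1e−4: large enough
to sit above the ODE-tolerance noise floor, small enough for curvature not to
bias the gradient (the √ε default stalls the optimizer, a failure mode we
guard against explicitly).

## Estimation

Stage 1 fits (w₀, λ₀, λ₁, k₁ₐ, k₂ₐ, k₁ᵦ, k₂ᵦ) simultaneously to the control
and single-agent arms, sharing the tumor parameters across arms.  Stage 2
fixes those and fits γ alone to the control plus combination arms (the control
carries no γ information but is included as fitted data, which feeds the
residual-variance estimate).  A joint 8-parameter fit exists for comparison.

* **Objective.** Σ_arms (1/n_arm)·Σ_obs (y−ŷ)²/y².  The 1/y² weights encode
  constant relative error; the 1/n_arm factor gives every arm the same total
  weight regardless of sampling density.  This equal-mean-contribution reading
  is the simplest implementation of per-arm residual normalization; an
  alternative (scaling by each arm's residual variance) would make the weights
  data-dependent and is noted but not used.
* **Optimizer.** Bounded trust-region least squares (`scipy.optimize.
  least_squares`, TRF) on log-transformed positive parameters; γ is fitted on
  the natural scale within [−100, 100] (a warning fires if the optimum hits a
  bound) after a coarse sign-symmetric log-spaced bracket.  Stage 1 uses
  multi-start: one data-driven heuristic start (log-linear fit to the early
  control points for w₀ and λ₀, late slope for λ₁, exposure-scaled potency
  guess) plus seeded log-uniform random starts, 8 by default.  The simulation
  studies below use 2 starts — on synthetic data the heuristic start converges
  reliably, and the study sizes were chosen to keep the full suite desk-scale.
* **Uncertainty.** Asymptotic: cov = s²(JᵀJ)⁻¹ from the scaled-residual
  Jacobian at the optimum (chain-ruled back to the natural scale),
  s² = SSR/(N−p), reported as CV% = 100·se/|estimate|.  A rank-deficient
  Jacobian yields flagged undefined CVs rather than an exception.  How the
  original analyses computed their CVs is not documented; this is the standard
  nonlinear-WLS choice.
* **RMSE** is unweighted, in grams, over the arms being fitted (combination
  arm for stage 2, all fitted arms pooled for stage 1 — the pooling choice is
  this package's, made explicit here).

## Interaction indexes

TEI_comb, Δ, TEI_add use the closed forms with all AUCs taken to infinity
(full washout), consistent with the asymptotic definition of the delay.  The
numeric route measures horizontal shifts between simulated combination, γ = 0
(PTGC) and control curves at a reference weight, default w_ref = 2·λ₁/λ₀ —
well inside the linear regrowth regime, where the delay has converged; the
asymptotic definition gives no operational recipe, so this is the package's
choice and it is configurable.  Time-at-weight uses the *last* upcrossing
(treated tumors shrink before regrowing) with linear interpolation.  |Δ| below
1e−6 days is treated as numerically zero: neither SC nor AC is reported and
the interaction is classified additive; otherwise SC (Δ > 0) or AC (Δ < 0) is
reported, and classification against γ̂ ± 1.96·se is used when a standard
error is available.  Whether published index values were computed from the
closed forms or from curves is not documented; both routes are provided and
agree to well under a percent in the washout scenarios tested.  The PTGC is
*defined* here as this model with γ = 0; whether it coincides numerically with
Bliss-independence zero-interaction constructions for every regimen is not
assumed.

## Synthetic data

The generator is the test bed for every estimation property, because the
underlying animal data exist only as published figures.  It simulates
noise-free group-mean curves per arm, draws n per-animal observations as
truth·(1 + cv·N(0,1)) (proportional noise — matching the 1/y² estimator
weights by construction; an additive-noise option is deliberately omitted so
recovery tests probe the estimator under its own assumptions), truncates
negative draws at 1e−4 g with a logged count, and reports mean ± SE (sd/√n).
Defaults: cv = 0.10, n = 8 animals/group, sampling every 3 days from day 8 to
41 (12 occasions), matching common xenograft practice.  Schedules come from
the eleven published combination arms (fixtures a1–f2), including the
half-day-spaced twice-daily regimens and the 0.25-day offset of the daily iv
drug on days it shares with CPT-11.  The shipped PK library and PD preset
(`example_pk_library`, `example_model_spec`) are *plausible synthetic
placeholders* chosen once for realistic magnitudes (drug half-lives of hours,
control switch to linear growth around day 23, single-agent delays of ~5 days,
interaction shift ~10 days at γ = 0.8); the true PK/PD values of the published
experiments are not public and are never hard-coded.

What the generator does **not** emulate: inter-animal parameter variability
(group means only), dropout/sacrifice, size-dependent measurement error, PK
interaction between the drugs.  Passing recovery tests therefore show the
estimator works when the model and noise assumptions hold; they do not certify
behavior under model misspecification.

## Study sizes in the acceptance suite

Recovery: 20 replicate experiments at cv = 0.10, γ_true = 1.0, staged fit with
2 starts (median relative error on γ̂ is the acceptance quantity).  Null
coverage: 50 replicates at γ = 0 with the interaction stage run at the true
single-agent parameters, 95 % CI coverage counted.  The acceptance *script*
uses 10 recovery and 20 null replicates and reports the same quantities; sizes
are the package's own desk-scale choices.

## Known limitations

* Linear (non-saturable) kill terms; nonlinear drug effects would have to be
  learnt in single-drug studies and substituted for k₂·c(t).
* Group-mean (naive-pooled) fitting only — no mixed-effects estimation,
  no bootstrap (asymptotic CIs only), two drugs only.
* γ is regimen-transportable only within a reasonable dose range; the indexes,
  not γ itself, are the cross-experiment comparison currency, since γ's value
  scales with the drug potencies and exposures.
* The closed-form indexes assume full washout and treatment early relative to
  the observation window; for treatments extending close to the end of
  observation, use the numeric route with an extended horizon.
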