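# Methods

## Model

The plasma concentration after an arbitrary dosing history is the
convolution of a parametric in-vivo input rate with the disposition unit
impulse response (UIR):

    Cp(t) = Σ_doses F·D_k · ∫₀^{t−t_k} (dr/dτ)(τ) · UIR(t − t_k − τ) dτ

`r(t)` is the cumulative fraction of dose released, from one of three nested
families: exponential (`1 − e^{−t/TD}`), single Weibull
(`1 − e^{−(t/TD)^SS}`) or a double-Weibull mixture with fraction `FF` in the
first process. `TD`-type parameters are the times to release 63.2 %
(1 − 1/e) of a process's dose, in hours; `SS`-type parameters are
dimensionless sigmoidicities. The UIR is mono- or bi-exponential (one or two
compartments), parameterized by apparent clearance `CL/F` (L/h) and
volume(s) (L); relative bioavailability is fixed at 1 and folded into the
apparent parameters, since no intravenous reference data constrain it.
Doses are in mg and concentrations reported in ng/mL (mg/L × 1000), the
conventional scale for paliperidone. Elimination is linear throughout;
saturable elimination is out of scope.

All release fractions `FF` are dimensionless fractions in [0, 1]. Published
tables for these products sometimes label `FF` "(%)" while printing values
like 0.676; values above 1 never occur, and only the fractional reading
makes the release mixture well-formed, so the percent label is treated as a
labeling slip and fractions are used everywhere.

### Product presets

`presets.yaml` ships the published population estimates for the oral
extended-release product (ER) and the 1- and 3-monthly depots (PP1M, PP3M),
each with its study dose groups, plus the hypothetical once-yearly product
(PP12M: TD = 22 h, SS = 1.6, TD1 = 180 h, SS1 = 2.13, FF = 0.2768), which
reuses the PP3M disposition (CL/F = 4.38 L/h, V/F = 11,700 L) — the
convention under which that product was explored. Calendar conventions for
regimen grids: 1 month = 720 h, 3 months = 2160 h, 1 year = 8760 h.

## Numerical realization of the convolution

Three interchangeable engines compute the same model; their agreement is a
standing test:

1. **ODE path** (`simulate_ode`): `dAp/dt = Σ F·D·(dr/dt) − kel·Ap`,
   `Cp = Ap/V`, integrated with LSODA at rtol 1e−8 / atol 1e−10 (mg scale).
   Integration restarts at every dose time so the solver never steps across
   an input discontinuity, the segment-end state is always evaluated
   explicitly, and each segment's first step is capped at 1/50 of the
   fastest release time scale so a sub-hour release pulse cannot be stepped
   over. The input rate uses the closed-form derivative of `r` by default;
   the central-finite-difference form `[r(t+Δ) − r(t−Δ)]/(2Δ)` is selectable
   (`rate="fd"`). Note the sign: the mathematically correct central
   difference is used — a non-decreasing `r` must give a non-negative rate
   (printed forms of this difference sometimes reverse the numerator; that
   is a typographical slip, not a modeling choice). The default step
   Δ = max(1e−4 h, 1e−4·t) balances truncation and round-off across the
   0.1 h–10,000 h range spanned by oral and depot products.
2. **Quadrature path** (`simulate_quadrature`): adaptive Gauss–Kronrod
   quadrature of the convolution integral per output time; the slow,
   independent oracle.
3. **Exponential-integrator path** (`simulate_expint`): because the UIR is a
   sum of exponentials, each mode obeys the exact recurrence
   `S(b) = S(a)e^{−λ(b−a)} + ∫ₐᵇ q(τ)e^{−λ(b−τ)}dτ`; interval integrals are
   7-point Gauss–Legendre on knots log-spaced across each dose's release
   window (64 per dose). This is ~30× faster than LSODA at ~1e−7 relative
   accuracy and is the default engine inside iterative fitting and design
   loops.

**Dose-instant singularity.** A sigmoidicity < 1 (the ER preset's slow
process has SS1 = 0.395) makes the Weibull rate diverge integrably at the
dose instant. Direct rate queries below ε = 1e−6 h are clamped to the value
at ε, with a warning. The simulation engines instead add the analytically
known mass released within [0, ε] (`F·D·r(ε)`) to the amount state as a jump
at the dose time and integrate the exact rate from ε onward — this conserves
mass to machine precision, whereas integrating a clamped rate would lose the
~0.25 % of dose the ER preset releases inside the first microhour of each
dose.

## Estimation

Fitting is pooled maximum likelihood under a proportional residual error:
`y_i = f_i·(1+ε_i)`, `ε ~ N(0, σ²)`, i.e. sd_i = σ·|f_i|, with an sd floor
of σ·1e−6 ng/mL so structural zeros at pre-dose times cannot produce an
infinite density; rows with zero concentration before the first dose are
dropped with a log message (no censored-data likelihood — the mean-profile
datasets this package targets contain no below-quantification records).
σ is profiled out analytically, positive parameters are estimated on the
log scale and fractions on the logit scale, and L-BFGS-B runs from a
user-supplied start plus `n_starts − 1` log-uniform ±50 % jitters (seeded;
default 10 starts — Weibull mixtures have local optima). Standard errors
come from the central-finite-difference Hessian of the full −2LL at the
optimum (covariance = 2·H⁻¹), delta-method-mapped to the natural scale; RSE%
= 100·SE/estimate. The reported parameter count k includes all estimated
quantities (structural thetas + σ + any ωs), the convention used for AIC
(−2LL + 2k) and BIC (−2LL + k·ln n).

**Label switching.** The double-Weibull mixture is exactly invariant under
swapping (FF, TD, SS) ↔ (1−FF, TD1, SS1). After optimization the labeling
closer to the initial values (log-scale distance) is reported; this changes
nothing about the fit, only which process is called "first", and keeps
recovery studies interpretable. Independently, a fit is flagged when FF
lands at a boundary or TD ≈ TD1 — the nested single-Weibull degeneracy.

**Random effects.** `fit_mixed_laplace` marginalizes per-occasion log-normal
random effects on named parameters by Laplace approximation: for each
occasion the conditional mode of η is found (warm-started across outer
iterations) and the marginal −2LL contribution is
`g(η̂) − q·log 2π + log det(½∇²g)`. The outer problem (thetas, log ω, log σ)
is solved with Nelder–Mead, since inner-optimization noise defeats
finite-difference gradients. ω → 0 reduces analytically to the pooled
likelihood (ω < 1e−8 short-circuits to it exactly); a singular inner Hessian
triggers a warning and a pooled refit. This is a deliberate small-data
stand-in for full conditional-estimation mixed-effects machinery: the data
this package fits are mean profiles per dose group, where inter-occasion
variability is a second-order refinement, so pooled ML is the default and
the validated path.

**%PE.** Percent prediction error is 100·(obs − pred)/obs (under-prediction
positive), zeros excluded with a reported count, pooled across dose groups;
the mean's 95 % CI is normal-approximation by default with a seeded
percentile bootstrap as an option (published comparison tables show
symmetric CIs, hence the normal default).

## Synthetic data

The generator emulates the mean concentration curve per dose group of the
product studies: noise-free curves simulated from a preset at its published
dose groups, multiplied by `1 + ε`, `ε ~ N(0, CV²)`, CV = 5 % by default,
one occasion per dose group, deterministic per seed. Sampling schedules are
a design choice (the source studies' exact times are not published): ER is
sampled densely over 0–96 h (24 points), PP1M over 0–2160 h (33 points), and
PP3M with 40 points over 0–8760 h of which 26 lie inside the < 100 h release
window — release-parameter information lives entirely in the absorption
phase, and a log-even spread over the year was verified to leave the mixture
fraction with ~12 % RSE, too little information for any optimizer to recover
it to a few percent. What these data do **not** emulate: between-subject
variability, sparse/irregular clinical sampling, assay quantification
limits, injection-site effects and digitization error of real mean curves.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the stated noise model, not field performance on clinical
data.

Recovery is summarized by the across-seed mean estimate (20 seeds in the
acceptance script; the per-seed ML estimates of the mixture parameters
scatter with RSEs up to ~20 % at 5 % noise, roughly symmetrically, so the
seed average is the meaningful bias measure). Acceptance-scale fits use 4
multi-starts; at these well-conditioned starting conditions (30 % offset)
all starts reach the same optimum, and the smaller start count is a
problem-size choice.

## Traditional comparators

The three comparator structures are implemented from their published
*descriptions* (their parameter estimates were never published in
accessible form): ER — two-compartment disposition with lagged zero-order
input followed by first-order absorption; PP1M — one-compartment with
parallel zero-/first-order input; PP3M — one-compartment with two parallel
saturable inputs, each a Hill function *of time*
(`t^γ/(T50^γ + t^γ)` scaled by its dose fraction, slow-process γ > 1
enforced). The time-Hill reading of "saturable process parameterized with a
Hill function" is an interpretation; an amount-dependent Michaelis–Menten
depot would need an extra scale parameter and does not produce the described
γ > 1 sigmoidal onset as directly. Defaults are chosen to produce realistic
product-shaped curves for exercising the comparison machinery, and each
model is validated against closed forms in its reducible limits (pure
first-order, constant infusion, Hill half-point, mass balance).

## Regimen design

Steady state is detected by simulating 4, 8, 16, … intervals until the last
two interval profiles agree within 1 % (configurable), up to a cap of 60
intervals, with a warning if unattained. Exposure metrics over the last
interval: Cmax, Cmin, Cavg = AUC_τ/τ (trapezoidal), fluctuation
(Cmax − Cmin)/Cavg. Concentrations map to D2 receptor occupancy through the
static Emax model `Emax·C/(EC50 + C)` with Emax = 100 % and EC50 = 4.9
ng/mL; `time_in_window` measures the fraction of an interval spent in the
60–80 % occupancy band.

Exposure matching implements two criteria because "similar steady-state
exposure" is underdetermined: (i) **Cavg matching** — exact under dose
linearity, since Cavg = F·D/(CL·τ) independent of release shape (asserted
numerically across presets); (ii) **L2 matching** — minimize the mean
squared difference of log steady-state concentrations over the candidate
interval, tiling the shorter-interval reference periodically. For a fixed
candidate the L2 problem is quadratic in log dose and solved in closed form
(the geometric-mean concentration ratio). For the once-yearly product these
give 1420 mg and 2043 mg respectively against the PP3M 350 mg q2160 h
reference — bracketing the published 1600 mg figure, whose criterion was not
stated. `design_release` searches release parameters (optionally co-optimizing
dose) by Nelder–Mead on the same log-profile loss; a flat target is rejected
(no dose of a washed-out linear system produces a constant profile).

## Known limitations

- The Laplace path supports diagonal Ω only, and its standard errors share
  the outer finite-difference machinery — adequate for the small-occasion
  datasets targeted here, not for rich population data.
- `superpose` interpolates a single-dose profile (PCHIP); its accuracy is
  bounded by the density of the single-dose grid, unlike the engines, which
  superpose inputs exactly.
- The Emax occupancy map is static; no effect-compartment delay or PD model
  is attached.
- Recovery guarantees are for the synthetic study conditions above; real
  digitized mean curves carry structured (non-proportional) error this
  package does not model.
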