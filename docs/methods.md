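# Methods

## The problem

A transcription factor in solution binds surface-tethered double-stranded
DNA probes in a label-free biosensor flow cell.  Two probe classes are
measured side by side: probes carrying the factor's consensus site
("specific") and probes of the same length without it ("nonspecific").  The
instrument reports the surface mass density σ(t) of bound protein per spot
during a stepwise titration in which the analyte concentration c is raised
through a doubling ladder (default 0.08 → 40.96 nM, capped by a final 50 nM
step, 3000 s per step, 30 °C, 150 mM NaCl).  The scientific question is how
much of the apparent affinity to the specific probe is genuinely
sequence-specific docking and how much is the nonspecific background that
any DNA provides — and, across temperature, how the specific gain splits
into enthalpy and entropy.

## Nested-well kinetic model

Binding is modelled as two sequential reactions along a conformational
coordinate: the protein first contacts the DNA nonspecifically (outer well),
and only from that state can it dock onto the consensus site (inner well):

    unbound  ⇌(kon1·c / koff1)  nonspecific  ⇌(kon2 / koff2)  specific

There is no direct unbound → specific channel: specific recognition is
reached through nonspecific contact.  With occupancies θ1 (nonspecific) and
θ2 (specific) as fractions of probe sites,

    dθ1/dt = kon1·c·(1 − θ1 − θ2) − koff1·θ1 − kon2·θ1 + koff2·θ2
    dθ2/dt = kon2·θ1 − koff2·θ2

Units are fixed: c in nM, time in s, kon1 in s⁻¹·nM⁻¹, the other rates in
s⁻¹.  Two equilibrium coefficients follow: K1 = koff1/kon1 (nM), the
nonspecific dissociation constant, and K2 = koff2/kon2 (dimensionless), the
ratio of nonspecifically to specifically bound protein at equilibrium.
Small K2 means strong selectivity.  The whole system equilibrates on a
Langmuir isotherm with the effective dissociation constant

    Kd = K1·K2/(1 + K2),    inverted as    K2 = Kd/(K1 − Kd).

Relaxation after a concentration step is a double exponential,
σ(c,t) = Σ(c)·(1 − B·e^(−t/τL) − (1−B)·e^(−t/τS)), whose times are the
negative reciprocal eigenvalues of the 2×2 rate matrix.  The discriminant
equals (kon1·c + koff1 − kon2 − koff2)² + 4·kon2·koff1, which is strictly
positive whenever kon2 > 0, so the eigenvalues are always real and distinct;
kon2 = 0 is the single-well limit, handled as an exact single exponential
with rate Γ(c) = kon1·c + koff1.  B, τS, τL and the mode amplitudes are
computed from the eigen-decomposition with initial condition θ = (0, 0) (or
the carried-over θ at later injections) rather than from tabulated formulas,
and are validated against an independent LSODA integration of the rate
equations (`ode_oracle`, agreement < 1e-8 over random parameter draws).

When the inner exchange is much faster than surface binding
(kon2 + koff2 ≫ 1/τ1, with τ1 = 1/(kon1·c + koff1)), τL approaches the
limit τL∞ = 1/(kon1·c + koff1·K2/(1+K2)) = 1/(kon1·(c + Kd)): the system
behaves as a single well with the effective Kd, B → 1, and the kinetics is
nearly exponential.  τL∞ > τ1 always — nesting can only slow the response.

Assumptions: excess analyte (c constant within a step, no depletion),
independent identical probe sites, no mass-transport limitation, at most one
protein per probe strand, no direct unbound → specific transitions.

## Synthetic data generator

`synthetic` produces the fixtures every other module is tested on.  A trace
is the exact piecewise analytic nested-well solution scaled by the
saturation density Σ∞, sampled at fixed intervals (default 10 s), plus
additive i.i.d. Gaussian noise; each trace's random stream is derived from
(seed, spot_id), so fixture sets are order-independent and fully
reproducible.  A probe pair shares Σ∞, kon1 and koff1; the specific member
adds the inner-well rates, the nonspecific member has kon2 = 0.

Default parameters are the measured study conditions: K1 = 200 nM (midpoint
of the 160–240 nM nonspecific range), K2 = 0.16 (the selectivity at 150 mM
NaCl), kon1 = 1.6e-5 s⁻¹·nM⁻¹, hence koff1 = 3.2e-3 s⁻¹ (≈300 s residence)
and Kd_eff ≈ 27.6 nM.  The inner-exchange default kon2 = 5e-2 s⁻¹ places the
generator in the fast-exchange regime (docking on a ~20 s timescale, versus
300–2000 s for the surface response), which is the regime the measured
kinetics indicate (τL ≈ τL∞, nearly exponential steps); kon2 itself is then
only weakly identifiable, exactly as in the real experiment, and tests that
need all four rates identifiable use a moderate kon2 = 1e-3 s⁻¹ fixture
instead.  Step duration 3000 s keeps even the slowest synthetic mode
(τL∞ ≈ 2.3e3 s at the lowest concentrations) near saturation within a step.

The K2(T) generator evaluates K2 = exp(ΔH/RT − ΔS/R) (defaults
ΔH = −12.8 kcal/mol, ΔS = −38.7 cal/(mol·K)) on a 6-point grid
288.15–310.15 K — the grid is a package choice, as the condition series it
emulates does not fix one — with optional multiplicative lognormal noise,
the natural noise model for a positive coefficient estimated on a log scale.

What the generator does *not* emulate: optical raw-signal conversion,
baseline drift (an option exists but is off by default), injection mixing
transients (the fitting layer's discard window is exercised with an explicit
spike fixture instead), probe-density effects, and analyte depletion.
Passing tests therefore demonstrate correctness of the analysis given the
model, not robustness to every instrumental artifact.

## Fitting pipeline

**Per-step reduction.**  Each injection is fitted by
σ(t) = σ_prev + (Σ(c) − σ_prev)·(1 − e^(−Γ(t−t0))) after discarding a 10 s
post-injection window (configurable).  Σ(c) is stored as the *absolute*
asymptote so it feeds the isotherm directly; σ_prev for step i+1 is step i's
fitted model evaluated at the injection time, so incomplete saturation
propagates instead of biasing the next increment.  Initialization: Γ from
the half-rise time, Σ from the last-decile mean.  If a step's rise is below
3× the noise estimate (from first differences) the step is flagged unusable
rather than fitted.  The initial slope is computed analytically as
σ'(c) = Γ·(Σ − σ_prev) for noise robustness; a finite-difference diagnostic
exists.  Standard errors come from the Jacobian at the optimum (unweighted
least squares per step, tight tolerances 1e-14).

**Isotherm.**  Σ(c) of the paired probes is fitted globally with
Σ(c) = Σ∞·c/(c + Kd), one shared Σ∞ and one Kd per class — the shared
asymptote encodes that the probe hosts the same maximal protein load with or
without the consensus site.  Identifiability warnings are attached when the
ladder is entirely below or entirely above the fitted Kd.

**Association rate.**  σ'(c)/Σ∞ is regressed through the origin against a
concentration regressor, pooling both classes into a single kon (the
measured class difference is below its uncertainty); koff = Kd·kon per
class.  Three regressors are offered.  The plain ``c`` regressor reproduces
the conventional plot but is exact only for binding that starts from empty
probes: on a doubling ladder, where each increment is about half the
concentration and late steps are partially saturated, it underestimates kon
severalfold.  ``delta_c`` removes part of that bias.  The closed-form
per-step slope is σ'/Σ∞ = kon·Kd·(c − c_eq)/(c_eq + Kd) with
c_eq = Kd·σ_prev/(Σ∞ − σ_prev) the concentration equivalent of the actual
baseline; the ``corrected`` regressor uses it and is unbiased across the
full ladder (to within the small finite-exchange correction on the specific
trace).  The default remains ``c``; recovery-oriented analyses should use
``corrected`` or, on single-well traces, the Γ-line fit Γ(c) = kon·c + koff,
which is exact there.

**Selectivity and uncertainty.**  K2 = Kd_sp/(Kd_ns − Kd_sp).  Its standard
error uses first-order propagation with the full (Σ∞, Kd_sp, Kd_ns)
covariance; a seeded residual bootstrap (default 500 resamples) is available
because the first-order error diverges as Kd_sp → Kd_ns.  Kd_sp ≥ Kd_ns is
a hard error: a specific probe cannot bind more weakly than its nonspecific
reference.

**Joint kinetic fit.**  Both raw traces are fitted simultaneously to the
nested-well solution in (log kon1, log K1, log kon2, log K2, Σ∞) to enforce
positivity, initialized from the stepwise/Langmuir estimates.  The result
reports whether the fit sits in the fast-exchange regime (τL within 5% of
τL∞ at every step of the ladder) and flags kon2 as a lower bound when its
log-scale standard error exceeds one e-fold; a fitted K2 > 50 is flagged as
collapse to the single-well model.

**Thermodynamics.**  ln K2 is regressed on 1/T (weights (K2/se)² when
per-point errors are supplied): slope·R = ΔH, −intercept·R = ΔS, with
R = 1.987e-3 kcal/(mol·K).  ΔG(T) = ΔH − T·ΔS = RT·ln K2(T) holds
identically by construction.  Because K2 is a dissociation-like ratio
(nonspecific over specific), ΔG = RT·ln K2 is *negative* when specific
docking is favoured — the sign convention is inverted relative to the usual
association convention and is kept deliberately.

## Numerical choices

- Eigen-decomposition via the explicit 2×2 quadratic; the discriminant is
  clamped at zero but is provably positive for valid nested-well rates, so
  no critically-damped branch is needed (the single-well case is exact).
- ODE oracle: LSODA, rtol 1e-11, atol 1e-13, re-anchored at every injection.
- All nonlinear fits: lmfit/MINPACK with xtol = ftol = gtol = 1e-14.
- K2 ↔ Kd round trip is guaranteed to 1e-12 relative only for K2 ≲ 1e3; the
  subtraction K1 − Kd amplifies rounding by ~(1 + K2), and beyond that the
  inverse is intrinsically ill-conditioned (Kd indistinguishable from K1).
- Degenerate inputs: flat steps are flagged, not fitted; Γ-line slopes
  indistinguishable from zero (kon < 2 se) return kon = 0 with a
  no-binding-signal flag; nonpositive K2, Kd or T raise typed errors.

## Problem sizes

Default analyses run on 11-step × 3000 s traces sampled at 10 s (3300
points per trace); the stochastic suites use 1000 random parameter draws
for the model invariants and 200 seeded replicates at 1% noise (sampled at
30 s) for the recovery calibration.  The whole test suite runs in well
under a minute on one core.

## Known limitations

- The ionic-strength dependence of K1, K2, kon is treated as tabulated
  per-condition input; no counterion-release model is fitted.
- Σ∞ is reported in instrument units; conversion to proteins-per-probe
  requires an instrument calibration that is out of scope.
- The per-class kon option exists but the pooled estimator is the default;
  with strongly unequal class kinetics the pooling assumption should be
  re-examined.
- Uncertainties from the per-step layer are propagated first-order; step
  fits on strongly double-exponential data (slow inner exchange) carry a
  model error that the quoted σ's do not include — the joint kinetic fit is
  the right tool there.
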