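# Methods

## Scope and model structure

The package estimates inertial delay — the minimum time to complete a
corrective movement under bounded muscle torque — for two idealized tasks
spanning the terrestrial-mammal size range, and expresses the results as
allometric power laws of body mass `M` (kg).

Both tasks are single-degree-of-freedom pendulums driven by a bang-bang
torque profile, the time-optimal strategy for a double integrator with a
symmetric torque bound. Muscles are assumed to switch between maximal
torques instantaneously: no activation/deactivation dynamics, no
force–velocity limits, no feedback loop. The computed delays are therefore
lower bounds on real movement times.

### Swing task

A distributed-mass pendulum hanging from the shoulder pivot:
`θ̈ = T/MOI − (M_limb g L_COM/MOI)·sin θ`, θ measured from the hanging
equilibrium. The movement magnitude is the **total excursion** Δθ; the
pendulum starts at rest at −Δθ/2, receives +T until the zero-angle
crossing, then −T until the angular velocity crosses zero. Because gravity
is conservative and the torque work is antisymmetric about the bottom of
the arc, the terminal angle is exactly +Δθ/2 (asserted to 1e-6 rad).

The gravity term restores toward the hanging equilibrium. A limb hanging
below its pivot admits no other sign; the destabilizing alternative is
available (`restoring_gravity=False`) for sensitivity checks but lengthens
delays at large amplitudes instead of shortening them, contradicting the
reference values the restoring sign reproduces. Gravity is a small
correction throughout (the 60° delay of a 1 kg animal is 43.3 ms versus
44.0 ms gravity-free) but grows in relative importance with mass, which
is what pulls the fitted exponent slightly below its gravity-free value
at large magnitudes.

### Posture task

A point-mass inverted pendulum on massless legs:
`θ̈ = T/(M L²) + (g/L)·sin θ`, θ from vertical, gravity destabilizing.
The perturbation is a forward push expressed as dimensionless velocity
`v_ND = v/√(gL)` (a Froude-like measure that evokes comparable responses
across sizes); the initial state is (0, −v_ND·√(g/L)). The counter-torque
+T acts first and reverses once, at a switch time chosen so that the
pendulum reaches upright exactly as its velocity vanishes.

The switch time is found by shooting: the position residual at the moment
the velocity returns to zero is monotone in the switch time, with a
guaranteed sign change between the instant the fall stops and the instant
the pendulum re-passes vertical under +T. Brent's method on that bracket
needs no initial guess and cannot diverge; the gravity-free closed form
(switch at 1/√2 of the total time) is used only for time scaling. Both
boundary conditions are met to 1e-6 (rad, rad/s).

Feasibility is decided by the braking arc alone: the pendulum escapes
capture once it passes the angle where gravity torque exceeds muscle
torque (`M g L sin θ_c = T`). The capture limit is found by bisection on
v_ND to 1e-3; an energy-balance closed form serves as an independent
oracle in the tests. Animals whose combined ankle torque exceeds `M g L`
(roughly ≤ 1 kg with the default tables) can recover from arbitrarily
fast pushes, and the search reports an infinite limit.

## Parameters

All size dependence enters through power laws `a·M^b` packaged as CSV
tables (coefficient = value at 1 kg, SI units, with 95% CIs):

* swing: forelimb mass (5.82e-2·M^1.00 kg), COM length
  (5.64e-2·M^0.36 m), MOI about the shoulder (2.52e-4·M^1.75 kg m²),
  triceps mass/length/moment arm;
* posture: forelimb and hindlimb lengths (pendulum length is their mean,
  so the point mass sits at a whole-body COM height), ankle-extensor
  mass/length/moment arm.

Muscle torque: volume = mass/density (1060 kg/m³), PCSA = volume/length,
force = PCSA × isometric stress (20 N/cm² = 2e5 N/m²; mammalian estimates
span 7–148 N/cm², hence the built-in torque-sensitivity analysis), torque
= force × moment arm. The shoulder antagonists are assumed to mirror the
triceps laws (one symmetric torque bound); the posture task multiplies
one ankle-extensor group by four legs. Gravity defaults to 9.81 m/s²;
density, stress, gravity, and the torque bound are all overridable.

Grids: seven masses geometrically spaced over 1 g – 10 t; swing
magnitudes 1–60° (10 log-spaced levels) for the headline fits — the
exponent is nearly flat in magnitude, so the average is insensitive to
the exact grid; posture perturbations 0.01–0.49 v_ND (15 log-spaced
levels), the upper end being the 10 t capture limit (0.496 computed here).

## Fitting and uncertainty

Per magnitude level, `log10(delay)` is regressed on `log10(M)` by OLS;
the intercept back-transforms to the 1-kg coefficient and the slope is
the exponent. Headline exponents are unweighted means across magnitude
levels. Fitted coefficients grow as √Δθ (swing) and nearly linearly in
v_ND (posture), matching the closed forms.

Monte Carlo: each draw samples every law's exponent from a
t-location-scale distribution (df = 20 by default; the source sample
sizes are unpublished) with scale = CI half-width / t-critical, and the
coefficient the same way on the log10 scale (positivity preserved). Draws
are independent within and across laws because the within-regression a–b
correlation cannot be recovered from printed intervals — the main reason
the resulting CIs are slightly wider than ones fitted to raw morphometric
data would be. CIs are the baseline point estimate ± 1.96 × sample SD,
with 500 draws in the scaled-down default (10,000-draw runs change the
endpoints by well under the reporting precision). The posture propagation
uses v_ND = 0.10 as its representative level: the sampled capture limit
of a 10 t animal ranges down to ≈ 0.19, so levels ≳ 0.2 make an
appreciable fraction of draws infeasible at the largest mass, while the
exponent itself is nearly flat across levels. Draws with any failed cell
are discarded; more than 1% failures aborts the run.

## Response times

Sensorimotor delay scales as M^0.21. Its magnitude is fixed by an anchor
convention rather than an external coefficient: it equals the swing
inertial delay of a 30° movement at 1 kg (≈ 31 ms), evaluated from the
fitted coefficient-versus-magnitude law so the crossover construction is
exact at the anchor. The posture analysis uses the analogous anchor
(equality at v_ND = 0.21, 1 kg); the two conventions fix nearly the same
coefficient, and a test enforces agreement to 10%.

Crossover magnitudes solve `k·mag^p·M^e = smd(M)` in closed form on the
separable fitted model. At the extreme body sizes the crossover exceeds
the simulated magnitude range (63° for 5 g > 60° maximum), so the
crossover *law* is an extrapolation of the fitted power laws; the API
refuses to extrapolate unless asked (`extrapolate=True`).

Relative response time divides (sensorimotor + inertial delay of a 30°
swing) by an available-movement-time law. The normalization is anchored
at the sprint swing duration of a 1 kg animal (148 ms) and uses the
characteristic-movement-time exponent 1/6 that falling and pendular
timescales share under geometric similarity — the scaling frame the
normalized results are expressed in. The empirical sprint-swing law
148·M^0.13 ms is available through `available_movement_time` and the
exponent can be overridden (`available_exponent=0.13`), which steepens
the fitted relative-response exponent accordingly.

## Numerical choices

* Integration: scipy `solve_ivp` RK45, rtol 1e-8 / atol 1e-10; switching
  and stopping located by the solver's event root-finding, with event
  directions constrained to suppress spurious triggers at the initial
  state. Halving tolerances moves delays by < 0.01%.
* Time caps at 100× the closed-form estimate guard non-termination; a
  capped integration is reported as a convergence failure, never a value.
* Shooting: Brent on the guaranteed bracket, xtol 1e-9 × the linear time
  scale; the boundary-condition check (1e-6) runs after every solve.
* Surfaces record failed cells as NaN with a convergence flag instead of
  aborting; fits skip incomplete magnitude levels with a log notice.
* Log base 10 throughout the regressions (any base yields the same power
  law).

## Synthetic data

`synthetic_data` emulates the statistical structure of the morphometric
datasets behind the parameter tables: masses log-uniform over 0.02–300 kg
(a typical specimen span), values scattered log-normally (default
σ_log10 = 0.05, which reproduces CI widths of the packaged tables' order
at n = 50) around a known truth law. It validates the regression stage
(exact recovery at σ = 0, calibrated recovery rates and ~95% CI coverage
at σ > 0) and provides drop-in replacement tables for end-to-end smoke
tests. What it does not emulate: phylogenetic correlation between
specimens, heteroscedastic measurement error, and the a–b sampling
covariance of a real regression — so passing tests certify the pipeline's
statistical machinery, not the biological representativeness of the
inputs.

## Known limitations

* Single-joint, rigid-body tasks; no multi-joint redundancy, no crouched
  versus columnar posture differences, no joint damping.
* Instantaneous torque switching; real activation dynamics would lengthen
  all delays, more so in small animals with short absolute delays.
* One muscle group per task stands in for all agonists and antagonists.
* The Monte Carlo intervals inherit the independence approximation
  described above and a conventional df = 20; the degrees of freedom are
  configurable (`df` argument) for sensitivity checks.
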