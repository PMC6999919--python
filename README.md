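# inertial-delays

How quickly can animals of different sizes produce corrective movements
when their muscles work at full capacity? Inertia opposes every corrective
motion, so even with instantaneous neural control a movement takes a
minimum time — the **inertial delay**. This package quantifies how that
delay scales with body mass *M* across terrestrial quadrupedal mammals
(one gram to ten metric tons), and compares it against the sensorimotor
delays of the stimulus–response pathway and the time available to complete
a movement.

It is aimed at comparative biomechanists and motor-control researchers who
want a fully reproducible, desk-scale implementation of the analysis: all
inputs are published allometric scaling laws packaged as CSV tables.

## The models

Two minimum-time (bang-bang) tasks are simulated with event-driven
Runge–Kutta integration:

* **Swing task** — a distributed-mass pendulum (forelimb about the
  shoulder) repositioned from rest at −Δθ/2 to rest at +Δθ/2:

      θ̈ = T/MOI − (M_limb · g · L_COM / MOI) · sin θ

  Maximal torque +T is applied until the zero-angle crossing, then −T
  until the velocity crosses zero. In the gravity-free point-mass limit
  the delay has the closed form t = 2·√(MOI·Δθ/T).

* **Posture task** — a point-mass inverted pendulum (whole body on stance
  limbs) pushed forward with dimensionless velocity v_ND = v/√(gL):

      θ̈ = T/(M·L²) + (g/L) · sin θ

  The single torque-switch time is the unknown of a two-point
  boundary-value problem, solved by shooting with a bracketed
  root-finder. Gravity-free limit: t = (1+√2)·M·L²·θ̇₀/T. Because gravity
  is destabilizing there is a capture limit — the largest v_ND from which
  upright rest is recoverable.

Body mass enters only through power laws *a·M^b* (limb inertial
properties, muscle mass/length/moment arm); muscle torque follows the
standard chain stress × PCSA × moment arm with density 1060 kg/m³ and
isometric stress 20 N/cm². Simulated delays are fitted per movement
magnitude as power laws of mass by log-log least squares, and input
uncertainty is propagated to 95% confidence intervals by Monte Carlo
resampling of the scaling laws from CI-derived t-distributions.

## Worked example

```python
import numpy as np
import inertial_delays as idl

masses = idl.mass_grid()                      # 7 masses, 1 g .. 10 t
mags = np.geomspace(1, 60, 10)                # total excursions, degrees

surface = idl.delay_surface_swing(masses, mags)
fits = idl.fit_delay_scaling(surface)
print(f"swing average exponent: {idl.average_exponent(fits):.3f}")
coef_60 = [f for f in fits if np.isclose(f.magnitude, 60)][0].coefficient
print(f"swing coefficient at 60 deg: {coef_60 * 1e3:.1f} ms")

smd = idl.build_sensorimotor_model(fits, anchor_magnitude=30.0)
law = idl.fit_crossover_law("swing", smd, fits, masses)
print(f"crossover law: {law.coefficient:.1f} * M^{law.exponent:.3f} deg")
```

prints

```
swing average exponent: 0.279
swing coefficient at 60 deg: 43.3 ms
crossover law: 30.0 * M^-0.139 deg
```

meaning: a 60° limb swing takes 43 ms in a 1 kg animal and grows as
roughly M^0.28 — faster than the M^0.21 of sensorimotor delay — so the
movement magnitude at which inertia becomes the dominant source of delay
shrinks with size as M^−0.14 (about 63° for a 5 g shrew, 9° for a 5 t
elephant).

The same analysis is scriptable from the shell:

```bash
inertial-delays simulate-swing --out results
inertial-delays simulate-posture --out results
inertial-delays fit --out results
inertial-delays response --out results
inertial-delays report --out results
```

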