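# efatrans

Micro-level transport-rate modelling and kinetic-dissolution analysis for
efavirenz concentration data.

Efavirenz is a first-line antiretroviral with low solubility, high
permeability and notoriously variable oral bioavailability. `efatrans`
models the transport of an idealised *solution particle* — the smallest
zero-sum movement entity of the drug solution, carrying equal pro- and
anti-solvation movement components at every concentration — in a
homogeneous uptake volume, and uses those models to classify the kinetic
solubility of the drug as a function of its plasma concentration. It is
aimed at pharmacometricians and PK modellers who want a reproducible,
tested implementation of this transport decomposition: model evaluators,
`nls`-style nonlinear least-squares fitters, derived-quantity analysis and
a seeded synthetic-data generator, wired together by a small CLI.

## The models

**Primary advection rate.** The anti-solvation movement rate *y* = −1/γ
(ml/(μg·h)) of a solution particle at concentration *x* (μg/ml) decomposes
into convection (Ricker), energy-dependent transport (Michaelis–Menten)
and passive, energy-independent transport (inverse Michaelis–Menten):

    y(x) = g·x·e^(−h·x)  +  n·x/(b + x)  +  m·(p/x + 1)
           └ convection ┘   └─ E_D (MM) ┘   └ E_I (passive) ┘

As *x* grows, convection → 0, E_D → *n* and E_I → *m*. The curve has two
turning points, and the concentration x̄ at which |E_D| = E_I marks the
hand-over between passive-dominated and energy-dependent-dominated
transport.

**Advection rate constant.** Scaling the advection rate by relative uptake
at full absorption gives the advection rate constant a_r = −A/(γV) (1/h),
which splits into a convection rate constant and a saturable (Hill-form)
transport rate constant:

    a_r(x) = ζ·x·e^(−λ·x) − |α|·x^ω/(κ + x^ω) = c_r(x) − st_r(x),   κ = η^ω

The identity a_r + st_r = c_r holds exactly. The root x_Ad of a_r bounds
the *good kinetics of dissolution* phase R_I; beyond it advection turns
negative (phase R_II, poor dissolution) until convection is effectively
extinct at x_C (phase R_III, undefined kinetics / insolubility), with
named solubility sub-regions in ε-neighbourhoods of the boundary points.

**Convection over a dosing interval.** For a single patient the convection
rate constant follows a Bateman profile in time,

    c_r(t) = j/(w−l)·(e^(−l·t) − e^(−w·t)),   t ∈ [0, 24] h,

whose derivative — the acceleration rate constant (1/h²) — starts at *j*,
crosses zero at ln(w/l)/(w−l) (the convection peak) and is negative
thereafter.

A macro mass balance k_e = −1/γ·(D/V − A/V) ties the advection rate to
dose *D* (600 mg), uptake volume *V* (35.56 L), bioavailable amount *A*
and the elimination rate constant *k_e*.

## Worked example

```python
import efatrans as et

primary = et.REFERENCE_PRIMARY          # published 600-mg estimates
rate = et.primary_advection_rate(1.44, primary)
print(f"advection rate at 1.44 ug/ml: {rate.total:.5f} ml/(ug.h)")

for tp in et.find_turning_points(primary):
    print(f"{tp.kind:8s} at x = {tp.x:6.3f} ug/ml, rate = {tp.rate:.5f}")

print(f"dominance crossover: {et.dominance_crossover(primary):.3f} ug/ml")

constants = et.REFERENCE_RATE_CONSTANT
bounds = et.solve_boundaries(constants)
print(f"good-dissolution boundary x_Ad = {bounds.x_ad:.2f} ug/ml")
print(f"convection-extinction point x_C = {bounds.x_c:.1f} ug/ml")
label = et.classify_kinetic_phase(2.0, constants, bounds)
print(f"x = 2 ug/ml: phase {label.phase.value}, {label.sub_region.value} soluble")

convection = et.REFERENCE_CONVECTION_TIME
print(f"initial acceleration: {et.acceleration_rate_constant(0.0, convection):.3f} /h^2")
print(f"acceleration sign change at t = {et.acceleration_zero_crossing(convection):.2f} h")
```

prints

```
advection rate at 1.44 ug/ml: 0.00813 ml/(ug.h)
minimum  at x =  1.196 ug/ml, rate = 0.00804
maximum  at x = 12.479 ug/ml, rate = 0.02114
dominance crossover: 0.971 ug/ml
good-dissolution boundary x_Ad = 32.80 ug/ml
convection-extinction point x_C = 125.9 ug/ml
x = 2 ug/ml: phase R_I, freely soluble
initial acceleration: 0.333 /h^2
acceleration sign change at t = 7.65 h
```

Reading: the advection-rate curve is nearly flat around its minimum
(≈0.0080–0.0081 ml/(μg·h) anywhere between 1.2 and 1.5 μg/ml) and peaks
at 12.5 μg/ml. Below 0.97 μg/ml passive transport dominates — the system
has little control over drug movement, one proposed explanation for
virological failure at trough levels under 1 μg/ml. The therapeutic range
(1–4 μg/ml) sits comfortably in the freely-soluble part of the
good-dissolution phase, which extends to 32.8 μg/ml. Convection of a fast
single-patient profile peaks 7.65 h after dosing, after which its
acceleration is negative, reaching −0.01596/h² at 24 h.

The same pipeline runs from the shell on synthetic data:

```sh
efatrans report --out-dir out --seed 7 --sigma 0
```

writes the simulated cohort and observation tables, the three fit reports,
`summary.json` (turning points, crossover, boundaries, zero crossing) and
the phase-classification grid into `out/`.

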