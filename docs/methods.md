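# Methods

## Model structure and assumptions

`efatrans` treats drug transport in a single, homogeneous, instantaneously
mixed uptake volume and describes it through the movement of a *solution
particle*, a zero-sum entity whose pro-solvation movements (convection,
passive transport) balance its anti-solvation movements (advection,
energy-dependent or saturable transport) at every concentration. Three
model families cover the two micro levels and the dosing-interval view:

1. **Primary advection rate** (rate vs concentration, six parameters):
   `y(x) = g·x·e^(−hx) + n·x/(b+x) + m·(p/x + 1)`. The Ricker term
   captures bulk convection that first grows with concentration and then
   declines in a finite volume; the Michaelis–Menten term captures
   carrier-mediated, energy-dependent transport that saturates at `n`; the
   inverse-MM term captures passive transport that falls with
   concentration towards the floor `m` (gradient-driven movement weakens
   as concentration rises). The passive term is written `m·(p/x + 1)` —
   this is the only reading compatible with its stated limit (→ `m` at
   large `x`) and with the definition of `p` (the concentration at which
   the passive rate is twice `m`); it diverges at `x = 0`, so
   concentrations must be strictly positive and the rest point `x₀ = 0`
   appears only as a phase label, never as an evaluable input.
2. **Advection rate constant** (1/h, five parameters):
   `a_r(x) = ζ·x·e^(−λx) + α·x^ω/(κ + x^ω)`, with the convection rate
   constant `c_r = ζ·x·e^(−λx)` and the saturable transport rate constant
   `st_r = −α·x^ω/(κ + x^ω)` (positive for the fitted negative `α`), so
   that `a_r = c_r − st_r` exactly. The Hill term is parameterised in
   `κ = η^ω` rather than the half-saturation `η` itself: `κ` is the
   quantity the inference table reports, and it decouples the otherwise
   strongly interacting (η, ω) pair during optimisation; `η = κ^(1/ω)` is
   exposed as a derived property.
3. **Convection in time** (three parameters):
   `c_r(t) = j/(w−l)·(e^(−lt) − e^(−wt))` over one 24-h dosing interval —
   a Bateman profile mirroring first-order absorption with first-order
   elimination — and its derivative, the acceleration rate constant.

The macro relation `k_e = −1/γ·(D/V − A/V)` (concentrations in
mg/L ≡ μg/ml) identifies the advection rate `−1/γ = k_e·V/(D−A)` from
macro quantities at the point of full absorption, where the uptake
concentration `x_u(t) = A/(V(1−k_e))·(e^(−k_e t) − e^(−t))` matches the
observed concentration. The absorption exponent is fixed at 1 h⁻¹ in this
formulation and is implemented exactly as written. γ itself is never
stored; only `−1/γ` is ever used, so the transport factor lives implicitly
in that rate.

Units throughout: concentration μg/ml, advection rate ml/(μg·h), rate
constants 1/h, acceleration 1/h², time h, dose and bioavailable amount mg,
volume L.

## Reference parameter sets

The package ships the published estimates for efavirenz at a 600-mg dose
with uptake volume 35.56 L as frozen constants
(`REFERENCE_PRIMARY`, `REFERENCE_RATE_CONSTANT`,
`REFERENCE_CONVECTION_TIME`); they are the defaults of the simulator and
the CLI pipeline and the inputs of `scripts/acceptance.py`.

## Fitting

Estimation is ordinary (unweighted) nonlinear least squares — the loss the
source analyses used — via seeded multi-start trust-region optimisation
(`scipy.optimize.least_squares`, `trf`, Jacobian-based variable scaling,
tolerances 1e−14). Default bounds are sign-constrained boxes spanning
three orders of magnitude around crude heuristics: Ricker peak location
and height for (g, h) and (ζ, λ) — with the peak search restricted to the
upper half of the grid, since the diverging passive term (primary model)
or a small-x convection bump (rate-constant model) otherwise masquerades
as the Ricker peak, and a fallback to a mid-grid peak when the curve never
rises above zero — the grid's geometric mid-point for the half-saturation
scales (b, p, κ), and the data scale for the sign-free asymptotes (n, α).
The first start is the heuristic itself; the remaining `n_starts − 1`
(default 19) are log-uniform magnitude draws inside the bounds with random
signs where allowed, drawn sequentially from the seed so that enlarging
the start budget can only improve the best loss. Standard errors come from
the Gauss–Newton covariance `s²(JᵀJ)⁻¹` with `s² = RSS/(N−k)`; t-values
are estimate/SE and p-values two-sided from the t distribution on `N−k`
degrees of freedom. A singular `JᵀJ` flags SEs as unavailable rather than
failing the fit. The Bateman profile is symmetric under exchanging
`w` and `l`; reported fits are canonicalised to `w > l`.

Because the number of observations behind the published inference tables
is not stated, reported SEs/t/p depend on whatever `N` the caller
supplies; the published SEs serve as qualitative context only and are not
reproduction targets.

## Derived quantities

* **Turning points**: the analytic derivative of the primary rate is
  pre-scanned on a 0.005-μg/ml grid for sign changes inside the fitted
  range (0.01, 15.5] (extrapolation requires an explicit domain argument)
  and each bracket is polished with Brent's method to ~1e−12; the sign
  change direction classifies minimum vs maximum. With the reference
  estimates this yields a minimum at 1.196 μg/ml (rate 0.00804) and a
  maximum at 12.479 μg/ml. The curve is extremely flat around the minimum
  — the rate stays within 0.0080–0.0082 ml/(μg·h) across roughly
  1.2–1.5 μg/ml — so the quoted minimum location 1.44 μg/ml is treated as
  approximate (it likely reflects unrounded estimates or a coarser grid);
  the package reports its computed location and does not force agreement.
* **Dominance crossover**: `|n|·x/(b+x) = m·(p/x+1)` is solved by
  bracketing on (1e−6, 10³). A crossover exists only when `|n| > m`;
  otherwise the passive floor can never be overtaken and the solver raises.
  Classification uses a relative tolerance of 1e−3 between the two
  magnitudes to define the balanced case.
* **Dissolution boundaries**: `x_Ad` is the Brent root of `a_r` beyond its
  maximum (pre-scan on 200 001 points up to 10³ μg/ml). The convection
  term is strictly positive at every finite concentration, so the
  extinction point `x_C` is defined by a tolerance: the smallest
  `x > x_Ad` with `c_r(x) ≤ ε_c`, default ε_c = 0.01/h — the system
  formally keeps dissolving, with great difficulty, and "undefined
  kinetics" is adopted once pro-solvation is in the neighbourhood of zero.
  Default neighbourhood radii ε₁..ε₄ = 0.5 μg/ml (no published values
  exist); construction validates `0 < x_Ad < x_C` and pairwise-disjoint
  neighbourhoods.
* **Phase classification** applies both the interval test and the defining
  inequalities on (a_r, c_r, st_r) with 1e−8 absolute slack, and raises if
  they disagree (a guard against boundaries computed from different
  parameters). Beyond `x_C` the tabulated `st_r` is frozen at its `x_C`
  value — saturation holds at the optimum dissolution capacity.
* **Acceleration**: the zero crossing `ln(w/l)/(w−l)` is closed-form and
  coincides with the convection peak; profiles tabulate `c_r` and its
  derivative on a caller-supplied grid within [0, 24] h.

## Numerical choices

Difference-of-exponential profiles switch to their confluent limits
(`j·t·e^(−lt)`; `A/V·t·e^(−t)`) when the exponent gap is below 1e−8,
avoiding catastrophic cancellation. Root polishing uses `brentq` with
xtol 1e−12. The decomposition `a_r + st_r = c_r` is exact by construction
(`a_r` is computed as the difference), to within one ulp of the larger
component.

## Synthetic data

The generator emulates the structure of a 61-patient simulated efavirenz
study: dose fixed at 600 mg, uptake volume at 35.56 L, elimination rate
constant log-normal with median 0.05/h and geometric CV 30%, bioavailable
fraction A/D ~ Beta(8, 8). The k_e median and the bioavailability shapes
are this package's choices (no patient-level distributions are published):
they keep every patient's Bateman concentration peak inside the fitted
range (0, 15.5] μg/ml and centre bioavailability at 50%, appropriate for a
drug with low and variable oral bioavailability. Observation noise is
multiplicative Gaussian with σ = 5% by default — rates span two orders of
magnitude across the fitted range, and tight published SEs imply small
*relative* scatter — with an additive option; σ = 0 returns the exact
curve. Rate observations are generated on a 200-point log-spaced grid over
[0.05, 15.5] μg/ml by default, convection profiles on a quarter-hour grid
over [0, 24] h. All generators are bit-reproducible under a fixed seed.
Pooling across patients is not modelled: the generator produces pooled
grids directly, since how the source study pooled its 61 patients into
single regressions is not recoverable.

What passing tests on these data do **not** show: robustness to real-data
features the generator omits — between-patient heterogeneity in the rate
curves themselves, non-Gaussian or autocorrelated residuals, sparse or
irregular sampling, assay limits of quantification.

## Known limitations

* **Identifiability at realistic noise.** Under 5% multiplicative noise on
  the default 200-point design, the curvature of the composite models
  leaves several parameters weakly identified: the Fisher information
  bounds the achievable relative precision of `n` and `b` (primary model)
  and `α`, `κ`, `ζ` (rate-constant model) at tens of percent, whatever the
  estimator. Precise parameter recovery should only be expected from
  low-noise or much larger designs; the fitted *curves*, and derived
  quantities read off them, are far better determined than the individual
  parameters.
* **Wald inference is asymptotic and assumes homoscedastic residuals.**
  Under multiplicative noise the Gauss–Newton SEs are mis-calibrated;
  coverage of Wald intervals is tested (and near-nominal) in the additive,
  small-noise regime where the assumptions hold.
* The published inference tables cannot be reproduced exactly (their `N`
  is unstated); point estimates and all derived quantities can.
* Phase labels are model-derived kinetic-solubility statements, not
  experimental solubility measurements, and no link to virological
  outcomes is modelled.

## Problem sizes

Default analyses use 200-point concentration grids, 97-point time grids,
a 0.005-μg/ml turning-point pre-scan, 20 multi-start draws per fit, and
100 replicates (3 starts each) for noisy-recovery summaries; the test
suite uses 60 replicates for interval-coverage checks.
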