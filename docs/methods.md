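# Methods

## Model and assumptions

The package integrates a five-compartment rumor-diffusion model with one
discrete delay and periodic proportional impulses.  The population is
homogeneously mixed (no network structure) and open: susceptibles enter at
rate π and every class leaves at rate μ.  Hesitation is modelled
mechanistically: a contact at time t−τ commits its outcome at time t,
discounted by the survival factor e^{−μτ} (only users still on the
platform resolve).  A fraction k of resolving hesitants becomes spreaders,
the rest refuters; spreaders exposed to media leave at rate γ₁ (a fraction
θ recovering directly, 1−θ turning refuter) and refuters lose interest at
rate γ₂.  Incidence saturates as αS/(1+ρS) per contact source — ρ is a
psychological inhibition constant, and ρ = 0 recovers the bilinear model.
Pulse "vaccination" (recurring popular-science campaigns) moves the
fraction φ of S to R instantaneously at t = nT, n ≥ 1; no impulse fires at
t = 0, matching the convention that each period is the half-open interval
(nT, (n+1)T].

Two deliberate modelling consequences are worth flagging:

* γ₁, γ₂ enter the equations as *rates* and are not capped at 1, even
  though they are probabilities per unit time in the parameter gloss.
* H is the integral of discounted incidence over the trailing delay window
  *only if* the initial data are consistent with that integral.  The
  benchmark experiments use point initial values with a constant history,
  which is deliberately inconsistent; H then carries a decaying transient
  and can legitimately undershoot zero by O(10⁻⁴).  For this reason the
  solver's non-negativity guard exempts H by default
  (`SolverConfig.nonneg_exempt`); S, I, D, R remain guarded because the
  invariant region argument protects them.

## Threshold quantities

All closed forms follow from the scalar comparison system
x' = π − μx, x(nT⁺) = (1−φ)x(nT), whose globally stable periodic solution
has post-pulse fixed point S* and supremum B = S*/(1−φ).  R₁ uses the
extremal constants α = max(α₁,α₂), ρ = min(ρ₁,ρ₂), σ = min(θγ₁+μ, γ₂+μ)
(an upper bound on spreading), R₂ the opposite extremes (a lower bound).
Consequences implemented and tested rather than proved: R₁ is strictly
decreasing in φ, τ and the ρ's; R₁ < 1 implies R₂ < 1 (so the verdict
bands never contradict); and sign(R₂−1) equals the sign of the
saturated-incidence form α′e^{−μτ}S*/((1+ρ′S*)σ′) − 1.

Two printed closed forms in the source material are typographically
ambiguous, so the package anchors them to their defining properties
instead: R₂ is taken as (α′e^{−μτ}/σ′ − ρ′)·S*, the unique reading
consistent with the permanence condition, and φ* is computed by bisection
on R₁(φ) = 1 (residual tolerance 1e−10), with the derived closed form
φ* = (e^{μT}−1)((π/μ)(αe^{−μτ}/σ − ρ) − 1) used only as a cross-check.
When R₁(0) ≤ 1 the root is reported as 0 with status `not_needed`; when
R₁ > 1 for all φ < 1, as NaN with status `unattainable`.

The permanence floor P = min(F*/2, F*e^{−σ′τ}) with F* = (μ/α)(R₂−1) is a
sufficient bound produced by the comparison argument, not a tight one; the
package reports it but does not assert simulated I+D ≥ P, and the tests
only require persistent runs to stay above the classification tolerance.

## Numerical scheme

Fixed-step classical RK4 by the method of steps.  `resolve_step` picks the
largest dt ≤ dt_target such that T/dt and τ/dt are integers, interpreting
τ and T as the decimal rationals they were written as (exact `Fraction`
gcd); incommensurable pairs are rejected rather than approximated.  This
makes every pulse instant, every delay lookup at whole steps, and every
propagated discontinuity (nT and its τ-translates) a grid node, so each
RK4 step integrates a smooth segment and no event detection is needed.

Delayed values at the half-step stage times are cubic Hermite
interpolations of the stored (state, derivative) node pairs, which keeps
the observed global order at 4 (error ratio ≈ 16 per step halving, checked
on a linear-decay benchmark, the pulsed scalar comparison system against
its exact piecewise solution, and the full delayed system by
self-convergence).  One subtlety: at nodes t = nT + τ the delayed argument
sits exactly on a pulse instant, where the vector field jumps; the stored
right-hand derivative there must use the delayed *right* limit (and the
left-hand derivative the left limit), otherwise the interpolant degrades
the scheme to second order.  Both one-sided limits and derivatives are
recorded at every impulse node.

States are never clipped: a guarded component below −1e−9 aborts the run
with a step-size error, and non-finite values abort with the offending
time.  The trajectory CSV contains t, S, H, I, D, R, N and an event column
(0 regular node, 1 impulse left limit, 2 impulse right limit).

## Long-run classification

`classify_long_run` inspects F(t) = I(t) + D(t) over the final `n_windows`
(default 5) whole pulse periods, which must lie after a burn-in of 50 % of
the horizon (the constant history injects a transient that the windows
must not see).  Extinct: max F < 1e−6; persistent: min F > 1e−4; otherwise
undetermined.  The defaults classify all benchmark schemes decisively at
their default horizons and are configurable.  The distance to the
rumor-free solution is phase-aligned on the impulse-epoch grid: right
limits are compared with S̃ₑ(nT⁺) = S*, left limits with the
end-of-period value, avoiding off-by-one-node artifacts.

## Benchmark schemes and horizons

The three packaged schemes share the initial state
(S, H, I, D, R)(0) = (0.92, 0.03, 0.02, 0.02, 0.01) and satisfy π = μ, so
N ≡ 1 and the simulated N doubles as an exact integrator oracle.  Default
horizons are 600 time units for scheme 1 (μ = 0.01 makes its transients an
order of magnitude slower) and 200 for schemes 2 and 3; with dt = 0.01
these horizons classify every benchmark configuration decisively while a
full experiment bundle stays in the seconds range on one core.  The
saturation-sweep experiment (`6.4`) fixes scheme 1 with φ = 0.2, T = 2,
τ = 1 — the base setting of the pulse-rate experiment — and the threshold
surface (`6.5`) uses the same base with 9×9 grids on φ, ρ ∈ [0, 0.4].

## What the benchmarks do and do not show

The scheme fixtures are synthetic parameter sets spanning the extinction
and permanence regimes, not fits to measured diffusion data.  Passing
tests demonstrate that the implementation reproduces the model's analytic
structure (thresholds, periodic solution, conservation law, convergence
order) and that threshold verdicts concord with simulated long-run
behavior under these conditions; they say nothing about how well the SHIDR
model describes any real rumor cascade, nor about network-structured or
stochastic extensions, which are out of scope.

## Known limitations

* Fixed step only; no adaptive error control or stiffness handling.  Very
  stiff parameter sets need a manually reduced dt_target.
* τ and T must be commensurable decimals (by design, to keep delay and
  pulse events on nodes).
* The permanence floor P is reported but loose — often an order of
  magnitude below the simulated lim inf.
* Arbitrary user histories are accepted as grid samples or callables, but
  their derivatives are estimated by finite differences, which can cost
  accuracy in the first delay interval if the history is rough.
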