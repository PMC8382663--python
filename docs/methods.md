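# Methods

## Model and scope

The toolkit implements the full HKB system of two coupled hybrid
oscillators, its linearisation, and the averaged (slow-flow) reduction
valid for weak damping and weak coupling relative to the pacing
frequency ω.  The averaging step itself (two-timing with the ansatz
x_i = r_i(T) cos(ωτ + φ_i(T))) is taken as given: the slow-flow
equations are the implementation contract, not re-derived symbolically.
Consequently everything the steady-state catalogue predicts is a
statement about the averaged dynamics; it transfers to the full model
only to leading order in the small damping/coupling parameters, and the
comparison utilities exist precisely to measure that gap.

The state ordering of the oscillator models is fixed as
(x1, x2, v1, v2).  The bookkeeping factor ε multiplying the whole
damping-plus-coupling bracket defaults to 1; weakly nonlinear regimes
are produced by choosing small coefficient magnitudes, which is how all
quantitative comparisons in the test suite are run.

## Parameters

| symbol | meaning | units | typical |
|---|---|---|---|
| γ | linear damping (destabilising when > 0) | 1/T | 0.05 – 1 |
| α, β | van der Pol / Rayleigh damping | 1/(L²T), T/L² | O(1) |
| a | linear coupling | 1/T | ±0.5 |
| b, c | nonlinear coupling | 1/(L²T), T/L² | ±0.5, 0 |
| ω | pacing frequency (control parameter) | 1/T | 1 – 10 |

Derived quantities: δ = (α+3βω²)/4, d = (b+3cω²)/4, μ = a/γ, κ = d/δ,
ν = 1/μ, σ = 1/κ.  The slow-flow analysis depends on the dimensional
coefficients only through (μ, κ) and, outside the canonical sign case,
the signs of γ and δ.  The default analysis convention is
s_γ = s_δ = +1, matching the experimentally usual positive γ, α, β; the
sign-generalised and (ν, σ) forms are opt-in.

## Steady-state catalogue and stability

All steady states of the reduced flow are closed-form: the
equal-amplitude branches I = (1,1,0), A with amplitude
√((1+2μ)/(1−8κ)) at φ = π, and L± = (1,1,±arccos(1+μ/2κ)); the
unequal-amplitude N branches built from the radicals
½√((1+3μ+4κ)/(1+κ)) ± ½√((1−μ)/(1+κ)); and the degenerate
zero-amplitude Z family.  Existence regions are evaluated with strict
inequalities; points within 1e−9 of a region edge are flagged
`boundary`, because every qualitative transition lives on those
measure-zero sets.  The quarter-period N branches exist only on the
line μ + κ = 0 and are therefore reported only within 1e−9 of it.

Analytic eigenvalues are attached for I, A and L±.  A central-difference
Jacobian (step 1e−6) of the slow-flow vector field serves as an
independent oracle for those formulas and is the *only* stability
decision procedure for the N branches and for sign-generalised
parameters, where no closed forms are available; inventing formulas for
those cases was deliberately avoided.  The Z family is reported as
`degenerate` rather than given a verdict: the polar phase equation is
singular at zero amplitude, so its linearisation there is not meaningful
in these coordinates.

## Numerical choices

* **Integrator**: adaptive Runge–Kutta (scipy `RK45`) with defaults
  rtol = 1e−9, atol = 1e−11.  No randomness anywhere; runs are
  reproducible bit-for-bit.
* **Amplitude guard**: the polar φ̇ equation divides by R₁R₂.  A guard
  radius of 1e−6 terminates integration, and trajectories entering it
  are classified as collapsing onto the Z family.  The regularised
  Cartesian form of the averaged phase equations is not part of the
  contract, so no attempt is made to continue through the singularity.
* **Phase convention**: phases are wrapped to (−π, π] on output;
  integration itself runs on the unwrapped lift (the vector field is
  2π-periodic in φ, so this is exact).  L⁻ is the negative-phase mirror
  of L⁺.
* **Settling**: convergence is declared when every state component
  varies by less than 1e−8 over a trailing window of 10 slow-time
  units, within a default horizon of 500 slow-time units; these resolve
  the slowest eigenvalue magnitudes of interest (O(0.1)) comfortably.
  The settled state is matched to the nearest catalogue branch within a
  distance of 1e−2 in (R₁, R₂, φ).
* **Slow-flow extraction**: the default analytic signal is the
  quadrature form z_i = x_i − i v_i/ω, exact for the averaging ansatz
  and free of edge effects; an FFT-based Hilbert route and a per-cycle
  peak-detection fallback are selectable.  Phases are anchored to
  x_i = r_i cos(ωt + φ_i).
* **Transition location**: plain bisection to a requested tolerance
  (default 1e−8), applied to eigenvalue real parts and line residuals.
* **Sign-generalised sweeps**: equilibria are located by Newton
  refinement seeded from the catalogue formulas plus a small fixed set
  of generic states, then classified by the numerical Jacobian.  Root
  finding from a finite seed list cannot prove exhaustiveness; grid
  points where no equilibrium is found are recorded explicitly.

## Comparison of theory and simulation

`compare_analytic_numeric` integrates the full oscillator model from
initial data near the predicted attractor for 80 slow-time units
(2 × 40/γ in physical time by default), extracts the slow flow, and
averages the trailing 10%.  In the weakly damped regime γ/ω ≤ 0.05 the
settled amplitudes agree with the averaged predictions to well under 2%
(the acceptance tests assert 2% across a 10-point grid); at γ/ω = O(1)
agreement degrades to qualitative — branch identity and phase are
preserved but amplitudes drift — which is the expected breakdown of the
weakly nonlinear approximation, not an integration artefact.  Problem
sizes used in the shipped tests (integration horizons of 40–80 slow-time
units, grids of 10–20 points per axis) were chosen as the smallest that
make these statements cleanly resolvable.

## Fixture choices

The literature parameter sets are shipped as fixtures with two
completions made here: the Leise–Cohen row carries no tabulated pacing
frequency or velocity-coupling value, so the fixture uses ω = 1 and
c = 0; the Słowiński row leaves a free in [−15, 15], so a = 1 and ω = 2
are shipped as a representative point.  The canonical (κ, μ) test points
include one per qualitative region; the bistable representative is
(κ, μ) = (0.1, −0.2), which lies strictly inside the wedge bounded by
μ = 0, κ = 1/8 and μ + 4κ = 0 (on that last line the anti-phase branch
is only marginally stable, so on-line points are avoided).

## Known limitations

* The large-amplitude saddle-node of the anti-phase branch is outside
  the weakly nonlinear analysis and is not computed in closed form; it
  can only emerge empirically from full-model sweeps as an unexplained
  transition.
* The catalogue-matching step of `settle` is defined on the (μ, κ)
  amplitude scale; settled states of the alternative (ν, σ) flow are
  mapped back through the amplitude-ratio identity
  r_I = √(κ/μ)·√(a/d), which requires μ/κ > 0 — otherwise the match is
  reported as `none`.
* Time-delay couplings, stochastic extensions and alternative coupling
  functional forms are out of scope.
* Passing the synthetic/simulated checks here validates the
  mathematics of the reduction, not the biological fidelity of the HKB
  model itself: the generator emulates noiseless, stationary-parameter
  oscillators, not measured movement data with drift, noise and
  nonstationary pacing.
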