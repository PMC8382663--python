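# hkb-coordination

Analysis and simulation toolkit for the Haken–Kelso–Bunz (HKB) model of
motor coordination: two nonlinearly coupled hybrid Rayleigh/van der Pol
oscillators whose relative phase φ = φ₁ − φ₂ is the standard order
parameter for rhythmic coordination (bimanual finger movement,
interpersonal coordination, human–machine interaction).

## The model

The full HKB model is

    ẍ₁ + ω²x₁ = (γ − αx₁² − βẋ₁²)ẋ₁ + [a + b(x₁−x₂)² + c(ẋ₁−ẋ₂)²](ẋ₁−ẋ₂)

and symmetrically for x₂, with pacing frequency ω > 0, linear damping γ,
van der Pol/Rayleigh coefficients α, β and coupling coefficients a, b, c.
Its linearisation decouples into normal modes η_I = x₁ + x₂ and
η_A = x₁ − x₂ with effective dampings γ and 2a + γ, giving the Hopf lines
HB_I: γ = 0 and HB_A: 2a + γ = 0 independently of all nonlinear
coefficients.

For weak damping and coupling, averaging over the fast oscillation yields
a three-dimensional slow flow for the amplitudes and relative phase.
Rescaling amplitudes by the in-phase limit-cycle radius
r_I = 2√(γ/(α+3βω²)) and time by s = γt/2 reduces that flow to

    Ṙ₁ = R₁ − R₁³ + (R₁ − R₂cos φ)(μ + κS),    S = R₁² + R₂² − 2R₁R₂cos φ,

(and symmetrically for R₂, with R₁R₂φ̇ = (R₁²+R₂²)sin φ (μ + κS)),
governed by only two dimensionless parameters:

* **μ = a/γ** — linear coupling over linear damping,
* **κ = d/δ** — combined nonlinear coupling d = (b+3cω²)/4 over combined
  nonlinear damping δ = (α+3βω²)/4,

with the reciprocal pair ν = 1/μ, σ = 1/κ available for sweeps through
γ = 0.  The package provides the closed-form steady-state catalogue of
this reduced flow (in-phase **I**, anti-phase **A**, phase-lagged **L±**
with φ* = ±arccos(1 + μ/2κ), unequal-amplitude **N** branches, degenerate
**Z** family), analytic eigenvalues and bifurcation lines (HB_A: μ = −½,
BP_AL: μ + 4κ = 0, BP_II: μ = 1, BP_AA: 3μ + 4κ + 1 = 0, BP_N: μ + κ = 0),
region charts, deterministic simulation of every model form, and
analytic-vs-numeric comparison utilities.

## Worked example

```python
from hkb import (HKBParams, to_mu_kappa, to_nu_sigma, branch_value, settle,
                 NondimParams)

p = HKBParams(gamma=1.0, alpha=1.0, beta=1.0, a=-0.5, b=0.5, c=0.0, omega=2.0)
nd = to_mu_kappa(p)
print(nd.mu, nd.kappa)        # -0.5 0.038461538461538464

br = branch_value("A", mu=-0.2, kappa=0.1)
print(br.R1_star, br.eigenvalues, br.stable)
# 1.7320508075688774 (-1.2, -8.000000000000002, -2.0000000000000004) True

res = settle("ahkb", NondimParams(-0.3, 0.05), [0.95, 1.05, 0.2])
print(res.matched_branch, res.final_state)
# I PolarState(R1=1.0, R2=1.0, phi=1.057441909036278e-12)
```

The first block maps a dimensional parameter set to (μ, κ) = (−0.5, 1/26):
negative μ means the linear coupling opposes the damping, so the in-phase
state is stable.  The second evaluates the anti-phase branch inside the
bistable wedge — amplitude √3, all three eigenvalues negative, so stable
in-phase and anti-phase motion coexist there.  The third integrates the
slow flow until it stops moving and identifies the attractor as the
in-phase state (1, 1, 0).

The same operations are exposed on a CLI:

```bash
hkb nondim --gamma 1 --alpha 1 --beta 1 --a 0.5 --b 0.5 --c 0 --omega 2
hkb steady-states --mu -0.2 --kappa 0.1
hkb chart --kappa -2:2 --mu -2:2 --n 200 --out chart.csv
hkb sweep --sigma 26 --nu -4:16 --n 200 --out sweep.csv
```

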