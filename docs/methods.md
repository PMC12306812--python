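# Methods

## Model

An outer hair cell (OHC) is reduced to three coupled linear subsystems.

**Piezoelectric motor population.**  The lateral wall holds N independent
two-state motors.  The long state adds length `a > 0` per motor and moves
charge `q < 0` inward; the open fraction `P` relaxes toward a Boltzmann
equilibrium set by the membrane potential and the axial force.  Only the
first-order expansion of that equilibrium around the operating point `P0` is
retained, which introduces the activity `γ = 4 P0 (1 − P0)` and a factor 1/4
on every Boltzmann-slope term.  All large-signal (saturating) behaviour is
out of scope: the model is the small-signal linearization, and γ is treated
as an independent knob in [0, 1] rather than recomputed from a shifting
operating point.

**Mechanics.**  The cell (stiffness `ko`) and an external spring `Ke` load a
mass and drag η.  The mass is never an input; it is defined by the resonance
frequency, `m = (ko + Ke)/ω_r²`, so scenarios are parameterized by `f_r`.
Two load connectivities (series / parallel) differ only in the transmission
factor `α_c` of external force onto the motors (1 versus `1 − K̄e`); the
difference is O(u_a) and vanishes as the gating parameter
`u_a = βa²Nko/4` goes to zero — a property-tested invariant.

**Membrane circuit and feedback.**  The membrane is an RC pair (C0, σ)
driven by two current sources: piezoelectric displacement current
`N q dP/dt` and the standing transducer current `i0` modulated by the hair
bundle, `r̂ = g p` with constant real gain `g = −|a N (1 − K̄e) gx|`.  The
bundle sensitivity is taken frequency independent (subtectorial shear equals
basilar-membrane displacement); the sign convention makes shortening
increase the transducer current, the amplifying configuration.  A scenario
flag (`amplifying=False`) flips the sign.

In reduced frequency `ω̄ = ω/ω_r` the closed loop is a single complex linear
equation per frequency (see README).  Every equation consumes only the
dimensionless groups `(u_a, K̄e, α_c, ω̄_η, ω̄_m, a₁, b₂)`; scenarios may
supply these directly, bypassing SI values, in which case the dimensionless
values win and a warning is logged.

## Parameters

| symbol | meaning | unit | reference default |
|---|---|---|---|
| q | charge per motor | C | −0.8·1.6e−19 |
| a | length per motor | m | 6.7e−14 |
| N | motor count | — | 3e7 |
| C0 | structural capacitance | F | 30e−12 |
| σ | steady conductance | S | 10e−9 |
| i0 | standing current | A | 0.3e−9 |
| ko | cell stiffness | N/m | 17e−3 |
| Ke | external stiffness | N/m | 20e−3 |
| gx | bundle sensitivity | 1/m | 1/(25e−9) |
| η | drag | N·s/m | 0.8e−7 |
| f_r | resonance frequency | Hz | 4000 |
| kBT | thermal energy | J | 4.142e−21 (300 K) |

The defaults are the published estimates for a 40 µm guinea-pig OHC at the
4 kHz place: stiffness from a 510 nN elastic modulus over the 30 µm exposed
length; `i0` from a −50 mV resting potential over a −80 mV basolateral
reversal through 100 MΩ (the "resting-potential mode"; a divider mode using
the endocochlear potential is also implemented); N from equating the peak
excess capacitance `βq²N/4` to 30 pF; `a` from a full motile excursion of 5%
of the cell length; η from plane shear of the subtectorial gap
(`η = viscosity·S/d`; the drag unit is N·s/m, the only dimensionally
consistent reading).

Two deliberate choices about internally inconsistent published values:

* **u_a carries the /4.**  The alternative reading `βa²Nko` (without /4)
  appears in one place in the source material, but only the /4 form — the
  Boltzmann-slope form used everywhere else in this package — reproduces the
  reference value 0.14 from the defaults.  The /4 form is used throughout.
* **A_h's conductance term uses the total motile charge Nq**, i.e.
  `A_h = a₁ − b₂ω̄_m` with `b₂ω̄_m = βσNq²/(4ω_r C0²)`.  This is what the
  first-order expansion of the exact loop actually produces (re-derived
  symbolically here) and it reproduces the reference value 0.013; a
  single-charge reading does not.

## Figure mode

The reference frequency-response plots correspond to `ω̄_η = 10`, while the
tabulated SI defaults give `(ko+Ke)/η/ω_r ≈ 18.4`; the `figure-mode`
scenario therefore pins `ω̄_η = 10` (and `α_c = 1`) on top of the
SI-derived groups.  The membrane crossover in figure mode is the SI-derived
`ω̄_m = 0.0133`: the alternative round value 0.1 that accompanies the
reference plots is irreconcilable with their stated approximation errors
(it yields exact-vs-expanded amplitude discrepancies of ~6% rather than
~0.1%) and with the low-frequency feature locations (amplitude upturn near
ω̄ ≈ 0.013, phase peak near 0.03), so it is surfaced only in the
`coefficient_report` comparison table.

That comparison table (`adopted_vs_printed`) also carries the published
coefficient values that are *not* recoverable from the tabulated defaults —
`A_h` component 0.165, `A_l = 862`, `B_l` component 12.429, which jointly
imply an effective feedback gain |g| ≈ 54 versus the 37 the defaults give.
They are reported side by side with the recomputed values and never used as
targets.

**Approximation-error caveat.**  On the figure-mode scenario the maximum
exact-vs-expanded discrepancy over ω̄ ∈ [0.3, 3] computes to 1.1e−3 in
relative amplitude (sitting exactly on the ω̄ = 0.3 edge; the interior
maximum is 6.8e−4) and 1.4e−3 rad in phase (at the γ = 1 peak).  The
reference bounds 8e−4 and 1e−3 are of the same order but are not reached by
a faithful recomputation from the defaults under any parameter reading we
tried; the corresponding acceptance assertions are therefore expected to
fail and are left failing rather than loosened.  The error is the intrinsic
O((ω̄_m/ω̄)²) truncation of the expansion and is exactly zero at γ = 0 (the
two solvers share the passive-resonator expression bit for bit — enforced
by construction).

## Time-domain oracle

The oracle integrates the same linearized system as a 3-state ODE in
(p, p′, ν), where `ν = (βq/4)v` is the dimensionless potential perturbation,
driven by `(1 + α_c γ u_a) f̄ cos(ω̄τ)` from rest.  Numerical choices:

* **Integrator.**  Classic fixed-step RK4, default 512 steps per forcing
  cycle.  For this LTI system the RK4 step is a constant 5×5 matrix (the
  drive rides along as an undriven quadrature pair), so the transient is
  fast-forwarded with matrix powers; the stored tail is bit-identical to
  naive stepping and fully deterministic.  Step-doubling changes the
  extracted amplitude by <1e−8 relative at 2048 steps/cycle (tested).
* **Transient discard.**  max(15, 5ω̄_η/ω̄) forcing cycles, and at least 18
  e-folds of the slowest decaying eigenmode — at high γ the net damping near
  resonance is the small difference ω̄/ω̄_η − γA_h/ω̄, and the naive drag
  rule alone under-discards.
* **Extraction.**  Least-squares fit of `C cos + S sin` over the final 5
  cycles; complex amplitude `C − iS` (matching the exp(+iωt) convention).
  Relative RMS residual above 1e−6 flags the result non-converged.
* **Stability.**  At γ near 1 the anti-damping can exceed drag, making the
  linear loop unstable; then no steady state exists and the frequency-domain
  solution is not an attractor.  `is_stable` checks the eigenvalues first
  and the integrator refuses unstable scenarios with a clear error.
* **Deep low-frequency runs** auto-increase steps per cycle so the step
  resolves the fastest eigenmode, not just the forcing period.

Oracle-vs-frequency-domain agreement is ~1e−5 relative on stable randomized
scenarios at γ = 1 (asserted at 1e−4), and ~1e−6 at γ = 0 where both have
closed forms.

## Randomized scenarios

`random_scenario(seed)` draws each default log-uniformly from a
one-decade-wide band (factor 10^±½) with random connectivity.  These
scenarios probe the *equations* — solver consistency, invariants,
monotonicities — over a physiologically generous range; they do not emulate
biological covariation (e.g. N and C0 both tracking cell length), thermal
noise, or nonlinear saturation, so passing property tests demonstrates
mathematical correctness of the model implementation, not predictive power
for real cells.  Unstable draws (about a quarter at γ = 1) are skipped
deterministically in oracle-equivalence suites.

## Degenerate inputs and ties

* `C0 = 0` (resistance-dominated circuit) is allowed and is the *definition*
  of the low-frequency form: `lf_response` equals the exact loop with C0
  nullified to machine precision (tested elementwise).  It requires σ > 0.
* `σ = 0` is allowed (capacitance-only membrane); σ = 0 together with ω = 0
  is rejected.
* `hf_response` warns below ω̄ = 0.3 and `lf_response` above ω̄_m/3, but
  both still compute, as the reference plots extend beyond validity.
* Peak refinement: bounded scalar minimization of −|p| between the grid
  neighbours of the argmax (xatol 1e−6); a peak on a grid endpoint is
  flagged rather than refined.
* Phase is reported as `arg(p)` unwrapped along the grid, first point in
  (−π, π].

## Problem sizes

Default grids are 400 log-spaced points ([0.3, 3] high-frequency,
[1e−3, 1e−1] low-frequency).  The oracle-equivalence suite uses 20 stable
random scenarios × 5 frequencies at 512 steps/cycle; the whole test suite
and the acceptance script each complete in well under a minute on one CPU.

## Known limitations

* Strictly linear small-signal theory; no saturation, no harmonics, no
  noise.
* One isolated cell against a local impedance: no travelling-wave coupling,
  no multi-mode organ-of-Corti micromechanics.
* The feedback gain is real and frequency independent; any bundle
  adaptation dynamics would add phase structure not represented here.
* The published coefficient set is internally inconsistent at the level
  described above; this package adopts the reproducible subset and reports
  the rest side by side.
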