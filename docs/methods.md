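# Model and methods

## Overview

`musasi` simulates cardiac half-sarcomere contraction by coupling two
scales. At the micro scale, every myosin head is a six-state Markov chain
(three detached states `N_XB`, `P_XB`, `N_ATP`; three strongly bound states
`XB_PreR`, `XB_PostR1`, `XB_PostR2`) advanced by Monte Carlo micro steps of
Δt ≈ 5 μs, with Ca²⁺ regulation by troponin/tropomyosin (T/T) gate units
and nearest-neighbour cooperativity. At the macro scale, a continuum stretch
λ(t) is advanced implicitly with a Newmark-β/Newton integrator at
ΔT ≈ 1.25 ms. The two scales are coupled by multiple-step active-stiffness
integration: all MC events of one macro interval are computed once on the
stretch path extrapolated with the start-of-interval stretch rate, and then,
inside every Newton iteration, the rod strains of the bound heads are
re-evaluated on the stretch path interpolated to the current trial end
stretch λ_{T+ΔT}, keeping the event sequence frozen. The active tension is
the impulse-matching average

T_act = 2 R_S / (SA₀ N_F n) · Σ_{j,i,k} δ_A dW/dx(x_{ij,k}),   x in nm, T in MPa,

and its derivative with respect to λ_{T+ΔT},

∂T_act/∂λ = 2 R_S / (SA₀ N_F n) · Σ δ_A d²W/dx² · (SL₀/2)(k/n − k_A/n) ≥ 0,

is assembled into the Newton matrix. Because (k/n − k_A/n) ≥ 0 for every
bound entry and the rod potential is convex, this active stiffness is
non-negative, which is what stabilises the implicit scheme. The explicit
comparator evaluates the same sum on the frozen extrapolated strains; it is
independent of the trial stretch, contributes no stiffness, and is only
stable when ΔT resolves μ_S/K_A(R_B) (≈ 0.35/R_B μs at the reference
parameters).

## Cross-bridge mechanics

* Rod: piecewise-quadratic strain energy W(x) = ½k± x², k₊ = 2 pN/nm
  (tension), k₋ = 1 pN/nm (compression; the rod buckles more easily), convex
  with continuous force at x = 0. Heads whose strain leaves [−10, 10] nm are
  forcibly detached into `N_ATP`.
* Attachment strain: drawn from the Boltzmann density ∝ exp(−W(x)/k_BT)
  truncated to the strain domain (two half-Gaussians, σ± = √(k_BT/k±)),
  k_BT = 4.28 pN·nm (310 K).
* Power strokes: lever-arm steps s₁ = 6 nm and s₂ = 4 nm with chemical
  drops E₀−E₁ = 36 and E₁−E₂ = 32 pN·nm. Two interchangeable rate laws:
  the destination-strain-energy (DSE) law
  h_f,i(x) = h_i exp(−(W(x+s_i) − (E_{i−1}−E_i))/k_BT),
  h_b,i(x+s_i) = h_i exp(−W(x)/k_BT), and the barrier-strain-energy (BSE,
  Kramers escape) law with the barrier at the mid strain. Both satisfy the
  Boltzmann condition h_f/h_b = exp(−ΔG_i(x)/k_BT) exactly; when either rate
  of a pair exceeds r_max = 10⁵ s⁻¹ the pair is rescaled so the larger
  equals r_max, which preserves the condition to machine precision.
* Attachment/detachment: P_XB → XB_PreR at k_a, XB_PreR → P_XB at k_d,
  XB_PostR2 → N_XB at k_off and N_ATP → N_XB at k_rec (the last two consume
  one ATP each, and are counted as such).

## Regulation and cooperativity

The N_XB ↔ P_XB exchange carries the cooperative factors γ^{ng} (forward)
and γ^{−ng} (backward), ng ∈ {0,1,2} counting nearest neighbours in weak- or
strong-binding states; γ = 40 by default. The T/T gate above each head is a
three-state chain off ↔ on_Ca ↔ open with first-order Ca²⁺ binding; only
the open state permits N_XB → P_XB. While any head below a unit is attached,
the unit's closing rate is multiplied by `hold_factor` = 0.15 — a steric
holding of tropomyosin by bound heads (the micro model's second, gate-borne
cooperativity pathway). Without it, the cooperative on-state at submaximal
Ca²⁺ is destroyed by sub-nanometre sustained stretch drifts: the γ²
amplification turns a per-head perturbation into collective cluster
extinction (measured: a 0.025 nm/interval drift suppressed binding two- to
three-fold in either direction).

## Parameters

Printed reference constants: γ = 40, N_M = 38 heads per filament,
N_F = 16 filaments (4–64 supported), SA₀ = 693 nm², R_S = 0.5,
SL₀/2 = 950 nm, k_rod = 2 pN/nm, r_max = 10⁵ s⁻¹, Δt₀ = 5 μs,
ΔT₀ = 1.25 ms, μ_S = 36.66 Pa·s, BSE prefactors g₁ = 20 s⁻¹,
g₂ = 0.1 s⁻¹, and the BSE attachment gate k_np × 1.1. The number of micro
steps per macro step is n = ⌊(ΔT − 0.5Δt₀)/Δt₀⌋ + 1 (250 at ΔT₀).

Kinetic constants without printed reference values are config fallbacks,
calibrated once against physiological targets and then frozen: k_np0 = 50 s⁻¹, k_pn0 = 1850 s⁻¹,
k_a = 12 s⁻¹, k_d = 500 s⁻¹, k_off = 200 s⁻¹, k_rec = 500 s⁻¹, DSE
prefactors h₁ = h₂ = 1000 s⁻¹, T/T (k_onCa = 150 μM⁻¹s⁻¹,
k_offCa = 3000 s⁻¹, k_open = 1500 s⁻¹, k_close = 250 s⁻¹, hold 0.15).
Calibration targets: half-activation of the γ = 40 force–pCa curve near
pCa 6 (measured 6.37 with Hill coefficient ≈ 4.6); essentially empty
strong-binding population at diastolic Ca²⁺ (10 % of peak; measured
XB_PostR2 ≈ 0.003 %); twitch peak binding ratio of a few percent (measured
≈ 0.04, consistent with the significance of even R_B ~ 0.02 for active
stiffness); activation and relaxation completing within a 1 s beat.

The Ca²⁺ drive is a parametric stand-in for a ventricular-myocyte
transient: a periodic double-exponential pulse (rise 20 ms, decay 150 ms,
period 1 s) normalised to a 1 μM peak riding on a 10 % diastolic pedestal.
The peak level is a convention, not a printed value.

## Micro-step sampling and validity

Per micro step, every head and every gate resolves at most one transition,
drawn with probability p_e = (r_e/r_tot)(1 − e^{−r_tot Δt}) using
start-of-step states for all hazards (synchronous update), so results do
not depend on iteration order. With r_max Δt = 0.5 the only admissible
excess of r_tot Δt over 0.5 is a small constant-rate rider on a capped
stroke edge; the engine tracks max(r_tot Δt) and raises beyond 0.55.
Randomness is counter-based (splitmix64-style hash of seed, global micro
step, entity id, draw index): one integer seed reproduces any run bitwise,
and every (filament, molecule) pair has its own logical stream.

## Macro integration

Newmark-β with Newton iterations on acceleration increments, exactly one
predictor solve at k = 0 (with the corrected right-hand side) followed by
plain Newton corrections; convergence is declared on the residual norm from
the second evaluation on, because the start-of-step residual vanishes
whenever the previous step converged. The testbeds default to β = 0.3025,
γ_N = 0.6: the slight numerical damping suppresses a velocity-ringing mode
that the undamped trapezoidal rule exhibits against Monte Carlo tension
noise and that would otherwise feed spurious sliding into the micro model
(β = ¼, γ_N = ½ remains available and is used in the energy-conservation
tests). During Newton trials, strains pushed beyond the rod domain are
clamped to the domain edge with dW/dx evaluated at the clamp and
d²W/dx² = 0 beyond it, keeping the residual continuous while the frozen MC
states are honoured. After convergence, the attachment stretches of heads
that attached within the interval are re-expressed on the interpolated path
to the converged stretch — the value the implicit tension actually used.

## Testbeds

* Uniaxial strip: single stretch DOF with
  m λ̈ + η λ̇ + T_pas(λ) + T_act = T_ext, η = μ_S (1 Pa·s = 10⁻³ MPa·ms),
  tiny consistent mass m = 10⁻⁷ MPa·ms², and an odd exponential passive law
  T_pas = c sinh(b(λ−1)) with c = 4 kPa, b = 15 (small-strain stiffness
  c·b = 60 kPa). Explicit-scheme divergence is reported, not raised.
* Serial myofibril chain: 40 half-sarcomeres (20 sarcomeres) with fixed
  ends; internal node positions are the DOFs, the Newton matrix is
  tridiagonal. Chain-specific calibration constants (the myofibril
  mechanical environment is not among the printed parameters): nodal drag
  20 MPa·ms — sized so kPa-scale tension imbalances translate into sliding
  of order 0.1 μm/s — and a stiffer titin-like element spring (c = 10 kPa,
  b = 15) so that an activated element stalls near 10 % shortening instead
  of creeping indefinitely.

The stability sweep classifies runs with the hard divergence detector
(|λ−1| > 0.5 or non-finite) and additionally reports a stretch-reversal
rate and the contraction-window mean tension, because the explicit scheme
at the macro step fails as a *bounded* macro-step oscillation: forced
detachment saturates the cross-bridge feedback, so the failure is wrong,
tension-suppressed waveforms without Newton breakdown rather than overflow.

## What the synthetic drive and testbeds do and do not show

The generator emulates beat-periodic Ca²⁺ forcing, isometric/isotonic
steady states and desk-scale mechanical coupling with a few hundred heads
per element. It does not emulate: filament-overlap (force–length)
dependence, 3D lattice geometry, whole-organ boundary conditions and
circulation, or transmural heterogeneity. Passing tests therefore
demonstrate the numerical properties of the coupling scheme (balance,
consistency, stability) and qualitative muscle physiology at element scale,
not organ-level predictions.

## Known limitations

* Spontaneous oscillatory contraction (SPOC) in the chain at constant
  0.3 μM Ca²⁺ does not emerge at the fallback kinetics: the model's tension
  and binding halve at sliding speeds of ~0.03 μm/s (about 30× more
  velocity-sensitive than cardiac muscle), because the feasible calibration
  window — diastole off at 0.1 μM, half-activation near pCa 6, twitch
  binding of a few percent, all with a single-Ca-site T/T gate and γ = 40 —
  forces a low attachment flux, and any sustained sliding then outruns
  re-attachment. In the chain this collapses activation (binding settles
  ~5× below the isometric value at the same Ca²⁺) before a sawtooth can
  organise. A frozen-node chain reproduces isometric binding exactly, so
  the deficiency is in the fallback kinetics, not the coupling. The
  corresponding acceptance test is left failing by design; see the
  reverse-stroke statistics it also reports for the DSE/BSE contrast.
* γ orders the force–pCa *position* cleanly (pCa50 6.33/6.15/5.74 for
  γ = 40/20/10) but not reliably the fitted *steepness*: activation spreads
  by gate-limited cooperative fronts whose width in Ca²⁺ is set by the
  single-site open-probability curve once γ ≥ 10, and the gate-hold latch
  adds a γ-independent steepening. A multi-site Ca²⁺ gate would be needed
  for a robust steepness ordering.
* Hill-type force–velocity behaviour is qualitatively correct (tension
  falls and ATP turnover rises with shortening speed) but quantitatively
  ~30× too steep in velocity, as above.

## Problem sizes used by the test-suite and acceptance script

Unit and property tests use 1–16 filaments per half-sarcomere and runs of
0.05–2 s; the master-equation check uses 10⁴ single-molecule replicates over
40 ms; the stability dichotomy uses 0.5 s twitches at ΔT₀ and ΔT₀/128; the
chain protocol uses 40 elements × 8 filaments over 2.5 s; the force–pCa
grids use 7–11 Ca²⁺ levels × 1–1.2 s. These sizes were chosen as the
smallest that keep Monte Carlo standard errors comfortably inside the
asserted tolerances.
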