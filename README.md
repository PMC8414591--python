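# musasi

Stochastic cross-bridge half-sarcomere simulation with multiple-step
active-stiffness integration: microsecond Monte Carlo myosin/troponin
dynamics coupled into a millisecond implicit continuum integrator.

## Who this is for

Researchers in computational muscle physiology and cardiac electromechanics
who need a molecularly stochastic contraction model — individual myosin
heads, power strokes, Ca²⁺-gated thin-filament regulation, nearest-neighbour
cooperativity — embedded in an implicit mechanical solver without losing
Newton stability. The package provides the coupling scheme, desk-scale
mechanical testbeds (a uniaxial strip and a serial myofibril chain), and the
standard physiological protocols (force–pCa, force–velocity, twitch,
constant-Ca²⁺ chain runs, explicit/implicit stability sweeps).

## The model in brief

Each half-sarcomere holds N_F × N_M myosin heads, each a six-state Markov
chain (N_XB, P_XB, N_ATP detached; XB_PreR, XB_PostR1, XB_PostR2 strongly
bound) advanced with micro steps Δt ≈ 5 μs. Power/reverse stroke rates obey
the Boltzmann condition

    h_f,i(x) / h_b,i(x+s_i) = exp(−ΔG_i(x)/k_BT),
    ΔG_i(x) = E_i + W(x+s_i) − E_{i−1} − W(x),

with W(x) the convex myosin-rod strain energy; rate pairs exceeding
r_max = 10⁵ s⁻¹ are rescaled so the condition is preserved exactly. A macro
interval [T, T+ΔT] runs n = ⌊(ΔT − 0.5Δt₀)/Δt₀⌋ + 1 micro steps on the
stretch path extrapolated with λ̇_T; inside every Newton iteration the rod
strains are re-evaluated on the path interpolated to the trial λ_{T+ΔT}
(events frozen), giving the active tension

    T_act = 2R_S/(SA₀ N_F n) Σ_{j,i,k} δ_A · dW/dx(x_{ij,T+kΔt})

and a consistent, provably non-negative active stiffness ∂T_act/∂λ_{T+ΔT}
that enters the Newmark-β/Newton matrix. With the reference constants the
macroscopic axial stiffness is K_A = (R_S/SA₀)·R_B·2N_M·k_rod·SL₀/2 =
104.2·R_B MPa, so an explicit treatment of the active tension is only
stable below ΔT ≈ μ_S/K_A ≈ 0.35/R_B μs — the reason the implicit
re-evaluation matters.

## Worked example

```python
from musasi import default_model, CaDriver, run_uniaxial_twitch

model = default_model()            # DSE stroke law, gamma=40, N_F=16
df = run_uniaxial_twitch(model=model, ca=CaDriver(), duration=1000.0, seed=1)
print(f"peak tension  {df.T_act.max()*1e3:6.2f} kPa")
print(f"peak binding  {df.R_B.max():6.4f}")
print(f"shortening    {(1-df.lam.min())*100:6.2f} %")
print(f"ATP / head    {df.atp.sum()/608:6.3f}")
print(f"max Newton    {df.newton_iters.max()}")
```

prints (seed 1):

```
peak tension   10.87 kPa
peak binding   0.0432
shortening     11.49 %
ATP / head     0.887
max Newton     4
```

meaning: under a 1 μM-peak Ca²⁺ transient the strip twitches to ~11 kPa
active tension with ~4 % of the 608 heads strongly bound at peak, shortens
by ~11 %, consumes ~0.9 ATP per myosin head per beat, and the implicit
solver never needs more than 4 Newton iterations per 1.25 ms step.

The command-line interface exposes the same protocols:

```bash
musasi force-pca --gamma 40 --nf 16 --seed 1 --out out/
musasi twitch --scheme explicit --DT 1.25 --seed 1 --out out/
musasi spoc --model bse --ca 0.3 --out out/
musasi stability --seed 1 --out out/
```

Each command writes CSV tables plus a `manifest.json` with the resolved
parameters; identical commands with identical seeds produce byte-identical
output.

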