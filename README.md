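# izhmass

A next-generation neural mass model of Izhikevich spiking-neuron
populations with conductance-based AMPA and GABA synapses and — the point
of the package — NMDA synapses carrying the full nonlinear
voltage-dependent magnesium block.

It is aimed at computational neuroscientists who need a mesoscopic
(population-level) building block that keeps both the mean firing rate
*r* and the mean membrane potential *v* as explicit state variables, so
that voltage-dependent synaptic mechanisms (NMDA coincidence detection,
neuromodulatory conductance scaling) act on the population the way they
act on single cells.

## The model

Each neuron is an Izhikevich (quadratic-integrate-and-fire + adaptation)
unit; after nondimensionalization (resting potential ↦ v = 0, NMDA
reversal ↦ v = 1) the all-to-all network reads

    dv_i/dt = v_i(v_i − α) − u_i + η_i + I + g_A(e_A − v_i) + g_G(e_G − v_i) + g_N f_N(v_i)
    du_i/dt = a(b v_i − u_i),      v_i > v_peak : v_i ← v_reset, u_i ← u_i + u_jump
    τ_s dg_s/dt = −g_s + J_s · (rate)

with Cauchy-distributed background currents η_i ~ Lorentzian(η̄, Δ) and
the NMDA driving term

    f_N(v) = (e_N − v) · B(v),    B(v) = [1 + ([Mg²⁺]₀/k₀) exp(|V_r|(v−1)/V₀)]⁻¹.

Because the Lorentzian-ansatz closure needs a polynomial voltage
equation, `izhmass` fits f_N with a quadratic–quadratic–linear piecewise
polynomial (continuous in value and slope at free knots v₀, v₁, fitted by
constrained least squares), which yields the exact mean-field equations

    dr/dt = r(−α − g_A − g_G) + 2 r v + g_N (∂f_N/∂v) r + Δ/π
    dv/dt = v(v − α) − u + η̄ + I − (1 + g_N p₂(v)) π² r² + g_A(e_A − v) + g_G(e_G − v) + g_N f_N(v)
    du/dt = a(b v − u) + u_jump r
    τ_s dg_s/dt = −g_s + J_s · r  (recurrent)  or  J_s · r_input  (external)

where p₂(v) is the smoothed (tanh-blended) quadratic coefficient of the
fit. Setting B ≡ 1 gives the classical *linear* NMDA approximation, kept
as a switchable mode for comparison. The Kuramoto order parameter follows
from the conformal map Z = (1 − W̄)/(1 + W̄), W = πr + iv.

Two canonical presets are built in: excitatory regular-spiking cortical
neurons (recurrent AMPA, external AMPA+NMDA input) and inhibitory
striatal medium spiny neurons (recurrent GABA, external AMPA+NMDA
input), each with every constant regenerated from its dimensional values.
A finite-N spiking-network simulator (numba-accelerated Euler with exact
per-neuron Mg²⁺ block) serves as the brute-force oracle for the
reduction.

## Worked example

```python
import numpy as np
from izhmass import (case1_preset, MeanFieldModel, MeanFieldState,
                     simulate_mean_field, find_fixed_points)

bundle = case1_preset(eta_bar=1.5, Delta=0.002)        # cortical RS preset
params = bundle.dimless.with_couplings(A={"J_rec": 6.0})
print(round(params.alpha, 3), round(params.syn["A"].tau_s, 2))
# 0.488 19.84

model = MeanFieldModel(params, fit=bundle.fit)          # nonlinear NMDA mode
fp = find_fixed_points(model)[0]
print(fp.stability, round(fp.state.r, 4), round(fp.state.v, 4))
# stable 0.1171 0.5925
```

The fixed point says: with background current η̄ = 1.5 the population sits
at a constant dimensionless rate r* = 0.117 (≈ 387 spk/s per neuron after
multiplying by the time scale k|V_r|/C_m = 3.31/ms) and mean potential
v* = 0.59, i.e. depolarized to about −34 mV. The same regime can be
cross-checked against the spiking network:

```python
from izhmass import NetworkConfig, simulate_network
cfg = NetworkConfig(params=params, N=10_000, T=300.0, seed=1,
                    u_init=fp.state.u, v_init=(fp.state.v, 0.3),
                    g_init=(fp.state.g_A, 0.0, 0.0), record_raster=False)
raster, trace = simulate_network(cfg)
print(round(trace.r[trace.rate_t > 150].mean(), 4))
# 0.1162
```

From the command line:

```bash
izhmass presets --case 1          # echo the resolved parameter bundle
izhmass scan --preset fig2        # eta bifurcation scan, JSON output
izhmass compare --preset fig4     # nonlinear-vs-linear NMDA comparison
```

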