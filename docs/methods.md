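# Methods

## Model and assumptions

`izhmass` implements the exact mean-field ("next-generation neural mass")
reduction of an all-to-all population of Izhikevich neurons with
conductance-based synapses, on the dimensionless scale in which the
resting potential maps to v = 0 and the glutamatergic reversal (0 mV) to
v = 1. The reduction rests on four assumptions:

1. **Lorentzian ansatz.** Membrane potentials across the population
   follow a Cauchy (Lorentzian) distribution at all times; together with
   Cauchy-distributed background currents η_i this closes the population
   density equation exactly, leaving ODEs for the mean rate r and mean
   potential v.
2. **Quadratic voltage equation.** Closure requires the single-neuron
   voltage equation to be (at most) quadratic in v. AMPA/GABA
   conductance terms are linear in v and pose no problem; the NMDA term
   f_N(v) = (e_N − v)B(v) is not polynomial and is replaced by the
   piecewise polynomial fit described below.
3. **Adiabatic adaptation.** The recovery current u is slow
   (a ≈ 0.002–0.006 in the presets, i.e. a timescale of hundreds of
   dimensionless time units) and is treated as common to all neurons in
   the reduction. The finite-N oracle deliberately keeps per-neuron u_i,
   so network-vs-mean-field discrepancies *include* the error of this
   approximation rather than hiding it.
4. **Infinite spike cutoff.** The reduction takes v_peak → ∞. The
   dimensionless parameter set therefore defaults to the large symmetric
   surrogate v_peak = +100, v_reset = −100. Mapping the physiological
   cutoffs (e.g. +30 mV / −65 mV) through the scaling instead is
   supported (`map_reset_bounds=True`) but biases the network's steady
   rate upward by a few percent relative to the reduction — measured
   directly with the oracle during development.

The slow NMDA conductance's contribution to the rate flux is neglected
in the reduction (its decay constant is 25–40× the voltage timescale),
which is why g_N multiplies ∂f_N/∂v rather than acquiring its own flux
term.

## The piecewise fit of the NMDA nonlinearity

f_N is approximated by a quadratic–quadratic–linear piecewise polynomial
with **free interior knots** (v₀, v₁). The optimization vector is
(a₀, a₁, a₂, b₂, v₀, v₁); the remaining middle-branch and tail
coefficients are *derived* from value- and slope-continuity at both
knots, so continuity is exact by construction rather than penalized.
Residuals are minimized with Levenberg–Marquardt over 500 uniform grid
points (coefficients are grid-insensitive at the reported precision).

The fitted interval is [v_cut, 2] with v_cut = −1.0 by default. The
choice matters: fitting from −1.2 shifts the lower-branch curvature
(a₂ ≈ 0.077 instead of ≈ 0.092) and the first knot by ~0.015. With
v_cut = −1.0 the fit reproduces the canonical coefficient tables for
both presets at two decimals, and the max absolute error over the fitted
interval is ≈ 0.012–0.014 (the enforced bound is 0.02). Below v_cut the
lower quadratic extrapolates; the mean-field trajectories of interest
stay well inside the fitted interval.

One sign in the canonical case-1 table deserves note: the middle-branch
curvature is stored as b₂ = −1.158. The positive value sometimes quoted
for this case breaks value- and slope-continuity at both knots by ~0.4,
while the negative value is continuous to ~10⁻³ and is what the fit
itself produces (the case-2 table is negative as printed). A regression
test pins this down.

Only p₂(v) — the quadratic coefficient as a function of v — enters the
reduced equations in smoothed form: three tanh steps of width σ = 0.15
centred at v_cut, v₀, v₁, keeping the vector field C¹. The rate
equation uses the closed-form derivative ∂f_N/∂v of the *exact* block,
not the piecewise derivative, again to avoid discontinuities.

## Parameters

Scaling relations (|V_r| in mV, k the quadratic factor, C_m the
capacitance): α = 1 + V_t/|V_r|, e_s = 1 + E_s/|V_r|,
τ_s = (k|V_r|/C_m)τ_syn, J_s = G_jump/(k|V_r|), a = C_m a_izh/(k|V_r|),
b = b_izh/(k|V_r|), u_jump = d/(kV_r²), I = Ī/(kV_r²). The factor
k|V_r|/C_m (per ms) converts dimensionless time and frequency to
physical units (f_Hz = f × k|V_r|/C_m × 1000).

Mg²⁺ block constants (physiological): [Mg²⁺]₀ = 1 mM, k₀ = 3.57 mM,
1/V₀ = −0.062/mV. At rest (v = 0, |V_r| ≈ 80 mV) B ≈ 0.02: the channel
is 98% blocked, the "coincidence detector" property.

Preset highlights:

| | case 1 (cortical RS) | case 2 (striatal MSN) |
|---|---|---|
| C_m, V_r, V_t, k | 1, −82.66, −42.344, 0.04 | 15.2, −80, −29.7, 1 |
| α | 0.488 | 0.629 |
| τ_A, τ_N, τ_G | 19.84, 529, (13.2; unused) | 31.58, 842.1, 21.05 |
| wiring | recurrent AMPA; input AMPA+NMDA | recurrent GABA; input AMPA+NMDA |

Case 1 stores V_r = −82.66 mV (for which d_jump = 8 − bV_r = 24.532 and
Ī = −bV_r = 16.532 are exact); the full factorization of the classical
0.04V² + 5V + 140 form gives −82.656, a difference that is invisible at
the reported precision. Case-2 adaptation constants (a = 0.01, b = −20,
u_jump = 91) are dimensional Izhikevich constants and pass through the
scaling like the rest.

The NMDA conductance equation uses τ_N by default. The alternative
convention in which g_N relaxes on the AMPA timescale is supported via
`DimensionlessParams.g_N_tau = "A"`; with external-input-driven NMDA
(both presets) the choice only affects transient duration, not the
steady conductance g_N* = J_N r_input.

## Numerics

- **Mean-field integration:** `solve_ivp` (LSODA, rtol 1e-8, atol 1e-10)
  sampled on a uniform grid (default dt = 0.1); a fixed-step RK4 mode at
  the same dt exists for strict step-size replication. Blow-up beyond
  |state| = 10⁶ aborts with the failure time.
- **Fixed points:** the conductances and u are eliminated analytically
  at equilibrium (g_s* = J_rec r + J_in r_input, u* = bv + u_jump r/a),
  reducing root-finding to (r, v); scipy's hybrid Newton runs from a
  standard seed set plus seeded random starts, duplicates merge at 1e-6,
  residuals must fall below 1e-9 against the full vector field.
  Stability comes from the eigenvalues of a central-finite-difference
  Jacobian (relative step 1e-6) of the full system; |Re λ| < 1e-7 is
  flagged marginal.
- **Scans:** naive continuation (each grid point seeded from its
  neighbor); folds appear as branch gaps plus fresh-seed branches, which
  is sufficient to recover the qualitative diagrams. Stability
  transitions are bisected to 1e-4 in the parameter and labelled Hopf
  when the crossing eigenvalue pair is complex.
- **Network oracle:** fixed-step explicit Euler, default dt = 1e-3
  (halving dt changes steady rates by < 0.5%; a convergence test
  enforces 2%). All-to-all coupling makes the conductances global
  scalars; each recurrent spike adds J_rec/(Nτ). Spikes are recorded at
  the crossing step without interpolation. Background currents use
  deterministic midpoint Cauchy quantiles by default (no sampling noise;
  for odd N the median neuron receives exactly η̄), i.i.d. draws
  optionally.
- **Rate/voltage estimators:** the population rate bins spike counts
  (default 0.5 time units); the mean potential is a trimmed mean over
  |v| ≤ 10, which excludes reset excursions but inherits a small
  (-0.01…-0.03) bias from the Lorentzian tails — visible in the
  voltage tolerance used by the oracle tests.
- **Spectra and synchrony:** rectangular-window periodogram
  (mean removed; Parseval holds to rounding), with slow/fast dominant
  peaks split at a configurable dimensionless frequency (default 0.05,
  chosen at the spectral gap of the studied regimes). Period estimates
  use the autocorrelation maximum past its first zero crossing, with a
  `min_period` guard to target the slow envelope of multiscale
  oscillations.

## Simulation horizons

Oscillation statistics discard the first 50% of each run; the default
horizon T = 2000 covers ≥ 10 slow cycles of the slowest studied regime
(period ≈ 150) after burn-in, enough for the amplitude and spectral-peak
comparisons to be insensitive to the initial condition (r = Δ/π,
v = −0.5, rest zero — initial conditions are a free choice of the
package). Network-vs-mean-field checks warm-start the network from the
mean-field equilibrium (or the cycle-averaged state) and use
T = 300–800 at N = 10⁴; warm-starting shortens the u transient
(timescale 1/a ≈ 165) without influencing where the network settles.

## What the oracle does and does not show

The finite-N network is a *synthetic* ground truth: it shares the
all-to-all topology, Cauchy heterogeneity and absent synaptic rise times
of the derivation. Agreement (steady rate ≈ 0.1–1% at N = 10⁴ with the
large symmetric cutoff, limit-cycle period within ~7%) validates the
reduction's algebra and the piecewise-fit treatment of the NMDA block,
including the per-neuron vs common adaptation approximation. It says
nothing about sparse connectivity, conduction delays, synaptic rise
times, finite-size noise beyond N = 10⁴, or non-Cauchy heterogeneity —
all outside the model class.

Known limitations: no two-parameter bifurcation surfaces or Floquet
analysis; continuation is grid-based (no pseudo-arclength), so very
narrow stable windows can be missed if the scan grid is coarser than the
window; the trimmed-voltage estimator's tail bias grows with r (scale
πr of the voltage distribution).
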