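"""Finite-N spiking-network oracle for the mean-field reduction.

Simulates the all-to-all population of Izhikevich neurons on the
dimensionless scale:

    dv_i/dt = v_i (v_i - alpha) - u_i + eta_i + I
              + g_A (e_A - v_i) + g_G (e_G - v_i) + g_N f_N(v_i)
    du_i/dt = a (b v_i - u_i)
    tau_s dg_s/dt = -g_s + J_in,s r_input(t)   (+ recurrent spike jumps)

with the reset ``v_i > v_peak -> v_i = v_reset, u_i += u_jump`` and
Cauchy-distributed background currents ``eta_i``.  Because coupling is
all-to-all, every neuron sees the same conductances and each recurrent
spike increments ``g_s`` by ``J_rec,s / (N tau_s)``; the adaptation
``u_i`` stays per-neuron (the mean-field's common-``u`` adiabatic
approximation is *not* applied here, so discrepancies bound that
approximation's error).

Integration is fixed-step explicit Euler (spike handling favors a fixed
step); the quadratic blow-up near threshold demands a small ``dt``
(default 1e-3), which is a config knob covered by a convergence test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import DimensionlessParams

__all__ = [
    "NetworkConfig", "SpikeRaster", "PopulationTrace",
    "sample_lorentzian", "simulate_network",
    "population_rate", "population_voltage",
]


def sample_lorentzian(eta_bar: float, Delta: float, N: int,
                      scheme: str = "deterministic",
                      seed: int | None = None) -> np.ndarray:
    """Background currents from the Cauchy(eta_bar, Delta) distribution.

    ``deterministic`` returns the N midpoint quantiles
    ``eta_bar + Delta tan(pi (q_i - 1/2))`` with ``q_i = (i + 1/2)/N``
    (for odd N the middle element is exactly ``eta_bar``); ``random``
    draws i.i.d. with the given seed.
    """
    if Delta <= 0:
        raise ValueError("Delta must be positive")
    if N < 1:
        raise ValueError("N must be at least 1")
    if scheme == "deterministic":
        q = (np.arange(N) + 0.5) / N
        return eta_bar + Delta * np.tan(np.pi * (q - 0.5))
    if scheme == "random":
        rng = np.random.default_rng(seed)
        return eta_bar + Delta * rng.standard_cauchy(N)
    raise ValueError("scheme must be 'deterministic' or 'random'")


@dataclass(frozen=True)
class NetworkConfig:
    """Configuration of one finite-N network run."""

    params: DimensionlessParams
    N: int = 10_000
    dt: float = 1e-3
    T: float = 100.0
    eta_assignment: str = "deterministic"  # or 'random'
    seed: int = 0
    rate_bin: float = 0.5  # window for the population-rate estimate
    sample_dt: float = 0.1  # sampling step for population traces
    v_avg_cut: float = 10.0  # |v| threshold excluding spike excursions
    v_init: tuple[float, float] = (-0.5, 0.2)  # mean, spread of initial v
    u_init: float = 0.0  # common initial adaptation (u settles on ~1/a)
    g_init: tuple[float, float, float] = (0.0, 0.0, 0.0)  # initial (g_A, g_N, g_G)
    record_raster: bool = True
    raster_cap: int = 5_000_000
    record_states: bool = False

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.dt <= 0 or self.T <= 0:
            raise ValueError("dt and T must be positive")
        if self.rate_bin < self.dt:
            raise ValueError("rate_bin must be at least dt")
        if self.sample_dt < self.dt:
            raise ValueError("sample_dt must be at least dt")
        if self.v_avg_cut <= self.params.alpha:
            raise ValueError("v_avg_cut must exceed alpha")


@dataclass(frozen=True)
class SpikeRaster:
    """Spike events (neuron index, time) of one run."""

    neuron: np.ndarray
    time: np.ndarray
    N: int
    T: float

    def __post_init__(self) -> None:
        if len(self.neuron) != len(self.time):
            raise ValueError("neuron and time arrays must have equal length")

    @property
    def n_spikes(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class PopulationTrace:
    """Binned population estimators of the mean-field variables."""

    t: np.ndarray  # sample times
    v_mean: np.ndarray  # trimmed mean membrane potential
    u_mean: np.ndarray
    g_A: np.ndarray
    g_N: np.ndarray
    g_G: np.ndarray
    kuramoto: np.ndarray  # complex N^-1 sum exp(2i arctan v_j)
    rate_t: np.ndarray  # rate-bin centers
    r: np.ndarray  # population rate per neuron per unit time
    all_excluded: np.ndarray  # flags: no neuron below v_avg_cut at sample
    v_states: np.ndarray | None = None  # (n_samples, N) if recorded


@njit(cache=True)
def _euler_loop(v, u, eta, g_A, g_N, g_G, dt, n_steps,
                alpha, I, a, b, u_jump, v_peak, v_reset,
                e_A, e_N, e_G, tau_A, tau_N, tau_G,
                jrec_A, jrec_N, jrec_G, jin_A, jin_N, jin_G,
                r_input, nonlinear, mg_ratio, slope,
                sample_every, v_avg_cut,
                counts, v_mean, u_mean, gA_tr, gN_tr, gG_tr,
                kur_re, kur_im, excluded,
                spike_n, spike_t, raster_cap, record_raster,
                v_states, record_states):
    N = v.shape[0]
    n_rec = 0
    overflow = False
    i_sample = 0
    last_vmean = 0.0
    for step in range(n_steps):
        rin = r_input[step]
        n_spk = 0
        for i in range(N):
            vi = v[i]
            if nonlinear:
                ex = slope * (vi - 1.0)
                if ex > 700.0:
                    ex = 700.0
                elif ex < -700.0:
                    ex = -700.0
                fN = (e_N - vi) / (1.0 + mg_ratio * np.exp(ex))
            else:
                fN = e_N - vi
            dv = (vi * (vi - alpha) - u[i] + eta[i] + I
                  + g_A * (e_A - vi) + g_G * (e_G - vi) + g_N * fN)
            du = a * (b * vi - u[i])
            vi += dt * dv
            u[i] += dt * du
            if vi > v_peak:
                vi = v_reset
                u[i] += u_jump
                n_spk += 1
                if record_raster:
                    if n_rec < raster_cap:
                        spike_n[n_rec] = i
                        spike_t[n_rec] = (step + 1) * dt
                        n_rec += 1
                    else:
                        overflow = True
            if not np.isfinite(vi) or not np.isfinite(u[i]):
                return n_rec, overflow, step, i
            v[i] = vi
        counts[step] = n_spk
        g_A += dt * (-g_A + jin_A * rin) / tau_A + jrec_A * n_spk / (N * tau_A)
        g_N += dt * (-g_N + jin_N * rin) / tau_N + jrec_N * n_spk / (N * tau_N)
        g_G += dt * (-g_G + jin_G * rin) / tau_G + jrec_G * n_spk / (N * tau_G)
        if (step + 1) % sample_every == 0:
            sv = 0.0
            su = 0.0
            cnt = 0
            kr = 0.0
            ki = 0.0
            for i in range(N):
                if abs(v[i]) <= v_avg_cut:
                    sv += v[i]
                    cnt += 1
                su += u[i]
                th = 2.0 * np.arctan(v[i])
                kr += np.cos(th)
                ki += np.sin(th)
            if cnt > 0:
                last_vmean = sv / cnt
            else:
                excluded[i_sample] = True
            v_mean[i_sample] = last_vmean
            u_mean[i_sample] = su / N
            gA_tr[i_sample] = g_A
            gN_tr[i_sample] = g_N
            gG_tr[i_sample] = g_G
            kur_re[i_sample] = kr / N
            kur_im[i_sample] = ki / N
            if record_states:
                for i in range(N):
                    v_states[i_sample, i] = v[i]
            i_sample += 1
    return n_rec, overflow, -1, -1


def simulate_network(cfg: NetworkConfig, r_input=0.0,
                     nmda_mode: str = "nonlinear") -> tuple[SpikeRaster, PopulationTrace]:
    """Integrate the network and return spikes plus population estimators.

    ``r_input`` may be a scalar or a per-step array of length T/dt.
    In ``linear`` mode the Mg2+ block is replaced by 1 (f_N = e_N - v);
    with ``g_N = 0`` both modes follow bit-identical trajectories.
    """
    if nmda_mode not in ("nonlinear", "linear"):
        raise ValueError("nmda_mode must be 'nonlinear' or 'linear'")
    p = cfg.params
    n_steps = int(round(cfg.T / cfg.dt))
    sample_every = max(1, int(round(cfg.sample_dt / cfg.dt)))
    n_samples = n_steps // sample_every

    rng = np.random.default_rng(cfg.seed)
    eta = sample_lorentzian(p.eta_bar, p.Delta, cfg.N,
                            scheme=cfg.eta_assignment, seed=cfg.seed)
    v = cfg.v_init[0] + cfg.v_init[1] * rng.standard_normal(cfg.N)
    u = np.full(cfg.N, float(cfg.u_init))

    r_in = np.broadcast_to(np.asarray(r_input, dtype=float),
                           (n_steps,)).copy() if np.ndim(r_input) else \
        np.full(n_steps, float(r_input))
    if len(r_in) != n_steps:
        raise ValueError("r_input series must have length T/dt")

    counts = np.zeros(n_steps, dtype=np.int64)
    v_mean = np.zeros(n_samples)
    u_mean = np.zeros(n_samples)
    gA_tr = np.zeros(n_samples)
    gN_tr = np.zeros(n_samples)
    gG_tr = np.zeros(n_samples)
    kur_re = np.zeros(n_samples)
    kur_im = np.zeros(n_samples)
    excluded = np.zeros(n_samples, dtype=np.bool_)
    cap = cfg.raster_cap if cfg.record_raster else 1
    spike_n = np.zeros(cap, dtype=np.int64)
    spike_t = np.zeros(cap)
    if cfg.record_states:
        if cfg.N * n_samples > 20_000_000:
            raise MemoryError("record_states would exceed the state-buffer limit; "
                              "reduce N, T or the sampling rate")
        v_states = np.zeros((n_samples, cfg.N))
    else:
        v_states = np.zeros((1, 1))

    chA, chN, chG = p.syn["A"], p.syn["N"], p.syn["G"]
    n_rec, overflow, bad_step, bad_i = _euler_loop(
        v, u, eta, *(float(g) for g in cfg.g_init), cfg.dt, n_steps,
        p.alpha, p.I, p.a, p.b, p.u_jump, p.v_peak, p.v_reset,
        chA.e_s, chN.e_s, chG.e_s,
        p.tau_of("A"), p.tau_of("N"), p.tau_of("G"),
        chA.J_rec, chN.J_rec, chG.J_rec,
        chA.J_input, chN.J_input, chG.J_input,
        r_in, nmda_mode == "nonlinear",
        p.mg.mg_conc / p.mg.k0, p.V_r_ref * p.mg.inv_V0,
        sample_every, cfg.v_avg_cut,
        counts, v_mean, u_mean, gA_tr, gN_tr, gG_tr,
        kur_re, kur_im, excluded,
        spike_n, spike_t, cap, cfg.record_raster,
        v_states, cfg.record_states,
    )
    if bad_step >= 0:
        raise FloatingPointError(
            f"non-finite state at t={(bad_step + 1) * cfg.dt:.4f}, neuron {bad_i}")
    if overflow:
        raise RuntimeError(
            f"raster buffer overflow ({cap} events); raise raster_cap or "
            "set record_raster=False")

    raster = SpikeRaster(neuron=spike_n[:n_rec].copy(),
                         time=spike_t[:n_rec].copy(), N=cfg.N, T=cfg.T)
    t_samples = (np.arange(1, n_samples + 1) * sample_every) * cfg.dt
    rate_t, r = _binned_rate(counts, cfg.dt, cfg.N, cfg.rate_bin)
    trace = PopulationTrace(
        t=t_samples, v_mean=v_mean, u_mean=u_mean,
        g_A=gA_tr, g_N=gN_tr, g_G=gG_tr,
        kuramoto=kur_re + 1j * kur_im,
        rate_t=rate_t, r=r, all_excluded=excluded,
        v_states=v_states if cfg.record_states else None,
    )
    return raster, trace


def _binned_rate(counts: np.ndarray, dt: float, N: int,
                 rate_bin: float) -> tuple[np.ndarray, np.ndarray]:
    per = max(1, int(round(rate_bin / dt)))
    n_bins = len(counts) // per
    trimmed = counts[: n_bins * per].reshape(n_bins, per)
    r = trimmed.sum(axis=1) / (N * per * dt)
    t = (np.arange(n_bins) + 0.5) * per * dt
    return t, r


def population_rate(raster: SpikeRaster, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Population rate r(t): spikes per neuron per unit time, centered bins.

    An empty raster yields an all-zero trace.  The rate conserves events:
    ``sum(r) * N * bin_width`` equals the total spike count (up to the
    partial final bin, which is dropped).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(1, int(np.floor(raster.T / bin_width + 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(raster.time, bins=edges)
    t = (edges[:-1] + edges[1:]) / 2
    return t, hist / (raster.N * bin_width)


def population_voltage(states: np.ndarray, v_avg_cut: float,
                       alpha: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Trimmed mean potential per sample, excluding spike excursions.

    ``states`` has shape (n_samples, N).  Neurons with |v| > v_avg_cut are
    excluded; when every neuron is excluded at a sample the previous value
    is carried and the sample flagged in the returned boolean array.
    """
    if v_avg_cut <= alpha:
        raise ValueError("v_avg_cut must exceed alpha")
    states = np.atleast_2d(np.asarray(states, dtype=float))
    keep = np.abs(states) <= v_avg_cut
    cnt = keep.sum(axis=1)
    sums = np.where(keep, states, 0.0).sum(axis=1)
    out = np.zeros(len(states))
    flags = cnt == 0
    prev = 0.0
    for i in range(len(states)):
        if cnt[i] > 0:
            prev = sums[i] / cnt[i]
        out[i] = prev
    return out, flags
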