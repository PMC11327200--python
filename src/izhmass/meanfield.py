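"""Mean-field (neural mass) equations and their time integration.

The Lorentzian-ansatz reduction of the heterogeneous Izhikevich population
yields ODEs for the mean firing rate ``r``, mean membrane potential ``v``,
mean adaptation current ``u`` and the synaptic conductances ``g_s``:

    dr/dt = r (-alpha - g_A - g_G) + 2 r v + g_N (df_N/dv) r + Delta/pi
    dv/dt = v (v - alpha) - u + eta + I - (1 + g_N p2(v)) pi^2 r^2
            + g_A (e_A - v) + g_G (e_G - v) + g_N f_N(v)
    du/dt = a (b v - u) + u_jump r
    tau_s dg_s/dt = -g_s + J_rec,s r + J_in,s r_input

In *nonlinear* mode the NMDA terms use the exact Mg2+-block ``f_N`` and its
closed-form derivative, with the smooth quadratic coefficient ``p2(v)``
from the piecewise fit.  In *linear* mode the block is dropped
(``f_N = e_N - v``, ``df_N/dv = -1``, ``p2 = 0``), which is the classical
linear-conductance NMDA approximation with the same slow decay constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .nmda import PiecewiseFit, dfN_dv, f_N_exact, fit_piecewise, p2_smooth
from .params import DimensionlessParams

__all__ = ["MeanFieldState", "MeanFieldModel", "Trajectory", "simulate_mean_field"]

STATE_VARS = ("r", "v", "u", "g_A", "g_N", "g_G")

NMDA_MODES = ("nonlinear", "linear")


@dataclass(frozen=True)
class MeanFieldState:
    """State of the reduced population model."""

    r: float
    v: float
    u: float = 0.0
    g_A: float = 0.0
    g_N: float = 0.0
    g_G: float = 0.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("mean firing rate r must be non-negative")
        for name in ("g_A", "g_N", "g_G"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([self.r, self.v, self.u, self.g_A, self.g_N, self.g_G])

    @classmethod
    def from_array(cls, y) -> "MeanFieldState":
        return cls(*(float(x) for x in y))


class MeanFieldModel:
    """Right-hand side of the mean-field equations for one parameter set.

    Parameters
    ----------
    params : DimensionlessParams
        Scaled neuron/synapse constants, heterogeneity and couplings.
    fit : PiecewiseFit, optional
        Piecewise approximation of f_N supplying the smooth p2(v); fitted
        on demand from ``params.V_r_ref`` when omitted.
    nmda_mode : {'nonlinear', 'linear'}
    """

    def __init__(
        self,
        params: DimensionlessParams,
        fit: PiecewiseFit | None = None,
        nmda_mode: str = "nonlinear",
    ):
        if nmda_mode not in NMDA_MODES:
            raise ValueError(f"nmda_mode must be one of {NMDA_MODES}")
        self.params = params
        self.nmda_mode = nmda_mode
        if fit is None and nmda_mode == "nonlinear":
            fit = fit_piecewise(fit_ref=params.V_r_ref, mg=params.mg)
        self.fit = fit

    # -- NMDA terms, mode-dependent --------------------------------------
    def f_N(self, v):
        if self.nmda_mode == "linear":
            return self.params.e_N - np.asarray(v, dtype=float)
        return f_N_exact(v, e_N=self.params.e_N,
                         fit_ref=self.params.V_r_ref, mg=self.params.mg)

    def dfN(self, v):
        if self.nmda_mode == "linear":
            return np.full_like(np.asarray(v, dtype=float), -1.0) if np.ndim(v) else -1.0
        return dfN_dv(v, e_N=self.params.e_N,
                      fit_ref=self.params.V_r_ref, mg=self.params.mg)

    def p2(self, v):
        if self.nmda_mode == "linear":
            return np.zeros_like(np.asarray(v, dtype=float)) if np.ndim(v) else 0.0
        return p2_smooth(v, self.fit)

    def i_syn(self, v, g_A, g_N, g_G):
        """Total synaptic current at (v, g) — the observable used for PSDs."""
        p = self.params
        return (g_A * (p.e_A - v) + g_G * (p.e_G - v) + g_N * self.f_N(v))

    # -- vector field -----------------------------------------------------
    def rhs(self, t: float, y, r_input: float = 0.0) -> np.ndarray:
        """Time derivative of ``y = (r, v, u, g_A, g_N, g_G)``."""
        p = self.params
        r, v, u, g_A, g_N, g_G = y
        pi2r2 = np.pi ** 2 * r * r
        dr = (r * (-p.alpha - g_A - g_G) + 2.0 * r * v
              + g_N * self.dfN(v) * r + p.Delta / np.pi)
        dv = (v * (v - p.alpha) - u + p.eta_bar + p.I
              - (1.0 + g_N * self.p2(v)) * pi2r2
              + g_A * (p.e_A - v) + g_G * (p.e_G - v) + g_N * self.f_N(v))
        du = p.a * (p.b * v - u) + p.u_jump * r
        out = np.empty(6)
        out[0], out[1], out[2] = dr, dv, du
        for i, key in ((3, "A"), (4, "N"), (5, "G")):
            ch = p.syn[key]
            drive = ch.J_rec * r + ch.J_input * r_input
            out[i] = (-y[i] + drive) / p.tau_of(key)
        return out

    def rhs_state(self, state: MeanFieldState, r_input: float = 0.0) -> np.ndarray:
        return self.rhs(0.0, state.to_array(), r_input=r_input)


@dataclass(frozen=True)
class Trajectory:
    """Solution of the mean-field ODEs on a uniform output grid."""

    t: np.ndarray
    y: np.ndarray  # shape (6, len(t)), rows in STATE_VARS order
    r_input: float
    nmda_mode: str

    def var(self, name: str) -> np.ndarray:
        return self.y[STATE_VARS.index(name)]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def final_state(self) -> MeanFieldState:
        y = self.y[:, -1].copy()
        y[0] = max(y[0], 0.0)
        y[3:] = np.maximum(y[3:], 0.0)
        return MeanFieldState.from_array(y)


_BLOWUP = 1e6


def simulate_mean_field(
    model: MeanFieldModel,
    initial: MeanFieldState,
    T: float,
    dt: float = 0.1,
    r_input: float = 0.0,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the mean-field equations over ``[0, T]``.

    ``method`` is any ``scipy.integrate.solve_ivp`` method (adaptive step
    with dense output sampled every ``dt``), or ``'rk4'`` for a fixed-step
    classical Runge-Kutta scheme at exactly ``dt`` — the replication mode
    matching a 0.1 fixed time step.
    """
    if dt <= 0 or T <= 0:
        raise ValueError("T and dt must be positive")
    t_eval = np.arange(0.0, T + dt / 2, dt)
    y0 = initial.to_array()

    if method == "rk4":
        y = np.empty((6, len(t_eval)))
        y[:, 0] = y0
        cur = y0.copy()
        for i in range(1, len(t_eval)):
            k1 = model.rhs(0.0, cur, r_input)
            k2 = model.rhs(0.0, cur + dt / 2 * k1, r_input)
            k3 = model.rhs(0.0, cur + dt / 2 * k2, r_input)
            k4 = model.rhs(0.0, cur + dt * k3, r_input)
            cur = cur + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            if not np.all(np.isfinite(cur)) or np.max(np.abs(cur)) > _BLOWUP:
                raise RuntimeError(
                    f"mean-field trajectory blew up at t={t_eval[i]:.3f}"
                )
            y[:, i] = cur
        return Trajectory(t=t_eval, y=y, r_input=r_input, nmda_mode=model.nmda_mode)

    def blowup(t, y, *_):
        return float(_BLOWUP - np.max(np.abs(y)))

    blowup.terminal = True
    sol = solve_ivp(
        model.rhs, (0.0, T), y0, t_eval=t_eval, args=(r_input,),
        method=method, rtol=rtol, atol=atol, events=blowup,
    )
    if sol.status == 1:  # event: blow-up
        raise RuntimeError(
            f"mean-field trajectory blew up at t={sol.t_events[0][0]:.3f}"
        )
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    return Trajectory(t=sol.t, y=sol.y, r_input=r_input, nmda_mode=model.nmda_mode)
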