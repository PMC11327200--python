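"""Fixed points, stability, bifurcation scans, spectra and synchrony.

The workflow mirrors how the model's dynamical regimes are mapped out:
locate equilibria of the mean-field vector field (the conductances are
eliminated analytically at steady state, reducing the root problem to
(r, v)), classify them by the eigenvalues of the full Jacobian, sweep a
control parameter (background current ``eta`` or input rate ``r_input``)
to locate stability transitions, and characterize oscillatory regimes via
the periodogram of the total synaptic current and the Kuramoto order
parameter obtained from (r, v) by the conformal map Z = (1 - W*)/(1 + W*)
with W = pi r + i v.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.optimize import root
from scipy.signal import periodogram as _sp_periodogram

from .meanfield import MeanFieldModel, MeanFieldState, Trajectory, simulate_mean_field
from .params import DimensionlessParams

__all__ = [
    "FixedPoint", "BranchScan", "Transition", "SpectrumResult", "SyncTrace",
    "find_fixed_points", "jacobian", "jacobian_eigenvalues", "scan_parameter",
    "kuramoto_order", "periodogram_psd", "compare_modes", "ModeComparison",
]

_RESIDUAL_TOL = 1e-9
_MARGINAL_BAND = 1e-7


@dataclass(frozen=True)
class FixedPoint:
    """Equilibrium of the mean-field system with its linear stability."""

    state: MeanFieldState
    eigenvalues: np.ndarray  # sorted by real part, descending
    stability: str  # 'stable' | 'unstable' | 'marginal'
    residual: float

    @property
    def leading(self) -> complex:
        return complex(self.eigenvalues[0])

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


def _equilibrium_conductances(params: DimensionlessParams, r: float,
                              r_input: float) -> tuple[float, float, float]:
    g = []
    for key in ("A", "N", "G"):
        ch = params.syn[key]
        g.append(ch.J_rec * r + ch.J_input * r_input)
    return tuple(g)


def _reduced_rhs(model: MeanFieldModel, rv, r_input: float) -> np.ndarray:
    """(r, v) residuals with u and g eliminated at equilibrium."""
    p = model.params
    r, v = rv
    g_A, g_N, g_G = _equilibrium_conductances(p, r, r_input)
    u = p.b * v + p.u_jump * r / p.a if p.a != 0 else 0.0
    F1 = (r * (-p.alpha - g_A - g_G) + 2.0 * r * v
          + g_N * model.dfN(v) * r + p.Delta / np.pi)
    F2 = (v * (v - p.alpha) - u + p.eta_bar + p.I
          - (1.0 + g_N * model.p2(v)) * np.pi ** 2 * r * r
          + g_A * (p.e_A - v) + g_G * (p.e_G - v) + g_N * model.f_N(v))
    return np.array([F1, F2])


def _full_state(model: MeanFieldModel, r: float, v: float,
                r_input: float) -> MeanFieldState:
    p = model.params
    g_A, g_N, g_G = _equilibrium_conductances(p, r, r_input)
    u = p.b * v + p.u_jump * r / p.a if p.a != 0 else 0.0
    return MeanFieldState(r=max(r, 0.0), v=v, u=u, g_A=g_A, g_N=g_N, g_G=g_G)


def jacobian(model: MeanFieldModel, state: MeanFieldState,
             r_input: float = 0.0, rel_step: float = 1e-6) -> np.ndarray:
    """Jacobian of the full 6-D vector field by central finite differences."""
    y0 = state.to_array()
    n = y0.size
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(1.0, abs(y0[j]))
        yp, ym = y0.copy(), y0.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (model.rhs(0.0, yp, r_input) - model.rhs(0.0, ym, r_input)) / (2 * h)
    if not np.all(np.isfinite(J)):
        # auto-refine once with a larger step before giving up
        J = jacobian(model, state, r_input, rel_step=rel_step * 100)
        if not np.all(np.isfinite(J)):
            raise FloatingPointError("Jacobian finite differences did not converge")
    return J


def jacobian_eigenvalues(model: MeanFieldModel, state: MeanFieldState,
                         r_input: float = 0.0) -> np.ndarray:
    """Eigenvalues of the Jacobian, sorted by descending real part."""
    eig = np.linalg.eigvals(jacobian(model, state, r_input))
    return eig[np.argsort(-eig.real)]


def _classify(eigenvalues: np.ndarray) -> str:
    lead = float(eigenvalues[0].real)
    if abs(lead) < _MARGINAL_BAND:
        return "marginal"
    return "stable" if lead < 0 else "unstable"


def find_fixed_points(
    model: MeanFieldModel,
    r_input: float = 0.0,
    seeds: list[tuple[float, float]] | None = None,
    n_random_seeds: int = 12,
    rng_seed: int = 0,
    merge_tol: float = 1e-6,
) -> list[FixedPoint]:
    """Locate equilibria of the mean-field system from multiple seeds.

    Roots of the reduced (r, v) system are found with a damped Newton
    solver (scipy's hybr), duplicates merged at ``merge_tol`` pairwise
    distance, and each survivor verified against the full vector field
    (residual < 1e-9) and classified via the full Jacobian spectrum.
    Returns the points sorted by r; an empty list when nothing converges.
    """
    p = model.params
    base = [
        (p.Delta / np.pi, -0.2),
        (0.05, 0.0),
        (0.2, 0.5),
        (0.5, 0.9),
        (1.0, 0.95),
    ]
    if seeds:
        base = list(seeds) + base
    rng = np.random.default_rng(rng_seed)
    for _ in range(n_random_seeds):
        base.append((float(10 ** rng.uniform(-2.5, 0.3)),
                     float(rng.uniform(-1.0, 1.2))))

    found: list[tuple[float, float]] = []
    for r0, v0 in base:
        if r0 < 0:
            continue
        sol = root(lambda rv: _reduced_rhs(model, rv, r_input),
                   np.array([r0, v0]), method="hybr", tol=1e-12)
        if not sol.success:
            continue
        r, v = sol.x
        if r <= 0 or not np.all(np.isfinite(sol.x)):
            continue
        if any(np.hypot(r - r2, v - v2) < merge_tol for r2, v2 in found):
            continue
        found.append((float(r), float(v)))

    points = []
    for r, v in found:
        state = _full_state(model, r, v, r_input)
        resid = float(np.max(np.abs(model.rhs(0.0, state.to_array(), r_input))))
        if resid > _RESIDUAL_TOL:
            continue
        eig = jacobian_eigenvalues(model, state, r_input)
        points.append(FixedPoint(state=state, eigenvalues=eig,
                                 stability=_classify(eig), residual=resid))
    points.sort(key=lambda fp: fp.state.r)
    return points


@dataclass(frozen=True)
class Transition:
    """Stability change bracketed between two parameter values."""

    param: str
    lower: float
    upper: float
    kind: str  # 'hopf' (complex leading pair) | 'real'
    direction: str  # 'loss' (stable->unstable) | 'gain'


@dataclass(frozen=True)
class BranchScan:
    """Fixed points tracked along a one-parameter sweep."""

    param: str
    grid: np.ndarray
    points: list[list[FixedPoint]]  # all equilibria at each grid value
    branch: list[FixedPoint | None]  # the tracked (continued) branch
    transitions: list[Transition]

    def branch_r(self) -> np.ndarray:
        return np.array([fp.state.r if fp else np.nan for fp in self.branch])

    def branch_stable(self) -> np.ndarray:
        return np.array([fp.is_stable if fp else False for fp in self.branch])


def _with_param(model: MeanFieldModel, param: str, value: float,
                r_input: float) -> tuple[MeanFieldModel, float]:
    if param == "eta":
        m = MeanFieldModel(model.params.with_eta(value), fit=model.fit,
                           nmda_mode=model.nmda_mode)
        return m, r_input
    if param == "r_input":
        return model, value
    raise ValueError("param must be 'eta' or 'r_input'")


def scan_parameter(
    model: MeanFieldModel,
    param: str,
    grid,
    r_input: float = 0.0,
    bisect_tol: float = 1e-4,
) -> BranchScan:
    """Sweep ``eta`` or ``r_input``, tracking equilibria and transitions.

    Each grid point's Newton solves are seeded from the neighbor's
    solutions plus the standard seed set (naive continuation; folds show
    up as branch gaps).  Stability transitions of the tracked branch are
    localized by bisection to ``bisect_tol`` in the parameter.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a monotonically increasing 1-D array")

    points: list[list[FixedPoint]] = []
    branch: list[FixedPoint | None] = []
    prev: FixedPoint | None = None
    for val in grid:
        m, ri = _with_param(model, param, val, r_input)
        seeds = None
        if prev is not None:
            seeds = [(prev.state.r, prev.state.v)]
        fps = find_fixed_points(m, r_input=ri, seeds=seeds)
        points.append(fps)
        cur = None
        if fps:
            if prev is None:
                cur = fps[0]
            else:
                cur = min(fps, key=lambda fp: np.hypot(
                    fp.state.r - prev.state.r, fp.state.v - prev.state.v))
        branch.append(cur)
        if cur is not None:
            prev = cur

    transitions: list[Transition] = []
    for i in range(len(grid) - 1):
        a, b = branch[i], branch[i + 1]
        if a is None or b is None:
            continue
        sa, sb = a.leading.real, b.leading.real
        if sa == 0 or sb == 0 or np.sign(sa) == np.sign(sb):
            continue
        lo, hi = float(grid[i]), float(grid[i + 1])
        fp_lo = a
        while hi - lo > bisect_tol:
            mid = 0.5 * (lo + hi)
            m, ri = _with_param(model, param, mid, r_input)
            fps = find_fixed_points(m, r_input=ri,
                                    seeds=[(fp_lo.state.r, fp_lo.state.v)])
            if not fps:
                break
            fp_mid = min(fps, key=lambda fp: np.hypot(
                fp.state.r - fp_lo.state.r, fp.state.v - fp_lo.state.v))
            if np.sign(fp_mid.leading.real) == np.sign(sa):
                lo, fp_lo = mid, fp_mid
            else:
                hi = mid
        crossing = b if np.sign(sb) > 0 else a
        kind = "hopf" if abs(crossing.leading.imag) > 1e-8 else "real"
        transitions.append(Transition(
            param=param, lower=lo, upper=hi, kind=kind,
            direction="loss" if sa < 0 else "gain"))
    return BranchScan(param=param, grid=grid, points=points,
                      branch=branch, transitions=transitions)


# ---------------------------------------------------------------------------
# synchrony and spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyncTrace:
    """Kuramoto order parameter along a trajectory."""

    t: np.ndarray
    R: np.ndarray
    Psi: np.ndarray


def kuramoto_order(r, v):
    """Kuramoto order parameter (R, Psi) from mean rate and potential.

    Uses the conformal map from the (r, v) half-plane to the unit disk:
    W = pi r + i v, Z = (1 - conj(W)) / (1 + conj(W)).  R = |Z| is the
    degree of synchrony (1 = fully synchronized point mass at r = 0),
    Psi = arg Z the mean phase.  R < 1 strictly whenever r > 0.
    """
    r = np.asarray(r, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(r < 0):
        raise ValueError("mean firing rate must be non-negative")
    W = np.pi * r + 1j * v
    denom = 1.0 + np.conj(W)
    if np.any(np.abs(denom) < 1e-12):
        raise ZeroDivisionError("Kuramoto map pole at W = -1")
    Z = (1.0 - np.conj(W)) / denom
    R, Psi = np.abs(Z), np.angle(Z)
    if np.ndim(R):
        return R, Psi
    return float(R), float(Psi)


def sync_trace(traj: Trajectory) -> SyncTrace:
    R, Psi = kuramoto_order(np.maximum(traj.var("r"), 0.0), traj.var("v"))
    return SyncTrace(t=traj.t, R=R, Psi=Psi)


@dataclass(frozen=True)
class SpectrumResult:
    """One-sided periodogram of a uniformly sampled signal."""

    freq: np.ndarray  # dimensionless (per unit dimensionless time)
    freq_hz: np.ndarray
    power: np.ndarray

    def dominant(self, fmin: float = 0.0, fmax: float = np.inf) -> tuple[float, float]:
        """(frequency, power) of the highest peak within [fmin, fmax]."""
        mask = (self.freq > max(fmin, 0.0)) & (self.freq <= fmax)
        if not np.any(mask):
            raise ValueError("no frequency bins in the requested band")
        idx = np.argmax(self.power[mask])
        return float(self.freq[mask][idx]), float(self.power[mask][idx])


def periodogram_psd(signal, dt: float, time_scale: float = 1.0) -> SpectrumResult:
    """Rectangular-window periodogram with the mean removed.

    ``dt`` is the (uniform) sampling step in dimensionless time;
    ``time_scale`` (k|V_r|/C_m per ms) converts dimensionless frequency
    to Hz via f_Hz = f * time_scale * 1000.  Satisfies Parseval:
    sum(P) * df = var(signal).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 256:
        raise ValueError("signal must be 1-D with at least 256 samples")
    f, P = _sp_periodogram(x, fs=1.0 / dt, window="boxcar", detrend="constant")
    return SpectrumResult(freq=f, freq_hz=f * time_scale * 1e3, power=P)


def dominant_period(signal, dt: float, min_period: float = 0.0) -> float:
    """Period of the dominant repetition in a signal via autocorrelation.

    Returns the lag (> ``min_period``) maximizing the autocorrelation of
    the mean-removed signal.  ``min_period`` excludes fast intra-burst
    structure when the target is the slow envelope of a multiscale
    oscillation; the searched lags are capped at half the record length.
    """
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    n = len(x)
    if n < 16:
        raise ValueError("signal too short for a period estimate")
    acf = np.correlate(x, x, mode="full")[n - 1:]
    lag0 = max(1, int(np.ceil(min_period / dt)))
    # skip the zero-lag lobe: search only past the first sign change
    negative = np.nonzero(acf < 0)[0]
    if len(negative):
        lag0 = max(lag0, int(negative[0]))
    lag1 = n // 2
    if lag0 >= lag1:
        raise ValueError("min_period exceeds half the record length")
    return float((lag0 + np.argmax(acf[lag0:lag1])) * dt)


def check_uniform_grid(t: np.ndarray, rtol: float = 1e-8) -> float:
    dt = np.diff(np.asarray(t, dtype=float))
    if len(dt) == 0 or np.any(np.abs(dt - dt[0]) > rtol * abs(dt[0])):
        raise ValueError("time grid must be uniform")
    return float(dt[0])


# ---------------------------------------------------------------------------
# nonlinear-vs-linear comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeSummary:
    """Post-burn-in statistics of one simulated mode."""

    nmda_mode: str
    r_amplitude: float  # peak-to-trough of the mean rate
    r_mean: float
    slow_peak: tuple[float, float]  # (freq, power) below the split
    fast_peak: tuple[float, float]  # (freq, power) above the split
    mean_R: float
    trajectory: Trajectory


@dataclass(frozen=True)
class ModeComparison:
    nonlinear: ModeSummary
    linear: ModeSummary

    @property
    def amplitude_ratio(self) -> float:
        return self.nonlinear.r_amplitude / self.linear.r_amplitude


def _summarize(model: MeanFieldModel, traj: Trajectory,
               burn_frac: float, split_freq: float) -> ModeSummary:
    n0 = int(burn_frac * len(traj.t))
    r = traj.var("r")[n0:]
    v = traj.var("v")[n0:]
    isyn = model.i_syn(v, traj.var("g_A")[n0:], traj.var("g_N")[n0:],
                       traj.var("g_G")[n0:])
    psd = periodogram_psd(isyn, traj.dt, model.params.time_scale)
    R, _ = kuramoto_order(np.maximum(r, 0.0), v)
    return ModeSummary(
        nmda_mode=traj.nmda_mode,
        r_amplitude=float(r.max() - r.min()),
        r_mean=float(r.mean()),
        slow_peak=psd.dominant(0.0, split_freq),
        fast_peak=psd.dominant(split_freq, np.inf),
        mean_R=float(R.mean()),
        trajectory=traj,
    )


def compare_modes(
    params: DimensionlessParams,
    fit,
    r_input: float,
    T: float = 2000.0,
    dt: float = 0.1,
    burn_frac: float = 0.5,
    split_freq: float = 0.05,
    initial: MeanFieldState | None = None,
    method: str = "LSODA",
) -> ModeComparison:
    """Run nonlinear and linear NMDA modes from identical initial conditions.

    Reports, per mode, the peak-to-trough amplitude of the mean rate, the
    dominant slow / fast periodogram peaks of the total synaptic current
    (split at ``split_freq`` in dimensionless frequency) and the mean
    Kuramoto magnitude, all computed after discarding the first
    ``burn_frac`` of the run.
    """
    if initial is None:
        initial = MeanFieldState(r=params.Delta / np.pi, v=-0.5, u=0.0)
    summaries = {}
    for mode in ("nonlinear", "linear"):
        model = MeanFieldModel(params, fit=fit, nmda_mode=mode)
        traj = simulate_mean_field(model, initial, T=T, dt=dt,
                                   r_input=r_input, method=method)
        summaries[mode] = _summarize(model, traj, burn_frac, split_freq)
    return ModeComparison(nonlinear=summaries["nonlinear"],
                          linear=summaries["linear"])
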