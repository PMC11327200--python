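"""The NMDA receptor voltage nonlinearity and its piecewise-polynomial fit.

The NMDAR driving term in the scaled voltage equation is

    f_N(v) = (e_N - v) * B(v),
    B(v)   = 1 / (1 + (mg/k0) * exp(|V_r| (v - 1) * inv_V0))

where ``B`` is the sigmoidal magnesium block (near 0 at rest, near 1 when
depolarized).  The Lorentzian-ansatz closure of the mean field requires the
voltage equation to be polynomial in ``v``, so ``f_N`` is approximated by a
quadratic-quadratic-linear piecewise polynomial over the physiological
range ``v in [-1.2, 2]``, with value and slope continuity at both interior
knots.  The quadratic coefficient ``p2(v)`` that enters the mean-field
equations is smoothed with tanh steps of width ``sigma`` so the reduced
system stays C^1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .params import MgBlockParams

__all__ = [
    "mg_block",
    "f_N_exact",
    "dfN_dv",
    "PiecewiseFit",
    "fit_piecewise",
    "piecewise_eval",
    "p2_smooth",
]

_EXP_CLIP = 700.0  # beyond this the block saturates to its analytic limit


def _block_exponent(v, fit_ref: float, mg: MgBlockParams):
    return np.clip(fit_ref * (np.asarray(v, dtype=float) - 1.0) * mg.inv_V0,
                   -_EXP_CLIP, _EXP_CLIP)


def mg_block(v, fit_ref: float, mg: MgBlockParams | None = None):
    """Voltage-dependent Mg2+ block ``B(v)`` on the dimensionless scale.

    Parameters
    ----------
    v : array_like
        Dimensionless membrane potential (resting = 0, NMDA reversal = 1).
    fit_ref : float
        |V_r| in mV; sets the steepness of the sigmoid on the v scale.
    mg : MgBlockParams, optional
        Block constants; defaults to physiological values.

    Strictly increasing, with limits 0 as v -> -inf and 1 as v -> +inf.
    """
    mg = mg if mg is not None else MgBlockParams()
    e = np.exp(_block_exponent(v, fit_ref, mg))
    out = 1.0 / (1.0 + (mg.mg_conc / mg.k0) * e)
    return out if np.ndim(v) else float(out)


def f_N_exact(v, e_N: float = 1.0, fit_ref: float = 82.66,
              mg: MgBlockParams | None = None):
    """Exact NMDAR driving term ``(e_N - v) B(v)``."""
    out = (e_N - np.asarray(v, dtype=float)) * mg_block(v, fit_ref, mg)
    return out if np.ndim(v) else float(out)


def dfN_dv(v, e_N: float = 1.0, fit_ref: float = 82.66,
           mg: MgBlockParams | None = None):
    """Closed-form derivative of ``f_N``.

    d f_N / dv = -B(v) - (mg/k0) |V_r| inv_V0 (e_N - v) exp(.) B(v)^2,
    the product rule applied to ``(e_N - v) B(v)``.  Tends to -1 as
    v -> +inf (where f_N ~ e_N - v) and to 0 from above as v -> -inf.
    """
    mg = mg if mg is not None else MgBlockParams()
    varr = np.asarray(v, dtype=float)
    e = np.exp(_block_exponent(varr, fit_ref, mg))
    B = 1.0 / (1.0 + (mg.mg_conc / mg.k0) * e)
    out = (-B
           - (mg.mg_conc / mg.k0) * fit_ref * mg.inv_V0
           * (e_N - varr) * e * B * B)
    return out if np.ndim(v) else float(out)


@dataclass(frozen=True)
class PiecewiseFit:
    """Quadratic-quadratic-linear approximation of ``f_N`` with its knots.

    Branches:  a0 + a1 v + a2 v^2   on (v_cut, v0)
               b0 + b1 v + b2 v^2   on (v0, v1)
               c0 + c1 v            on (v1, inf)
    ``sigma`` is the tanh smoothing width used by :func:`p2_smooth`.
    """

    a0: float
    a1: float
    a2: float
    b0: float
    b1: float
    b2: float
    c0: float
    c1: float
    v_cut: float
    v0: float
    v1: float
    sigma: float = 0.15
    fit_ref: float = 82.66
    max_abs_err: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.v_cut < self.v0 < self.v1):
            raise ValueError("knots must satisfy v_cut < v0 < v1")
        lo = self.a0 + self.a1 * self.v0 + self.a2 * self.v0 ** 2
        mid0 = self.b0 + self.b1 * self.v0 + self.b2 * self.v0 ** 2
        mid1 = self.b0 + self.b1 * self.v1 + self.b2 * self.v1 ** 2
        tail = self.c0 + self.c1 * self.v1
        if abs(lo - mid0) > 1e-2 or abs(mid1 - tail) > 1e-2:
            raise ValueError("piecewise branches are not value-continuous at the knots")
        dlo = self.a1 + 2 * self.a2 * self.v0
        dmid0 = self.b1 + 2 * self.b2 * self.v0
        dmid1 = self.b1 + 2 * self.b2 * self.v1
        if abs(dlo - dmid0) > 5e-2 or abs(dmid1 - self.c1) > 5e-2:
            raise ValueError("piecewise branches are not slope-continuous at the knots")
        if self.c1 >= 0:
            raise ValueError("tail slope c1 must be negative (f_N ~ e_N - v)")

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PiecewiseFit":
        return cls(**json.loads(Path(path).read_text()))


def piecewise_eval(fit: PiecewiseFit, v):
    """Evaluate the raw (unsmoothed) piecewise polynomial."""
    varr = np.asarray(v, dtype=float)
    lower = fit.a0 + fit.a1 * varr + fit.a2 * varr ** 2
    mid = fit.b0 + fit.b1 * varr + fit.b2 * varr ** 2
    tail = fit.c0 + fit.c1 * varr
    out = np.where(varr < fit.v0, lower, np.where(varr < fit.v1, mid, tail))
    return out if np.ndim(v) else float(out)


def p2_smooth(v, fit: PiecewiseFit):
    """Smooth quadratic coefficient p2(v): tanh blend of 0 -> a2 -> b2 -> 0.

    Three logistic steps of width ``sigma`` centred at v_cut, v0 and v1.
    Plateaus at a2 on (v_cut, v0), b2 on (v0, v1) and 0 outside.
    """
    varr = np.asarray(v, dtype=float)
    s = fit.sigma
    out = (fit.a2 / 2.0 * (1.0 + np.tanh((varr - fit.v_cut) / s))
           + (fit.b2 - fit.a2) / 2.0 * (1.0 + np.tanh((varr - fit.v0) / s))
           - fit.b2 / 2.0 * (1.0 + np.tanh((varr - fit.v1) / s)))
    return out if np.ndim(v) else float(out)


def _assemble(theta, v):
    """Piecewise curve from the free parameter vector.

    Free parameters are the lower-branch quadratic, the middle-branch
    curvature and the two knots; the remaining coefficients follow from
    value+slope continuity at v0 (middle branch) and v1 (linear tail).
    """
    a0, a1, a2, b2, v0, v1 = theta
    b1 = a1 + 2.0 * a2 * v0 - 2.0 * b2 * v0
    b0 = (a0 + a1 * v0 + a2 * v0 ** 2) - b1 * v0 - b2 * v0 ** 2
    c1 = b1 + 2.0 * b2 * v1
    c0 = (b0 + b1 * v1 + b2 * v1 ** 2) - c1 * v1
    lower = a0 + a1 * v + a2 * v ** 2
    mid = b0 + b1 * v + b2 * v ** 2
    tail = c0 + c1 * v
    curve = np.where(v < v0, lower, np.where(v < v1, mid, tail))
    return curve, (b0, b1, c0, c1)


def fit_piecewise(
    fit_ref: float = 82.66,
    v_range: tuple[float, float] = (-1.2, 2.0),
    grid_n: int = 500,
    e_N: float = 1.0,
    mg: MgBlockParams | None = None,
    v_cut: float = -1.0,
    sigma: float = 0.15,
    knots0: tuple[float, float] = (0.6, 1.1),
) -> PiecewiseFit:
    """Constrained least-squares piecewise fit of ``f_N``.

    The knots (v0, v1) are free optimization variables alongside the
    coefficients; value and slope continuity at both knots are imposed
    exactly by construction (the middle branch and tail are parameterized
    through their boundary values).  Raises if the optimizer fails to
    reach a max absolute error of 0.02 over the fitted interval.

    ``v_cut`` is the lower end of the fitted interval and the first
    smoothing knot of :func:`p2_smooth`; the least-squares residuals span
    ``[v_cut, v_range[1]]``.  With the default -1.0 the resulting
    coefficients are insensitive to the grid density and reproduce, at
    two decimals, the canonical tables for both neuron presets.
    """
    lo, hi = v_range
    if lo > -1.2 or hi < 2.0:
        raise ValueError("v_range must span at least [-1.2, 2]")
    if grid_n < 100:
        raise ValueError("grid_n must be at least 100")
    if not lo <= v_cut < 0.0:
        raise ValueError("v_cut must lie in [v_range[0], 0)")
    v = np.linspace(v_cut, hi, grid_n)
    target = f_N_exact(v, e_N=e_N, fit_ref=fit_ref, mg=mg)

    # initial lower branch: quadratic through the subthreshold segment
    mask = v <= knots0[0]
    a2_0, a1_0, a0_0 = np.polyfit(v[mask], target[mask], 2)
    theta0 = np.array([a0_0, a1_0, a2_0, -1.0, knots0[0], knots0[1]])

    def residuals(theta):
        if theta[4] >= theta[5] - 1e-3 or theta[4] <= v_cut or theta[5] >= hi:
            return np.full_like(v, 1e3)
        curve, _ = _assemble(theta, v)
        return curve - target

    sol = least_squares(residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14)
    curve, (b0, b1, c0, c1) = _assemble(sol.x, v)
    max_err = float(np.max(np.abs(curve - target)))
    if not sol.success or max_err > 0.02:
        raise RuntimeError(
            f"piecewise fit did not converge: max |error| = {max_err:.4f}"
        )
    a0, a1, a2, b2, v0, v1 = sol.x
    if not (v_cut < v0 < v1):
        raise RuntimeError(f"degenerate knot ordering: v_cut={v_cut}, v0={v0}, v1={v1}")
    return PiecewiseFit(
        a0=float(a0), a1=float(a1), a2=float(a2),
        b0=float(b0), b1=float(b1), b2=float(b2),
        c0=float(c0), c1=float(c1),
        v_cut=float(v_cut), v0=float(v0), v1=float(v1),
        sigma=float(sigma), fit_ref=float(fit_ref),
        max_abs_err=max_err,
    )
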