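"""Parameter containers and the dimensional <-> dimensionless mapping.

The microscopic model is an all-to-all population of Izhikevich neurons

    C_m dV/dT = k (V - V_r)(V - V_t) - U + I_bar + I_syn
    dU/dT     = a_izh (b_izh (V - V_r) - U)

with a spike reset at ``V_peak`` and conductance-based AMPA / NMDA / GABA
synapses.  All analysis is done on the rescaled (dimensionless) system

    v = 1 + V/|V_r|,   u = U/(k |V_r|^2),   t = (k |V_r| / C_m) T

so that the resting potential maps to ``v = 0`` and the NMDA reversal
(0 mV) maps to ``v = 1``.  :func:`nondimensionalize` implements the full
set of scaling relations; :func:`dimensionalize` inverts it given the
scale constants (k, C_m) that the forward map absorbs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "MgBlockParams",
    "DimensionalNeuronParams",
    "SynapseSpecDim",
    "SynapseChannel",
    "DimensionlessParams",
    "nondimensionalize",
    "dimensionalize",
    "SYNAPSE_KINDS",
]

SYNAPSE_KINDS = ("AMPA", "NMDA", "GABA")

#: single-letter channel keys used throughout the dimensionless model
_KIND_TO_KEY = {"AMPA": "A", "NMDA": "N", "GABA": "G"}


@dataclass(frozen=True)
class MgBlockParams:
    """Constants of the sigmoidal voltage-dependent Mg2+ block of NMDAR.

    ``B(V) = 1 / (1 + (mg_conc / k0) * exp(V * inv_V0))`` with the standard
    values for physiological extracellular magnesium: 1 mM concentration,
    binding constant 3.57 mM and inverse voltage scale -0.062 / mV.
    """

    mg_conc: float = 1.0  # mM
    k0: float = 3.57  # mM
    inv_V0: float = -0.062  # 1/mV

    def __post_init__(self) -> None:
        if self.mg_conc <= 0:
            raise ValueError("mg_conc must be positive")
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.inv_V0 >= 0:
            raise ValueError("inv_V0 must be negative")


@dataclass(frozen=True)
class DimensionalNeuronParams:
    """Physical constants of the Izhikevich neuron (mV, ms, pF scales)."""

    C_m: float  # membrane capacitance
    V_r: float  # resting potential, mV (< 0)
    V_t: float  # threshold potential, mV
    k: float  # quadratic scale
    a_izh: float  # recovery rate, 1/ms
    b_izh: float  # recovery-voltage coupling
    d_jump: float  # recovery increment per spike
    I_bar: float = 0.0  # applied current
    V_peak: float = 30.0  # spike cutoff, mV
    V_reset: float = -65.0  # post-spike reset, mV

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.V_r == 0:
            raise ValueError("V_r must be nonzero (the scaling divides by |V_r|)")
        if not self.V_r < self.V_t:
            raise ValueError("require V_r < V_t")
        if not self.V_peak > self.V_t:
            raise ValueError("require V_peak > V_t")


@dataclass(frozen=True)
class SynapseSpecDim:
    """Dimensional description of one synapse type."""

    kind: str  # one of SYNAPSE_KINDS
    E_s: float  # reversal potential, mV
    tau_syn: float  # decay time constant, ms
    G_jump: float = 0.0  # conductance increment per spike

    def __post_init__(self) -> None:
        if self.kind not in SYNAPSE_KINDS:
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.G_jump < 0:
            raise ValueError("G_jump must be non-negative")


@dataclass(frozen=True)
class SynapseChannel:
    """Dimensionless channel: scaled reversal, decay constant and couplings.

    ``J_rec`` multiplies the population's own rate; ``J_input`` multiplies an
    external input rate.  Either may be zero (channel absent / input-only).
    """

    e_s: float
    tau_s: float
    J_rec: float = 0.0
    J_input: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")


@dataclass(frozen=True)
class DimensionlessParams:
    """Complete parameter set of the scaled population model.

    ``syn`` maps channel keys 'A', 'N', 'G' to :class:`SynapseChannel`.
    ``eta_bar`` and ``Delta`` are the center and half-width of the Cauchy
    (Lorentzian) distribution of background currents.  ``time_scale`` is
    k|V_r|/C_m in 1/ms and converts dimensionless time/frequency back to
    ms / kHz.  ``g_N_tau`` selects which channel's decay constant drives
    the NMDA conductance equation (default its own).
    """

    alpha: float
    a: float
    b: float
    u_jump: float
    I: float
    eta_bar: float
    Delta: float
    syn: Mapping[str, SynapseChannel]
    V_r_ref: float  # |V_r| in mV, retained for the Mg-block evaluation
    time_scale: float  # k|V_r|/C_m per ms
    mg: MgBlockParams = field(default_factory=MgBlockParams)
    v_peak: float = 100.0
    v_reset: float = -100.0
    g_N_tau: str = "N"

    def __post_init__(self) -> None:
        if self.Delta <= 0:
            raise ValueError("Delta must be positive")
        if self.V_r_ref <= 0:
            raise ValueError("V_r_ref is |V_r| and must be positive")
        for key in ("A", "N", "G"):
            if key not in self.syn:
                raise ValueError(f"syn must define channel {key!r}")
        if self.g_N_tau not in self.syn:
            raise ValueError("g_N_tau must name an existing channel")

    # -- convenience accessors -------------------------------------------
    @property
    def e_A(self) -> float:
        return self.syn["A"].e_s

    @property
    def e_N(self) -> float:
        return self.syn["N"].e_s

    @property
    def e_G(self) -> float:
        return self.syn["G"].e_s

    def tau_of(self, key: str) -> float:
        """Decay constant governing channel ``key`` (honours ``g_N_tau``)."""
        if key == "N":
            return self.syn[self.g_N_tau].tau_s
        return self.syn[key].tau_s

    def with_eta(self, eta_bar: float) -> "DimensionlessParams":
        return replace(self, eta_bar=eta_bar)

    def with_couplings(self, **kw: Mapping[str, float]) -> "DimensionlessParams":
        """Return a copy with J_rec / J_input overridden per channel.

        Keyword form: ``with_couplings(A={'J_rec': 6, 'J_input': 6})``.
        """
        syn = dict(self.syn)
        for key, vals in kw.items():
            if key not in syn:
                raise ValueError(f"unknown channel {key!r}")
            syn[key] = replace(syn[key], **vals)
        return replace(self, syn=syn)


def nondimensionalize(
    dim: DimensionalNeuronParams,
    synapses: list[SynapseSpecDim],
    eta_bar: float = 0.0,
    Delta: float = 0.02,
    mg: MgBlockParams | None = None,
    map_reset_bounds: bool = False,
) -> DimensionlessParams:
    """Map physical constants onto the dimensionless parameter set.

    The scaling relations are

        alpha  = 1 + V_t/|V_r|          e_s    = 1 + E_s/|V_r|
        tau_s  = (k|V_r|/C_m) tau_syn   J_s    = G_jump/(k|V_r|)
        a      = C_m a_izh/(k|V_r|)     b      = b_izh/(k|V_r|)
        u_jump = d_jump/(k V_r^2)       I      = I_bar/(k V_r^2)

    ``eta_bar`` / ``Delta`` parameterize the heterogeneous background
    current and are already dimensionless.  Synapse kinds not listed get a
    placeholder channel with zero coupling.

    The scaled reset bounds default to the large symmetric surrogate
    (+/-100) of the ``v_peak -> infinity`` limit assumed by the mean-field
    reduction; pass ``map_reset_bounds=True`` to carry the physiological
    ``V_peak`` / ``V_reset`` through the scaling instead.
    """
    vr = abs(dim.V_r)
    kvr = dim.k * vr
    kvr2 = dim.k * vr * vr
    time_scale = kvr / dim.C_m

    channels: dict[str, SynapseChannel] = {}
    for spec in synapses:
        key = _KIND_TO_KEY[spec.kind]
        if key in channels:
            raise ValueError(f"duplicate synapse kind {spec.kind}")
        channels[key] = SynapseChannel(
            e_s=1.0 + spec.E_s / vr,
            tau_s=time_scale * spec.tau_syn,
            J_rec=spec.G_jump / kvr,
        )
    # absent channels: inert placeholders (unit reversal, unit decay)
    for key in ("A", "N", "G"):
        channels.setdefault(key, SynapseChannel(e_s=1.0, tau_s=1.0))

    return DimensionlessParams(
        alpha=1.0 + dim.V_t / vr,
        a=dim.C_m * dim.a_izh / kvr,
        b=dim.b_izh / kvr,
        u_jump=dim.d_jump / kvr2,
        I=dim.I_bar / kvr2,
        eta_bar=eta_bar,
        Delta=Delta,
        syn=channels,
        V_r_ref=vr,
        time_scale=time_scale,
        mg=mg if mg is not None else MgBlockParams(),
        v_peak=1.0 + dim.V_peak / vr if map_reset_bounds else 100.0,
        v_reset=1.0 + dim.V_reset / vr if map_reset_bounds else -100.0,
    )


def dimensionalize(
    p: DimensionlessParams,
    C_m: float,
    k: float,
    V_peak: float | None = None,
    V_reset: float | None = None,
) -> tuple[DimensionalNeuronParams, list[SynapseSpecDim]]:
    """Invert :func:`nondimensionalize` given the absorbed scale constants.

    The forward map loses (C_m, k); supplying them makes the inversion
    exact: ``dimensionalize(nondimensionalize(d, s), d.C_m, d.k)`` recovers
    the inputs to floating-point accuracy.
    """
    if C_m <= 0 or k <= 0:
        raise ValueError("C_m and k must be positive")
    vr = p.V_r_ref
    kvr = k * vr
    kvr2 = k * vr * vr
    dim = DimensionalNeuronParams(
        C_m=C_m,
        V_r=-vr,
        V_t=(p.alpha - 1.0) * vr,
        k=k,
        a_izh=p.a * kvr / C_m,
        b_izh=p.b * kvr,
        d_jump=p.u_jump * kvr2,
        I_bar=p.I * kvr2,
        V_peak=V_peak if V_peak is not None else (p.v_peak - 1.0) * vr,
        V_reset=V_reset if V_reset is not None else (p.v_reset - 1.0) * vr,
    )
    key_to_kind = {v: kk for kk, v in _KIND_TO_KEY.items()}
    specs = [
        SynapseSpecDim(
            kind=key_to_kind[key],
            E_s=(ch.e_s - 1.0) * vr,
            tau_syn=ch.tau_s * C_m / kvr,
            G_jump=ch.J_rec * kvr,
        )
        for key, ch in p.syn.items()
    ]
    return dim, specs
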