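"""Config files, tidy CSV/JSON output and reproducibility sidecars.

All quantities are dimensionless unless the column name carries a
``_mV`` / ``_ms`` / ``_Hz`` suffix.  Every CLI run writes a JSON sidecar
echoing the fully resolved configuration, the seed and the package
version, so any output file can be regenerated from its sidecar alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import BranchScan, ModeComparison
from .meanfield import STATE_VARS, Trajectory
from .network import PopulationTrace, SpikeRaster

__all__ = [
    "RunConfig", "load_config", "save_config",
    "trajectory_frame", "trace_frame", "raster_frame",
    "scan_to_dict", "comparison_to_dict", "write_sidecar",
]


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one CLI run."""

    preset: str = "fig4"  # figure preset id, or 'case1'/'case2'
    command: str = "simulate"  # simulate | network | scan | compare | fit
    nmda_mode: str = "nonlinear"
    r_input: float | None = None  # None: use the preset's value
    T: float = 2000.0
    dt: float = 0.1
    N: int = 10_000
    network_dt: float = 1e-3
    seed: int = 0
    out_dir: str = "izhmass_out"
    overrides: dict = field(default_factory=dict)  # e.g. {"eta": 0.02}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config key(s): {sorted(bad)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# tidy frames / dicts
# ---------------------------------------------------------------------------

def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Mean-field trajectory as a tidy frame (time, r, v, u, g_A, g_N, g_G)."""
    data = {"time": traj.t}
    for i, name in enumerate(STATE_VARS):
        data[name] = traj.y[i]
    return pd.DataFrame(data)


def trace_frame(trace: PopulationTrace) -> pd.DataFrame:
    """Network population estimators as a tidy frame."""
    df = pd.DataFrame({
        "time": trace.t,
        "v_mean": trace.v_mean,
        "u_mean": trace.u_mean,
        "g_A": trace.g_A,
        "g_N": trace.g_N,
        "g_G": trace.g_G,
        "kuramoto_R": np.abs(trace.kuramoto),
    })
    rate = pd.DataFrame({"time": trace.rate_t, "r": trace.r})
    return df.merge(rate, on="time", how="outer").sort_values("time")


def raster_frame(raster: SpikeRaster) -> pd.DataFrame:
    return pd.DataFrame({"neuron_id": raster.neuron, "time": raster.time})


def _fixed_point_dict(fp) -> dict:
    s = fp.state
    return {
        "r": s.r, "v": s.v, "u": s.u,
        "g_A": s.g_A, "g_N": s.g_N, "g_G": s.g_G,
        "stability": fp.stability,
        "residual": fp.residual,
        "eigenvalues_re": [float(e.real) for e in fp.eigenvalues],
        "eigenvalues_im": [float(e.imag) for e in fp.eigenvalues],
    }


def scan_to_dict(scan: BranchScan) -> dict:
    return {
        "param": scan.param,
        "grid": [float(g) for g in scan.grid],
        "branch": [_fixed_point_dict(fp) if fp else None for fp in scan.branch],
        "all_points": [[_fixed_point_dict(fp) for fp in fps] for fps in scan.points],
        "transitions": [dataclasses.asdict(tr) for tr in scan.transitions],
    }


def comparison_to_dict(cmp: ModeComparison, time_scale: float) -> dict:
    out = {}
    for mode in ("nonlinear", "linear"):
        s = getattr(cmp, mode)
        out[mode] = {
            "r_amplitude": s.r_amplitude,
            "r_mean": s.r_mean,
            "slow_peak_freq": s.slow_peak[0],
            "slow_peak_freq_Hz": s.slow_peak[0] * time_scale * 1e3,
            "slow_peak_power": s.slow_peak[1],
            "fast_peak_freq": s.fast_peak[0],
            "fast_peak_freq_Hz": s.fast_peak[0] * time_scale * 1e3,
            "fast_peak_power": s.fast_peak[1],
            "mean_R": s.mean_R,
        }
    out["amplitude_ratio_nonlinear_over_linear"] = cmp.amplitude_ratio
    return out


def write_sidecar(path: str | Path, cfg: RunConfig, extra: dict | None = None) -> None:
    """Reproducibility sidecar: resolved config + seed + package version."""
    from . import __version__

    payload = {"config": cfg.to_dict(), "seed": cfg.seed, "version": __version__}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
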