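"""Canonical parameter sets, the stiffness-sweep driver and Hertz utilities.

The two canonical whole-cell parameter sets differ only in the motor and
clutch inventory: the "low" cell has 1,000 motors and 750 clutches, the
"high" cell 10,000 motors and 7,500 clutches, with the per-module maxima
and cell-body clutch count scaled by the same factor of ten and the actin
budget unchanged.  Sweeping the substrate spring constant with each set
exposes the biphasic stiffness optima and their shift.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .analysis import (AnalysisError, mean_aspect_ratio,
                       random_motility_coefficient, summarize_flow_traction)
from .engine import run_simulation
from .params import SimulationParameters

__all__ = [
    "make_fixture", "SweepSpec", "run_sweep", "sweep_seed",
    "hertz_indentation_depth", "hertz_young_modulus", "buoyant_bead_force",
    "DEFAULT_KAPPA_S_GRID",
]

# Six log-spaced points covering the swept stiffness axes (pN/nm).
DEFAULT_KAPPA_S_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)

_BASE = dict(
    k_on=1.0,            # 1/s
    k_off_star=0.1,      # 1/s
    F_b=2.0,             # pN
    kappa_c=0.8,         # pN/nm
    kappa_s=10.0,        # pN/nm, overridden by sweeps
    kappa_cell=1e4,      # pN/nm (near-rigid cell spring)
    F_m=2.0,             # pN
    v_m_star=120.0,      # nm/s
    v_p_star=200.0,      # nm/s
    k_mod_star=1.0,      # 1/s
    k_cap=0.001,         # 1/s
    l_in=5000.0,         # nm
    l_min=500.0,         # nm
    A_T=100000.0,        # nm of F-actin equivalent
)

_FIXTURES = {
    "low": dict(_BASE, n_m_tot=1000, n_c_tot=750, n_m_star=100, n_c_star=75,
                n_c_cell=10),
    "high": dict(_BASE, n_m_tot=10000, n_c_tot=7500, n_m_star=1000,
                 n_c_star=750, n_c_cell=100),
}


def make_fixture(name: str, **overrides) -> SimulationParameters:
    """Return the "low" or "high" motor/clutch parameter set.

    Keyword overrides (e.g. ``kappa_s=0.1``) replace individual fields.
    """
    try:
        base = dict(_FIXTURES[name])
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from "
                         f"{sorted(_FIXTURES)}") from None
    base.update(overrides)
    return SimulationParameters(**base)


def fixture_names() -> Tuple[str, ...]:
    return tuple(sorted(_FIXTURES))


# ---------------------------------------------------------------------------
# stiffness sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """One stiffness-sweep experiment.

    Seeds are a pure function of (base_seed, stiffness index, replicate
    index), so sweep cells are order-independent and embarrassingly
    parallel.
    """
    params: SimulationParameters
    kappa_s_grid: Sequence[float] = DEFAULT_KAPPA_S_GRID
    replicates: int = 4
    t_end: float = 7200.0            # s
    record_interval: float = 5.0     # s
    exclude_time: float = 3600.0     # s discarded as transient
    sample_interval: float = 900.0   # s, morphology/motility sampling
    base_seed: int = 0
    metrics: Tuple[str, ...] = ("flow", "traction", "aspect", "motility")

    def __post_init__(self) -> None:
        grid = np.asarray(self.kappa_s_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("kappa_s grid must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def sweep_seed(base_seed: int, i_kappa: int, i_rep: int) -> int:
    """Deterministic per-cell seed, independent of execution order."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(i_kappa, i_rep))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def run_sweep(spec: SweepSpec, backend: str = "kernel") -> pd.DataFrame:
    """Execute the sweep and analyse each trajectory.

    Returns a long-format table with columns ``stiffness`` (pN/nm),
    ``replicate``, ``metric`` and ``value``.  Metrics that cannot be
    computed from the configured run length (e.g. motility from runs
    shorter than a few sampling intervals) are omitted.
    """
    rows = []
    for ik, kappa_s in enumerate(spec.kappa_s_grid):
        p = spec.params.replace(kappa_s=float(kappa_s))
        for ir in range(spec.replicates):
            seed = sweep_seed(spec.base_seed, ik, ir)
            try:
                traj = run_simulation(p, spec.t_end, spec.record_interval,
                                      seed=seed, backend=backend)
                values = {}
                if "flow" in spec.metrics or "traction" in spec.metrics:
                    flow, trac = summarize_flow_traction(
                        traj, exclude_time=spec.exclude_time)
                    if "flow" in spec.metrics:
                        values["flow"] = flow
                    if "traction" in spec.metrics:
                        values["traction"] = trac
                if "aspect" in spec.metrics:
                    try:
                        values["aspect"] = mean_aspect_ratio(
                            traj, sample_interval=spec.sample_interval,
                            exclude_time=spec.exclude_time)
                    except AnalysisError:
                        pass
                if "motility" in spec.metrics:
                    try:
                        values["motility"] = random_motility_coefficient(
                            traj, sample_interval=spec.sample_interval,
                            exclude_time=spec.exclude_time)
                    except AnalysisError:
                        pass
            except Exception as err:
                raise RuntimeError(
                    f"sweep cell failed at kappa_s={kappa_s}, "
                    f"replicate={ir}: {err}") from err
            for metric, value in values.items():
                rows.append((float(kappa_s), ir, metric, value))
    return pd.DataFrame(rows, columns=["stiffness", "replicate", "metric",
                                       "value"])


# ---------------------------------------------------------------------------
# Hertz bead indentation
# ---------------------------------------------------------------------------

def hertz_indentation_depth(R: float, r: float) -> float:
    """Bead indentation depth from bead radius R and contact radius r (m).

    ``delta = R - sqrt(R^2 - r^2)``; monotone increasing in r on [0, R].
    """
    if R <= 0:
        raise ValueError("bead radius must be > 0")
    if not 0 <= r <= R:
        raise ValueError("contact radius must lie in [0, R]")
    return R - math.sqrt(R * R - r * r)


def hertz_young_modulus(f: float, R: float, delta: float,
                        nu: float = 0.3) -> float:
    """Young's modulus (Pa) from Hertz spherical indentation.

    ``E = 3 f (1 - nu^2) / (4 sqrt(R) delta^{3/2})`` with f the
    buoyancy-corrected bead force (N), R the bead radius (m), delta the
    indentation depth (m) and nu the gel Poisson ratio (0.3 for
    polyacrylamide here).
    """
    if f <= 0 or R <= 0:
        raise ValueError("force and radius must be > 0")
    if delta <= 0:
        raise ValueError("indentation depth must be > 0")
    if not 0 <= nu < 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    return 3.0 * f * (1.0 - nu * nu) / (4.0 * math.sqrt(R) * delta ** 1.5)


def buoyant_bead_force(R: float, rho_bead: float = 2600.0,
                       rho_medium: float = 1000.0, g: float = 9.81) -> float:
    """Buoyancy-corrected weight (N) of a glass bead of radius R (m).

    Default bead density 2,600 kg/m^3 (measured for the indentation beads);
    the surrounding medium is water-like.
    """
    if R <= 0:
        raise ValueError("bead radius must be > 0")
    return 4.0 / 3.0 * math.pi * R ** 3 * (rho_bead - rho_medium) * g
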