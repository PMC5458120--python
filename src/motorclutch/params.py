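"""Simulation parameters: validation and flat key=value configuration I/O.

Internal units throughout the package: length nm, force pN, stiffness pN/nm,
time s.  Trajectory output converts positions to micrometres.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class SimulationParameters:
    """Full parameterisation of the whole-cell motor-clutch simulator.

    Attributes
    ----------
    k_on : float
        Clutch binding rate (1/s).
    k_off_star : float
        Unloaded clutch off-rate (1/s).
    F_b : float
        Characteristic bond rupture force of the Bell model (pN).
    kappa_c : float
        Clutch spring constant (pN/nm).
    kappa_s : float
        Substrate spring constant (pN/nm); the swept stiffness axis.
    kappa_cell : float
        Cell spring constant linking each module to the cell body (pN/nm).
    F_m : float
        Single-motor stall force (pN).
    v_m_star : float
        Unloaded motor (retrograde flow) velocity (nm/s).
    v_p_star : float
        Maximum F-actin polymerization speed (nm/s).
    k_mod_star : float
        Maximum module nucleation rate (1/s).
    k_cap : float
        Module capping rate (1/s).
    l_in : float
        Initial module length (nm).
    l_min : float
        Minimum module length below which a module is destroyed (nm).
    n_m_tot, n_c_tot : int
        Total motors and clutches in the cell.
    n_m_star, n_c_star : int
        Maximum motors / clutches assigned to a single module.
    n_c_cell : int
        Clutches permanently associated with the cell body.
    A_T : float
        Total actin budget, in nm of filament length equivalent.
    rng_seed : int
        Seed for the simulation's random number stream.
    """

    k_on: float
    k_off_star: float
    F_b: float
    kappa_c: float
    kappa_s: float
    kappa_cell: float
    F_m: float
    v_m_star: float
    v_p_star: float
    k_mod_star: float
    k_cap: float
    l_in: float
    l_min: float
    n_m_tot: int
    n_c_tot: int
    n_m_star: int
    n_c_star: int
    n_c_cell: int
    A_T: float
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        # Kinetic rates may be zero (a zero rate disables that process);
        # mechanical constants and speeds must be strictly positive.
        for name in ("k_on", "k_off_star", "k_mod_star", "k_cap"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")
        for name in ("F_b", "kappa_c", "kappa_s", "kappa_cell", "F_m",
                     "v_m_star", "v_p_star", "A_T"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be finite and > 0, got {v}")
        if not 0 < self.l_min < self.l_in:
            raise ParameterError(
                f"need 0 < l_min < l_in, got l_min={self.l_min}, l_in={self.l_in}")
        for name in ("n_m_tot", "n_c_tot", "n_m_star", "n_c_star", "n_c_cell"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 0):
                raise ParameterError(f"{name} must be a non-negative int, got {v!r}")
        if self.n_m_tot < 1 or self.n_c_tot < 1:
            raise ParameterError("n_m_tot and n_c_tot must be >= 1")
        if self.n_c_cell > self.n_c_tot:
            raise ParameterError("n_c_cell must not exceed n_c_tot")
        if self.n_m_star > self.n_m_tot:
            raise ParameterError("n_m_star must not exceed n_m_tot")
        if self.n_c_star > self.n_c_tot - self.n_c_cell:
            raise ParameterError("n_c_star must not exceed n_c_tot - n_c_cell")

    def replace(self, **kwargs) -> "SimulationParameters":
        """Return a copy with the given fields replaced (and revalidated)."""
        return dataclasses.replace(self, **kwargs)

    # -- flat key=value configuration files --------------------------------

    _INT_FIELDS = ("n_m_tot", "n_c_tot", "n_m_star", "n_c_star", "n_c_cell",
                   "rng_seed")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: Union[str, Path]) -> None:
        lines = [f"{k} = {v!r}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParameters":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        missing = names - set(d) - {"rng_seed"}
        if missing:
            raise ParameterError(f"missing parameter keys: {sorted(missing)}")
        kwargs = {}
        for k, v in d.items():
            if k in cls._INT_FIELDS:
                iv = int(float(v))
                if float(v) != iv:
                    raise ParameterError(f"{k} must be an integer, got {v}")
                kwargs[k] = iv
            else:
                kwargs[k] = float(v)
        return cls(**kwargs)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SimulationParameters":
        """Read a flat ``key = value`` file; unknown keys are an error."""
        d: dict = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"line {ln}: expected 'key = value': {raw!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            if k in d:
                raise ParameterError(f"line {ln}: duplicate key {k!r}")
            d[k] = v
        return cls.from_dict(d)
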