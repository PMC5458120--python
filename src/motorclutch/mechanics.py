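"""Domain types and elementary constitutive relations of the motor-clutch model.

The cell is a set of motor-clutch *modules* pulling on a central body.  Each
module is a one-dimensional chain along its axis: substrate spring (kappa_s)
-- parallel molecular clutches (kappa_c each) -- rigid F-actin -- myosin
motors -- cell spring (kappa_cell) -- cell body.  Motors drive retrograde
F-actin flow; engaged clutches transmit the motor force to the substrate and
rupture stochastically at a force-accelerated (Bell) rate, producing the
load-and-fail dynamics whose stiffness dependence the simulator predicts.

Sign convention: per-module scalar displacements are measured along the
module axis with *inward* (toward the cell body, the direction of retrograde
flow) positive.  A bound clutch stores its actin-side displacement ``a``;
its spring extension is ``a - x_s`` where ``x_s`` is the shared substrate
spring displacement, and positive extensions mean tension.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List

import numpy as np

from .params import ParameterError, SimulationParameters

__all__ = [
    "Clutch", "Module", "CellState",
    "bell_off_rate", "motor_velocity", "polymerization_speed",
    "module_birth_rate", "allocate_on_birth",
    "module_substrate_displacement", "module_force",
]


# ---------------------------------------------------------------------------
# constitutive relations
# ---------------------------------------------------------------------------

def bell_off_rate(F_c: float, p: SimulationParameters) -> float:
    """Bell-model slip-bond off-rate ``k*_off * exp(F_c / F_b)`` (1/s).

    ``F_c`` is the magnitude of the clutch spring force projected on the
    module axis (pN); it must be non-negative.
    """
    if F_c < 0:
        raise ValueError(f"clutch force magnitude must be >= 0, got {F_c}")
    return p.k_off_star * math.exp(F_c / p.F_b)


def motor_velocity(F_load: float, n_m: int, p: SimulationParameters) -> float:
    """Linear stall law for the motor ensemble: ``v*_m (1 - F/(n_m F_m))``.

    Clamped below at zero so a super-stall transient cannot reverse the flow.
    A module with no motors generates no flow (and can bear no load).
    """
    if n_m == 0:
        if F_load != 0:
            raise ValueError("a module without motors cannot bear load")
        return 0.0
    v = p.v_m_star * (1.0 - F_load / (n_m * p.F_m))
    return v if v > 0.0 else 0.0


def polymerization_speed(A_G: float, p: SimulationParameters) -> float:
    """F-actin polymerization speed, proportional to the G-actin fraction."""
    if not 0.0 <= A_G <= A_T_tol(p):
        raise ValueError(f"A_G={A_G} outside [0, A_T={p.A_T}]")
    return p.v_p_star * min(A_G, p.A_T) / p.A_T


def module_birth_rate(A_G: float, p: SimulationParameters) -> float:
    """Module nucleation rate ``k*_mod (A_G/A_T)^4``.

    The fourth-power dependence on the G-actin fraction reflects the
    cooperativity of actin nucleation.
    """
    if not 0.0 <= A_G <= A_T_tol(p):
        raise ValueError(f"A_G={A_G} outside [0, A_T={p.A_T}]")
    return p.k_mod_star * (min(A_G, p.A_T) / p.A_T) ** 4


def A_T_tol(p: SimulationParameters) -> float:
    # tolerate round-off above A_T from pool accounting
    return p.A_T * (1.0 + 1e-9)


def allocate_on_birth(n_m_free: int, n_c_free: int,
                      p: SimulationParameters) -> tuple:
    """Motors and clutches assigned to a newborn module.

    Proportional to the free-pool fractions, ``round(n*_m n_m,free/n_m,tot)``
    and ``round(n*_c n_c,free/n_c,tot)`` (round half up), each capped at the
    available pool.  Degenerate pools yield zero-motor/zero-clutch modules.
    """
    if not 0 <= n_m_free <= p.n_m_tot:
        raise ValueError("n_m_free outside [0, n_m_tot]")
    if not 0 <= n_c_free <= p.n_c_tot:
        raise ValueError("n_c_free outside [0, n_c_tot]")
    n_m = _round_half_up(p.n_m_star * n_m_free / p.n_m_tot)
    n_c = _round_half_up(p.n_c_star * n_c_free / p.n_c_tot)
    return min(n_m, n_m_free), min(n_c, n_c_free)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# per-module spring algebra
# ---------------------------------------------------------------------------

def module_substrate_displacement(module: "Module",
                                  p: SimulationParameters) -> float:
    """Equilibrium substrate spring displacement for the module.

    Instantaneous balance at the substrate node:
    ``kappa_s x_s = sum_bound kappa_c (a_i - x_s)``.
    """
    idx = module.bound
    n_b = int(idx.sum())
    if n_b == 0:
        return 0.0
    s_a = float(module.a[idx].sum())
    return p.kappa_c * s_a / (p.kappa_s + n_b * p.kappa_c)


def module_force(module: "Module", p: SimulationParameters) -> float:
    """Signed axial force transmitted by the module, ``kappa_s x_s`` (pN)."""
    return p.kappa_s * module.x_s


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Clutch:
    """One molecular clutch: a Hookean spring bond to the substrate."""
    state: str          # "free" or "bound"
    x_c: float = 0.0    # spring extension (nm), signed along the module axis
    anchor: float = 0.0  # substrate-side attachment coordinate (nm)

    def force(self, p: SimulationParameters) -> float:
        """Clutch spring force ``kappa_c * x_c`` (pN)."""
        return p.kappa_c * self.x_c


@dataclass
class Module:
    """One motor-clutch protrusion.

    Clutch ensemble state is stored as arrays over the module's assigned
    clutches: ``bound`` flags, actin-side displacements ``a`` (inward
    positive, meaningful where bound) and ``dist``, the remaining F-actin
    travel before each bound clutch's attachment point reaches the motor
    position (forced unbinding).
    """
    theta: float
    length: float
    capped: bool
    n_m: int
    n_c: int
    bound: np.ndarray
    a: np.ndarray
    dist: np.ndarray
    x_s: float = 0.0
    x_cell: float = 0.0
    module_id: int = 0

    @classmethod
    def fresh(cls, theta: float, length: float, n_m: int, n_c: int,
              module_id: int = 0) -> "Module":
        return cls(theta=theta, length=length, capped=False, n_m=n_m, n_c=n_c,
                   bound=np.zeros(n_c, dtype=bool),
                   a=np.zeros(n_c), dist=np.zeros(n_c), module_id=module_id)

    @property
    def u(self) -> np.ndarray:
        """Outward unit vector of the module axis."""
        return np.array([math.cos(self.theta), math.sin(self.theta)])

    @property
    def n_bound(self) -> int:
        return int(self.bound.sum())

    def clutch_extensions(self) -> np.ndarray:
        """Extensions ``a_i - x_s`` of the bound clutches (nm)."""
        return self.a[self.bound] - self.x_s

    @property
    def clutches(self) -> List[Clutch]:
        out = []
        for i in range(self.n_c):
            if self.bound[i]:
                out.append(Clutch("bound", float(self.a[i] - self.x_s),
                                  anchor=float(self.a[i])))
            else:
                out.append(Clutch("free"))
        return out

    def tip(self, body: np.ndarray) -> np.ndarray:
        """Substrate-frame module tip position (nm, 2-vector)."""
        return np.asarray(body, dtype=float) + self.length * self.u


@dataclass
class CellState:
    """Complete mechanical state of the simulated cell."""
    body: np.ndarray                  # (2,) nm
    modules: List[Module]
    n_m_free: int
    n_c_free: int
    A_G: float                        # nm of G-actin
    body_bound: np.ndarray            # (n_c_cell,) bool
    body_e: np.ndarray                # (n_c_cell, 2) clutch extension vectors
    x_s_cell: np.ndarray = field(default_factory=lambda: np.zeros(2))
    t: float = 0.0
    next_module_id: int = 0

    @property
    def body_clutches(self) -> List[Clutch]:
        out = []
        for i in range(len(self.body_bound)):
            if self.body_bound[i]:
                ext = float(np.linalg.norm(self.body_e[i]))
                out.append(Clutch("bound", ext))
            else:
                out.append(Clutch("free"))
        return out

    def check_invariants(self, p: SimulationParameters,
                         atol: float = 1e-6) -> None:
        """Raise if motor/clutch/actin conservation is violated."""
        n_m = self.n_m_free + sum(m.n_m for m in self.modules)
        if n_m != p.n_m_tot:
            raise AssertionError(f"motor conservation violated: {n_m} != {p.n_m_tot}")
        n_c = self.n_c_free + p.n_c_cell + sum(m.n_c for m in self.modules)
        if n_c != p.n_c_tot:
            raise AssertionError(f"clutch conservation violated: {n_c} != {p.n_c_tot}")
        a_tot = self.A_G + sum(m.length for m in self.modules)
        if not math.isclose(a_tot, p.A_T, rel_tol=0, abs_tol=atol * p.A_T):
            raise AssertionError(f"actin conservation violated: {a_tot} != {p.A_T}")
        if self.A_G < -atol * p.A_T:
            raise AssertionError(f"negative G-actin pool: {self.A_G}")


def initial_state(p: SimulationParameters) -> CellState:
    """A cell with three equally spaced modules of length l_in, none bound."""
    state = CellState(
        body=np.zeros(2),
        modules=[],
        n_m_free=p.n_m_tot,
        n_c_free=p.n_c_tot - p.n_c_cell,
        A_G=p.A_T,
        body_bound=np.zeros(p.n_c_cell, dtype=bool),
        body_e=np.zeros((p.n_c_cell, 2)),
    )
    for k in range(3):
        theta = 2.0 * math.pi * k / 3.0
        n_m, n_c = allocate_on_birth(state.n_m_free, state.n_c_free, p)
        mod = Module.fresh(theta, p.l_in, n_m, n_c, module_id=state.next_module_id)
        state.next_module_id += 1
        state.n_m_free -= n_m
        state.n_c_free -= n_c
        state.A_G -= p.l_in
        state.modules.append(mod)
    if state.A_G < 0:
        raise ParameterError("A_T too small for three initial modules of l_in")
    return state
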