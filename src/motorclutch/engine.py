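"""Direct Gillespie event loop with deterministic inter-event mechanics.

The simulator alternates stochastic events (clutch binding/unbinding, module
birth and capping, drawn by the direct SSA: two uniform random numbers per
iteration) with deterministic mechanics between events (retrograde flow,
polymerization, quasi-static spring-network balance).  One loop iteration:

1.  build the event table from the current (equilibrated) state,
2.  draw the waiting time and the event to execute,
3.  hold the F-actin flow and polymerization speeds fixed and advance the
    state explicitly over the waiting time,
4.  execute the event, destroy modules shorter than ``l_min``,
5.  re-solve the whole-cell force balance for the new body position and
    redistribute cell-spring, clutch and substrate-spring extensions.

Snapshots are taken at exact multiples of the recording interval during the
deterministic advance (motion is linear within an interval, so this equals
interpolation to the record time).  When no stochastic event is possible
(all kinetic rates zero) the dynamics are integrated in record-interval
chunks with velocities refreshed at each chunk.

This module holds the readable reference implementation operating on
:class:`~motorclutch.mechanics.CellState`; :func:`run_simulation` defaults to
a numba-compiled kernel (:mod:`motorclutch._kernel`) implementing the
identical algorithm on flat arrays.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .mechanics import (CellState, Module, allocate_on_birth, bell_off_rate,
                        initial_state, module_birth_rate,
                        module_substrate_displacement, motor_velocity,
                        polymerization_speed)
from .params import SimulationParameters
from .trajectory import (CELL_COLUMNS, MODULE_COLUMNS, NM_PER_UM, Trajectory)

# Relative force-balance tolerance: residual <= FB_TOL * n_m_tot * F_m.
FB_TOL = 1e-6


class ForceBalanceError(RuntimeError):
    """Force balance failed to reach tolerance; carries the residual (pN)."""

    def __init__(self, residual: float):
        super().__init__(f"force-balance residual {residual:.3e} pN above tolerance")
        self.residual = residual


# ---------------------------------------------------------------------------
# event table
# ---------------------------------------------------------------------------

@dataclass
class Event:
    kind: str        # clutch_bind | clutch_unbind | body_clutch_bind |
                     # body_clutch_unbind | module_birth | module_cap
    module: int = -1  # index into state.modules (module-targeted kinds)
    clutch: int = -1  # clutch slot within the module / body-clutch index
    rate: float = 0.0


@dataclass
class EventTable:
    events: List[Event] = field(default_factory=list)
    total_rate: float = 0.0


def max_modules(p: SimulationParameters) -> int:
    """Hard cap on concurrent modules implied by the actin budget."""
    return int(p.A_T / p.l_min) + 4


def build_event_table(state: CellState, p: SimulationParameters) -> EventTable:
    """Enumerate every possible event with its current rate.

    Order is fixed (module clutches in module order, body clutches, module
    birth, capping) so that event selection is reproducible.
    """
    state.check_invariants(p)
    table = EventTable()
    total = 0.0
    for j, mod in enumerate(state.modules):
        for i in range(mod.n_c):
            if mod.bound[i]:
                F_c = p.kappa_c * abs(mod.a[i] - mod.x_s)
                ev = Event("clutch_unbind", j, i, bell_off_rate(F_c, p))
            else:
                ev = Event("clutch_bind", j, i, p.k_on)
            table.events.append(ev)
            total += ev.rate
    for i in range(p.n_c_cell):
        if state.body_bound[i]:
            F_c = p.kappa_c * math.sqrt(state.body_e[i, 0] ** 2
                                        + state.body_e[i, 1] ** 2)
            ev = Event("body_clutch_unbind", -1, i, bell_off_rate(F_c, p))
        else:
            ev = Event("body_clutch_bind", -1, i, p.k_on)
        table.events.append(ev)
        total += ev.rate
    if state.A_G >= p.l_in and len(state.modules) < max_modules(p):
        birth = module_birth_rate(state.A_G, p)
    else:
        birth = 0.0
    table.events.append(Event("module_birth", rate=birth))
    total += birth
    for j, mod in enumerate(state.modules):
        if not mod.capped:
            table.events.append(Event("module_cap", j, rate=p.k_cap))
            total += p.k_cap
    table.total_rate = total
    return table


def draw_event_time(total_rate: float, urn1: float) -> float:
    """Exponential waiting time ``ln(1/urn1)/total_rate``; inf if no event."""
    if total_rate <= 0.0:
        return math.inf
    if not 0.0 < urn1 < 1.0:
        raise ValueError("urn1 must lie strictly in (0, 1)")
    return math.log(1.0 / urn1) / total_rate


def select_event(table: EventTable, urn2: float) -> Event:
    """Direct-method selection: first event with cumulative rate >= urn2*total."""
    if table.total_rate <= 0.0 or not table.events:
        raise ValueError("cannot select from an empty or zero-rate table")
    threshold = urn2 * table.total_rate
    acc = 0.0
    last_positive = None
    for ev in table.events:
        acc += ev.rate
        if ev.rate > 0.0:
            last_positive = ev
        if acc >= threshold and ev.rate > 0.0:
            return ev
    return last_positive  # guard against round-off at threshold ~ total


# ---------------------------------------------------------------------------
# deterministic mechanics
# ---------------------------------------------------------------------------

def module_flow_rate(module: Module, state: CellState,
                     p: SimulationParameters) -> float:
    """Retrograde flow of one module at its current motor load (nm/s).

    The motor ensemble bears the substrate-spring force ``kappa_s * x_s``;
    compressive (negative) transients leave the motors unloaded.
    """
    load = max(p.kappa_s * module.x_s, 0.0)
    if module.n_m == 0:
        return 0.0
    return motor_velocity(load, module.n_m, p)


def advance_deterministic(state: CellState, dt: float, p: SimulationParameters,
                          flows: Optional[List[float]] = None,
                          v_p: Optional[float] = None) -> CellState:
    """Explicit first-order advance over ``dt`` at held velocities (in place).

    Module lengths change by ``(v_p - v_f) dt`` (capped modules do not
    polymerize), the G-actin pool is debited/credited accordingly
    (polymerization truncated at the available pool), bound-clutch actin
    ends translate with the flow, and attachments that pass the motor
    position unbind forcibly.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return state
    if flows is None:
        flows = [module_flow_rate(m, state, p) for m in state.modules]
    if v_p is None:
        v_p = polymerization_speed(min(max(state.A_G, 0.0), p.A_T), p)
    poly = [v_p * dt if not m.capped else 0.0 for m in state.modules]
    total_poly = sum(poly)
    if total_poly > state.A_G and total_poly > 0.0:
        scale = max(state.A_G, 0.0) / total_poly
        poly = [q * scale for q in poly]
        total_poly = sum(poly)
    total_depoly = 0.0
    for mod, v_f, grow in zip(state.modules, flows, poly):
        shrink = v_f * dt
        new_len = mod.length + grow - shrink
        if new_len < 0.0:
            depoly = mod.length + grow
            new_len = 0.0
        else:
            depoly = shrink
        mod.length = new_len
        total_depoly += depoly
        if mod.n_bound:
            idx = mod.bound
            mod.a[idx] += v_f * dt
            mod.dist[idx] -= v_f * dt
            forced = idx & (mod.dist <= 0.0)
            if forced.any():
                mod.bound[forced] = False
                mod.a[forced] = 0.0
                mod.dist[forced] = 0.0
        mod.x_s = module_substrate_displacement(mod, p)
    state.A_G += total_depoly - total_poly
    state.t += dt
    return state


def execute_event(state: CellState, event: Event, p: SimulationParameters,
                  rng: np.random.Generator) -> CellState:
    """Apply one stochastic event to the state (in place)."""
    if event.kind == "clutch_bind":
        mod = state.modules[event.module]
        if mod.bound[event.clutch]:
            raise ValueError("clutch_bind targets an already bound clutch")
        mod.bound[event.clutch] = True
        mod.a[event.clutch] = mod.x_s          # zero extension at binding
        mod.dist[event.clutch] = mod.length    # attaches at the module tip
    elif event.kind == "clutch_unbind":
        mod = state.modules[event.module]
        if not mod.bound[event.clutch]:
            raise ValueError("clutch_unbind targets an unbound clutch")
        mod.bound[event.clutch] = False
        mod.a[event.clutch] = 0.0
        mod.dist[event.clutch] = 0.0
        mod.x_s = module_substrate_displacement(mod, p)
    elif event.kind == "body_clutch_bind":
        if state.body_bound[event.clutch]:
            raise ValueError("body_clutch_bind targets a bound clutch")
        state.body_bound[event.clutch] = True
        state.body_e[event.clutch] = 0.0       # zero extension at binding
    elif event.kind == "body_clutch_unbind":
        if not state.body_bound[event.clutch]:
            raise ValueError("body_clutch_unbind targets an unbound clutch")
        e_rm = state.body_e[event.clutch].copy()
        state.body_bound[event.clutch] = False
        state.body_e[event.clutch] = 0.0
        n_b = int(state.body_bound.sum())
        # substrate node springs back; remaining clutches re-balance
        d_s = -p.kappa_c * e_rm / (p.kappa_s + n_b * p.kappa_c)
        state.x_s_cell += d_s
        state.body_e[state.body_bound] -= d_s
        if n_b == 0:
            state.x_s_cell[:] = 0.0
    elif event.kind == "module_birth":
        theta = rng.random() * 2.0 * math.pi
        n_m, n_c = allocate_on_birth(state.n_m_free, state.n_c_free, p)
        mod = Module.fresh(theta, p.l_in, n_m, n_c,
                           module_id=state.next_module_id)
        state.next_module_id += 1
        state.n_m_free -= n_m
        state.n_c_free -= n_c
        state.A_G -= p.l_in
        state.modules.append(mod)
    elif event.kind == "module_cap":
        state.modules[event.module].capped = True
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")
    return state


def destroy_short_modules(state: CellState, p: SimulationParameters) -> CellState:
    """Remove modules with length < l_min, returning their resources."""
    survivors = []
    for mod in state.modules:
        if mod.length < p.l_min:
            state.n_m_free += mod.n_m
            state.n_c_free += mod.n_c
            state.A_G += mod.length
        else:
            survivors.append(mod)
    state.modules = survivors
    return state


# ---------------------------------------------------------------------------
# whole-cell force balance
# ---------------------------------------------------------------------------

def _module_internal_equilibrate(mod: Module, delta: float,
                                 p: SimulationParameters) -> None:
    """Re-balance one module's chain after the body moved by ``delta``
    along the module axis (outward positive).

    The rigid filament translates by ``dphi`` (inward positive, carrying all
    bound-clutch actin ends), and the substrate node and cell spring take
    the extensions dictated by the series balance
    ``kappa_cell x_cell = sum kappa_c x_c,i = kappa_s x_s``.
    """
    n_b = mod.n_bound
    if n_b == 0:
        mod.x_s = 0.0
        mod.x_cell = 0.0
        return
    idx = mod.bound
    s_a = float(mod.a[idx].sum())
    beta = p.kappa_s * p.kappa_c / (p.kappa_s + n_b * p.kappa_c)
    dphi = (p.kappa_cell * (mod.x_cell - delta) - beta * s_a) \
        / (p.kappa_cell + beta * n_b)
    mod.a[idx] += dphi
    s_a += n_b * dphi
    mod.x_s = p.kappa_c * s_a / (p.kappa_s + n_b * p.kappa_c)
    mod.x_cell = mod.x_cell - dphi - delta


def _chain_stiffness(mod: Module, p: SimulationParameters) -> float:
    n_b = mod.n_bound
    if n_b == 0:
        return 0.0
    return 1.0 / (1.0 / p.kappa_s + 1.0 / (n_b * p.kappa_c)
                  + 1.0 / p.kappa_cell)


def _solve_psd_2x2(M: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Solve the symmetric PSD system M d = g, minimum-norm on null space."""
    tr = M[0, 0] + M[1, 1]
    scale = tr if tr > 1.0 else 1.0
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    if det > 1e-12 * scale * scale:
        return np.linalg.solve(M, g)
    if tr <= 1e-12 * scale:
        return np.zeros(2)
    lam = 0.5 * (tr + math.sqrt(max(tr * tr - 4.0 * det, 0.0)))
    if abs(M[0, 0] - lam) > abs(M[1, 1] - lam):
        v = np.array([M[0, 1], lam - M[0, 0]])
    else:
        v = np.array([lam - M[1, 1], M[0, 1]])
    n = math.hypot(v[0], v[1])
    v = np.array([1.0, 0.0]) if n == 0.0 else v / n
    return (float(g @ v) / lam) * v


def net_body_force(state: CellState, p: SimulationParameters) -> np.ndarray:
    """Vector sum of module forces and the cell-body force (pN)."""
    g = np.zeros(2)
    for mod in state.modules:
        g += p.kappa_s * mod.x_s * mod.u
    for i in range(p.n_c_cell):
        if state.body_bound[i]:
            g -= p.kappa_c * state.body_e[i]
    return g


def solve_force_balance(state: CellState, p: SimulationParameters) -> np.ndarray:
    """Steps 10-11: move the body to zero net force and redistribute springs.

    Each module acts on the body as a one-dimensional chain of springs
    (substrate, parallel bound clutches, cell spring) along its axis; the
    cell-body clutch ensemble acts isotropically through the central
    substrate spring.  At fixed clutch engagement the network is linear, so
    a single Newton step with the analytic chain stiffnesses is exact; the
    residual is checked against ``FB_TOL * n_m_tot * F_m``.

    Returns the new body position (nm); mutates the state in place.
    """
    # internal equilibration at fixed body, collecting forces and stiffnesses
    M = np.zeros((2, 2))
    g = np.zeros(2)
    for mod in state.modules:
        _module_internal_equilibrate(mod, 0.0, p)
        u = mod.u
        g += p.kappa_s * mod.x_s * u
        M += _chain_stiffness(mod, p) * np.outer(u, u)
    n_bb = int(state.body_bound.sum())
    if n_bb:
        g -= p.kappa_c * state.body_e[state.body_bound].sum(axis=0)
        k_body = n_bb * p.kappa_c * p.kappa_s / (p.kappa_s + n_bb * p.kappa_c)
        M[0, 0] += k_body
        M[1, 1] += k_body
    d = _solve_psd_2x2(M, g)
    # apply the body displacement
    for mod in state.modules:
        _module_internal_equilibrate(mod, float(d @ mod.u), p)
    if n_bb:
        d_s = n_bb * p.kappa_c / (p.kappa_s + n_bb * p.kappa_c) * d
        state.x_s_cell += d_s
        state.body_e[state.body_bound] += d - d_s
    state.body = state.body + d
    residual = float(np.linalg.norm(net_body_force(state, p)))
    if residual > FB_TOL * p.n_m_tot * p.F_m:
        raise ForceBalanceError(residual)
    return state.body


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def _snapshot(state: CellState, p: SimulationParameters,
              flows: List[float], cell_rows: list, mod_rows: list) -> None:
    traction = 0.0
    for mod in state.modules:
        traction += abs(p.kappa_s * mod.x_s)
    traction += p.kappa_s * math.hypot(state.x_s_cell[0], state.x_s_cell[1])
    mean_flow = float(np.mean(flows)) if flows else math.nan
    cell_rows.append((state.t, state.body[0] / NM_PER_UM,
                      state.body[1] / NM_PER_UM, len(state.modules),
                      traction, mean_flow))
    for mod, v_f in zip(state.modules, flows):
        mod_rows.append((state.t, mod.module_id, mod.theta, mod.length,
                         p.kappa_s * mod.x_s, v_f))


def run_from_state(state: CellState, p: SimulationParameters, t_end: float,
                   record_interval: float,
                   rng: np.random.Generator) -> Trajectory:
    """Run the reference event loop from an arbitrary state."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if record_interval <= 0:
        raise ValueError("record_interval must be > 0")
    n_rec = int(math.floor(t_end / record_interval + 1e-9)) + 1
    cell_rows: list = []
    mod_rows: list = []
    irec = 0
    flows = [module_flow_rate(m, state, p) for m in state.modules]
    _snapshot(state, p, flows, cell_rows, mod_rows)
    irec += 1
    events = 0
    while state.t < t_end:
        table = build_event_table(state, p)
        if table.total_rate > 0.0:
            dt = draw_event_time(table.total_rate, rng.random())
            event = select_event(table, rng.random())
            fires = state.t + dt <= t_end
            t_target = min(state.t + dt, t_end)
        else:
            event, fires = None, False
            t_target = min(irec * record_interval, t_end) if irec < n_rec \
                else t_end
        flows = [module_flow_rate(m, state, p) for m in state.modules]
        v_p = polymerization_speed(min(max(state.A_G, 0.0), p.A_T), p)
        while irec < n_rec and irec * record_interval <= t_target:
            t_rec = irec * record_interval
            advance_deterministic(state, t_rec - state.t, p, flows, v_p)
            state.t = t_rec
            _snapshot(state, p, flows, cell_rows, mod_rows)
            irec += 1
        advance_deterministic(state, t_target - state.t, p, flows, v_p)
        state.t = t_target
        if fires and event is not None:
            execute_event(state, event, p, rng)
            events += 1
        destroy_short_modules(state, p)
        solve_force_balance(state, p)
    cell = pd.DataFrame(cell_rows, columns=CELL_COLUMNS)
    modules = pd.DataFrame(mod_rows, columns=MODULE_COLUMNS)
    traj = Trajectory(cell=cell, modules=modules, params=p,
                      record_interval=record_interval)
    traj.info = {"events": events, "backend": "reference"}
    return traj


def run_simulation(p: SimulationParameters, t_end: float,
                   record_interval: float, seed: Optional[int] = None,
                   backend: str = "kernel") -> Trajectory:
    """Simulate one cell from the standard initial condition.

    The cell starts with three equally spaced modules of length ``l_in`` and
    no clutches bound.  ``seed`` overrides ``p.rng_seed``.  ``backend`` is
    ``"kernel"`` (numba-accelerated, default) or ``"reference"``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if record_interval <= 0:
        raise ValueError("record_interval must be > 0")
    if seed is None:
        seed = p.rng_seed
    rng = np.random.Generator(np.random.PCG64(seed))
    if backend == "reference":
        state = initial_state(p)
        return run_from_state(state, p, t_end, record_interval, rng)
    if backend != "kernel":
        raise ValueError(f"unknown backend {backend!r}")
    from ._kernel import run_kernel
    return run_kernel(p, t_end, record_interval, rng)
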