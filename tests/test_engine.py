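"""Event engine: table construction, SSA draws, deterministic mechanics,
force balance, and whole-run properties."""
import math

import numpy as np
import pytest
from scipy import stats

from motorclutch import (CellState, EventTable, Event, Module,
                         advance_deterministic, build_event_table,
                         destroy_short_modules, draw_event_time,
                         execute_event, initial_state, module_flow_rate,
                         run_from_state, run_simulation, select_event,
                         solve_force_balance)
from motorclutch.engine import FB_TOL, net_body_force
from motorclutch.mechanics import module_substrate_displacement


def empty_cell(p):
    """A cell with no modules and full pools."""
    return CellState(body=np.zeros(2), modules=[],
                     n_m_free=p.n_m_tot, n_c_free=p.n_c_tot - p.n_c_cell,
                     A_G=p.A_T,
                     body_bound=np.zeros(p.n_c_cell, dtype=bool),
                     body_e=np.zeros((p.n_c_cell, 2)))


def one_module_cell(p, n_m, n_c, length=None, theta=0.0):
    """A cell with a single module holding the entire F-actin budget."""
    length = p.A_T if length is None else length
    mod = Module.fresh(theta, length, n_m, n_c)
    return CellState(body=np.zeros(2), modules=[mod],
                     n_m_free=p.n_m_tot - n_m,
                     n_c_free=p.n_c_tot - p.n_c_cell - n_c,
                     A_G=p.A_T - length,
                     body_bound=np.zeros(p.n_c_cell, dtype=bool),
                     body_e=np.zeros((p.n_c_cell, 2))), mod


# ---------------------------------------------------------------------------
# event table
# ---------------------------------------------------------------------------

class TestEventTable:
    def test_rates_compose_bell_and_birth(self, small_params):
        """2 free + 1 unloaded bound clutch, uncapped module, A_G=0:
        rates are [k_on, k_on, k_off*, (birth 0), k_cap]."""
        p = small_params.replace(n_c_cell=0)
        state, mod = one_module_cell(p, n_m=5, n_c=3)
        mod.bound[2] = True   # bound at zero extension
        table = build_event_table(state, p)
        by_kind = {(e.kind, e.clutch): e.rate for e in table.events}
        assert by_kind[("clutch_bind", 0)] == p.k_on
        assert by_kind[("clutch_bind", 1)] == p.k_on
        assert by_kind[("clutch_unbind", 2)] == pytest.approx(p.k_off_star)
        assert by_kind[("module_birth", -1)] == 0.0
        assert by_kind[("module_cap", -1)] == p.k_cap
        assert table.total_rate == pytest.approx(
            2 * p.k_on + p.k_off_star + p.k_cap)

    def test_empty_cell_only_birth(self, small_params):
        p = small_params.replace(n_c_cell=0)
        state = empty_cell(p)
        table = build_event_table(state, p)
        assert [e.kind for e in table.events] == ["module_birth"]
        assert table.total_rate == pytest.approx(p.k_mod_star)

    def test_bound_clutch_at_rupture_force(self, small_params):
        p = small_params.replace(n_c_cell=0)
        state, mod = one_module_cell(p, n_m=5, n_c=1)
        mod.bound[0] = True
        # choose a so that the equilibrated clutch tension equals F_b
        mod.a[0] = p.F_b * (p.kappa_s + p.kappa_c) / (p.kappa_c * p.kappa_s)
        mod.x_s = module_substrate_displacement(mod, p)
        assert p.kappa_c * (mod.a[0] - mod.x_s) == pytest.approx(p.F_b)
        table = build_event_table(state, p)
        unbind = [e for e in table.events if e.kind == "clutch_unbind"][0]
        assert unbind.rate == pytest.approx(p.k_off_star * math.e)


class TestSsaDraws:
    def test_event_time_values(self):
        assert draw_event_time(2.0, math.exp(-1)) == pytest.approx(0.5)
        assert draw_event_time(1.0, math.exp(-3)) == pytest.approx(3.0)
        assert draw_event_time(5.0, 1 - 1e-13) == pytest.approx(0.0, abs=1e-12)
        assert draw_event_time(0.0, 0.5) == math.inf

    def test_select_first_cumulative_index(self):
        table = EventTable(events=[Event("a", rate=1.0), Event("b", rate=3.0)],
                           total_rate=4.0)
        assert select_event(table, 0.2).kind == "a"   # cumulative 1 >= 0.8
        assert select_event(table, 0.5).kind == "b"
        with pytest.raises(ValueError):
            select_event(EventTable(), 0.5)

    def test_selection_frequencies_match_rates(self, rng):
        rates = [1.0, 3.0, 6.0]
        table = EventTable(
            events=[Event(k, rate=r) for k, r in zip("abc", rates)],
            total_rate=sum(rates))
        n = 100_000
        counts = {"a": 0, "b": 0, "c": 0}
        for _ in range(n):
            counts[select_event(table, rng.random()).kind] += 1
        for k, r in zip("abc", rates):
            p_expect = r / sum(rates)
            sigma = math.sqrt(n * p_expect * (1 - p_expect))
            assert abs(counts[k] - n * p_expect) < 3 * sigma


# ---------------------------------------------------------------------------
# deterministic mechanics
# ---------------------------------------------------------------------------

class TestFlowRate:
    def test_unloaded_module_flows_at_vmax(self, small_params):
        state, mod = one_module_cell(small_params, n_m=5, n_c=3)
        assert module_flow_rate(mod, state, small_params) == \
            small_params.v_m_star

    def test_series_spring_load_sharing(self, small_params):
        """One bound clutch, kappa_c = kappa_s = 1: a 10 nm actin-side
        displacement splits equally, so the motors see 5 pN."""
        p = small_params.replace(kappa_c=1.0, kappa_s=1.0)
        state, mod = one_module_cell(p, n_m=5, n_c=1)
        mod.bound[0] = True
        mod.a[0] = 10.0
        mod.x_s = module_substrate_displacement(mod, p)
        assert mod.x_s == pytest.approx(5.0)
        expected = p.v_m_star * (1 - 5.0 / (5 * p.F_m))
        assert module_flow_rate(mod, state, p) == pytest.approx(expected)

    def test_stall(self, small_params):
        p = small_params.replace(kappa_s=1.0)
        state, mod = one_module_cell(p, n_m=1, n_c=1)
        mod.bound[0] = True
        mod.a[0] = 1e9   # far beyond stall
        mod.x_s = module_substrate_displacement(mod, p)
        assert module_flow_rate(mod, state, p) == 0.0


class TestAdvance:
    def test_net_length_change_and_conservation(self, small_params):
        p = small_params
        state, mod = one_module_cell(p, n_m=5, n_c=3, length=50000.0)
        a_before = state.A_G + mod.length
        v_p = p.v_p_star * state.A_G / p.A_T
        advance_deterministic(state, 2.0, p)
        # unloaded: flow = v_m*; uncapped growth at v_p
        assert mod.length == pytest.approx(50000.0 + (v_p - p.v_m_star) * 2.0)
        assert state.A_G + mod.length == pytest.approx(a_before)

    def test_capped_module_only_shrinks(self, small_params):
        p = small_params
        state, mod = one_module_cell(p, n_m=5, n_c=3, length=50000.0)
        mod.capped = True
        advance_deterministic(state, 2.0, p)
        assert mod.length == pytest.approx(50000.0 - p.v_m_star * 2.0)

    def test_flow_stretches_bound_clutches(self, small_params):
        p = small_params
        state, mod = one_module_cell(p, n_m=5, n_c=2, length=50000.0)
        mod.bound[0] = True
        mod.a[0] = 0.0
        mod.dist[0] = 50000.0
        advance_deterministic(state, 1.0, p)
        assert mod.a[0] > 0.0
        assert mod.dist[0] < 50000.0

    def test_attachment_passing_motor_forces_unbind(self, small_params):
        p = small_params
        state, mod = one_module_cell(p, n_m=5, n_c=1, length=50000.0)
        mod.bound[0] = True
        mod.dist[0] = p.v_m_star * 0.5   # reaches the motor within 1 s
        advance_deterministic(state, 1.0, p)
        assert not mod.bound[0]


class TestExecuteAndDestroy:
    def test_bind_unbind_involution_at_zero_load(self, small_params):
        p = small_params.replace(n_c_cell=0)
        state, mod = one_module_cell(p, n_m=5, n_c=2)
        rng = np.random.default_rng(0)
        execute_event(state, Event("clutch_bind", 0, 1), p, rng)
        assert mod.bound[1] and mod.a[1] == mod.x_s == 0.0
        execute_event(state, Event("clutch_unbind", 0, 1), p, rng)
        assert not mod.bound[1] and mod.a[1] == 0.0

    def test_birth_with_full_pools(self, small_params, rng):
        p = small_params.replace(n_c_cell=0)
        state = empty_cell(p)
        execute_event(state, Event("module_birth"), p, rng)
        mod = state.modules[0]
        assert (mod.n_m, mod.n_c) == (p.n_m_star, p.n_c_star)
        assert mod.length == p.l_in
        assert state.n_m_free == p.n_m_tot - p.n_m_star
        assert state.A_G == pytest.approx(p.A_T - p.l_in)
        state.check_invariants(p)

    def test_destroy_strict_threshold_and_credit(self, small_params, rng):
        p = small_params
        state = empty_cell(p)
        short = Module.fresh(0.0, p.l_min - 1e-9, 3, 2)
        exact = Module.fresh(1.0, p.l_min, 2, 1)
        state.modules = [short, exact]
        state.n_m_free -= 5
        state.n_c_free -= 3
        state.A_G = p.A_T - short.length - exact.length
        a_g = state.A_G
        destroy_short_modules(state, p)
        assert state.modules == [exact]
        assert state.n_m_free == p.n_m_tot - 2
        assert state.A_G == pytest.approx(a_g + p.l_min - 1e-9)
        state.check_invariants(p)


# ---------------------------------------------------------------------------
# force balance
# ---------------------------------------------------------------------------

def bound_module(p, theta, a_value, n_m=5, n_c=2, length=20000.0):
    mod = Module.fresh(theta, length, n_m, n_c)
    mod.bound[0] = True
    mod.a[0] = a_value
    mod.dist[0] = length
    mod.x_s = module_substrate_displacement(mod, p)
    mod.x_cell = p.kappa_s * mod.x_s / p.kappa_cell   # series-consistent
    return mod


class TestForceBalance:
    def test_no_bound_clutches_body_unchanged(self, small_params):
        p = small_params
        state = empty_cell(p)
        state.modules = [Module.fresh(0.3, 20000.0, 5, 2)]
        state.n_m_free -= 5
        state.n_c_free -= 2
        state.A_G -= 20000.0
        pos = solve_force_balance(state, p)
        assert np.allclose(pos, 0.0)

    @pytest.mark.parametrize("thetas", [
        (0.0, math.pi),
        (0.0, 2 * math.pi / 3, 4 * math.pi / 3),
    ])
    def test_symmetric_modules_cancel(self, small_params, thetas):
        p = small_params
        state = empty_cell(p)
        state.modules = [bound_module(p, th, 25.0) for th in thetas]
        state.n_m_free -= 5 * len(thetas)
        state.n_c_free -= 2 * len(thetas)
        state.A_G -= 20000.0 * len(thetas)
        pos = solve_force_balance(state, p)
        assert np.allclose(pos, 0.0, atol=1e-9)

    def test_one_dimensional_closed_form(self, small_params):
        """Single +x module against bound body clutches: the body moves by
        F0 / (k_module + k_body) with the hand-derived chain stiffnesses."""
        p = small_params
        state = empty_cell(p)
        state.modules = [bound_module(p, 0.0, 25.0)]
        state.n_m_free -= 5
        state.n_c_free -= 2
        state.A_G -= 20000.0
        state.body_bound[:] = True   # all body clutches engaged, relaxed
        kc, ks, kcell = p.kappa_c, p.kappa_s, p.kappa_cell
        x_s0 = kc * 25.0 / (ks + kc)
        F0 = ks * x_s0
        k_mod = 1.0 / (1.0 / ks + 1.0 / kc + 1.0 / kcell)
        n_b = p.n_c_cell
        k_body = n_b * kc * ks / (ks + n_b * kc)
        expected = F0 / (k_mod + k_body)
        pos = solve_force_balance(state, p)
        assert pos[0] == pytest.approx(expected, rel=1e-9)
        assert pos[1] == pytest.approx(0.0, abs=1e-12)
        # series equality after the solve
        mod = state.modules[0]
        clutch_force = p.kappa_c * float(
            (mod.a[mod.bound] - mod.x_s).sum())
        assert p.kappa_cell * mod.x_cell == pytest.approx(clutch_force)
        assert p.kappa_s * mod.x_s == pytest.approx(clutch_force)
        # residual within tolerance
        assert np.linalg.norm(net_body_force(state, p)) <= \
            FB_TOL * p.n_m_tot * p.F_m


# ---------------------------------------------------------------------------
# whole runs
# ---------------------------------------------------------------------------

class TestRunProperties:
    def test_record_of_initial_state_only(self, small_params):
        traj = run_simulation(small_params, t_end=0.5, record_interval=1000.0,
                              seed=7, backend="reference")
        assert len(traj.cell) == 1
        assert traj.cell.loc[0, "t_s"] == 0.0
        assert traj.cell.loc[0, "n_modules"] == 3

    def test_zero_rates_body_frozen_modules_destroyed(self, small_params):
        """With binding, birth and capping disabled (and negligible
        polymerization) modules shorten at v_m* and are destroyed; the body
        never moves."""
        p = small_params.replace(k_on=0.0, k_mod_star=0.0, k_cap=0.0,
                                 v_p_star=1e-9, n_c_cell=0)
        t_destroy = (p.l_in - p.l_min) / p.v_m_star   # ~37.5 s
        traj = run_simulation(p, t_end=2 * t_destroy, record_interval=5.0,
                              seed=1, backend="reference")
        assert np.allclose(traj.positions_um(), 0.0)
        early = traj.cell[traj.cell["t_s"] < t_destroy - 5.0]
        assert (early["n_modules"] == 3).all()
        assert (early["mean_flow_nm_s"] == p.v_m_star).all()
        assert traj.cell.iloc[-1]["n_modules"] == 0

    def test_same_seed_same_trajectory(self, small_params):
        for backend in ("reference", "kernel"):
            t1 = run_simulation(small_params, 20.0, 5.0, seed=42,
                                backend=backend)
            t2 = run_simulation(small_params, 20.0, 5.0, seed=42,
                                backend=backend)
            assert t1.cell.equals(t2.cell)
            assert t1.modules.equals(t2.modules)

    def test_backends_agree(self, small_params):
        """The numba kernel and the op-level reference implementation follow
        the same event sequence and produce matching trajectories."""
        ref = run_simulation(small_params, 30.0, 5.0, seed=3,
                             backend="reference")
        ker = run_simulation(small_params, 30.0, 5.0, seed=3,
                             backend="kernel")
        assert ref.info["events"] == ker.info["events"]
        assert np.allclose(ref.positions_um(), ker.positions_um(),
                           atol=1e-9)
        assert np.allclose(ref.cell["total_traction_pN"],
                           ker.cell["total_traction_pN"], atol=1e-8)

    def test_mass_conservation_through_run(self, small_params):
        p = small_params
        state = initial_state(p)
        rng = np.random.default_rng(11)
        run_from_state(state, p, 40.0, 10.0, rng)
        state.check_invariants(p)

    def test_invalid_run_arguments(self, small_params):
        with pytest.raises(ValueError):
            run_simulation(small_params, -1.0, 5.0)
        with pytest.raises(ValueError):
            run_simulation(small_params, 10.0, 0.0)


class TestWaitingTimes:
    def test_exponential_under_frozen_rates(self, small_params):
        """With a constant total rate (k_on = k*_off, negligible forces) the
        inter-event waiting times are exponential (KS p > 0.01, n = 1e4)."""
        p = small_params.replace(k_on=0.5, k_off_star=0.5, F_b=1e12,
                                 k_mod_star=0.0, k_cap=0.0, n_c_cell=16)
        state = empty_cell(p)
        rng = np.random.default_rng(2024)
        total = 16 * 0.5
        waits = np.empty(10_000)
        for i in range(waits.size):
            table = build_event_table(state, p)
            assert table.total_rate == pytest.approx(total)
            waits[i] = draw_event_time(table.total_rate, rng.random())
            ev = select_event(table, rng.random())
            execute_event(state, ev, p, rng)
        ks = stats.kstest(waits, "expon", args=(0, 1 / total))
        assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# single-module load-and-fail against an independent oracle
# ---------------------------------------------------------------------------

def oracle_single_module_mean_flow(n_m, n_c, k_on, k_off, F_b, kc, ks, v_m,
                                   F_m, t_end, seed):
    """Brute-force SSA for one classic motor-clutch unit with a fixed cell.

    Tracks actin-side positions of each clutch directly and recomputes the
    substrate node from scratch every iteration; structured independently
    of the package engine.
    """
    rng = np.random.default_rng(seed)
    pos = np.zeros(n_c)
    bound = np.zeros(n_c, dtype=bool)
    t = 0.0
    integral = 0.0
    while t < t_end:
        sub = kc * pos[bound].sum() / (ks + kc * bound.sum()) \
            if bound.any() else 0.0
        load = max(ks * sub, 0.0)
        v = max(v_m * (1.0 - load / (n_m * F_m)), 0.0)
        rates = np.full(n_c, k_on)
        rates[bound] = k_off * np.exp(kc * np.abs(pos[bound] - sub) / F_b)
        total = rates.sum()
        dt = rng.exponential(1.0 / total)
        step = min(dt, t_end - t)
        integral += v * step
        pos[bound] += v * step
        if t + dt > t_end:
            break
        i = rng.choice(n_c, p=rates / total)
        if bound[i]:
            bound[i] = False
            pos[i] = 0.0
        else:
            sub_new = kc * pos[bound].sum() / (ks + kc * bound.sum()) \
                if bound.any() else 0.0
            bound[i] = True
            pos[i] = sub_new
        t += dt
    return integral / t_end


def engine_single_module_mean_flow(p, n_m, n_c, t_end, seed):
    """Mean retrograde flow from the engine ops with a pinned cell body."""
    from motorclutch.engine import (advance_deterministic, build_event_table,
                                    draw_event_time, execute_event,
                                    module_flow_rate, select_event)
    state, mod = one_module_cell(p, n_m, n_c)
    rng = np.random.default_rng(seed)
    t = 0.0
    integral = 0.0
    while t < t_end:
        table = build_event_table(state, p)
        dt = draw_event_time(table.total_rate, rng.random())
        ev = select_event(table, rng.random())
        v = module_flow_rate(mod, state, p)
        step = min(dt, t_end - t)
        advance_deterministic(state, step, p, flows=[v], v_p=0.0)
        integral += v * step
        if t + dt > t_end:
            break
        execute_event(state, ev, p, rng)
        t += dt
    return integral / t_end


@pytest.fixture(scope="module")
def single_module_params():
    from motorclutch import SimulationParameters
    return SimulationParameters(
        k_on=1.0, k_off_star=0.1, F_b=2.0, kappa_c=0.8, kappa_s=1.0,
        kappa_cell=1e4, F_m=2.0, v_m_star=120.0, v_p_star=1e-9,
        k_mod_star=0.0, k_cap=0.0, l_in=5000.0, l_min=100.0,
        n_m_tot=10, n_c_tot=10, n_m_star=10, n_c_star=10, n_c_cell=0,
        A_T=2e6)


SINGLE_MODULE_GRID = (1e-5, 0.01, 0.1, 1.0, 10.0, 1000.0)


@pytest.fixture(scope="module")
def flow_curves(single_module_params):
    t_end = 1500.0
    engine, oracle = [], []
    for i, ks in enumerate(SINGLE_MODULE_GRID):
        p = single_module_params.replace(kappa_s=ks)
        engine.append(engine_single_module_mean_flow(
            p, 10, 10, t_end, seed=100 + i))
        oracle.append(oracle_single_module_mean_flow(
            10, 10, p.k_on, p.k_off_star, p.F_b, p.kappa_c, ks,
            p.v_m_star, p.F_m, t_end, seed=900 + i))
    return np.array(engine), np.array(oracle)


class TestSingleModuleLoadAndFail:
    def test_engine_matches_oracle(self, flow_curves, single_module_params):
        engine, oracle = flow_curves
        assert np.all(np.abs(engine - oracle)
                      <= 0.08 * single_module_params.v_m_star)

    def test_biphasic_with_interior_minimum(self, flow_curves):
        for curve in flow_curves:
            k = int(np.argmin(curve))
            assert 0 < k < len(curve) - 1

    def test_soft_and_stiff_limits_recover_flow(self, flow_curves,
                                                single_module_params):
        """In the soft limit load builds too slowly to slow the motors, so
        flow approaches v_m* from below; in the stiff limit flow recovers to
        the frictional-slippage plateau, well above the interior minimum
        (the plateau sits below v_m*, set by single-clutch loading)."""
        v_m = single_module_params.v_m_star
        for curve in flow_curves:
            assert curve.min() < 0.5 * v_m
            assert v_m > curve[0] > 0.9 * v_m          # soft limit
            assert curve[-1] > curve.min() + 0.2 * v_m  # stiff recovery
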