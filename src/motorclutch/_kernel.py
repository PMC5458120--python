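"""numba-compiled event loop.

Implements exactly the algorithm of :mod:`motorclutch.engine` (same event
ordering, same random-draw sequence from the shared ``np.random.Generator``)
on flat arrays, so that whole-cell runs with thousands of clutches are
tractable.  Modules live in fixed slots; ``order`` keeps insertion order so
the event-table traversal matches the reference implementation's list
order.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from numba import njit

from .params import SimulationParameters
from .trajectory import CELL_COLUMNS, MODULE_COLUMNS, NM_PER_UM, Trajectory

__all__ = ["run_kernel"]


@njit(cache=True)
def _mod_xs(s, bound, a, nc, kc, ks):
    nb = 0
    sa = 0.0
    for i in range(nc[s]):
        if bound[s, i]:
            nb += 1
            sa += a[s, i]
    if nb == 0:
        return 0.0
    return kc * sa / (ks + nb * kc)


@njit(cache=True)
def _solve2x2(m00, m01, m11, g0, g1):
    """Symmetric PSD 2x2 solve; minimum-norm on (near-)singular directions."""
    tr = m00 + m11
    scale = tr if tr > 1.0 else 1.0
    det = m00 * m11 - m01 * m01
    if det > 1e-12 * scale * scale:
        inv = 1.0 / det
        return (m11 * g0 - m01 * g1) * inv, (m00 * g1 - m01 * g0) * inv
    if tr <= 1e-12 * scale:
        return 0.0, 0.0
    lam = 0.5 * (tr + math.sqrt(max(tr * tr - 4.0 * det, 0.0)))
    if abs(m00 - lam) > abs(m11 - lam):
        v0, v1 = m01, lam - m00
    else:
        v0, v1 = lam - m11, m01
    n = math.sqrt(v0 * v0 + v1 * v1)
    if n == 0.0:
        v0, v1 = 1.0, 0.0
    else:
        v0, v1 = v0 / n, v1 / n
    proj = (g0 * v0 + g1 * v1) / lam
    return proj * v0, proj * v1


@njit(cache=True)
def _equilibrate(order, n_act, theta, nc, bound, a, xs, xcell, bb, be, sc,
                 body, n_c_cell, kc, ks, kcell):
    """Whole-cell force balance (steps 10-11).  Returns the residual (pN)."""
    m00 = 0.0
    m01 = 0.0
    m11 = 0.0
    g0 = 0.0
    g1 = 0.0
    # pass 1: internal equilibration at fixed body; collect force/stiffness
    for oi in range(n_act):
        s = order[oi]
        nb = 0
        sa = 0.0
        for i in range(nc[s]):
            if bound[s, i]:
                nb += 1
                sa += a[s, i]
        if nb == 0:
            xs[s] = 0.0
            xcell[s] = 0.0
            continue
        beta = ks * kc / (ks + nb * kc)
        dphi = (kcell * xcell[s] - beta * sa) / (kcell + beta * nb)
        for i in range(nc[s]):
            if bound[s, i]:
                a[s, i] += dphi
        sa += nb * dphi
        xs[s] = kc * sa / (ks + nb * kc)
        xcell[s] = xcell[s] - dphi
        ux = math.cos(theta[s])
        uy = math.sin(theta[s])
        F = ks * xs[s]
        g0 += F * ux
        g1 += F * uy
        keff = 1.0 / (1.0 / ks + 1.0 / (nb * kc) + 1.0 / kcell)
        m00 += keff * ux * ux
        m01 += keff * ux * uy
        m11 += keff * uy * uy
    nbb = 0
    ex = 0.0
    ey = 0.0
    for i in range(n_c_cell):
        if bb[i]:
            nbb += 1
            ex += be[i, 0]
            ey += be[i, 1]
    g0 -= kc * ex
    g1 -= kc * ey
    if nbb > 0:
        kb = nbb * kc * ks / (ks + nbb * kc)
        m00 += kb
        m11 += kb
    d0, d1 = _solve2x2(m00, m01, m11, g0, g1)
    # pass 2: apply the body displacement
    for oi in range(n_act):
        s = order[oi]
        nb = 0
        sa = 0.0
        for i in range(nc[s]):
            if bound[s, i]:
                nb += 1
                sa += a[s, i]
        if nb == 0:
            continue
        delta = d0 * math.cos(theta[s]) + d1 * math.sin(theta[s])
        beta = ks * kc / (ks + nb * kc)
        dphi = (kcell * (xcell[s] - delta) - beta * sa) / (kcell + beta * nb)
        for i in range(nc[s]):
            if bound[s, i]:
                a[s, i] += dphi
        sa += nb * dphi
        xs[s] = kc * sa / (ks + nb * kc)
        xcell[s] = xcell[s] - dphi - delta
    if nbb > 0:
        fac = nbb * kc / (ks + nbb * kc)
        dsx = fac * d0
        dsy = fac * d1
        sc[0] += dsx
        sc[1] += dsy
        for i in range(n_c_cell):
            if bb[i]:
                be[i, 0] += d0 - dsx
                be[i, 1] += d1 - dsy
    body[0] += d0
    body[1] += d1
    # residual
    r0 = 0.0
    r1 = 0.0
    for oi in range(n_act):
        s = order[oi]
        ux = math.cos(theta[s])
        uy = math.sin(theta[s])
        r0 += ks * xs[s] * ux
        r1 += ks * xs[s] * uy
    for i in range(n_c_cell):
        if bb[i]:
            r0 -= kc * be[i, 0]
            r1 -= kc * be[i, 1]
    return math.sqrt(r0 * r0 + r1 * r1)


@njit(cache=True)
def _advance(dt, vp, order, n_act, capped, length, nc, bound, a, dist, flows,
             xs, kc, ks, A_G):
    """Explicit advance at held velocities; returns the new G-actin pool."""
    if dt <= 0.0:
        return A_G
    total_poly = 0.0
    for oi in range(n_act):
        if not capped[order[oi]]:
            total_poly += vp * dt
    scale = 1.0
    if total_poly > A_G and total_poly > 0.0:
        scale = (A_G if A_G > 0.0 else 0.0) / total_poly
    total_poly = 0.0
    total_depoly = 0.0
    for oi in range(n_act):
        s = order[oi]
        grow = 0.0 if capped[s] else vp * dt * scale
        shrink = flows[s] * dt
        nl = length[s] + grow - shrink
        if nl < 0.0:
            depoly = length[s] + grow
            nl = 0.0
        else:
            depoly = shrink
        length[s] = nl
        total_poly += grow
        total_depoly += depoly
        vdt = flows[s] * dt
        if vdt != 0.0:
            for i in range(nc[s]):
                if bound[s, i]:
                    a[s, i] += vdt
                    dist[s, i] -= vdt
                    if dist[s, i] <= 0.0:   # attachment passed the motor
                        bound[s, i] = False
                        a[s, i] = 0.0
                        dist[s, i] = 0.0
        xs[s] = _mod_xs(s, bound, a, nc, kc, ks)
    return A_G + total_depoly - total_poly


@njit(cache=True)
def _run(k_on, k_off_star, F_b, kc, ks, kcell, F_m, v_m_star, v_p_star,
         k_mod_star, k_cap, l_in, l_min, n_m_tot, n_c_tot, n_m_star,
         n_c_star, n_c_cell, A_T, t_end, rec_dt, n_rec, maxm, maxc, rng,
         rec_t, rec_x, rec_y, rec_nmod, rec_trac, rec_flow,
         mrec_t, mrec_id, mrec_theta, mrec_len, mrec_F, mrec_flow):
    used = np.zeros(maxm, np.bool_)
    order = np.zeros(maxm, np.int64)
    theta = np.zeros(maxm)
    length = np.zeros(maxm)
    capped = np.zeros(maxm, np.bool_)
    nm = np.zeros(maxm, np.int64)
    nc = np.zeros(maxm, np.int64)
    xs = np.zeros(maxm)
    xcell = np.zeros(maxm)
    mid = np.zeros(maxm, np.int64)
    bound = np.zeros((maxm, maxc), np.bool_)
    a = np.zeros((maxm, maxc))
    dist = np.zeros((maxm, maxc))
    crate = np.zeros((maxm, maxc))
    nbcell = n_c_cell if n_c_cell > 0 else 1
    brate = np.zeros(nbcell)
    bb = np.zeros(nbcell, np.bool_)
    be = np.zeros((nbcell, 2))
    sc = np.zeros(2)
    body = np.zeros(2)
    flows = np.zeros(maxm)

    n_act = 0
    n_m_free = n_m_tot
    n_c_free = n_c_tot - n_c_cell
    A_G = A_T
    next_id = 0
    for k in range(3):
        s = k
        used[s] = True
        order[n_act] = s
        n_act += 1
        theta[s] = 2.0 * math.pi * k / 3.0
        length[s] = l_in
        amn = int(math.floor(n_m_star * n_m_free / n_m_tot + 0.5))
        if amn > n_m_free:
            amn = n_m_free
        acn = int(math.floor(n_c_star * n_c_free / n_c_tot + 0.5))
        if acn > n_c_free:
            acn = n_c_free
        nm[s] = amn
        nc[s] = acn
        mid[s] = next_id
        next_id += 1
        n_m_free -= amn
        n_c_free -= acn
        A_G -= l_in

    t = 0.0
    irec = 0
    n_mrec = 0
    events = 0
    max_resid = 0.0
    max_drift = 0.0
    cons_ok = True

    # flows at the initial state, then the first snapshot
    for oi in range(n_act):
        s = order[oi]
        if nm[s] == 0:
            flows[s] = 0.0
        else:
            load = ks * xs[s]
            if load < 0.0:
                load = 0.0
            v = v_m_star * (1.0 - load / (nm[s] * F_m))
            flows[s] = v if v > 0.0 else 0.0

    # --- snapshot at t = 0
    trac = 0.0
    fsum = 0.0
    for oi in range(n_act):
        s = order[oi]
        trac += abs(ks * xs[s])
        fsum += flows[s]
    trac += ks * math.sqrt(sc[0] * sc[0] + sc[1] * sc[1])
    rec_t[irec] = t
    rec_x[irec] = body[0]
    rec_y[irec] = body[1]
    rec_nmod[irec] = n_act
    rec_trac[irec] = trac
    rec_flow[irec] = fsum / n_act if n_act > 0 else np.nan
    for oi in range(n_act):
        s = order[oi]
        mrec_t[n_mrec] = t
        mrec_id[n_mrec] = mid[s]
        mrec_theta[n_mrec] = theta[s]
        mrec_len[n_mrec] = length[s]
        mrec_F[n_mrec] = ks * xs[s]
        mrec_flow[n_mrec] = flows[s]
        n_mrec += 1
    irec += 1

    while t < t_end:
        # --- step 2: event rates
        total = 0.0
        for oi in range(n_act):
            s = order[oi]
            for i in range(nc[s]):
                if bound[s, i]:
                    r = k_off_star * math.exp(kc * abs(a[s, i] - xs[s]) / F_b)
                else:
                    r = k_on
                crate[s, i] = r
                total += r
        for i in range(n_c_cell):
            if bb[i]:
                ext = math.sqrt(be[i, 0] ** 2 + be[i, 1] ** 2)
                r = k_off_star * math.exp(kc * ext / F_b)
            else:
                r = k_on
            brate[i] = r
            total += r
        if A_G >= l_in and n_act < maxm:
            ag = min(max(A_G, 0.0), A_T)
            birth = k_mod_star * (ag / A_T) ** 4
        else:
            birth = 0.0
        total += birth
        for oi in range(n_act):
            if not capped[order[oi]]:
                total += k_cap

        # --- steps 3-4: waiting time and event choice
        ev_kind = -1   # 0 bind, 1 unbind, 2 body bind, 3 body unbind,
        ev_s = -1      # 4 birth, 5 cap
        ev_i = -1
        fires = False
        if total > 0.0:
            u1 = rng.random()
            dt = math.log(1.0 / u1) / total
            u2 = rng.random()
            thr = u2 * total
            acc = 0.0
            lk = -1
            ls = -1
            li = -1
            done = False
            for oi in range(n_act):
                if done:
                    break
                s = order[oi]
                for i in range(nc[s]):
                    r = crate[s, i]
                    acc += r
                    if r > 0.0:
                        lk = 1 if bound[s, i] else 0
                        ls = s
                        li = i
                        if acc >= thr:
                            done = True
                            break
            if not done:
                for i in range(n_c_cell):
                    r = brate[i]
                    acc += r
                    if r > 0.0:
                        lk = 3 if bb[i] else 2
                        ls = -1
                        li = i
                        if acc >= thr:
                            done = True
                            break
            if not done:
                acc += birth
                if birth > 0.0:
                    lk = 4
                    ls = -1
                    li = -1
                    if acc >= thr:
                        done = True
            if not done:
                for oi in range(n_act):
                    s = order[oi]
                    if not capped[s]:
                        acc += k_cap
                        if k_cap > 0.0:
                            lk = 5
                            ls = s
                            li = -1
                            if acc >= thr:
                                done = True
                                break
            ev_kind = lk
            ev_s = ls
            ev_i = li
            fires = t + dt <= t_end
            t_target = t + dt if fires else t_end
        else:
            t_target = irec * rec_dt if irec < n_rec else t_end
            if t_target > t_end:
                t_target = t_end

        # --- step 5: flow rates (held over the interval)
        for oi in range(n_act):
            s = order[oi]
            if nm[s] == 0:
                flows[s] = 0.0
            else:
                load = ks * xs[s]
                if load < 0.0:
                    load = 0.0
                v = v_m_star * (1.0 - load / (nm[s] * F_m))
                flows[s] = v if v > 0.0 else 0.0
        ag = min(max(A_G, 0.0), A_T)
        vp = v_p_star * ag / A_T

        # --- steps 6-7: deterministic advance, with snapshots at records
        while irec < n_rec and irec * rec_dt <= t_target:
            t_r = irec * rec_dt
            A_G = _advance(t_r - t, vp, order, n_act, capped, length, nc,
                           bound, a, dist, flows, xs, kc, ks, A_G)
            t = t_r
            trac = 0.0
            fsum = 0.0
            for oi in range(n_act):
                s = order[oi]
                trac += abs(ks * xs[s])
                fsum += flows[s]
            trac += ks * math.sqrt(sc[0] * sc[0] + sc[1] * sc[1])
            rec_t[irec] = t
            rec_x[irec] = body[0]
            rec_y[irec] = body[1]
            rec_nmod[irec] = n_act
            rec_trac[irec] = trac
            rec_flow[irec] = fsum / n_act if n_act > 0 else np.nan
            for oi in range(n_act):
                s = order[oi]
                mrec_t[n_mrec] = t
                mrec_id[n_mrec] = mid[s]
                mrec_theta[n_mrec] = theta[s]
                mrec_len[n_mrec] = length[s]
                mrec_F[n_mrec] = ks * xs[s]
                mrec_flow[n_mrec] = flows[s]
                n_mrec += 1
            irec += 1
        A_G = _advance(t_target - t, vp, order, n_act, capped, length, nc,
                       bound, a, dist, flows, xs, kc, ks, A_G)
        t = t_target

        # --- step 8: execute the event
        if fires and ev_kind >= 0:
            events += 1
            if ev_kind == 0:
                bound[ev_s, ev_i] = True
                a[ev_s, ev_i] = xs[ev_s]
                dist[ev_s, ev_i] = length[ev_s]
            elif ev_kind == 1:
                bound[ev_s, ev_i] = False
                a[ev_s, ev_i] = 0.0
                dist[ev_s, ev_i] = 0.0
                xs[ev_s] = _mod_xs(ev_s, bound, a, nc, kc, ks)
            elif ev_kind == 2:
                bb[ev_i] = True
                be[ev_i, 0] = 0.0
                be[ev_i, 1] = 0.0
            elif ev_kind == 3:
                e0 = be[ev_i, 0]
                e1 = be[ev_i, 1]
                bb[ev_i] = False
                be[ev_i, 0] = 0.0
                be[ev_i, 1] = 0.0
                nbb = 0
                for i in range(n_c_cell):
                    if bb[i]:
                        nbb += 1
                ds0 = -kc * e0 / (ks + nbb * kc)
                ds1 = -kc * e1 / (ks + nbb * kc)
                sc[0] += ds0
                sc[1] += ds1
                for i in range(n_c_cell):
                    if bb[i]:
                        be[i, 0] -= ds0
                        be[i, 1] -= ds1
                if nbb == 0:
                    sc[0] = 0.0
                    sc[1] = 0.0
            elif ev_kind == 4:
                th = rng.random() * 2.0 * math.pi
                amn = int(math.floor(n_m_star * n_m_free / n_m_tot + 0.5))
                if amn > n_m_free:
                    amn = n_m_free
                acn = int(math.floor(n_c_star * n_c_free / n_c_tot + 0.5))
                if acn > n_c_free:
                    acn = n_c_free
                snew = -1
                for s2 in range(maxm):
                    if not used[s2]:
                        snew = s2
                        break
                used[snew] = True
                order[n_act] = snew
                n_act += 1
                theta[snew] = th
                length[snew] = l_in
                capped[snew] = False
                nm[snew] = amn
                nc[snew] = acn
                xs[snew] = 0.0
                xcell[snew] = 0.0
                mid[snew] = next_id
                next_id += 1
                for i in range(maxc):
                    bound[snew, i] = False
                    a[snew, i] = 0.0
                    dist[snew, i] = 0.0
                n_m_free -= amn
                n_c_free -= acn
                A_G -= l_in
            elif ev_kind == 5:
                capped[ev_s] = True

        # --- step 9: destroy short modules
        w = 0
        for oi in range(n_act):
            s = order[oi]
            if length[s] < l_min:
                n_m_free += nm[s]
                n_c_free += nc[s]
                A_G += length[s]
                used[s] = False
                for i in range(nc[s]):
                    bound[s, i] = False
                    a[s, i] = 0.0
                    dist[s, i] = 0.0
            else:
                order[w] = s
                w += 1
        n_act = w

        # --- steps 10-11: force balance
        resid = _equilibrate(order, n_act, theta, nc, bound, a, xs, xcell,
                             bb, be, sc, body, n_c_cell, kc, ks, kcell)
        if resid > max_resid:
            max_resid = resid

        # conservation diagnostics
        tm = n_m_free
        tc = n_c_free + n_c_cell
        al = A_G
        for oi in range(n_act):
            s = order[oi]
            tm += nm[s]
            tc += nc[s]
            al += length[s]
        if tm != n_m_tot or tc != n_c_tot:
            cons_ok = False
        drift = abs(al - A_T)
        if drift > max_drift:
            max_drift = drift

    return irec, n_mrec, events, max_resid, max_drift, cons_ok


def run_kernel(p: SimulationParameters, t_end: float, record_interval: float,
               rng: np.random.Generator) -> Trajectory:
    """Run the compiled event loop and package the records."""
    from .engine import FB_TOL, ForceBalanceError, max_modules

    maxm = max_modules(p)
    maxc = max(p.n_c_star, 1)
    n_rec = int(math.floor(t_end / record_interval + 1e-9)) + 1
    rec_t = np.zeros(n_rec)
    rec_x = np.zeros(n_rec)
    rec_y = np.zeros(n_rec)
    rec_nmod = np.zeros(n_rec, np.int64)
    rec_trac = np.zeros(n_rec)
    rec_flow = np.zeros(n_rec)
    nmr = n_rec * maxm
    mrec_t = np.zeros(nmr)
    mrec_id = np.zeros(nmr, np.int64)
    mrec_theta = np.zeros(nmr)
    mrec_len = np.zeros(nmr)
    mrec_F = np.zeros(nmr)
    mrec_flow = np.zeros(nmr)

    irec, n_mrec, events, max_resid, max_drift, cons_ok = _run(
        p.k_on, p.k_off_star, p.F_b, p.kappa_c, p.kappa_s, p.kappa_cell,
        p.F_m, p.v_m_star, p.v_p_star, p.k_mod_star, p.k_cap, p.l_in,
        p.l_min, p.n_m_tot, p.n_c_tot, p.n_m_star, p.n_c_star, p.n_c_cell,
        p.A_T, float(t_end), float(record_interval), n_rec, maxm, maxc, rng,
        rec_t, rec_x, rec_y, rec_nmod, rec_trac, rec_flow,
        mrec_t, mrec_id, mrec_theta, mrec_len, mrec_F, mrec_flow)

    if not cons_ok:
        raise AssertionError("motor/clutch conservation violated in kernel run")
    if max_resid > FB_TOL * p.n_m_tot * p.F_m:
        raise ForceBalanceError(max_resid)
    cell = pd.DataFrame({
        "t_s": rec_t[:irec],
        "x_um": rec_x[:irec] / NM_PER_UM,
        "y_um": rec_y[:irec] / NM_PER_UM,
        "n_modules": rec_nmod[:irec],
        "total_traction_pN": rec_trac[:irec],
        "mean_flow_nm_s": rec_flow[:irec],
    })[CELL_COLUMNS]
    modules = pd.DataFrame({
        "t_s": mrec_t[:n_mrec],
        "module_id": mrec_id[:n_mrec],
        "theta_rad": mrec_theta[:n_mrec],
        "length_nm": mrec_len[:n_mrec],
        "force_pN": mrec_F[:n_mrec],
        "flow_nm_s": mrec_flow[:n_mrec],
    })[MODULE_COLUMNS]
    traj = Trajectory(cell=cell, modules=modules, params=p,
                      record_interval=record_interval)
    traj.info = {"events": events, "backend": "kernel",
                 "max_residual_pN": max_resid,
                 "max_actin_drift_nm": max_drift}
    return traj
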