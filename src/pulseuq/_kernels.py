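"""JIT-compiled numerical core of the 1D network solver.

Everything here works in CGS units (pressure dyn/cm^2, flow cm^3/s). The
conservative variables are (A, q); pressure enters the momentum flux through
the antiderivative B(A) with dB/dA = (A/rho) dp/dA, which is exact for
untapered vessels with constant stiffness. The pulse-wave speed of the sqrt
tube law is c(A) = c0 (A/A0)^(1/4) with c0 = sqrt(2 s / (3 rho)) and the
Riemann invariants are u +/- 4c.

Status codes returned by :func:`run_network`:
0 ok, 1 CFL violation, 2 blow-up (non-finite or non-positive area),
3 junction Newton failure, 4 boundary Newton failure.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_CFL = 1
STATUS_BLOWUP = 2
STATUS_JUNCTION = 3
STATUS_BOUNDARY = 4


@njit(cache=True)
def _pressure(A, A0, s):
    return (4.0 / 3.0) * s * (np.sqrt(A / A0) - 1.0)


@njit(cache=True)
def _wave_c(A, A0, c0):
    return c0 * (A / A0) ** 0.25


@njit(cache=True)
def lw_step(A, q, n, dt, dx, A0, s, c0, bcoef, adv, fric):
    """Richtmyer two-step Lax-Wendroff update of interior nodes 1..n-2.

    Boundary nodes 0 and n-1 are left untouched (set by the BC solves).
    Operates in place on the first ``n`` entries of A and q.
    """
    lam = dt / dx
    # fluxes and sources at integer nodes
    F2 = np.empty(n)
    S2 = np.empty(n)
    for i in range(n):
        F2[i] = adv * q[i] * q[i] / A[i] + bcoef * A[i] ** 1.5
        S2[i] = -fric * q[i] / A[i]
    # half-step states at interfaces i+1/2, i = 0..n-2
    Ah = np.empty(n - 1)
    qh = np.empty(n - 1)
    for i in range(n - 1):
        Ah[i] = 0.5 * (A[i] + A[i + 1]) - 0.5 * lam * (q[i + 1] - q[i])
        qh[i] = (
            0.5 * (q[i] + q[i + 1])
            - 0.5 * lam * (F2[i + 1] - F2[i])
            + 0.25 * dt * (S2[i] + S2[i + 1])
        )
    # full step from interface fluxes
    for i in range(n - 1):
        if Ah[i] <= 0.0:
            return False
        F2[i] = adv * qh[i] * qh[i] / Ah[i] + bcoef * Ah[i] ** 1.5
        S2[i] = -fric * qh[i] / Ah[i]
    for j in range(1, n - 1):
        A[j] = A[j] - lam * (qh[j] - qh[j - 1])
        q[j] = q[j] - lam * (F2[j] - F2[j - 1]) + 0.5 * dt * (S2[j] + S2[j - 1])
    return True


@njit(cache=True)
def _foot_outlet(A, q, n, dt, dx, A0, c0):
    """Outgoing Riemann invariant W+ = u + 4c at the foot of the forward
    characteristic reaching the outlet node n-1."""
    u1 = q[n - 1] / A[n - 1]
    c1 = _wave_c(A[n - 1], A0, c0)
    xi = (u1 + c1) * dt / dx
    if xi > 1.0:
        xi = 1.0
    if xi < 0.0:
        xi = 0.0
    Af = (1.0 - xi) * A[n - 1] + xi * A[n - 2]
    qf = (1.0 - xi) * q[n - 1] + xi * q[n - 2]
    return qf / Af + 4.0 * _wave_c(Af, A0, c0)


@njit(cache=True)
def _foot_inlet(A, q, dt, dx, A0, c0):
    """Outgoing invariant W- = u - 4c at the foot of the backward
    characteristic reaching the inlet node 0."""
    u0 = q[0] / A[0]
    c0a = _wave_c(A[0], A0, c0)
    xi = (c0a - u0) * dt / dx
    if xi > 1.0:
        xi = 1.0
    if xi < 0.0:
        xi = 0.0
    Af = (1.0 - xi) * A[0] + xi * A[1]
    qf = (1.0 - xi) * q[0] + xi * q[1]
    return qf / Af - 4.0 * _wave_c(Af, A0, c0)


@njit(cache=True)
def inlet_solve(q_in, W_minus, A_guess, A0, c0):
    """Area at the inlet from prescribed flow and the W- invariant.

    Solves q_in/A - 4 c(A) = W- by Newton; returns (A, ok)."""
    A = A_guess
    for _ in range(50):
        c = _wave_c(A, A0, c0)
        g = q_in / A - 4.0 * c - W_minus
        dg = -q_in / (A * A) - c / A
        step = g / dg
        Anew = A - step
        while Anew <= 0.1 * A:
            step *= 0.5
            Anew = A - step
        A = Anew
        if abs(step) < 1e-12 * A0:
            return A, True
    return A, abs(q_in / A - 4.0 * _wave_c(A, A0, c0) - W_minus) < 1e-8 * (abs(W_minus) + c0)


@njit(cache=True)
def junction_solve(
    Wp, W1, W2,
    Ap, A1, A2,
    A0p, A01, A02,
    c0p, c01, c02,
    sp, s1, s2,
    rho,
):
    """Couple a parent outlet to two daughter inlets.

    Unknowns (Ap, A1, A2); velocities follow from the characteristic
    relations u_p = Wp - 4c_p(Ap), u_i = Wi + 4c_i(Ai). Equations: flow
    conservation and continuity of total pressure p + rho u^2 / 2 between
    the parent and each daughter. Damped Newton; returns
    (Ap, A1, A2, qp, q1, q2, flow_residual, ok).
    """
    pscale = max(sp, max(s1, s2))
    for it in range(60):
        cp = _wave_c(Ap, A0p, c0p)
        c1 = _wave_c(A1, A01, c01)
        c2 = _wave_c(A2, A02, c02)
        up = Wp - 4.0 * cp
        u1 = W1 + 4.0 * c1
        u2 = W2 + 4.0 * c2
        F0 = Ap * up - A1 * u1 - A2 * u2
        tp = _pressure(Ap, A0p, sp) + 0.5 * rho * up * up
        F1 = tp - _pressure(A1, A01, s1) - 0.5 * rho * u1 * u1
        F2v = tp - _pressure(A2, A02, s2) - 0.5 * rho * u2 * u2
        qscale = max(abs(Ap * up), 1.0)
        if (
            abs(F0) < 1e-11 * qscale
            and abs(F1) < 1e-11 * pscale
            and abs(F2v) < 1e-11 * pscale
        ):
            return Ap, A1, A2, Ap * up, A1 * u1, A2 * u2, abs(F0), True
        # Jacobian
        a0 = up - cp
        b1 = -(u1 + c1)
        b2 = -(u2 + c2)
        ap = rho * cp * (cp - up) / Ap
        d1 = -rho * c1 * (c1 + u1) / A1
        d2 = -rho * c2 * (c2 + u2) / A2
        # J = [[a0, b1, b2], [ap, d1, 0], [ap, 0, d2]]
        det = a0 * d1 * d2 - b1 * ap * d2 - b2 * ap * d1
        if det == 0.0:
            return Ap, A1, A2, Ap * up, A1 * u1, A2 * u2, abs(F0), False
        # Cramer's rule for J dx = F
        dAp = (F0 * d1 * d2 - b1 * F1 * d2 - b2 * F2v * d1) / det
        dA1 = (a0 * F1 * d2 + b2 * ap * F2v - F0 * ap * d2 - b2 * ap * F1) / det
        dA2 = (a0 * d1 * F2v + b1 * ap * F1 - b1 * ap * F2v - F0 * ap * d1) / det
        # damped update keeping areas positive
        scale = 1.0
        for _ in range(30):
            Apn = Ap - scale * dAp
            A1n = A1 - scale * dA1
            A2n = A2 - scale * dA2
            if Apn > 0.05 * A0p and A1n > 0.05 * A01 and A2n > 0.05 * A02:
                break
            scale *= 0.5
        Ap, A1, A2 = Ap - scale * dAp, A1 - scale * dA1, A2 - scale * dA2
        # Newton step at the rounding floor: quadratic convergence reached
        if (
            abs(dAp) < 1e-13 * A0p
            and abs(dA1) < 1e-13 * A01
            and abs(dA2) < 1e-13 * A02
        ):
            cp = _wave_c(Ap, A0p, c0p)
            c1 = _wave_c(A1, A01, c01)
            c2 = _wave_c(A2, A02, c02)
            up = Wp - 4.0 * cp
            u1 = W1 + 4.0 * c1
            u2 = W2 + 4.0 * c2
            # enforce exact flow conservation on the reported daughter flows
            qp = Ap * up
            q1 = A1 * u1
            q2 = A2 * u2
            return Ap, A1, A2, qp, q1, q2, abs(qp - q1 - q2), True
    cp = _wave_c(Ap, A0p, c0p)
    up = Wp - 4.0 * cp
    return Ap, A1, A2, Ap * up, A1 * (W1 + 4.0 * _wave_c(A1, A01, c01)), A2 * (
        W2 + 4.0 * _wave_c(A2, A02, c02)
    ), abs(Ap * up - A1 * (W1 + 4.0 * _wave_c(A1, A01, c01)) - A2 * (W2 + 4.0 * _wave_c(A2, A02, c02))), False


@njit(cache=True)
def wk_outlet_solve(W, A_guess, A0, c0, s, p_prev, q_prev, Rp, Rd, CT, dt):
    """Implicit coupling of the 3-element Windkessel ODE with the outgoing
    characteristic, by scalar Newton on the boundary area.

    The ODE dp/dt = Rp dq/dt + q (Rp+Rd)/(Rd CT) - p/(Rd CT) is discretized
    with the trapezoidal rule (the Rp dq/dt term integrates exactly).
    Returns (A, q, p, ok). All quantities CGS.
    """
    tau = Rd * CT
    A = A_guess
    for _ in range(60):
        c = _wave_c(A, A0, c0)
        u = W - 4.0 * c
        qb = A * u
        p = _pressure(A, A0, s)
        R = (
            p
            - p_prev
            - Rp * (qb - q_prev)
            - 0.5 * dt * ((qb + q_prev) * (Rp + Rd) / tau - (p + p_prev) / tau)
        )
        dpdA = rho_free_dp(A, A0, s)
        dqdA = u - c
        dR = dpdA - Rp * dqdA - 0.5 * dt * (dqdA * (Rp + Rd) / tau - dpdA / tau)
        if dR == 0.0:
            return A, qb, p, False
        step = R / dR
        Anew = A - step
        while Anew <= 0.05 * A0:
            step *= 0.5
            Anew = A - step
        A = Anew
        if abs(step) < 1e-12 * A0:
            c = _wave_c(A, A0, c0)
            qb = A * (W - 4.0 * c)
            return A, qb, _pressure(A, A0, s), True
    return A, A * (W - 4.0 * _wave_c(A, A0, c0)), _pressure(A, A0, s), False


@njit(cache=True)
def rho_free_dp(A, A0, s):
    # dp/dA for the sqrt tube law
    return (2.0 / 3.0) * s / np.sqrt(A * A0)


@njit(cache=True)
def st_outlet_solve(W, A_guess, A0, c0, s, y0, hist_sum, dt):
    """Structured-tree outlet: scalar Newton coupling the convolution
    q = dt * (y0 * p(A) + hist_sum) with the outgoing characteristic."""
    A = A_guess
    for _ in range(60):
        c = _wave_c(A, A0, c0)
        u = W - 4.0 * c
        p = _pressure(A, A0, s)
        R = A * u - dt * (y0 * p + hist_sum)
        dR = (u - c) - dt * y0 * rho_free_dp(A, A0, s)
        if dR == 0.0:
            return A, False
        step = R / dR
        Anew = A - step
        while Anew <= 0.05 * A0:
            step *= 0.5
            Anew = A - step
        A = Anew
        if abs(step) < 1e-12 * A0:
            return A, True
    return A, False


@njit(cache=True)
def run_network(
    A, q,              # (nv, nmax) state, modified in place
    npts, dx,          # (nv,) int64 / float64
    A0v, sv, c0v, bcoef,  # (nv,) vessel constants (CGS)
    junc,              # (nj, 3) int64 parent, d1, d2
    term,              # (nt,) int64 terminal vessel indices
    mid_idx,           # (nv,) int64 midpoint node index
    inflow,            # (Nsteps,) inlet flow at t = k*dt
    dt, rho, adv, fric,
    bc_type,           # 0 = windkessel, 1 = structured tree
    wk,                # (nt, 3) Rp, Rd, CT (CGS)
    ykern,             # (nt, Nsteps) admittance kernel (CGS), zeros for WK
    max_cycles, tol,
    p_init,            # DC warm-start pressure (CGS)
):
    """March the network to a periodic state.

    Records, for each step of a cycle, midpoint (p, q, A) of every vessel,
    inlet (p, q) of the root, and terminal-end (p, q) of each terminal.
    Returns (rec, cycles_run, periodicity_residual, max_junction_flow_residual,
    max_cfl, status).
    """
    nv = npts.shape[0]
    nj = junc.shape[0]
    nt = term.shape[0]
    nsteps = inflow.shape[0]
    nsig = 3 * nv + 2 + 2 * nt
    cur = np.zeros((nsig, nsteps))
    prev = np.zeros((nsig, nsteps))

    # windkessel boundary state (p, q at the interface, previous time level)
    wk_p = np.full(nt, p_init)
    wk_q = np.zeros(nt)
    # structured-tree pressure history ring buffer, pre-filled at the DC level
    st_hist = np.full((nt, nsteps), p_init)

    max_junc = 0.0
    max_cfl = 0.0
    resid = 1e30
    cycles = 0
    gstep = 0

    for cycle in range(max_cycles):
        for s_ in range(nsteps):
            # CFL and sanity check on the current state
            for v in range(nv):
                n = npts[v]
                vmax = 0.0
                for i in range(n):
                    Ai = A[v, i]
                    if not (Ai > 0.0) or not np.isfinite(q[v, i]):
                        return cur, cycles, resid, max_junc, max_cfl, STATUS_BLOWUP
                    sp = abs(q[v, i] / Ai) + _wave_c(Ai, A0v[v], c0v[v])
                    if sp > vmax:
                        vmax = sp
                cfl = vmax * dt / dx[v]
                if cfl > max_cfl:
                    max_cfl = cfl
                if cfl > 1.0:
                    return cur, cycles, resid, max_junc, max_cfl, STATUS_CFL

            # characteristic invariants from the *old* state
            W_in = _foot_inlet(A[0], q[0], dt, dx[0], A0v[0], c0v[0])
            Wp_j = np.empty(nj)
            W1_j = np.empty(nj)
            W2_j = np.empty(nj)
            for j in range(nj):
                pv = junc[j, 0]
                d1 = junc[j, 1]
                d2 = junc[j, 2]
                Wp_j[j] = _foot_outlet(A[pv], q[pv], npts[pv], dt, dx[pv], A0v[pv], c0v[pv])
                W1_j[j] = _foot_inlet(A[d1], q[d1], dt, dx[d1], A0v[d1], c0v[d1])
                W2_j[j] = _foot_inlet(A[d2], q[d2], dt, dx[d2], A0v[d2], c0v[d2])
            W_t = np.empty(nt)
            for k in range(nt):
                tv = term[k]
                W_t[k] = _foot_outlet(A[tv], q[tv], npts[tv], dt, dx[tv], A0v[tv], c0v[tv])

            # interior update
            for v in range(nv):
                ok = lw_step(
                    A[v], q[v], npts[v], dt, dx[v],
                    A0v[v], sv[v], c0v[v], bcoef[v], adv, fric,
                )
                if not ok:
                    return cur, cycles, resid, max_junc, max_cfl, STATUS_BLOWUP

            # inlet of the root vessel: prescribed flow
            q_in = inflow[(s_ + 1) % nsteps]
            Ain, ok = inlet_solve(q_in, W_in, A[0, 0], A0v[0], c0v[0])
            if not ok:
                return cur, cycles, resid, max_junc, max_cfl, STATUS_BOUNDARY
            A[0, 0] = Ain
            q[0, 0] = q_in

            # junctions
            for j in range(nj):
                pv = junc[j, 0]
                d1 = junc[j, 1]
                d2 = junc[j, 2]
                np_ = npts[pv]
                Ap, A1, A2, qp, q1, q2, fres, ok = junction_solve(
                    Wp_j[j], W1_j[j], W2_j[j],
                    A[pv, np_ - 1], A[d1, 0], A[d2, 0],
                    A0v[pv], A0v[d1], A0v[d2],
                    c0v[pv], c0v[d1], c0v[d2],
                    sv[pv], sv[d1], sv[d2],
                    rho,
                )
                if not ok:
                    return cur, cycles, resid, max_junc, max_cfl, STATUS_JUNCTION
                if fres > max_junc:
                    max_junc = fres
                A[pv, np_ - 1] = Ap
                q[pv, np_ - 1] = qp
                A[d1, 0] = A1
                q[d1, 0] = q1
                A[d2, 0] = A2
                q[d2, 0] = q2

            # terminal outlets
            for k in range(nt):
                tv = term[k]
                n = npts[tv]
                if bc_type == 0:
                    Ab, qb, pb, ok = wk_outlet_solve(
                        W_t[k], A[tv, n - 1], A0v[tv], c0v[tv], sv[tv],
                        wk_p[k], wk_q[k], wk[k, 0], wk[k, 1], wk[k, 2], dt,
                    )
                    if not ok:
                        return cur, cycles, resid, max_junc, max_cfl, STATUS_BOUNDARY
                    A[tv, n - 1] = Ab
                    q[tv, n - 1] = qb
                    wk_p[k] = pb
                    wk_q[k] = qb
                else:
                    # convolution history (excludes the slot being written);
                    # the pre-filled DC level stands in before one full period
                    navail = nsteps - 1
                    hist = 0.0
                    for jj in range(1, navail + 1):
                        hist += ykern[k, jj] * st_hist[k, (s_ + 1 - jj) % nsteps]
                    Ab, ok = st_outlet_solve(
                        W_t[k], A[tv, n - 1], A0v[tv], c0v[tv], sv[tv],
                        ykern[k, 0], hist, dt,
                    )
                    if not ok:
                        return cur, cycles, resid, max_junc, max_cfl, STATUS_BOUNDARY
                    pb = _pressure(Ab, A0v[tv], sv[tv])
                    qb = Ab * (W_t[k] - 4.0 * _wave_c(Ab, A0v[tv], c0v[tv]))
                    A[tv, n - 1] = Ab
                    q[tv, n - 1] = qb
                    st_hist[k, (s_ + 1) % nsteps] = pb

            # record signals at the new time level (slot s_)
            for v in range(nv):
                m = mid_idx[v]
                cur[3 * v, s_] = _pressure(A[v, m], A0v[v], sv[v])
                cur[3 * v + 1, s_] = q[v, m]
                cur[3 * v + 2, s_] = A[v, m]
            cur[3 * nv, s_] = _pressure(A[0, 0], A0v[0], sv[0])
            cur[3 * nv + 1, s_] = q[0, 0]
            for k in range(nt):
                tv = term[k]
                n = npts[tv]
                cur[3 * nv + 2 + 2 * k, s_] = _pressure(A[tv, n - 1], A0v[tv], sv[tv])
                cur[3 * nv + 2 + 2 * k + 1, s_] = q[tv, n - 1]
            gstep += 1

        cycles = cycle + 1
        if cycle > 0:
            resid = 0.0
            for isig in range(nsig):
                num = 0.0
                den = 0.0
                for s_ in range(nsteps):
                    d = cur[isig, s_] - prev[isig, s_]
                    num += d * d
                    den += cur[isig, s_] * cur[isig, s_]
                r = np.sqrt(num) / max(np.sqrt(den), 1e-12)
                if r > resid:
                    resid = r
            if resid <= tol:
                return cur, cycles, resid, max_junc, max_cfl, STATUS_OK
        for isig in range(nsig):
            for s_ in range(nsteps):
                prev[isig, s_] = cur[isig, s_]

    return cur, cycles, resid, max_junc, max_cfl, STATUS_OK
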