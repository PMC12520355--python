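"""Two-step Lax-Wendroff solution of the 1D blood-flow system on a network.

The hyperbolic system

    dA/dt + dq/dx = 0
    dq/dt + d/dx[ (g+2)/(g+1) q^2/A + B(A) ] = -2 pi mu (g+2)/rho * (q/A)

is advanced with the Richtmyer two-step scheme in conservative variables
(A, q); the pressure gradient is folded into the flux antiderivative B(A)
(exact for untapered vessels). The inlet prescribes the flow waveform and
recovers area from the outgoing characteristic; junctions enforce flow
conservation and continuity of total pressure; outlets delegate to the
Windkessel or Structured Tree couplings. Cycles are run until the midpoint
waveforms repeat to a relative L2 tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .physics import (
    MMHG_TO_CGS,
    BloodProperties,
    HemoDomainError,
    ParameterVector,
    VesselNetwork,
    stiffness,
)
from .structured_tree import StructuredTreeParams, admittance_kernel, root_impedance

__all__ = [
    "GridSpec",
    "HemoSolution",
    "SolverError",
    "BlowupError",
    "CFLError",
    "flux_and_source",
    "lax_wendroff_step",
    "lax_wendroff_periodic",
    "junction_solve",
    "simulate",
]


class SolverError(RuntimeError):
    """Base class for time-stepping failures."""


class BlowupError(SolverError):
    pass


class CFLError(SolverError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Discretization and convergence controls.

    n_points spatial nodes per vessel (dx = L/(n_points-1)); the time step is
    set from the target CFL number and checked against 1 at every step.
    """

    n_points: int = 32
    cfl: float = 0.5
    period: float = 0.85
    max_cycles: int = 8
    periodicity_tol: float = 1e-3
    n_time_out: int = 256

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise HemoDomainError("need at least 8 points per vessel")
        if not (0 < self.cfl <= 1):
            raise HemoDomainError("target CFL must be in (0, 1]")
        if self.period <= 0:
            raise HemoDomainError("period must be positive")


@dataclass
class HemoSolution:
    """Midpoint time series over one converged period.

    ``midpoint[vessel]`` maps to arrays 'p' (mmHg), 'q' (mL/s), 'A' (cm^2) of
    length n_time_out; ``inlet`` and ``terminal[vessel]`` hold boundary-node
    (p, q) series used by the DC-consistency diagnostics.
    """

    time: np.ndarray
    midpoint: dict[str, dict[str, np.ndarray]]
    inlet: dict[str, np.ndarray]
    terminal: dict[str, dict[str, np.ndarray]]
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.time}
        for v, sig in self.midpoint.items():
            for k, arr in sig.items():
                cols[f"{k}_{v}"] = arr
        return pd.DataFrame(cols)

    def signal(self, vessel: str, kind: str) -> np.ndarray:
        return self.midpoint[vessel][kind]


def flux_and_source(A, q, props: BloodProperties, stiff_mmHg: float, A0: float):
    """Fluxes and sources of the conservative system (CGS).

    Returns ((F_mass, F_momentum), (S_mass, S_momentum)) with
    F_momentum = (g+2)/(g+1) q^2/A + B(A) and S_momentum the viscous friction.
    """
    A = np.asarray(A, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(A <= 0):
        raise BlowupError("non-positive area in flux evaluation")
    s_cgs = stiff_mmHg * MMHG_TO_CGS
    bcoef = 4.0 * s_cgs / (9.0 * props.density * np.sqrt(A0))
    F1 = q.copy()
    F2 = props.advective_coefficient * q**2 / A + bcoef * A**1.5
    S1 = np.zeros_like(q)
    S2 = -props.friction_coefficient * q / A
    return (F1, F2), (S1, S2)


def _vessel_constants(A0: float, stiff_mmHg: float, props: BloodProperties):
    s_cgs = stiff_mmHg * MMHG_TO_CGS
    c0 = np.sqrt(2.0 * s_cgs / (3.0 * props.density))
    bcoef = 4.0 * s_cgs / (9.0 * props.density * np.sqrt(A0))
    return s_cgs, c0, bcoef


def lax_wendroff_step(A, q, dt: float, dx: float, props: BloodProperties,
                      stiff_mmHg: float, A0: float):
    """One Richtmyer step updating interior nodes; boundary nodes unchanged.

    Aborts on CFL violation or loss of area positivity.
    """
    A = np.array(A, dtype=float)
    q = np.array(q, dtype=float)
    s_cgs, c0, bcoef = _vessel_constants(A0, stiff_mmHg, props)
    cmax = float(np.max(np.abs(q / A) + c0 * (A / A0) ** 0.25))
    if cmax * dt / dx > 1.0:
        raise CFLError(f"CFL {cmax * dt / dx:.3f} > 1")
    ok = _kernels.lw_step(
        A, q, len(A), dt, dx, A0, s_cgs, c0, bcoef,
        props.advective_coefficient, props.friction_coefficient,
    )
    if not ok:
        raise BlowupError("negative area at a half step")
    return A, q


def lax_wendroff_periodic(A, q, n_steps: int, dt: float, dx: float,
                          props: BloodProperties, stiff_mmHg: float, A0: float):
    """March a periodic single-vessel domain (used by convergence studies).

    The physical nodes are A[0..n-1] at x = j dx on a domain of period
    n dx; one ghost node on each side implements the wrap.
    """
    A = np.asarray(A, dtype=float)
    q = np.asarray(q, dtype=float)
    n = len(A)
    Ag = np.empty(n + 2)
    qg = np.empty(n + 2)
    Ag[1:-1], qg[1:-1] = A, q
    s_cgs, c0, bcoef = _vessel_constants(A0, stiff_mmHg, props)
    for _ in range(n_steps):
        Ag[0], qg[0] = Ag[n], qg[n]           # node -1 == node n-1
        Ag[n + 1], qg[n + 1] = Ag[1], qg[1]   # node n == node 0
        ok = _kernels.lw_step(
            Ag, qg, n + 2, dt, dx, A0, s_cgs, c0, bcoef,
            props.advective_coefficient, props.friction_coefficient,
        )
        if not ok:
            raise BlowupError("negative area at a half step")
    return Ag[1:-1].copy(), qg[1:-1].copy()


def junction_solve(W_parent, W_d1, W_d2, A_init, A0s, stiff_mmHg, props: BloodProperties):
    """Couple one parent outlet to two daughter inlets (CGS interface).

    Parameters are triples (parent, d1, d2): initial areas, reference areas,
    stiffnesses in mmHg. Returns (A, q) triples and the flow residual.
    """
    cons = [_vessel_constants(A0s[i], stiff_mmHg[i], props) for i in range(3)]
    Ap, A1, A2, qp, q1, q2, fres, ok = _kernels.junction_solve(
        W_parent, W_d1, W_d2,
        A_init[0], A_init[1], A_init[2],
        A0s[0], A0s[1], A0s[2],
        cons[0][1], cons[1][1], cons[2][1],
        cons[0][0], cons[1][0], cons[2][0],
        props.density,
    )
    if not ok:
        raise SolverError(f"junction Newton failed (flow residual {fres:.3e})")
    return (Ap, A1, A2), (qp, q1, q2), fres


def _order_vessels(network: VesselNetwork) -> list[str]:
    """Root-first breadth-first vessel order."""
    order = [network.root]
    queue = [network.root]
    while queue:
        v = queue.pop(0)
        for d in network[v].daughters:
            order.append(d)
            queue.append(d)
    return order


def simulate(
    network: VesselNetwork,
    theta: ParameterVector,
    inflow,
    grid: GridSpec | None = None,
    props: BloodProperties | None = None,
) -> HemoSolution:
    """Run the network to a periodic state and return midpoint series.

    ``inflow`` is a callable t -> q (mL/s), periodic with ``grid.period``
    (e.g. :class:`pulseuq.fixtures.InflowWaveform`). The outlet boundary
    condition follows ``theta.variant`` ('wk' or 'st').
    """
    grid = grid or GridSpec()
    props = props or BloodProperties()
    wall = theta.wall()

    order = _order_vessels(network)
    nv = len(order)
    idx = {name: i for i, name in enumerate(order)}
    vessels = [network[name] for name in order]

    npts = np.full(nv, grid.n_points, dtype=np.int64)
    dx = np.array([v.length / (grid.n_points - 1) for v in vessels])
    A0v = np.array([v.area for v in vessels])
    s_mmhg = np.array([stiffness(v.radius, wall) for v in vessels])
    sv = s_mmhg * MMHG_TO_CGS
    c0v = np.sqrt(2.0 * sv / (3.0 * props.density))
    bcoef = 4.0 * sv / (9.0 * props.density * np.sqrt(A0v))
    mid_idx = np.array([int(round((grid.n_points - 1) / 2))] * nv, dtype=np.int64)

    junc = np.array(
        [[idx[p], idx[d1], idx[d2]] for p, d1, d2 in network.junctions],
        dtype=np.int64,
    ).reshape(-1, 3)
    term_names = network.terminals
    term = np.array([idx[t] for t in term_names], dtype=np.int64)
    nt = len(term_names)

    # time step from a conservative speed estimate; refined on retry
    t_probe = np.linspace(0.0, grid.period, 512, endpoint=False)
    q_probe = np.asarray([float(inflow(t)) for t in t_probe])
    q_peak = float(np.max(np.abs(q_probe)))
    vmax = 1.15 * (1.2 * float(np.max(c0v)) + q_peak / float(np.min(A0v)))
    dt0 = grid.cfl * float(np.min(dx)) / vmax
    nsteps = int(np.ceil(grid.period / dt0))

    if theta.variant == "wk":
        bc_type = 0
        wk = np.array(
            [
                [theta.values["Rp1"], theta.values["Rd1"], theta.values["CT1"]],
                [theta.values["Rp2"], theta.values["Rd2"], theta.values["CT2"]],
            ]
        )
        wk[:, :2] *= MMHG_TO_CGS
        wk[:, 2] /= MMHG_TO_CGS
        if nt != 2:
            raise HemoDomainError("the Windkessel variant expects 2 terminals")
    elif theta.variant == "st":
        bc_type = 1
        wk = np.zeros((nt, 3))
    else:
        raise HemoDomainError(f"unknown variant {theta.variant!r}")

    status = None
    for attempt in range(3):
        dt = grid.period / nsteps
        t_in = np.arange(nsteps) * dt
        inflow_steps = np.asarray([float(inflow(t)) for t in t_in])

        if bc_type == 1:
            st_params = StructuredTreeParams(
                theta.values["alpha"], theta.values["beta"],
                theta.values["lrr"], theta.values["rmin"],
            )
            omega = 2.0 * np.pi * np.arange(nsteps // 2 + 1) / grid.period
            ykern = np.empty((nt, nsteps))
            dc_admittance = 0.0
            for k, tname in enumerate(term_names):
                spec = root_impedance(
                    network[tname].radius, st_params, omega, props, wall
                )
                ykern[k] = admittance_kernel(spec.Z * MMHG_TO_CGS, nsteps, dt)
                dc_admittance += 1.0 / (spec.dc * MMHG_TO_CGS)
        else:
            ykern = np.zeros((nt, nsteps))
            dc_admittance = sum(1.0 / (wk[k, 0] + wk[k, 1]) for k in range(nt))

        # DC warm start: begin at the mean operating pressure
        co = float(np.mean(inflow_steps))
        p_init = co / dc_admittance
        nmax = int(np.max(npts))
        A = A0v[:, None] * (1.0 + 3.0 * p_init / (4.0 * sv[:, None])) ** 2
        A = np.ascontiguousarray(np.broadcast_to(A, (nv, nmax)).copy())
        q = np.zeros((nv, nmax))

        rec, cycles, resid, junc_res, cfl_max, status = _kernels.run_network(
            A, q, npts, dx, A0v, sv, c0v, bcoef,
            junc, term, mid_idx, inflow_steps,
            dt, props.density,
            props.advective_coefficient, props.friction_coefficient,
            bc_type, wk, ykern, grid.max_cycles, grid.periodicity_tol,
            p_init,
        )
        if status == _kernels.STATUS_OK:
            break
        nsteps *= 2  # halve dt and retry
    else:
        pass

    if status == _kernels.STATUS_CFL:
        raise CFLError(f"CFL violation persisted (max CFL {cfl_max:.3f})")
    if status == _kernels.STATUS_BLOWUP:
        raise BlowupError("solution blew up (non-finite or non-positive area)")
    if status in (_kernels.STATUS_JUNCTION, _kernels.STATUS_BOUNDARY):
        raise SolverError("boundary/junction Newton failed to converge")

    periodic = resid <= grid.periodicity_tol
    if not periodic:
        warnings.warn(
            f"simulation did not reach a periodic state "
            f"(residual {resid:.2e} after {cycles} cycles)",
            RuntimeWarning,
        )

    # resample the recorded cycle (slot s <-> time (s+1) dt) onto Nt points
    t_rec = (np.arange(nsteps) + 1) * dt
    t_out = np.arange(grid.n_time_out) * grid.period / grid.n_time_out
    t_full = np.concatenate(([0.0], t_rec))

    def _resample(row):
        vals = np.concatenate(([row[-1]], row))  # value at t=0 is value at t=T
        return np.interp(t_out, t_full, vals)

    midpoint: dict[str, dict[str, np.ndarray]] = {}
    for i, name in enumerate(order):
        midpoint[name] = {
            "p": _resample(rec[3 * i]) / MMHG_TO_CGS,
            "q": _resample(rec[3 * i + 1]),
            "A": _resample(rec[3 * i + 2]),
        }
    inlet = {
        "p": _resample(rec[3 * nv]) / MMHG_TO_CGS,
        "q": _resample(rec[3 * nv + 1]),
    }
    terminal: dict[str, dict[str, np.ndarray]] = {}
    for k, tname in enumerate(term_names):
        terminal[tname] = {
            "p": _resample(rec[3 * nv + 2 + 2 * k]) / MMHG_TO_CGS,
            "q": _resample(rec[3 * nv + 2 + 2 * k + 1]),
        }

    meta = {
        "cycles": int(cycles),
        "periodicity_residual": float(resid),
        "periodic": bool(periodic),
        "max_junction_flow_residual": float(junc_res),
        "max_cfl": float(cfl_max),
        "dt": float(dt),
        "n_steps_per_cycle": int(nsteps),
        "variant": theta.variant,
    }
    return HemoSolution(time=t_out, midpoint=midpoint, inlet=inlet,
                        terminal=terminal, meta=meta)
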