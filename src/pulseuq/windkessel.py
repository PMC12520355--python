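"""Three-element Windkessel outflow boundary condition.

The distal vasculature beyond each terminal vessel is lumped into a proximal
resistance Rp, a distal resistance Rd, and a total compliance CT, governed by

    dp/dt = Rp dq/dt + q (Rp + Rd) / (Rd CT) - p / (Rd CT).

Steady state gives p = q (Rp + Rd): the DC input impedance is Rp + Rd, and
the complex input impedance is Z(w) = Rp + Rd / (1 + i w Rd CT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physics import MMHG_TO_CGS, HemoDomainError
from ._kernels import wk_outlet_solve

__all__ = [
    "WindkesselParams",
    "wk_rhs",
    "integrate_windkessel",
    "input_impedance",
    "dc_impedance",
    "wk_outlet_step",
]


@dataclass(frozen=True)
class WindkesselParams:
    """One terminal's Windkessel elements (mmHg s/mL, mL/mmHg)."""

    Rp: float
    Rd: float
    CT: float

    def __post_init__(self) -> None:
        if self.Rp <= 0 or self.Rd <= 0 or self.CT <= 0:
            raise HemoDomainError("Windkessel elements must be strictly positive")


def wk_rhs(p: float, q: float, dqdt: float, params: WindkesselParams) -> float:
    """Right-hand side dp/dt of the Windkessel ODE (mmHg/s)."""
    tau = params.Rd * params.CT
    return params.Rp * dqdt + q * (params.Rp + params.Rd) / tau - p / tau


def integrate_windkessel(q, dt: float, params: WindkesselParams, p0: float = 0.0):
    """Trapezoidal integration of the Windkessel ODE for a given flow series.

    The Rp dq/dt term integrates exactly to Rp (q_{n+1} - q_n); the remaining
    terms use the trapezoidal rule (A-stable, second order). Returns p(t) with
    p[0] = p0. Units follow the inputs (mmHg, mL/s, s).
    """
    q = np.asarray(q, dtype=float)
    tau = params.Rd * params.CT
    Rsum = params.Rp + params.Rd
    p = np.empty_like(q)
    p[0] = p0
    a = 0.5 * dt / tau
    for n in range(len(q) - 1):
        rhs = (
            p[n]
            + params.Rp * (q[n + 1] - q[n])
            + a * ((q[n] + q[n + 1]) * Rsum - p[n])
        )
        p[n + 1] = rhs / (1.0 + a)
    return p


def input_impedance(omega, params: WindkesselParams):
    """Complex input impedance Z(omega) = Rp + Rd / (1 + i omega Rd CT)."""
    omega = np.asarray(omega, dtype=float)
    return params.Rp + params.Rd / (1.0 + 1j * omega * params.Rd * params.CT)


def dc_impedance(params: WindkesselParams) -> float:
    """Zero-frequency input impedance Rp + Rd."""
    return params.Rp + params.Rd


def wk_outlet_step(
    W_plus: float,
    A_guess: float,
    A0: float,
    stiff_mmHg: float,
    params: WindkesselParams,
    p_prev_mmHg: float,
    q_prev: float,
    dt: float,
    density: float = 1.055,
):
    """One implicit boundary step coupling the ODE to the vessel end.

    ``W_plus`` is the outgoing Riemann invariant u + 4c (cm/s) carried to the
    boundary node by the forward characteristic. Returns (A, q, p_mmHg).
    """
    s_cgs = stiff_mmHg * MMHG_TO_CGS
    c0 = np.sqrt(2.0 * s_cgs / (3.0 * density))
    A, qb, p_cgs, ok = wk_outlet_solve(
        W_plus, A_guess, A0, c0, s_cgs,
        p_prev_mmHg * MMHG_TO_CGS, q_prev,
        params.Rp * MMHG_TO_CGS, params.Rd * MMHG_TO_CGS, params.CT / MMHG_TO_CGS,
        dt,
    )
    if not ok:
        raise RuntimeError("Windkessel boundary Newton failed to converge")
    return float(A), float(qb), float(p_cgs / MMHG_TO_CGS)
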