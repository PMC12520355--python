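"""Variance-based Sobol' sensitivity indices from PCE coefficients.

With an orthonormal polynomial basis, the variance of each PCA score is the
sum of its squared non-constant coefficients, and first/total-order Sobol'
indices per principal component are coefficient sums over the corresponding
multi-index subsets. Pointwise-in-time indices for the reconstructed signal
follow from the component indices plus cross-component covariance terms:

    S_iY(t) = [ sum_q S_iq Var[c_q] eta_q(t)^2
                + 2 sum_{q<q*} Cov_i^{qq*} eta_q eta_q* ] / Var[Y](t)

with Cov_i^{qq*} = sum_{k in A_Si} z_qk z_q*k, and the total-order index via
the complement 1 - Var[E[Y|theta_~i]]/Var[Y] where the conditional keeps
exactly the multi-indices with no dependence on dimension i. The denominator
Var[Y](t) uses the same coefficient algebra, so the indices are internally
consistent; truncation of the PCA basis can push pointwise totals slightly
outside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pce import PCEModel

__all__ = ["SobolResult", "component_sobol", "pointwise_sobol", "sensitivity_ranking"]


@dataclass
class SobolResult:
    """Component-level and pointwise-in-time Sobol' indices for one signal."""

    signal: str
    param_names: tuple[str, ...]
    S_comp: np.ndarray    # (P, M) first-order per principal component
    ST_comp: np.ndarray   # (P, M) total-order per principal component
    S_time: np.ndarray    # (P, Nt) pointwise first-order
    ST_time: np.ndarray   # (P, Nt) pointwise total-order
    var_time: np.ndarray  # (Nt,) coefficient-implied Var[Y](t)


def component_sobol(model: PCEModel, q: int | None = None):
    """First/total-order indices of the PCA scores, from coefficients.

    Returns (S, ST) of shape (P, M), or the (P,) pair for one component when
    ``q`` is given. Components with zero variance yield NaN.
    """
    coef = model.coef
    P = model.mindex.P
    M = model.M
    nonconst = model.mindex.indices.sum(axis=1) > 0
    var_q = np.sum(coef[nonconst] ** 2, axis=0)  # (M,)
    # components whose variance is at the least-squares rounding floor are
    # constant in the prior box: their indices are undefined
    floor = (1e-12 * (1.0 + np.abs(coef[~nonconst]).sum(axis=0))) ** 2
    live = var_q > floor
    S = np.empty((P, M))
    ST = np.empty((P, M))
    for i in range(P):
        ks = model.mindex.first_order_set(i)
        kt = model.mindex.total_order_set(i)
        with np.errstate(divide="ignore", invalid="ignore"):
            S[i] = np.where(live, np.sum(coef[ks] ** 2, axis=0) / var_q, np.nan)
            ST[i] = np.where(live, np.sum(coef[kt] ** 2, axis=0) / var_q, np.nan)
    if q is not None:
        return S[:, q], ST[:, q]
    return S, ST


def pointwise_sobol(model: PCEModel, basis=None) -> SobolResult:
    """Pointwise-in-time indices reconstructed from the component algebra.

    Includes both the per-component variance terms and the q < q* covariance
    cross-terms. Var[Y](t) = 0 at a time point yields NaN there.
    """
    basis = basis if basis is not None else model.basis
    if basis is None:
        raise ValueError("a PCA basis is required for pointwise indices")
    coef = model.coef                      # (K, M)
    eta = basis.components                 # (Nt, M)
    if eta.shape[1] != model.M:
        raise ValueError("model and basis disagree on M")
    P = model.mindex.P
    nonconst = model.mindex.indices.sum(axis=1) > 0

    # coefficient-implied score covariance (diagonal = Var[c_q])
    C_full = coef[nonconst].T @ coef[nonconst]            # (M, M)
    var_t = np.einsum("tq,qr,tr->t", eta, C_full, eta)    # (Nt,)

    S_time = np.empty((P, eta.shape[0]))
    ST_time = np.empty((P, eta.shape[0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(P):
            ks = model.mindex.first_order_set(i)
            kc = model.mindex.complement_set(i)
            Ci = coef[ks].T @ coef[ks]                    # Var/Cov of E[c_q | theta_i]
            Cc = coef[kc].T @ coef[kc]                    # of E[c_q | theta_~i]
            num_i = np.einsum("tq,qr,tr->t", eta, Ci, eta)
            num_c = np.einsum("tq,qr,tr->t", eta, Cc, eta)
            S_time[i] = np.where(var_t > 0, num_i / var_t, np.nan)
            ST_time[i] = np.where(var_t > 0, 1.0 - num_c / var_t, np.nan)

    S_comp, ST_comp = component_sobol(model)
    return SobolResult(
        signal=model.signal,
        param_names=model.prior.names,
        S_comp=S_comp,
        ST_comp=ST_comp,
        S_time=S_time,
        ST_time=ST_time,
        var_time=var_t,
    )


def sensitivity_ranking(result: SobolResult, threshold: float = 0.01):
    """Rank parameters by max-over-time total-order index.

    Returns a list of (name, max_ST, non_influential) sorted most to least
    influential; parameters whose max ST falls below ``threshold`` are
    flagged. Cutoffs of this kind are heuristic and configurable.
    """
    max_st = np.nanmax(result.ST_time, axis=1)
    order = np.argsort(-max_st)
    return [
        (result.param_names[i], float(max_st[i]), bool(max_st[i] < threshold))
        for i in order
    ]
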