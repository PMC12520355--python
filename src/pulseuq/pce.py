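"""Legendre polynomial-chaos expansion over PCA scores.

Parameters with uniform priors are mapped affinely to xi in [-1, 1]^P; the
surrogate is a total-degree-m expansion

    c_q(theta) = sum_k z_qk phi_k(xi),    phi_k(xi) = prod_i psi_{a_ki}(xi_i),

fit per score column by ordinary least squares on a training design. The
univariate basis used internally is the *orthonormal* Legendre family under
the uniform probability density on [-1, 1] (psi_j = sqrt(2j+1) P_j, unit
variance), so every normalization factor is 1 and the Sobol' formulas reduce
to sums of squared coefficients. The classical L2 norm gamma_j = 2/(2j+1) of
the unnormalized family is exposed through :func:`legendre_norm` for
reference; Sobol' ratios are identical under either convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

__all__ = [
    "PriorSpec",
    "MultiIndexSet",
    "PCEModel",
    "legendre_1d",
    "legendre_norm",
    "multi_index_set",
    "design_matrix",
    "fit_ols",
    "predict_scores",
    "predict_timeseries",
    "msre",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors and the affine map to [-1, 1]^P."""

    names: tuple[str, ...]
    bounds: np.ndarray  # (P, 2)

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float).reshape(-1, 2)
        if np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("every prior must satisfy lo < hi")
        if len(self.names) != len(b):
            raise ValueError("names/bounds length mismatch")
        object.__setattr__(self, "bounds", b)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def P(self) -> int:
        return len(self.names)

    def to_unit(self, theta) -> np.ndarray:
        """theta -> xi in [-1, 1]^P."""
        theta = np.asarray(theta, dtype=float)
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return 2.0 * (theta - lo) / (hi - lo) - 1.0

    def from_unit(self, xi) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return lo + 0.5 * (xi + 1.0) * (hi - lo)

    def contains(self, theta, tol: float = 1e-12) -> bool:
        xi = self.to_unit(theta)
        return bool(np.all(np.abs(xi) <= 1.0 + tol))

    @property
    def midpoint(self) -> np.ndarray:
        return self.bounds.mean(axis=1)


def legendre_1d(j: int, x):
    """Legendre polynomial P_j(x) on [-1, 1] by the three-term recurrence."""
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValueError("Legendre argument outside [-1, 1]")
    if j < 0:
        raise ValueError("degree must be >= 0")
    p_prev = np.ones_like(x)
    if j == 0:
        return p_prev if p_prev.ndim else float(p_prev)
    p = x.copy()
    for n in range(1, j):
        p, p_prev = ((2 * n + 1) * x * p - n * p_prev) / (n + 1), p
    return p if p.ndim else float(p)


def legendre_norm(j: int) -> float:
    """L2 norm gamma_j = int_{-1}^{1} P_j(x)^2 dx = 2 / (2j + 1)."""
    if j < 0:
        raise ValueError("degree must be >= 0")
    return 2.0 / (2 * j + 1)


def _legendre_table(x, m: int) -> np.ndarray:
    """Orthonormal Legendre values: table[n, j] = sqrt(2j+1) P_j(x_n)."""
    x = np.asarray(x, dtype=float)
    tab = np.empty((len(x), m + 1))
    tab[:, 0] = 1.0
    if m >= 1:
        tab[:, 1] = x
    for n in range(1, m):
        tab[:, n + 1] = ((2 * n + 1) * x * tab[:, n] - n * tab[:, n - 1]) / (n + 1)
    tab *= np.sqrt(2.0 * np.arange(m + 1) + 1.0)
    return tab


@dataclass(frozen=True)
class MultiIndexSet:
    """Total-degree multi-index set {a in N^P : sum a_i <= m}."""

    P: int
    degree: int
    indices: np.ndarray = field(default=None)  # (K, P), lexicographic

    def __post_init__(self) -> None:
        if self.indices is None:
            object.__setattr__(self, "indices", _total_degree(self.P, self.degree))
        K = comb(self.P + self.degree, self.degree)
        if self.indices.shape != (K, self.P):
            raise ValueError("multi-index cardinality mismatch")

    def __len__(self) -> int:
        return self.indices.shape[0]

    def first_order_set(self, i: int) -> np.ndarray:
        """A_Si: indices active only in dimension i (excludes index 0)."""
        a = self.indices
        others = np.delete(np.arange(self.P), i)
        return np.flatnonzero((a[:, i] > 0) & (a[:, others].sum(axis=1) == 0))

    def total_order_set(self, i: int) -> np.ndarray:
        """A_STi: indices active in dimension i."""
        return np.flatnonzero(self.indices[:, i] > 0)

    def complement_set(self, i: int) -> np.ndarray:
        """Non-constant indices with no dependence on dimension i."""
        a = self.indices
        return np.flatnonzero((a[:, i] == 0) & (a.sum(axis=1) > 0))


def _total_degree(P: int, m: int) -> np.ndarray:
    if P < 1 or m < 0:
        raise ValueError("need P >= 1 and m >= 0")
    out: list[tuple[int, ...]] = []

    def rec(prefix: tuple[int, ...], remaining: int, budget: int) -> None:
        if remaining == 0:
            out.append(prefix)
            return
        for a in range(budget + 1):
            rec(prefix + (a,), remaining - 1, budget - a)

    rec((), P, m)
    arr = np.array(sorted(out), dtype=np.int64)
    return arr


def multi_index_set(P: int, m: int) -> MultiIndexSet:
    """Lexicographically ordered total-degree index set, |set| = C(P+m, m)."""
    return MultiIndexSet(P=P, degree=m)


def design_matrix(xi, mindex: MultiIndexSet) -> np.ndarray:
    """Evaluate the orthonormal tensor basis at xi (N x P) -> Phi (N x K)."""
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    if xi.shape[1] != mindex.P:
        raise ValueError("xi dimension mismatch")
    m = mindex.degree
    tables = [_legendre_table(xi[:, i], m) for i in range(mindex.P)]
    K = len(mindex)
    Phi = np.ones((xi.shape[0], K))
    for i in range(mindex.P):
        Phi *= tables[i][:, mindex.indices[:, i]]
    return Phi


@dataclass
class PCEModel:
    """Fitted PCE over the PCA scores of one output signal."""

    mindex: MultiIndexSet
    coef: np.ndarray          # (K, M)
    prior: PriorSpec
    basis: "object" = None    # attached PCABasis (optional for score-only use)
    signal: str = ""
    condition_number: float = np.nan
    train_r2: np.ndarray = None   # (M,)
    n_train: int = 0

    @property
    def M(self) -> int:
        return self.coef.shape[1]


def fit_ols(theta_train, scores, prior: PriorSpec, mindex: MultiIndexSet,
            basis=None, signal: str = "") -> PCEModel:
    """Least-squares PCE fit of the score matrix (N x M).

    Solved per score column with a rank-revealing SVD factorization (never
    the literal normal-equations inverse); reports the design-matrix
    condition number and per-component training R^2.
    """
    theta_train = np.atleast_2d(np.asarray(theta_train, dtype=float))
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    K = len(mindex)
    n = theta_train.shape[0]
    if n < K:
        raise ValueError(
            f"under-determined OLS: {n} samples < {K} basis terms; "
            "lower the degree or add samples"
        )
    xi = prior.to_unit(theta_train)
    if np.any(np.abs(xi) > 1.0 + 1e-9):
        raise ValueError("training samples outside the prior box")
    Phi = design_matrix(xi, mindex)
    coef, _, rank, sv = np.linalg.lstsq(Phi, scores, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if rank < K:
        raise ValueError(f"rank-deficient design (rank {rank} < {K}, cond {cond:.2e})")
    resid = scores - Phi @ coef
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum((scores - scores.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return PCEModel(
        mindex=mindex, coef=coef, prior=prior, basis=basis, signal=signal,
        condition_number=cond, train_r2=r2, n_train=n,
    )


def predict_scores(model: PCEModel, theta, check_bounds: bool = True) -> np.ndarray:
    """PCA-score prediction at theta (single vector or batch)."""
    theta = np.asarray(theta, dtype=float)
    single = theta.ndim == 1
    theta = np.atleast_2d(theta)
    if check_bounds and not model.prior.contains(theta):
        import warnings

        warnings.warn("prediction outside the prior box (extrapolation)", RuntimeWarning)
    Phi = design_matrix(model.prior.to_unit(theta), model.mindex)
    s = Phi @ model.coef
    return s[0] if single else s


def predict_timeseries(model: PCEModel, theta, check_bounds: bool = True) -> np.ndarray:
    """Time-domain prediction mu + sum_qk z_qk phi_k(theta) eta_q."""
    if model.basis is None:
        raise ValueError("model has no attached PCA basis")
    from .pca import inverse_transform

    theta = np.asarray(theta, dtype=float)
    single = theta.ndim == 1
    s = predict_scores(model, theta, check_bounds=check_bounds)
    out = inverse_transform(np.atleast_2d(s), model.basis)
    return out[0] if single else out


def msre(y_true, y_pred) -> np.ndarray:
    """Per-sample mean square relative error, max-normalized.

    e_i = mean_t [ (Y_i(t) - Yhat_i(t)) / max_t Y_i(t) ]^2. Returns the
    (N,) vector; report mean or median over samples as needed.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    ymax = y_true.max(axis=1)
    if np.any(ymax == 0):
        raise ValueError("signal with zero maximum; MSRE undefined")
    r = (y_true - y_pred) / ymax[:, None]
    return np.mean(r**2, axis=1)
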