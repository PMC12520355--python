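"""Karhunen-Loeve / PCA reduction of time-series model output.

An ensemble Y (N_samp x Nt) of one output signal is decomposed as

    Y(theta, t) ~= mu(t) + sum_q c_q(theta) eta_q(t),  q = 1..M,

with mu the ensemble mean, eta_q the orthonormal right singular vectors of
the centered ensemble, and c_q the scores. The per-component explained
variance fractions are the normalized squared singular values. One basis is
fit per output signal; signals are not mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCABasis", "fit_pca", "inverse_transform", "explained_cumulative"]


@dataclass(frozen=True)
class PCABasis:
    """Truncated orthonormal basis of one signal's output ensemble."""

    mean: np.ndarray          # (Nt,)
    components: np.ndarray    # (Nt, M), columns orthonormal
    variances: np.ndarray     # (M,) score variances (ddof=1)
    fractions: np.ndarray     # (M,) explained-variance fractions of all Nt
    n_samples: int
    signal: str = ""

    @property
    def M(self) -> int:
        return self.components.shape[1]

    @property
    def n_time(self) -> int:
        return self.components.shape[0]


def fit_pca(Y, M: int, signal: str = "") -> tuple[PCABasis, np.ndarray]:
    """Fit the top-M PCA basis of an (N_samp x Nt) ensemble.

    Returns (basis, scores) with scores of shape (N_samp, M). The sign of
    each component is fixed so its maximum-magnitude entry is positive.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("ensemble must be 2D (samples x time)")
    if not np.all(np.isfinite(Y)):
        raise ValueError("ensemble contains non-finite entries")
    n, nt = Y.shape
    if M >= min(n, nt):
        raise ValueError(f"M={M} must be < min(N_samp, Nt) = {min(n, nt)}")
    mu = Y.mean(axis=0)
    Xc = Y - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|entry| of each component positive
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    total = float(np.sum(s**2))
    fractions = s[:M] ** 2 / total if total > 0 else np.zeros(M)
    scores = U[:, :M] * s[:M]
    variances = s[:M] ** 2 / (n - 1)
    basis = PCABasis(
        mean=mu,
        components=Vt[:M].T.copy(),
        variances=variances,
        fractions=fractions,
        n_samples=n,
        signal=signal,
    )
    return basis, scores


def inverse_transform(scores, basis: PCABasis) -> np.ndarray:
    """Reconstruct signals: mu + scores @ components.T."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] != basis.M:
        raise ValueError(f"score width {scores.shape[1]} != M={basis.M}")
    out = basis.mean + scores @ basis.components.T
    return out


def explained_cumulative(basis: PCABasis, m: int | None = None) -> float:
    """Cumulative explained-variance fraction of the first m components."""
    m = basis.M if m is None else m
    if m > basis.M:
        raise ValueError("m exceeds the basis truncation")
    return float(np.sum(basis.fractions[:m]))
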