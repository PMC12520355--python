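"""Structured-tree outflow boundary condition.

Each terminal 1D vessel is terminated by a self-similar asymmetric binary
tree: a branch of radius r spawns daughters of radii (alpha*r, beta*r) as
long as r exceeds the minimum radius rmin; daughters at or below rmin are
kept as leaves. Segment lengths are L = lrr * r. The root input impedance
Z(omega) is computed in the frequency domain from a linearized, viscous
(Womersley) transmission-line model of each segment, combined in parallel at
bifurcations, with leaves terminated by a zero load. The PDE coupling is the
time-domain convolution q(L,t) = int_0^t p(L,tau) y(t - tau) dtau with y the
inverse-transformed admittance kernel.

At omega = 0 every segment contributes its Poiseuille resistance
8 mu L / (pi r^4) in series with its load, so Z(0) is the DC resistance of
the whole tree -- a formulation-independent anchor used by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import jve

from .physics import (
    MMHG_TO_CGS,
    BloodProperties,
    HemoDomainError,
    WallParams,
    stiffness,
)

__all__ = [
    "StructuredTreeParams",
    "ImpedanceSpectrum",
    "tree_radii",
    "tree_size",
    "vessel_impedance",
    "root_impedance",
    "admittance_kernel",
    "convolve_admittance",
]

_MAX_GENERATIONS = 60


@dataclass(frozen=True)
class StructuredTreeParams:
    """Tree geometry parameters, shared by both terminal vessels."""

    alpha: float
    beta: float
    lrr: float
    rmin: float

    def __post_init__(self) -> None:
        if not (0.0 < self.beta <= self.alpha):
            raise HemoDomainError("require 0 < beta <= alpha")
        if self.alpha >= 1.0:
            raise HemoDomainError("alpha >= 1 gives a divergent tree")
        if self.rmin <= 0 or self.lrr <= 0:
            raise HemoDomainError("rmin and lrr must be positive")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Root impedance Z(omega_k) at harmonics omega_k = 2 pi k / T.

    Z is in mmHg s/mL; Z(0) is real and positive. The Hermitian extension
    Z(-omega) = conj(Z(omega)) makes the time-domain kernel real.
    """

    omega: np.ndarray  # rad/s
    Z: np.ndarray      # complex, mmHg s/mL
    period: float      # s

    def __post_init__(self) -> None:
        z0 = self.Z[0]
        if abs(z0.imag) > 1e-12 * abs(z0) or z0.real <= 0:
            raise HemoDomainError("Z(0) must be real and positive")

    @property
    def dc(self) -> float:
        return float(self.Z[0].real)


def _class_map(r_root: float, params: StructuredTreeParams) -> dict[tuple[int, int], float]:
    """Radius classes (i, j) -> radius r_root alpha^i beta^j for every branch
    class present in the tree."""
    classes: dict[tuple[int, int], float] = {}
    stack = [(0, 0)]
    while stack:
        i, j = stack.pop()
        if (i, j) in classes:
            continue
        if i + j > _MAX_GENERATIONS:
            raise HemoDomainError(
                f"structured tree exceeds {_MAX_GENERATIONS} generations; "
                "raise rmin or lower alpha"
            )
        r = r_root * params.alpha**i * params.beta**j
        classes[(i, j)] = r
        if r > params.rmin:
            stack.append((i + 1, j))
            stack.append((i, j + 1))
    return classes


def tree_radii(r_root: float, params: StructuredTreeParams, max_vessels: int = 10**6):
    """Radii of every branch, by explicit (non-memoized) recursion.

    A branch always exists once spawned; it spawns daughters (alpha r, beta r)
    iff its own radius exceeds rmin.
    """
    if r_root <= 0:
        raise HemoDomainError("root radius must be positive")
    radii: list[float] = []
    stack = [(r_root, 0)]
    while stack:
        r, gen = stack.pop()
        if gen > _MAX_GENERATIONS:
            raise HemoDomainError("structured tree exceeds the generation cap")
        radii.append(r)
        if len(radii) > max_vessels:
            raise HemoDomainError("structured tree exceeds the vessel cap")
        if r > params.rmin:
            stack.append((r * params.alpha, gen + 1))
            stack.append((r * params.beta, gen + 1))
    return np.array(radii)


def tree_size(r_root: float, params: StructuredTreeParams, memoize: bool = True):
    """Number of branches in the tree and the per-class generation map.

    With ``memoize=True`` subtree counts are shared across the (i, j) radius
    classes (identical by self-similarity); the result is bit-identical to
    explicit enumeration.
    """
    if not memoize:
        return len(tree_radii(r_root, params)), None
    classes = _class_map(r_root, params)
    counts: dict[tuple[int, int], int] = {}
    for (i, j) in sorted(classes, key=lambda ij: classes[ij]):
        r = classes[(i, j)]
        if r > params.rmin:
            counts[(i, j)] = 1 + counts[(i + 1, j)] + counts[(i, j + 1)]
        else:
            counts[(i, j)] = 1
    return counts[(0, 0)], classes


def _womersley_fj(omega, r: float, props: BloodProperties):
    """F_J = 2 J1(z) / (z J0(z)) with z = i^{3/2} w0, w0 = r sqrt(rho w/mu).

    Uses exponentially scaled Bessel functions so the ratio stays finite at
    high Womersley number.
    """
    w0 = r * np.sqrt(props.density * np.asarray(omega) / props.viscosity)
    z = w0 * np.exp(0.75j * np.pi)
    # jve shares the scaling factor exp(-|Im z|), so the ratio is exact
    ratio = jve(1, z) / jve(0, z)
    return 2.0 * ratio / z


def vessel_impedance(omega, r: float, lrr: float, props: BloodProperties,
                     wall: WallParams, Z_L=0.0):
    """Input impedance (CGS, dyn s/cm^5) of one tree segment with load Z_L.

    Linearized Womersley transmission line: wall compliance from the tube-law
    stiffness at radius r, segment length L = lrr * r. At omega = 0 the
    segment contributes the Poiseuille resistance 8 mu lrr / (pi r^3) in
    series with Z_L.
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if np.any(omega < 0):
        raise HemoDomainError("omega must be non-negative")
    Z_L = np.broadcast_to(np.asarray(Z_L, dtype=complex), omega.shape)
    A0 = np.pi * r * r
    L = lrr * r
    s_cgs = stiffness(r, wall) * MMHG_TO_CGS
    C = 3.0 * A0 / (2.0 * s_cgs)

    Z = np.empty(omega.shape, dtype=complex)
    zero = omega == 0.0
    R_pois = 8.0 * props.viscosity * L / (np.pi * r**4)
    Z[zero] = R_pois + Z_L[zero]
    nz = ~zero
    if np.any(nz):
        w = omega[nz]
        fj = _womersley_fj(w, r, props)
        c = np.sqrt(A0 * (1.0 - fj) / (props.density * C))
        g = C * c  # characteristic admittance
        t = np.tan(w * L / c)
        zl = Z_L[nz]
        Z[nz] = (1j * t / g + zl) / (1.0 + 1j * g * zl * t)
    return Z


def root_impedance(
    r_root: float,
    params: StructuredTreeParams,
    omega,
    props: BloodProperties,
    wall: WallParams,
    memoize: bool = True,
) -> ImpedanceSpectrum:
    """Root input impedance of the whole tree at the given harmonics.

    Post-order combination: leaves are terminated with Z_L = 0; at each
    bifurcation the daughters combine in parallel, 1/Z = 1/Z_d1 + 1/Z_d2.
    With ``memoize=True`` (default) impedances are shared across (i, j)
    radius classes. ``omega`` is in rad/s; the result is in mmHg s/mL.
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if memoize:
        classes = _class_map(r_root, params)
        zmap: dict[tuple[int, int], np.ndarray] = {}
        for (i, j) in sorted(classes, key=lambda ij: classes[ij]):
            r = classes[(i, j)]
            if r > params.rmin:
                zd1 = zmap[(i + 1, j)]
                zd2 = zmap[(i, j + 1)]
                load = zd1 * zd2 / (zd1 + zd2)
            else:
                load = 0.0
            zmap[(i, j)] = vessel_impedance(omega, r, params.lrr, props, wall, load)
        Z_cgs = zmap[(0, 0)]
    else:
        def _rec(r: float, gen: int) -> np.ndarray:
            if gen > _MAX_GENERATIONS:
                raise HemoDomainError("structured tree exceeds the generation cap")
            if r > params.rmin:
                zd1 = _rec(r * params.alpha, gen + 1)
                zd2 = _rec(r * params.beta, gen + 1)
                load = zd1 * zd2 / (zd1 + zd2)
            else:
                load = 0.0
            return vessel_impedance(omega, r, params.lrr, props, wall, load)

        Z_cgs = _rec(r_root, 0)

    if not np.all(np.isfinite(Z_cgs)):
        k = int(np.flatnonzero(~np.isfinite(Z_cgs))[0])
        raise HemoDomainError(f"non-finite tree impedance at harmonic {k}")
    period = 2.0 * np.pi / omega[1] if len(omega) > 1 and omega[1] > 0 else np.inf
    return ImpedanceSpectrum(omega=omega, Z=Z_cgs / MMHG_TO_CGS, period=period)


def admittance_kernel(Z, n_steps: int, dt: float):
    """Real time-domain admittance kernel y(t) from the impedance harmonics.

    ``Z`` holds Z(omega_k) for k = 0..n_steps//2 (any consistent units).
    The kernel satisfies q_n = dt * sum_j y_j p_{n-j} (circular convolution
    over one period), i.e. DFT(y)_k = 1 / (Z_k dt). The Hermitian extension
    is formed explicitly and the imaginary residue checked.
    """
    Z = np.asarray(Z, dtype=complex)
    if len(Z) != n_steps // 2 + 1:
        raise ValueError("need n_steps//2 + 1 harmonics")
    if not np.all(np.isfinite(Z)) or np.any(np.abs(Z) == 0.0):
        raise HemoDomainError("invalid impedance harmonics for kernel inversion")
    adm = 1.0 / Z
    full = np.empty(n_steps, dtype=complex)
    full[: len(adm)] = adm
    full[len(adm):] = np.conj(adm[1: n_steps - len(adm) + 1][::-1])
    if n_steps % 2 == 0:
        full[n_steps // 2] = full[n_steps // 2].real
    y = np.fft.ifft(full) / dt
    if np.max(np.abs(y.imag)) > 1e-10 * max(np.max(np.abs(y.real)), 1e-300):
        raise HemoDomainError("admittance kernel is not real")
    return y.real


def convolve_admittance(p, kernel, dt: float):
    """Periodic discrete convolution q_n = dt * sum_j y_j p_{n-j}.

    ``p`` and ``kernel`` must share the period grid (length n_steps).
    """
    p = np.asarray(p, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if p.shape != kernel.shape:
        raise ValueError("pressure history and kernel must share the grid")
    q = np.fft.ifft(np.fft.fft(p) * np.fft.fft(kernel))
    return dt * q.real
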