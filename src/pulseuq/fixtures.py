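"""Synthetic study conditions: network geometry, inflow waveform, nominal
parameters, priors, sampling designs, and analytic toy problems.

These fixtures emulate a normal adult pulmonary circulation on the 3-vessel
MPA/LPA/RPA network: ~90 mL/s mean inflow over a 0.85 s beat, a ~45/55
LPA/RPA flow split, and ~15 mmHg mean MPA pressure at the nominal Windkessel
parameters. They are plausible stand-ins chosen once, not measurements. The
toy problems carry closed-form truths that anchor the Sobol' and
profile-likelihood oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .physics import HemoDomainError, ParameterVector, Vessel, VesselNetwork
from .pce import PriorSpec
from .solver import GridSpec, SolverError, simulate

__all__ = [
    "InflowWaveform",
    "make_inflow",
    "default_network",
    "nominal_parameters",
    "make_priors",
    "sample_design",
    "toy_problems",
    "SIGNALS",
    "generate_ensemble",
]

#: the five output signals used throughout: (key, vessel, state)
SIGNALS = (
    ("MPA_p", "MPA", "p"),
    ("LPA_q", "LPA", "q"),
    ("RPA_q", "RPA", "q"),
    ("LPA_A", "LPA", "A"),
    ("RPA_A", "RPA", "A"),
)


@dataclass(frozen=True)
class InflowWaveform:
    """Smooth periodic inlet flow: raised-sine systolic pulse on a low
    constant diastolic baseline; C^1-periodic with time-mean exactly CO.

    q(t) = a sin^2(pi t / ts) for t < ts, plus baseline b, with
    ts = systolic_fraction * T, b = diastolic_fraction * CO and a chosen so
    the period mean equals CO.
    """

    period: float = 0.85                # s
    co: float = 90.0                    # mL/s mean
    systolic_fraction: float = 0.35
    diastolic_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.period <= 0 or self.co <= 0:
            raise HemoDomainError("period and CO must be positive")
        if not (0.05 < self.systolic_fraction < 0.9):
            raise HemoDomainError("systolic fraction outside validity range")
        if not (0.0 <= self.diastolic_fraction < 1.0):
            raise HemoDomainError("diastolic fraction must be in [0, 1)")

    @property
    def baseline(self) -> float:
        return self.diastolic_fraction * self.co

    @property
    def amplitude(self) -> float:
        ts = self.systolic_fraction * self.period
        return (self.co - self.baseline) * 2.0 * self.period / ts

    def __call__(self, t):
        t = np.asarray(t, dtype=float) % self.period
        ts = self.systolic_fraction * self.period
        pulse = np.where(t < ts, np.sin(np.pi * t / ts) ** 2, 0.0)
        out = self.amplitude * pulse + self.baseline
        return out if out.ndim else float(out)

    def samples(self, n: int) -> np.ndarray:
        return self(np.arange(n) * self.period / n)


def make_inflow(period: float = 0.85, co: float = 90.0,
                systolic_fraction: float = 0.35,
                diastolic_fraction: float = 0.10) -> InflowWaveform:
    """Construct the inlet waveform representative of MPA flow."""
    return InflowWaveform(period, co, systolic_fraction, diastolic_fraction)


def default_network() -> VesselNetwork:
    """3-vessel pulmonary network (plausible adult dimensions, cm)."""
    return VesselNetwork(
        vessels=(
            Vessel("MPA", length=5.0, radius=1.35, daughters=("LPA", "RPA")),
            Vessel("LPA", length=3.0, radius=0.93),
            Vessel("RPA", length=4.0, radius=0.95),
        ),
        root="MPA",
    )


_NOMINAL_WK = {
    "k1": 10.0, "k2": 2.0, "k3": 30.0,
    "Rp1": 0.05, "Rp2": 0.04, "Rd1": 0.32, "Rd2": 0.26,
    "CT1": 1.2, "CT2": 1.5,
}
_NOMINAL_ST = {
    "k1": 10.0, "k2": 2.0, "k3": 30.0,
    "alpha": 0.88, "beta": 0.66, "lrr": 50.0, "rmin": 0.01,
}


def nominal_parameters(variant: str = "wk") -> ParameterVector:
    """Nominal parameter vector for the chosen boundary-condition variant."""
    if variant == "wk":
        return ParameterVector("wk", dict(_NOMINAL_WK))
    if variant == "st":
        return ParameterVector("st", dict(_NOMINAL_ST))
    raise HemoDomainError(f"unknown variant {variant!r}")


def make_priors(nominal: ParameterVector, half_width: float = 0.5) -> PriorSpec:
    """Uniform priors [theta (1-h), theta (1+h)] around the nominal values."""
    if half_width <= 0:
        raise HemoDomainError("prior half-width must be positive (h=0 is degenerate)")
    if half_width >= 1:
        raise HemoDomainError("half-width >= 1 gives a non-positive lower bound")
    vals = nominal.to_array()
    bounds = np.column_stack([vals * (1 - half_width), vals * (1 + half_width)])
    return PriorSpec(names=nominal.names, bounds=bounds)


def sample_design(prior: PriorSpec, n: int, seed: int, method: str = "lhs") -> np.ndarray:
    """Reproducible sampling design inside the prior box (N x P).

    Latin-hypercube by default (one point per 1/N stratum in each marginal);
    N = 1 returns the prior midpoint by convention.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if n == 1:
        return prior.midpoint[None, :]
    if method == "lhs":
        u = qmc.LatinHypercube(d=prior.P, seed=seed).random(n)
    elif method == "random":
        u = np.random.default_rng(seed).random((n, prior.P))
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    return prior.from_unit(2.0 * u - 1.0)


def generate_ensemble(
    n: int,
    seed: int,
    variant: str = "wk",
    prior: PriorSpec | None = None,
    grid: GridSpec | None = None,
    network: VesselNetwork | None = None,
    inflow: InflowWaveform | None = None,
    verbose: bool = False,
):
    """Run the simulator on an LHS design and collect the five output signals.

    Samples whose simulation fails (blow-up / non-convergence) are dropped,
    mirroring standard practice for surrogate training sets. Returns
    (theta (n_ok x P), signals dict key -> (n_ok x Nt), mask (n,), time).
    """
    network = network or default_network()
    grid = grid or GridSpec()
    inflow = inflow or make_inflow(period=grid.period)
    prior = prior or make_priors(nominal_parameters(variant))
    theta = sample_design(prior, n, seed)
    nt_out = grid.n_time_out
    sigs = {key: np.empty((n, nt_out)) for key, _, _ in SIGNALS}
    mask = np.zeros(n, dtype=bool)
    time = None
    for i in range(n):
        pv = ParameterVector.from_array(variant, theta[i])
        try:
            sol = simulate(network, pv, inflow, grid)
        except SolverError:
            continue
        mask[i] = True
        time = sol.time
        for key, vessel, state in SIGNALS:
            sigs[key][i] = sol.signal(vessel, state)
        if verbose and (i + 1) % 50 == 0:
            print(f"  {i + 1}/{n} simulations done")
    sigs = {k: v[mask] for k, v in sigs.items()}
    return theta[mask], sigs, mask, time


# ---------------------------------------------------------------------------
# analytic toy problems anchoring the oracles
# ---------------------------------------------------------------------------

def toy_problems() -> dict:
    """Registry of analytic cases with documented closed-form truths."""
    return {
        "sobol_polynomial": _toy_sobol_polynomial(),
        "sobol_time_varying": _toy_sobol_time_varying(),
        "profile_linear_gaussian": _toy_profile_linear_gaussian(),
        "structured_tree_symmetric": _toy_symmetric_tree(),
    }


def _toy_sobol_polynomial() -> dict:
    """f(xi) = xi1 + 2 xi2 + xi1 xi2 on uniform [-1,1]^2.

    ANOVA: V1 = 1/3, V2 = 4/3, V12 = 1/9, V = 16/9, so
    S = (3/16, 12/16) and ST = (4/16, 13/16).
    """

    def f(xi):
        xi = np.atleast_2d(xi)
        return xi[:, 0] + 2.0 * xi[:, 1] + xi[:, 0] * xi[:, 1]

    return {
        "f": f,
        "P": 2,
        "degree": 2,
        "S": np.array([3.0 / 16.0, 12.0 / 16.0]),
        "ST": np.array([4.0 / 16.0, 13.0 / 16.0]),
    }


def _toy_sobol_time_varying() -> dict:
    """Y(t, xi) = a(t) xi1 + b(t) xi2: additive, so
    S_iY(t) = ST_iY(t) = a(t)^2 / (a^2 + b^2) (resp. b^2)."""
    t = np.linspace(0.0, 1.0, 32)
    a = 1.0 + 0.5 * np.sin(2 * np.pi * t)
    b = 0.5 + 0.3 * np.cos(2 * np.pi * t)

    def f(xi):
        xi = np.atleast_2d(xi)
        return xi[:, [0]] * a[None, :] + xi[:, [1]] * b[None, :]

    denom = a**2 + b**2
    return {
        "f": f,
        "P": 2,
        "degree": 1,
        "t": t,
        "S1": a**2 / denom,
        "S2": b**2 / denom,
    }


def _toy_profile_linear_gaussian() -> dict:
    """y = th1 x + th2 + eps, eps ~ N(0, sigma^2), on a fixed design.

    With the design-weighted objective g = sum r^2 / w and the chi-square
    threshold g_MLE + Delta(a)/2, the weight w = 2 sigma^2 makes g the true
    Gaussian negative log-likelihood (up to constants), so the profile CI is
    theta_hat +/- z_{1-a/2} SE (1.96 SE at a = 0.05).
    """
    rng = np.random.default_rng(7)
    x = np.linspace(0.0, 1.0, 40)
    sigma = 0.1
    theta_true = np.array([1.5, 0.5])
    y = theta_true[0] * x + theta_true[1] + rng.normal(0, sigma, len(x))

    def model(theta):
        theta = np.atleast_2d(theta)
        return theta[:, [0]] * x[None, :] + theta[:, [1]]

    X = np.column_stack([x, np.ones_like(x)])
    theta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    cov = sigma**2 * np.linalg.inv(X.T @ X)
    return {
        "x": x,
        "y": y,
        "sigma": sigma,
        "weight": 2.0 * sigma**2,
        "model": model,
        "theta_true": theta_true,
        "theta_hat": theta_hat,
        "se": np.sqrt(np.diag(cov)),
    }


def _toy_symmetric_tree() -> dict:
    """Symmetric structured tree (alpha = beta): after one bifurcation the
    DC resistance is R_root + R_child/2 with R_x the segment Poiseuille
    resistance 8 mu lrr / (pi r^3)."""
    from .structured_tree import StructuredTreeParams

    r_root = 0.1
    params = StructuredTreeParams(alpha=0.7, beta=0.7, lrr=20.0, rmin=0.05)

    def poiseuille(r, mu, lrr):
        return 8.0 * mu * lrr / (np.pi * r**3)

    return {"r_root": r_root, "params": params, "segment_resistance": poiseuille}
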