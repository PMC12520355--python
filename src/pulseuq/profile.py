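"""Univariate profile-likelihood identifiability analysis on the surrogate.

The design-weighted objective (the negative log-likelihood up to constants)
is g(theta) = sum_s sum_t (y_s(t) - M_s(t; theta))^2 / w_s, where the
per-signal weight w_s is the time-average of that signal's data -- a
nondimensionalization that puts pressure, flow and area residuals on a
common scale in the noise-free setting. Three experimental designs are
supported: D1 uses MPA pressure only; D2 adds LPA/RPA area; D3 adds LPA/RPA
flow.

For each parameter the profile PL_i(c) = min over the other free parameters
of g with theta_i = c is swept over +/-50% of the MLE, and the confidence
interval is the contiguous sub-level set under g_MLE + Delta(a)/2 with
Delta(a) the (1-a) chi-square(1) quantile (3.8415 at a = 0.05). A profile
bounded on both sides classifies the parameter as identifiable, on one side
as one-sided, and a curve entirely below the threshold as flat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2, qmc

from .pce import design_matrix

__all__ = [
    "DesignSpec",
    "ProfileConfig",
    "ProfileResult",
    "ProfileLikelihood",
    "ProfileLikelihoodResults",
    "neg_log_likelihood",
    "fit_mle",
    "profile_parameter",
    "confidence_interval",
    "profile_workflow",
    "simulator_check",
    "chi2_delta",
]

_DESIGN_SIGNALS = {
    "D1": ("MPA_p",),
    "D2": ("MPA_p", "LPA_A", "RPA_A"),
    "D3": ("MPA_p", "LPA_q", "RPA_q"),
}


@dataclass(frozen=True)
class DesignSpec:
    """An experimental design: which signals enter the likelihood."""

    design_id: str
    signals: tuple[str, ...]

    @classmethod
    def from_id(cls, design_id: str) -> "DesignSpec":
        if design_id not in _DESIGN_SIGNALS:
            raise ValueError(f"unknown design {design_id!r}; use D1, D2 or D3")
        return cls(design_id, _DESIGN_SIGNALS[design_id])

    def weights(self, data: dict) -> dict[str, float]:
        """Per-signal scalar Sigma entries: the time-average of the data."""
        w = {}
        for s in self.signals:
            if s not in data:
                raise KeyError(f"design signal {s!r} missing from data")
            ws = float(np.mean(data[s]))
            if ws <= 0:
                raise ValueError(f"non-positive weight for signal {s!r}")
            w[s] = ws
        return w


@dataclass(frozen=True)
class ProfileConfig:
    """Profiling controls."""

    alpha: float = 0.05
    grid_size: int = 41
    range_fraction: float = 0.5
    diff_step: float = 1e-4
    max_iter: int = 300
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("significance level must be in (0, 1)")
        if self.grid_size < 5:
            raise ValueError("need at least 5 grid points")
        if not (0 < self.range_fraction < 1):
            raise ValueError("profile range fraction must be in (0, 1)")


def chi2_delta(alpha: float = 0.05) -> float:
    """Delta(a) = icdf(chi^2_1, 1 - a); 3.8415 at a = 0.05."""
    return float(chi2.ppf(1.0 - alpha, df=1))


def _make_model_fn(predictor, signals: tuple[str, ...]):
    """Return f(theta) -> dict of predicted signals.

    ``predictor`` is a PCESurrogateResults (fast path: one design-matrix
    evaluation shared across signals) or any callable theta -> dict.
    """
    if callable(predictor) and not hasattr(predictor, "models"):
        def fn(theta):
            out = predictor(np.asarray(theta, dtype=float))
            return {s: np.asarray(out[s], dtype=float) for s in signals}

        return fn

    models = [predictor.models[s] for s in signals]
    for s in signals:
        if s not in predictor.models:
            raise KeyError(f"signal {s!r} missing from the surrogate")
    prior = predictor.prior
    mindex = models[0].mindex

    def fn(theta):
        xi = prior.to_unit(np.asarray(theta, dtype=float))[None, :]
        phi = design_matrix(xi, mindex)
        out = {}
        for s, m in zip(signals, models):
            scores = phi @ m.coef
            out[s] = (m.basis.mean + scores @ m.basis.components.T)[0]
        return out

    return fn


def neg_log_likelihood(theta, predictor, design: DesignSpec, data: dict,
                       weights: dict | None = None) -> float:
    """Design-weighted sum of squared residuals g(theta)."""
    weights = weights or design.weights(data)
    fn = _make_model_fn(predictor, design.signals)
    pred = fn(theta)
    g = 0.0
    for s in design.signals:
        r = np.asarray(data[s], dtype=float) - pred[s]
        g += float(np.sum(r * r)) / weights[s]
    return g


class _Objective:
    """Residual vector of the weighted likelihood over the free parameters."""

    def __init__(self, predictor, design: DesignSpec, data: dict,
                 free_idx, theta_base, weights: dict | None = None):
        self.fn = _make_model_fn(predictor, design.signals)
        self.signals = design.signals
        self.weights = weights or design.weights(data)
        self.data = {s: np.asarray(data[s], dtype=float) for s in design.signals}
        self.free_idx = np.asarray(free_idx, dtype=int)
        self.theta_base = np.asarray(theta_base, dtype=float).copy()

    def full_theta(self, x):
        th = self.theta_base.copy()
        th[self.free_idx] = x
        return th

    def residuals(self, x):
        pred = self.fn(self.full_theta(x))
        parts = [
            (self.data[s] - pred[s]) / np.sqrt(self.weights[s])
            for s in self.signals
        ]
        return np.concatenate(parts)

    def value(self, x) -> float:
        r = self.residuals(x)
        return float(r @ r)


def _minimize(obj: _Objective, x0, config: ProfileConfig):
    n = len(x0)
    res = least_squares(
        obj.residuals, x0, method="lm",
        diff_step=config.diff_step,
        max_nfev=config.max_iter * (n + 1),
    )
    return res.x, 2.0 * res.cost


def fit_mle(predictor, data: dict, design: DesignSpec, prior,
            free_names=None, theta_init=None, fixed: dict | None = None,
            config: ProfileConfig | None = None, weights: dict | None = None):
    """Levenberg-Marquardt MLE of the free parameters, with multistart.

    Returns (theta_full, g_mle, free_idx). Fixed parameters keep the values
    in ``fixed`` (or the init); starts are the init plus seeded LHS draws
    inside the prior box.
    """
    config = config or ProfileConfig()
    names = list(prior.names)
    fixed = dict(fixed or {})
    if free_names is None:
        free_names = [n for n in names if n not in fixed]
    free_idx = np.array([names.index(n) for n in free_names], dtype=int)

    base = np.asarray(
        theta_init if theta_init is not None else prior.midpoint, dtype=float
    ).copy()
    for k, v in fixed.items():
        base[names.index(k)] = v

    obj = _Objective(predictor, design, data, free_idx, base, weights=weights)
    starts = [base[free_idx]]
    if config.n_starts > 1:
        u = qmc.LatinHypercube(d=len(free_idx), seed=config.seed).random(
            config.n_starts - 1
        )
        lo = prior.bounds[free_idx, 0]
        hi = prior.bounds[free_idx, 1]
        starts.extend(list(lo + u * (hi - lo)))

    best_x, best_g = None, np.inf
    failures = 0
    for x0 in starts:
        try:
            x, g = _minimize(obj, x0, config)
        except Exception:
            failures += 1
            continue
        if g < best_g:
            best_x, best_g = x, g
    if best_x is None:
        raise RuntimeError(f"all {failures} optimizer starts failed")
    return obj.full_theta(best_x), best_g, free_idx


@dataclass
class ProfileResult:
    """Profile-likelihood curve and confidence interval for one parameter."""

    name: str
    grid: np.ndarray
    pl: np.ndarray            # profiled objective values (NaN where failed)
    theta_opt: np.ndarray     # (G, P) re-optimized full parameter vectors
    mle: np.ndarray           # full-theta MLE
    g_mle: float
    threshold: float
    ci: tuple[float, float] = (np.nan, np.nan)
    identifiability: str = ""

    @property
    def identifiable(self) -> bool:
        return self.identifiability == "identifiable"


def profile_parameter(predictor, data: dict, design: DesignSpec, prior,
                      name: str, theta_mle, g_mle: float,
                      fixed: dict | None = None,
                      config: ProfileConfig | None = None,
                      weights: dict | None = None) -> ProfileResult:
    """Profile one parameter over +/-range_fraction of its MLE value.

    The sweep moves outward from the MLE in both directions, warm-starting
    each re-optimization from the neighboring optimum. Optimizer failures
    are recorded as NaN, never interpolated.
    """
    config = config or ProfileConfig()
    names = list(prior.names)
    fixed = dict(fixed or {})
    i = names.index(name)
    theta_mle = np.asarray(theta_mle, dtype=float)
    other_free = [
        n for n in names if n != name and n not in fixed
    ]
    free_idx = np.array([names.index(n) for n in other_free], dtype=int)

    v = theta_mle[i]
    grid = np.linspace(
        v * (1.0 - config.range_fraction), v * (1.0 + config.range_fraction),
        config.grid_size,
    )
    G, P = len(grid), len(names)
    pl = np.full(G, np.nan)
    theta_opt = np.full((G, P), np.nan)

    base = theta_mle.copy()
    obj = _Objective(predictor, design, data, free_idx, base, weights=weights)

    i_start = int(np.argmin(np.abs(grid - v)))
    order = list(range(i_start, G)) + list(range(i_start - 1, -1, -1))
    warm: dict[int, np.ndarray] = {}
    for g_idx in order:
        nb = g_idx - 1 if g_idx > i_start else g_idx + 1
        x0 = warm.get(nb, theta_mle[free_idx] if len(free_idx) else np.empty(0))
        obj.theta_base = theta_mle.copy()
        obj.theta_base[i] = grid[g_idx]
        try:
            if len(free_idx) == 0:
                x, val = np.empty(0), obj.value(np.empty(0))
            else:
                x, val = _minimize(obj, x0, config)
        except Exception:
            continue
        pl[g_idx] = val
        warm[g_idx] = x
        theta_opt[g_idx] = obj.full_theta(x)

    threshold = g_mle + 0.5 * chi2_delta(config.alpha)
    ci, cls = confidence_interval(grid, pl, g_mle, config.alpha)
    return ProfileResult(
        name=name, grid=grid, pl=pl, theta_opt=theta_opt, mle=theta_mle,
        g_mle=g_mle, threshold=threshold, ci=ci, identifiability=cls,
    )


def confidence_interval(grid, pl, g_mle: float, alpha: float = 0.05):
    """Confidence interval and identifiability class from a profile curve.

    The threshold is g_MLE + Delta(a)/2. The CI is the contiguous sub-level
    interval around the profile minimum; bounds interior to the grid are
    located by linear interpolation. Classes: both bounds interior ->
    identifiable; one -> one-sided; curve entirely below the threshold ->
    flat.
    """
    grid = np.asarray(grid, dtype=float)
    pl = np.asarray(pl, dtype=float)
    ok = np.isfinite(pl)
    if not np.any(ok):
        raise ValueError("profile curve contains no successful points")
    threshold = g_mle + 0.5 * chi2_delta(alpha)
    finite_min = np.nanmin(pl)
    if finite_min > threshold:
        raise ValueError(
            f"profile minimum {finite_min:.3g} above the threshold "
            f"{threshold:.3g}; inconsistent g_MLE"
        )
    imin = int(np.nanargmin(pl))
    below = np.where(ok, pl <= threshold, False)

    lo_edge = imin
    while lo_edge > 0 and below[lo_edge - 1]:
        lo_edge -= 1
    hi_edge = imin
    while hi_edge < len(grid) - 1 and below[hi_edge + 1]:
        hi_edge += 1

    if lo_edge == 0:
        lo = -np.inf
    else:
        x0, x1 = grid[lo_edge - 1], grid[lo_edge]
        y0, y1 = pl[lo_edge - 1], pl[lo_edge]
        lo = x0 + (threshold - y0) * (x1 - x0) / (y1 - y0)
    if hi_edge == len(grid) - 1:
        hi = np.inf
    else:
        x0, x1 = grid[hi_edge], grid[hi_edge + 1]
        y0, y1 = pl[hi_edge], pl[hi_edge + 1]
        hi = x0 + (threshold - y0) * (x1 - x0) / (y1 - y0)

    n_bounded = int(np.isfinite(lo)) + int(np.isfinite(hi))
    if n_bounded == 2:
        cls = "identifiable"
    elif n_bounded == 1:
        cls = "one-sided"
    else:
        cls = "flat"
    return (float(lo), float(hi)), cls


class ProfileLikelihood:
    """Model object: a surrogate (or simulator callable), data, and a design.

    ``fit()`` computes the MLE and every univariate profile, returning a
    :class:`ProfileLikelihoodResults`.
    """

    def __init__(self, predictor, data: dict, design, prior=None,
                 fixed: dict | None = None, config: ProfileConfig | None = None,
                 theta_init=None, weights: dict | None = None):
        self.predictor = predictor
        self.data = data
        self.design = (
            design if isinstance(design, DesignSpec) else DesignSpec.from_id(design)
        )
        self.prior = prior if prior is not None else predictor.prior
        self.fixed = dict(fixed or {})
        self.config = config or ProfileConfig()
        self.theta_init = theta_init
        self.weights = weights

    def fit(self) -> "ProfileLikelihoodResults":
        theta_mle, g_mle, free_idx = fit_mle(
            self.predictor, self.data, self.design, self.prior,
            fixed=self.fixed, theta_init=self.theta_init, config=self.config,
            weights=self.weights,
        )
        names = list(self.prior.names)
        profiles: dict[str, ProfileResult] = {}
        for i in free_idx:
            name = names[i]
            profiles[name] = profile_parameter(
                self.predictor, self.data, self.design, self.prior,
                name, theta_mle, g_mle, fixed=self.fixed, config=self.config,
                weights=self.weights,
            )
        return ProfileLikelihoodResults(self, theta_mle, g_mle, profiles)


class ProfileLikelihoodResults:
    """MLE, profile curves, confidence intervals, classifications."""

    def __init__(self, model: ProfileLikelihood, theta_mle, g_mle: float,
                 profiles: dict[str, ProfileResult]):
        self.model = model
        self.theta_mle = np.asarray(theta_mle, dtype=float)
        self.g_mle = float(g_mle)
        self.profiles = profiles

    @property
    def classification(self) -> dict[str, str]:
        return {k: p.identifiability for k, p in self.profiles.items()}

    def summary(self) -> str:
        names = list(self.model.prior.names)
        lines = [
            f"Profile likelihood ({self.model.design.design_id}), "
            f"-LL(MLE) = {self.g_mle:.4g}, "
            f"Delta(a)/2 = {0.5 * chi2_delta(self.model.config.alpha):.4f}",
            f"  fixed: {sorted(self.model.fixed) or 'none'}",
            f"  {'param':>6s} {'MLE':>10s} {'CI low':>10s} {'CI high':>10s}  class",
        ]
        for name, p in self.profiles.items():
            mle_v = self.theta_mle[names.index(name)]
            lines.append(
                f"  {name:>6s} {mle_v:>10.4g} {p.ci[0]:>10.4g} {p.ci[1]:>10.4g}"
                f"  {p.identifiability}"
            )
        return "\n".join(lines)

    def plot(self, names=None, ax=None):
        """Profile curves with the chi-square threshold."""
        import matplotlib.pyplot as plt

        names = names or list(self.profiles)
        n = len(names)
        fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), squeeze=False)
        for axi, name in zip(axes[0], names):
            p = self.profiles[name]
            axi.plot(p.grid, p.pl, "o-", ms=3)
            axi.axhline(p.threshold, color="C3", ls="--")
            axi.set_title(f"{name} ({p.identifiability})")
            axi.set_xlabel(name)
        axes[0][0].set_ylabel("-LL")
        return fig


def profile_workflow(predictor, data: dict, designs, fixing_sequence,
                     prior=None, config: ProfileConfig | None = None):
    """Repeated MLE + profiling per design per fixing level.

    ``fixing_sequence`` is a list of parameter-name collections to freeze
    cumulatively (level 0 fixes nothing). Parameters are frozen at their
    current inferred values, not at any a-priori truth. Returns
    {design_id: [ProfileLikelihoodResults per level]}.
    """
    config = config or ProfileConfig()
    out: dict[str, list[ProfileLikelihoodResults]] = {}
    for design_id in designs:
        design = (
            design_id if isinstance(design_id, DesignSpec)
            else DesignSpec.from_id(design_id)
        )
        levels: list[ProfileLikelihoodResults] = []
        fixed: dict[str, float] = {}
        pr = prior if prior is not None else predictor.prior
        names = list(pr.names)
        if len(fixing_sequence) and all(
            len(set(level)) >= len(names) for level in fixing_sequence
        ):
            raise ValueError("a fixing level leaves no free parameters")
        res = ProfileLikelihood(
            predictor, data, design, prior=pr, fixed={}, config=config
        ).fit()
        levels.append(res)
        current = res.theta_mle
        for level in fixing_sequence:
            for nm in level:
                fixed[nm] = float(current[names.index(nm)])
            if len(fixed) >= len(names):
                raise ValueError("empty free parameter set after fixing")
            res = ProfileLikelihood(
                predictor, data, design, prior=pr, fixed=dict(fixed),
                config=config, theta_init=current,
            ).fit()
            levels.append(res)
            current = res.theta_mle
        out[design.design_id] = levels
    return out


def simulator_check(profile: ProfileResult, design: DesignSpec, data: dict,
                    model_fn, weights: dict | None = None):
    """Re-evaluate the profiled optima through another model (the simulator).

    ``model_fn(theta) -> dict of signals``; failures are recorded as NaN.
    Returns (surrogate_curve, model_curve) over the profile grid.
    """
    weights = weights or design.weights(data)
    out = np.full(len(profile.grid), np.nan)
    for g_idx in range(len(profile.grid)):
        th = profile.theta_opt[g_idx]
        if not np.all(np.isfinite(th)):
            continue
        try:
            pred = model_fn(th)
        except Exception:
            continue
        g = 0.0
        for s in design.signals:
            r = np.asarray(data[s], dtype=float) - np.asarray(pred[s], dtype=float)
            g += float(np.sum(r * r)) / weights[s]
        out[g_idx] = g
    return profile.pl.copy(), out
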