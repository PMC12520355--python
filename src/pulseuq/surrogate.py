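"""PCA-PCE surrogate as a Model / Results pair.

:class:`PCESurrogate` is constructed from a training design and the raw
simulated time series of one or more output signals; :meth:`PCESurrogate.fit`
reduces each signal by PCA, regresses the scores on the orthonormal Legendre
basis, and returns a :class:`PCESurrogateResults` carrying the per-signal
models, fit diagnostics, prediction, MSRE validation, Sobol' sensitivity,
archiving and plotting.
"""

from __future__ import annotations

import numpy as np

from .pca import fit_pca, inverse_transform, explained_cumulative
from .pce import (
    PriorSpec,
    PCEModel,
    fit_ols,
    msre as _msre,
    multi_index_set,
    predict_scores,
    predict_timeseries,
)
from .sobol import SobolResult, pointwise_sobol

__all__ = ["PCESurrogate", "PCESurrogateResults"]


class PCESurrogate:
    """Surrogate model specification over a simulation training set.

    Parameters
    ----------
    theta : (N, P) array
        Training parameter samples inside the prior box.
    signals : dict[str, (N, Nt) array]
        Simulated time series per output signal.
    prior : PriorSpec
        Uniform prior box defining the [-1, 1] mapping.
    degree : int
        Total polynomial degree m of the expansion.
    n_components : int
        Number of principal components M retained per signal.
    time : (Nt,) array, optional
        Output time grid (for plotting and bookkeeping).
    """

    def __init__(self, theta, signals: dict, prior: PriorSpec,
                 degree: int = 5, n_components: int = 5, time=None):
        self.theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if self.theta.shape[1] != prior.P:
            raise ValueError("theta width does not match the prior dimension")
        self.signals = {k: np.asarray(v, dtype=float) for k, v in signals.items()}
        for k, v in self.signals.items():
            if v.shape[0] != self.theta.shape[0]:
                raise ValueError(f"signal {k!r} sample count mismatch")
        self.prior = prior
        self.degree = int(degree)
        self.n_components = int(n_components)
        self.time = None if time is None else np.asarray(time, dtype=float)

    def fit(self) -> "PCESurrogateResults":
        mindex = multi_index_set(self.prior.P, self.degree)
        models: dict[str, PCEModel] = {}
        for key, Y in self.signals.items():
            basis, scores = fit_pca(Y, self.n_components, signal=key)
            models[key] = fit_ols(self.theta, scores, self.prior, mindex,
                                  basis=basis, signal=key)
        return PCESurrogateResults(self, models)


class PCESurrogateResults:
    """Fitted PCA-PCE surrogates for every output signal."""

    def __init__(self, model: PCESurrogate, models: dict[str, PCEModel]):
        self.model = model
        self.models = models
        self.prior = model.prior
        self.signal_names = tuple(models)

    def __getitem__(self, signal: str) -> PCEModel:
        return self.models[signal]

    def predict(self, theta, signal: str | None = None, check_bounds: bool = True):
        """Time-series prediction; dict over signals unless one is named."""
        if signal is not None:
            return predict_timeseries(self.models[signal], theta, check_bounds)
        return {
            k: predict_timeseries(m, theta, check_bounds)
            for k, m in self.models.items()
        }

    def predict_scores(self, theta, signal: str, check_bounds: bool = True):
        return predict_scores(self.models[signal], theta, check_bounds)

    def msre(self, theta_test, signals_test: dict) -> dict[str, np.ndarray]:
        """Per-sample MSRE on held-out simulations, per signal."""
        out = {}
        for key, y in signals_test.items():
            pred = predict_timeseries(self.models[key], theta_test,
                                      check_bounds=False)
            out[key] = _msre(y, pred)
        return out

    def sobol(self, signal: str) -> SobolResult:
        """Coefficient-based Sobol' indices (component + pointwise)."""
        return pointwise_sobol(self.models[signal])

    def explained_variance(self, signal: str, m: int | None = None) -> float:
        return explained_cumulative(self.models[signal].basis, m)

    def reconstruct(self, signal: str, scores) -> np.ndarray:
        return inverse_transform(scores, self.models[signal].basis)

    def summary(self) -> str:
        lines = [
            "PCA-PCE surrogate summary",
            f"  parameters: {', '.join(self.prior.names)}",
            f"  degree m = {self.model.degree}, "
            f"basis size K = {len(next(iter(self.models.values())).mindex)}, "
            f"M = {self.model.n_components} components, "
            f"N_train = {self.model.theta.shape[0]}",
            "",
            f"  {'signal':>8s} {'cum.var(M)':>11s} {'cond(Phi)':>10s} {'min R2':>8s}",
        ]
        for key, m in self.models.items():
            lines.append(
                f"  {key:>8s} {explained_cumulative(m.basis):>10.4%} "
                f"{m.condition_number:>10.2e} {np.min(m.train_r2):>8.4f}"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        """Archive the fitted surrogate (HDF5)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["degree"] = self.model.degree
            f.attrs["n_components"] = self.model.n_components
            f.attrs["param_names"] = list(self.prior.names)
            f.create_dataset("prior_bounds", data=self.prior.bounds)
            if self.model.time is not None:
                f.create_dataset("time", data=self.model.time)
            for key, m in self.models.items():
                g = f.create_group(f"signals/{key}")
                g.create_dataset("coef", data=m.coef)
                g.create_dataset("pca_mean", data=m.basis.mean)
                g.create_dataset("pca_components", data=m.basis.components)
                g.create_dataset("pca_variances", data=m.basis.variances)
                g.create_dataset("pca_fractions", data=m.basis.fractions)
                g.attrs["n_samples"] = m.basis.n_samples
                g.attrs["condition_number"] = m.condition_number
                g.create_dataset("train_r2", data=m.train_r2)
                g.attrs["n_train"] = m.n_train

    @classmethod
    def load(cls, path: str) -> "PCESurrogateResults":
        import h5py

        from .pca import PCABasis

        with h5py.File(path, "r") as f:
            names = tuple(
                n.decode() if isinstance(n, bytes) else str(n)
                for n in f.attrs["param_names"]
            )
            prior = PriorSpec(names=names, bounds=f["prior_bounds"][()])
            degree = int(f.attrs["degree"])
            M = int(f.attrs["n_components"])
            time = f["time"][()] if "time" in f else None
            mindex = multi_index_set(prior.P, degree)
            models: dict[str, PCEModel] = {}
            signals_stub: dict[str, np.ndarray] = {}
            for key in f["signals"]:
                g = f[f"signals/{key}"]
                basis = PCABasis(
                    mean=g["pca_mean"][()],
                    components=g["pca_components"][()],
                    variances=g["pca_variances"][()],
                    fractions=g["pca_fractions"][()],
                    n_samples=int(g.attrs["n_samples"]),
                    signal=key,
                )
                models[key] = PCEModel(
                    mindex=mindex,
                    coef=g["coef"][()],
                    prior=prior,
                    basis=basis,
                    signal=key,
                    condition_number=float(g.attrs["condition_number"]),
                    train_r2=g["train_r2"][()],
                    n_train=int(g.attrs["n_train"]),
                )
                signals_stub[key] = np.zeros((1, basis.n_time))
        stub = PCESurrogate(
            theta=np.tile(prior.midpoint, (1, 1)),
            signals=signals_stub, prior=prior, degree=degree,
            n_components=M, time=time,
        )
        return cls(stub, models)

    # ------------------------------------------------------------------
    # plotting
    # ------------------------------------------------------------------
    def plot_prediction(self, theta, signal: str, y_true=None, ax=None):
        """Plot the surrogate prediction (and optional truth) for one signal."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.time
        if t is None:
            t = np.arange(self.models[signal].basis.n_time)
        ax.plot(t, self.predict(theta, signal, check_bounds=False), label="surrogate")
        if y_true is not None:
            ax.plot(t, y_true, "--", label="simulator")
        ax.set_xlabel("time (s)")
        ax.set_ylabel(signal)
        ax.legend()
        return ax
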