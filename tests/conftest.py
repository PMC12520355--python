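"""Shared fixtures: study conditions and session-scoped simulation ensembles.

The heavier ensembles (used by the acceptance-level checks) are generated
once per session at the study conditions: +/-50% uniform priors around the
nominal Windkessel parameters, Latin-hypercube designs, default solver grid.
"""

import warnings

import numpy as np
import pytest

import pulseuq as pq
from pulseuq import fixtures as fx
from pulseuq.surrogate import PCESurrogate


@pytest.fixture(scope="session")
def network():
    return fx.default_network()


@pytest.fixture(scope="session")
def inflow():
    return fx.make_inflow()


@pytest.fixture(scope="session")
def grid():
    return pq.GridSpec()


@pytest.fixture(scope="session")
def props():
    return pq.BloodProperties()


@pytest.fixture(scope="session")
def wk_prior():
    return fx.make_priors(fx.nominal_parameters("wk"))


@pytest.fixture(scope="session")
def wk_solution(network, inflow, grid):
    """One converged Windkessel simulation at the nominal parameters."""
    return pq.simulate(network, fx.nominal_parameters("wk"), inflow, grid)


@pytest.fixture(scope="session")
def wk_ensemble_200(wk_prior, grid):
    """200-sample LHS Windkessel ensemble (PCA variance experiments)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        theta, sigs, mask, time = fx.generate_ensemble(
            200, seed=11, variant="wk", prior=wk_prior, grid=grid
        )
    assert mask.sum() >= 190, "too many failed training simulations"
    return theta, sigs, time


@pytest.fixture(scope="session")
def wk_surrogate_600(wk_prior, grid):
    """Degree-3 PCA-PCE surrogate trained on 600 Windkessel simulations."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        theta, sigs, mask, time = fx.generate_ensemble(
            600, seed=17, variant="wk", prior=wk_prior, grid=grid
        )
    assert mask.sum() >= 570, "too many failed training simulations"
    res = PCESurrogate(theta, sigs, wk_prior, degree=3, n_components=5,
                       time=time).fit()
    return res


@pytest.fixture(scope="session")
def wk_test_50(wk_prior, grid):
    """50 held-out test simulations (disjoint LHS seed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        theta, sigs, mask, time = fx.generate_ensemble(
            50, seed=23, variant="wk", prior=wk_prior, grid=grid
        )
    assert mask.sum() >= 48
    return theta, sigs


@pytest.fixture(scope="session")
def wk_nominal_data(wk_solution):
    """Noise-free 'measurements': the five signals at the nominal theta."""
    return {
        key: wk_solution.signal(vessel, state)
        for key, vessel, state in fx.SIGNALS
    }
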