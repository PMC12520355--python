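"""Legendre basis, multi-indices, OLS fitting, prediction, MSRE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulseuq.pce import (
    PriorSpec,
    design_matrix,
    fit_ols,
    legendre_1d,
    legendre_norm,
    msre,
    multi_index_set,
    predict_scores,
    predict_timeseries,
)


class TestLegendre:
    def test_degree_zero_and_norm(self):
        assert legendre_1d(0, 0.37) == 1.0
        assert legendre_norm(0) == 2.0
        assert legendre_norm(2) == pytest.approx(2.0 / 5.0)

    def test_endpoint_identity(self):
        for j in range(6):
            assert legendre_1d(j, 1.0) == pytest.approx(1.0, rel=1e-13)

    def test_orthogonality_by_quadrature(self):
        x, w = np.polynomial.legendre.leggauss(12)
        p2 = legendre_1d(2, x)
        p3 = legendre_1d(3, x)
        assert np.sum(w * p2 * p3) == pytest.approx(0.0, abs=1e-14)
        assert np.sum(w * p2 * p2) == pytest.approx(2.0 / 5.0, rel=1e-13)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            legendre_1d(3, 1.1)

    def test_orthonormal_design_matrix_unit_variance(self):
        """Columns of Phi have unit variance under the uniform density."""
        x, w = np.polynomial.legendre.leggauss(20)
        mindex = multi_index_set(1, 4)
        phi = design_matrix(x[:, None], mindex)
        # E[phi_k^2] = sum w/2 * phi^2 = 1
        moments = 0.5 * (w[:, None] * phi**2).sum(axis=0)
        assert np.allclose(moments, 1.0, atol=1e-12)


class TestMultiIndex:
    def test_cardinalities(self):
        assert len(multi_index_set(2, 2)) == 6
        assert len(multi_index_set(9, 5)) == 2002

    def test_enumeration_p2_m2(self):
        idx = {tuple(a) for a in multi_index_set(2, 2).indices}
        assert idx == {(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)}

    def test_subset_partition_identity(self):
        m = multi_index_set(3, 4)
        first = [set(m.first_order_set(i)) for i in range(3)]
        # A_Si are pairwise disjoint and exclude index 0
        zero = int(np.flatnonzero(m.indices.sum(axis=1) == 0)[0])
        for i in range(3):
            assert zero not in first[i]
            assert first[i] <= set(m.total_order_set(i))
            for j in range(i):
                assert not (first[i] & first[j])
        # A_Si union + interactions + {0} partitions the set
        union = set().union(*first)
        interactions = {
            k for k in range(len(m))
            if np.count_nonzero(m.indices[k]) >= 2
        }
        assert union | interactions | {zero} == set(range(len(m)))
        # complement sets: non-constant indices with a_i = 0
        for i in range(3):
            comp = set(m.complement_set(i))
            assert comp == set(range(len(m))) - set(m.total_order_set(i)) - {zero}


class TestPriorSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(("a",), np.array([[1.0, 1.0]]))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        lo=st.floats(-10, 10),
        width=st.floats(1e-3, 20),
        u=st.floats(0, 1),
    )
    def test_round_trip(self, lo, width, u):
        prior = PriorSpec(("x",), np.array([[lo, lo + width]]))
        theta = np.array([lo + u * width])
        xi = prior.to_unit(theta)
        assert abs(prior.from_unit(xi)[0] - theta[0]) < 1e-12 * max(1, abs(theta[0]))

    def test_midpoint_maps_to_zero(self):
        prior = PriorSpec(("a", "b"), np.array([[1.0, 3.0], [0.5, 4.5]]))
        assert np.allclose(prior.to_unit(prior.midpoint), 0.0)


class TestFitOLS:
    def _prior(self, P):
        return PriorSpec(
            tuple(f"t{i}" for i in range(P)),
            np.column_stack([np.ones(P), 3 * np.ones(P)]),
        )

    def test_exact_polynomial_reproduction(self):
        rng = np.random.default_rng(1)
        P, m = 3, 3
        prior = self._prior(P)
        mindex = multi_index_set(P, m)
        z_true = rng.normal(size=(len(mindex), 2))
        theta = prior.from_unit(rng.uniform(-1, 1, (200, P)))
        scores = design_matrix(prior.to_unit(theta), mindex) @ z_true
        model = fit_ols(theta, scores, prior, mindex)
        theta_test = prior.from_unit(rng.uniform(-1, 1, (50, P)))
        truth = design_matrix(prior.to_unit(theta_test), mindex) @ z_true
        pred = predict_scores(model, theta_test)
        assert np.max(np.abs(pred - truth)) < 1e-8

    def test_constant_scores_give_constant_term_only(self):
        prior = self._prior(2)
        mindex = multi_index_set(2, 2)
        rng = np.random.default_rng(2)
        theta = prior.from_unit(rng.uniform(-1, 1, (30, 2)))
        scores = np.full((30, 1), 7.5)
        model = fit_ols(theta, scores, prior, mindex)
        zero_row = int(np.flatnonzero(mindex.indices.sum(axis=1) == 0)[0])
        assert model.coef[zero_row, 0] == pytest.approx(7.5, rel=1e-12)
        others = np.delete(model.coef[:, 0], zero_row)
        assert np.max(np.abs(others)) < 1e-10

    def test_underdetermined_raises(self):
        prior = self._prior(2)
        mindex = multi_index_set(2, 3)  # K = 10
        with pytest.raises(ValueError, match="under-determined"):
            fit_ols(np.full((5, 2), 2.0), np.zeros((5, 1)), prior, mindex)

    def test_rank_deficiency_raises(self):
        prior = self._prior(2)
        mindex = multi_index_set(2, 2)
        theta = np.tile(prior.from_unit(np.array([[0.2, -0.4]])), (10, 1))
        with pytest.raises(ValueError):
            fit_ols(theta, np.zeros((10, 1)), prior, mindex)

    def test_coefficient_variance_matches_sampled_scores(self):
        """Sum of squared non-constant coefficients ~ prior variance of the
        predicted scores (orthonormal basis: gamma_hat = 1)."""
        rng = np.random.default_rng(3)
        prior = self._prior(2)
        mindex = multi_index_set(2, 3)
        z = rng.normal(size=(len(mindex), 1))
        theta = prior.from_unit(rng.uniform(-1, 1, (400, 2)))
        scores = design_matrix(prior.to_unit(theta), mindex) @ z
        model = fit_ols(theta, scores, prior, mindex)
        dense = prior.from_unit(rng.uniform(-1, 1, (100000, 2)))
        sample_var = np.var(predict_scores(model, dense), axis=0)
        nonconst = mindex.indices.sum(axis=1) > 0
        coef_var = np.sum(model.coef[nonconst] ** 2, axis=0)
        assert sample_var[0] == pytest.approx(coef_var[0], rel=0.02)


class TestPrediction:
    def test_degree_one_model_is_affine(self):
        prior = PriorSpec(("a", "b"), np.array([[0.0, 2.0], [0.0, 2.0]]))
        mindex = multi_index_set(2, 1)
        rng = np.random.default_rng(4)
        theta = prior.from_unit(rng.uniform(-1, 1, (20, 2)))
        scores = 1.0 + 2.0 * theta[:, [0]] - 0.5 * theta[:, [1]]
        model = fit_ols(theta, scores, prior, mindex)
        t1, t2 = np.array([0.5, 1.0]), np.array([1.5, 1.0])
        mid = 0.5 * (t1 + t2)
        s1 = predict_scores(model, t1)
        s2 = predict_scores(model, t2)
        sm = predict_scores(model, mid)
        assert sm == pytest.approx(0.5 * (s1 + s2), rel=1e-12)

    def test_batch_vs_single_agree(self):
        prior = PriorSpec(("a", "b"), np.array([[0.0, 2.0], [0.0, 2.0]]))
        mindex = multi_index_set(2, 2)
        rng = np.random.default_rng(5)
        theta = prior.from_unit(rng.uniform(-1, 1, (30, 2)))
        scores = rng.normal(size=(30, 3))
        model = fit_ols(theta, scores, prior, mindex)
        batch = predict_scores(model, theta[:5])
        singles = np.array([predict_scores(model, t) for t in theta[:5]])
        assert np.max(np.abs(batch - singles)) < 1e-12

    def test_extrapolation_warns(self):
        prior = PriorSpec(("a",), np.array([[0.0, 1.0]]))
        mindex = multi_index_set(1, 1)
        model = fit_ols(
            np.linspace(0, 1, 9)[:, None], np.zeros((9, 1)), prior, mindex
        )
        with pytest.warns(RuntimeWarning):
            predict_scores(model, np.array([2.0]))

    def test_timeseries_requires_basis(self):
        prior = PriorSpec(("a",), np.array([[0.0, 1.0]]))
        mindex = multi_index_set(1, 1)
        model = fit_ols(
            np.linspace(0, 1, 9)[:, None], np.zeros((9, 1)), prior, mindex
        )
        with pytest.raises(ValueError):
            predict_timeseries(model, np.array([0.5]))


class TestMSRE:
    def test_perfect_surrogate_is_zero(self):
        y = np.random.default_rng(0).uniform(1, 2, (5, 16))
        assert np.all(msre(y, y) == 0.0)

    def test_constant_offset_hand_value(self):
        """Offset delta on a signal with max 1: per-sample MSRE = delta^2."""
        y = np.vstack([np.linspace(0, 1, 10), np.linspace(0.5, 1, 10)])
        delta = 0.03
        e = msre(y, y + delta)
        assert e[0] == pytest.approx(delta**2, rel=1e-12)
        assert e[1] == pytest.approx(delta**2, rel=1e-12)

    def test_non_negative_and_zero_max_error(self):
        y = np.random.default_rng(1).normal(size=(4, 8)) + 10
        pred = y + np.random.default_rng(2).normal(size=(4, 8))
        assert np.all(msre(y, pred) >= 0)
        with pytest.raises(ValueError):
            msre(np.zeros((1, 4)), np.zeros((1, 4)))


class TestSurrogateOnAnalyticSimulator:
    """Model/Results workflow on a cheap analytic 'simulator'."""

    @staticmethod
    def _simulate(theta, t):
        # smooth nonlinear map from 3 parameters to a time series
        a, b, c = theta[:, [0]], theta[:, [1]], theta[:, [2]]
        return (
            a * np.sin(2 * np.pi * t)[None, :]
            + np.sqrt(b) * np.cos(2 * np.pi * t)[None, :]
            + 0.3 * a * c
            + 5.0
        )

    def test_msre_weakly_decreases_with_training_size(self):
        from pulseuq.surrogate import PCESurrogate

        rng = np.random.default_rng(6)
        prior = PriorSpec(("a", "b", "c"),
                          np.array([[0.5, 1.5], [0.5, 1.5], [0.5, 1.5]]))
        t = np.linspace(0, 1, 32)
        th_test = prior.from_unit(rng.uniform(-1, 1, (40, 3)))
        y_test = self._simulate(th_test, t)

        def median_msre(n, seed):
            th = prior.from_unit(
                np.random.default_rng(seed).uniform(-1, 1, (n, 3))
            )
            res = PCESurrogate(
                th, {"y": self._simulate(th, t)}, prior, degree=3,
                n_components=4,
            ).fit()
            return float(np.median(res.msre(th_test, {"y": y_test})["y"]))

        assert median_msre(1200, 8) <= median_msre(600, 7) * 1.05

    def test_save_load_round_trip(self, tmp_path):
        from pulseuq.surrogate import PCESurrogate, PCESurrogateResults

        rng = np.random.default_rng(9)
        prior = PriorSpec(("a", "b", "c"),
                          np.array([[0.5, 1.5], [0.5, 1.5], [0.5, 1.5]]))
        t = np.linspace(0, 1, 16)
        th = prior.from_unit(rng.uniform(-1, 1, (80, 3)))
        res = PCESurrogate(th, {"y": self._simulate(th, t)}, prior,
                           degree=2, n_components=3, time=t).fit()
        path = str(tmp_path / "model.h5")
        res.save(path)
        back = PCESurrogateResults.load(path)
        probe = prior.midpoint * 1.01
        assert np.allclose(res.predict(probe, "y"), back.predict(probe, "y"),
                           atol=1e-12)
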