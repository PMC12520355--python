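"""Profile-likelihood machinery against closed-form oracles."""

import numpy as np
import pytest

from pulseuq import fixtures as fx
from pulseuq.pce import PriorSpec
from pulseuq.profile import (
    DesignSpec,
    ProfileConfig,
    ProfileLikelihood,
    chi2_delta,
    confidence_interval,
    fit_mle,
    neg_log_likelihood,
    profile_parameter,
    simulator_check,
)

TOY = fx.toy_problems()["profile_linear_gaussian"]
DESIGN = DesignSpec("toy", ("y",))
DATA = {"y": TOY["y"]}
WEIGHTS = {"y": TOY["weight"]}
PRIOR = PriorSpec(("th1", "th2"), np.array([[0.5, 3.0], [0.1, 1.5]]))
CFG = ProfileConfig(n_starts=3)


def _predictor(theta):
    return {"y": TOY["model"](theta)[0]}


class TestNegLogLikelihood:
    def test_truth_with_exact_model_is_zero(self):
        data = {"y": TOY["model"](TOY["theta_true"])[0]}
        g = neg_log_likelihood(TOY["theta_true"], _predictor, DESIGN, data,
                               weights=WEIGHTS)
        assert g == pytest.approx(0.0, abs=1e-20)

    def test_constant_residual_hand_sum(self):
        """Constant residual delta with weight w: g = Nt delta^2 / w."""
        nt, delta, w = 40, 0.3, 1.7
        data = {"y": TOY["model"](TOY["theta_true"])[0] + delta}
        g = neg_log_likelihood(TOY["theta_true"], _predictor, DESIGN, data,
                               weights={"y": w})
        assert g == pytest.approx(nt * delta**2 / w, rel=1e-12)

    def test_doubling_weight_halves_contribution(self):
        data = {"y": TOY["model"](TOY["theta_true"])[0] + 0.2}
        g1 = neg_log_likelihood(TOY["theta_true"], _predictor, DESIGN, data,
                                weights={"y": 1.0})
        g2 = neg_log_likelihood(TOY["theta_true"], _predictor, DESIGN, data,
                                weights={"y": 2.0})
        assert g1 == pytest.approx(2 * g2, rel=1e-12)

    def test_default_weights_are_data_means(self):
        w = DesignSpec.from_id("D1").weights({"MPA_p": np.array([10.0, 20.0])})
        assert w == {"MPA_p": 15.0}


class TestMLE:
    def test_matches_closed_form_weighted_least_squares(self):
        theta, g, _ = fit_mle(_predictor, DATA, DESIGN, PRIOR,
                              config=CFG, weights=WEIGHTS)
        assert np.max(np.abs(theta - TOY["theta_hat"])) < 1e-8

    def test_exact_data_from_truth_converges_immediately(self):
        data = {"y": TOY["model"](TOY["theta_true"])[0]}
        theta, g, _ = fit_mle(
            _predictor, data, DESIGN, PRIOR,
            theta_init=TOY["theta_true"],
            config=ProfileConfig(n_starts=1), weights=WEIGHTS,
        )
        assert g < 1e-10

    def test_parameter_order_invariance(self):
        theta, _, _ = fit_mle(_predictor, DATA, DESIGN, PRIOR,
                              config=CFG, weights=WEIGHTS)
        prior_swapped = PriorSpec(("th2", "th1"),
                                  PRIOR.bounds[::-1].copy())

        def predictor_swapped(th):
            return {"y": TOY["model"](np.array([th[1], th[0]]))[0]}

        theta_s, _, _ = fit_mle(predictor_swapped, DATA, DESIGN, prior_swapped,
                                config=CFG, weights=WEIGHTS)
        assert np.max(np.abs(theta_s[::-1] - theta)) < 1e-6


class TestConfidenceInterval:
    def test_chi_square_threshold_value(self):
        assert chi2_delta(0.05) == pytest.approx(3.8415, abs=5e-5)

    def test_analytic_parabola(self):
        """PL = c + (th - th_hat)^2 / s: CI = th_hat +/- sqrt(Delta s / 2)."""
        c, th_hat, s = 2.0, 1.3, 0.07
        grid = np.linspace(0.3, 2.3, 40001)
        pl = c + (grid - th_hat) ** 2 / s
        (lo, hi), cls = confidence_interval(grid, pl, g_mle=c, alpha=0.05)
        half = np.sqrt(chi2_delta(0.05) * s / 2)
        assert cls == "identifiable"
        assert lo == pytest.approx(th_hat - half, abs=1e-8)
        assert hi == pytest.approx(th_hat + half, abs=1e-8)

    def test_flat_curve(self):
        grid = np.linspace(0, 1, 41)
        (lo, hi), cls = confidence_interval(grid, np.full(41, 1.0), 1.0)
        assert cls == "flat"
        assert lo == -np.inf and hi == np.inf

    def test_one_sided_curve(self):
        grid = np.linspace(0, 1, 101)
        pl = 5.0 * grid**2  # minimum at the left edge, rises past threshold
        (lo, hi), cls = confidence_interval(grid, pl, 0.0)
        assert cls == "one-sided"
        assert lo == -np.inf and np.isfinite(hi)

    def test_inconsistent_inputs_raise(self):
        grid = np.linspace(0, 1, 41)
        with pytest.raises(ValueError):
            confidence_interval(grid, np.full(41, 10.0), 0.0)


class TestProfiling:
    def test_gaussian_toy_ci_matches_normal_theory(self):
        """With Sigma = 2 sigma^2 the profile CI is theta_hat +/- 1.96 SE."""
        res = ProfileLikelihood(_predictor, DATA, DESIGN, prior=PRIOR,
                                config=CFG, weights=WEIGHTS).fit()
        z = 1.959964
        for i, nm in enumerate(("th1", "th2")):
            p = res.profiles[nm]
            assert p.identifiability == "identifiable"
            assert p.ci[0] == pytest.approx(TOY["theta_hat"][i] - z * TOY["se"][i],
                                            abs=2e-3)
            assert p.ci[1] == pytest.approx(TOY["theta_hat"][i] + z * TOY["se"][i],
                                            abs=2e-3)
            # profile bounded below by the global optimum
            assert np.nanmin(p.pl) >= res.g_mle - 1e-6

    def test_linear_toy_profile_is_exact_parabola(self):
        """Profiling th1 in the linear model: PL matches the analytic
        profiled residual sum of squares."""
        theta_mle, g_mle, _ = fit_mle(_predictor, DATA, DESIGN, PRIOR,
                                      config=CFG, weights=WEIGHTS)
        prof = profile_parameter(_predictor, DATA, DESIGN, PRIOR, "th1",
                                 theta_mle, g_mle, config=CFG, weights=WEIGHTS)
        x, y, w = TOY["x"], TOY["y"], TOY["weight"]
        for gv, pl in zip(prof.grid, prof.pl):
            # analytic: minimize over intercept at fixed slope
            b = np.mean(y - gv * x)
            rss = np.sum((y - gv * x - b) ** 2) / w
            assert pl == pytest.approx(rss, rel=1e-8, abs=1e-10)

    def test_inert_parameter_is_flat(self):
        """A parameter the model ignores has a flat profile."""

        def predictor(th):
            return {"y": TOY["model"](np.array([th[0], TOY["theta_hat"][1]]))[0]}

        res = ProfileLikelihood(predictor, DATA, DESIGN, prior=PRIOR,
                                config=CFG, weights=WEIGHTS).fit()
        assert res.profiles["th2"].identifiability == "flat"
        assert res.profiles["th1"].identifiability == "identifiable"

    def test_single_free_parameter_profile_is_slice(self):
        theta_mle, g_mle, _ = fit_mle(
            _predictor, DATA, DESIGN, PRIOR,
            fixed={"th2": TOY["theta_hat"][1]}, config=CFG, weights=WEIGHTS,
        )
        prof = profile_parameter(
            _predictor, DATA, DESIGN, PRIOR, "th1", theta_mle, g_mle,
            fixed={"th2": TOY["theta_hat"][1]}, config=CFG, weights=WEIGHTS,
        )
        for gv, pl in zip(prof.grid, prof.pl):
            th = theta_mle.copy()
            th[0] = gv
            direct = neg_log_likelihood(th, _predictor, DESIGN, DATA,
                                        weights=WEIGHTS)
            assert pl == pytest.approx(direct, rel=1e-10)

    def test_additional_signal_never_widens_ci(self):
        """Adding an informative second signal (D1 -> D3 analog) tightens
        or preserves the analytic CI."""
        design2 = DesignSpec("toy2", ("y", "y2"))
        rng = np.random.default_rng(11)
        y2 = TOY["model"](TOY["theta_true"])[0] + rng.normal(0, TOY["sigma"], 40)

        def predictor2(th):
            out = TOY["model"](th)[0]
            return {"y": out, "y2": out}

        w2 = {"y": TOY["weight"], "y2": TOY["weight"]}
        res1 = ProfileLikelihood(_predictor, DATA, DESIGN, prior=PRIOR,
                                 config=CFG, weights=WEIGHTS).fit()
        res2 = ProfileLikelihood(predictor2, {**DATA, "y2": y2}, design2,
                                 prior=PRIOR, config=CFG, weights=w2).fit()
        for nm in ("th1", "th2"):
            w1 = res1.profiles[nm].ci[1] - res1.profiles[nm].ci[0]
            w2_ = res2.profiles[nm].ci[1] - res2.profiles[nm].ci[0]
            assert w2_ <= w1 * 1.05

    def test_simulator_check_identity_for_exact_surrogate(self):
        theta_mle, g_mle, _ = fit_mle(_predictor, DATA, DESIGN, PRIOR,
                                      config=CFG, weights=WEIGHTS)
        prof = profile_parameter(_predictor, DATA, DESIGN, PRIOR, "th1",
                                 theta_mle, g_mle, config=CFG, weights=WEIGHTS)
        surr_curve, sim_curve = simulator_check(prof, DESIGN, DATA, _predictor,
                                                weights=WEIGHTS)
        ok = np.isfinite(surr_curve)
        assert np.allclose(surr_curve[ok], sim_curve[ok], rtol=1e-10)

    def test_workflow_ladder_with_inert_parameter(self):
        """Fixing an inert parameter at its inferred value leaves the other
        profile unchanged within optimizer tolerance."""
        from pulseuq.profile import profile_workflow

        def predictor(th):
            return {"y": TOY["model"](np.array([th[0], TOY["theta_hat"][1]]))[0]}

        out = profile_workflow(predictor, DATA, [DESIGN], [("th2",)],
                               prior=PRIOR, config=CFG)
        levels = out["toy"]
        assert len(levels) == 2
        assert set(levels[0].profiles) == {"th1", "th2"}
        assert set(levels[1].profiles) == {"th1"}
        p0 = levels[0].profiles["th1"]
        p1 = levels[1].profiles["th1"]
        assert p1.identifiability == "identifiable"
        assert np.allclose(p0.pl, p1.pl, rtol=1e-6, atol=1e-9)

    def test_simulator_check_with_biased_model(self):
        """A constant bias delta on the signal shifts the re-evaluated
        likelihood by the predictable Sigma-weighted amount."""
        theta_mle, g_mle, _ = fit_mle(_predictor, DATA, DESIGN, PRIOR,
                                      config=CFG, weights=WEIGHTS)
        prof = profile_parameter(_predictor, DATA, DESIGN, PRIOR, "th1",
                                 theta_mle, g_mle, config=CFG, weights=WEIGHTS)
        delta = 0.05

        def biased(th):
            return {"y": TOY["model"](th)[0] + delta}

        _, sim_curve = simulator_check(prof, DESIGN, DATA, biased,
                                       weights=WEIGHTS)
        # g_biased = g + (2 sum(r) delta + Nt delta^2) / w with r the
        # unbiased residual; verify at the profile minimum
        k = int(np.nanargmin(prof.pl))
        th = prof.theta_opt[k]
        r = DATA["y"] - TOY["model"](th)[0]
        expected = prof.pl[k] + (-2 * np.sum(r) * delta + 40 * delta**2) / TOY["weight"]
        assert sim_curve[k] == pytest.approx(expected, rel=1e-10)
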