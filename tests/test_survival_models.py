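"""Likelihoods, MLE fitting, quantiles, AIC and parameter covariance."""

import numpy as np
import pytest

from survineq import (
    PseudoIPD,
    TruthSpec,
    fit_mixture,
    fit_parametric,
    log_likelihood,
    parameter_covariance,
    quantile,
    simulate_trial,
    survival_at,
)
from survineq.exceptions import AllCensoredError, InputError
from tests.conftest import make_model


class TestLogLikelihood:
    def test_exponential_event_closed_form(self):
        ipd = PseudoIPD.from_records([10.0], [1])
        assert log_likelihood("exponential", (0.1,), ipd) == pytest.approx(
            np.log(0.1) - 1.0
        )

    def test_exponential_censored_closed_form(self):
        ipd = PseudoIPD.from_records([10.0], [0])
        assert log_likelihood("exponential", (0.1,), ipd) == pytest.approx(-1.0)

    def test_linear_in_weights(self, weibull_trial):
        base = log_likelihood("weibull", (1.4, 14.0), weibull_trial)
        doubled = PseudoIPD(
            time=weibull_trial.time,
            event=weibull_trial.event,
            weight=weibull_trial.weight * 2,
            study=weibull_trial.study,
            arm=weibull_trial.arm,
        )
        assert log_likelihood("weibull", (1.4, 14.0), doubled) == pytest.approx(
            2 * base
        )

    def test_invalid_density_rejected_not_crashed(self):
        ipd = PseudoIPD.from_records([1.0, 2.0], [1, 1])
        assert log_likelihood("weibull", (np.nan, 10.0), ipd) == -np.inf


class TestFitParametric:
    def test_exponential_closed_form_mle(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10.0, 100)
        t *= 1000.0 / t.sum()  # Σt = 1000 over n=100 → MLE rate 0.1
        fit = fit_parametric(
            PseudoIPD.from_records(t, np.ones(100, dtype=int)), "exponential"
        )
        assert fit.params_natural["rate"] == pytest.approx(0.1, rel=1e-5)
        assert fit.loglik == pytest.approx(100 * np.log(0.1) - 100, rel=1e-9)
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)

    def test_exponential_censored_closed_form(self):
        ipd = PseudoIPD.from_records([2.0, 4.0, 6.0], [1, 1, 0])
        fit = fit_parametric(ipd, "exponential")
        assert fit.params_natural["rate"] == pytest.approx(2.0 / 12.0, rel=1e-5)

    def test_matches_lifelines_weibull(self, weibull_trial):
        """Independent oracle: lifelines' WeibullFitter on the same data."""
        lifelines = pytest.importorskip("lifelines")
        fit = fit_parametric(weibull_trial, "weibull")
        wf = lifelines.WeibullFitter().fit(weibull_trial.time, weibull_trial.event)
        assert fit.params_natural["scale"] == pytest.approx(wf.lambda_, rel=1e-4)
        assert fit.params_natural["shape"] == pytest.approx(wf.rho_, rel=1e-4)
        assert fit.loglik == pytest.approx(wf.log_likelihood_, rel=1e-6)

    def test_all_censored_rejected(self):
        ipd = PseudoIPD.from_records([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(AllCensoredError):
            fit_parametric(ipd, "exponential")

    def test_mixture_family_rejected(self, weibull_trial):
        with pytest.raises(InputError):
            fit_parametric(weibull_trial, "gamma+weibull")


class TestFitMixture:
    def test_nests_single_family(self, weibull_trial):
        """A 2-component mixture can never fit worse than its component."""
        single = fit_parametric(weibull_trial, "weibull")
        mixture = fit_mixture(weibull_trial, "weibull+weibull", n_starts=4, seed=0)
        assert mixture.loglik >= single.loglik - 1e-3

    def test_component_order_by_median(self):
        spec = TruthSpec(
            family="lognormal+lognormal",
            params={"mix_weight": 0.6, "c1_meanlog": 1.5, "c1_sdlog": 0.4,
                    "c2_meanlog": 3.0, "c2_sdlog": 0.3},
            n=3000, accrual_months=0.0, followup_months=200.0, seed=9,
        )
        fit = fit_mixture(simulate_trial(spec), "lognormal+lognormal",
                          n_starts=4, seed=1)
        assert fit.params_natural["c1_meanlog"] < fit.params_natural["c2_meanlog"]

    def test_near_degenerate_mixture_reduces_to_component(self, weibull_trial):
        """π≈1 → the mixture survival equals component 1's everywhere."""
        fit = fit_mixture(weibull_trial, "weibull+weibull", n_starts=4, seed=0)
        pi = fit.params_natural["mix_weight"]
        forced = make_model(
            "weibull+weibull",
            mix_weight=1.0 - 1e-9,
            c1_shape=fit.params_natural["c1_shape"],
            c1_scale=fit.params_natural["c1_scale"],
            c2_shape=2.0,
            c2_scale=50.0,
        )
        component = make_model("weibull", shape=fit.params_natural["c1_shape"],
                               scale=fit.params_natural["c1_scale"])
        t = np.linspace(0.0, 60.0, 61)
        np.testing.assert_allclose(
            survival_at(forced, t), survival_at(component, t), atol=1e-4
        )
        assert 0.0 < pi < 1.0

    def test_bad_n_starts_rejected(self, weibull_trial):
        with pytest.raises(InputError):
            fit_mixture(weibull_trial, "weibull+weibull", n_starts=0)


class TestSurvivalAndQuantile:
    def test_exponential_survival(self):
        model = make_model("exponential", rate=0.1)
        assert survival_at(model, 10.0) == pytest.approx(np.exp(-1))

    def test_weibull_survival(self):
        model = make_model("weibull", shape=2.0, scale=10.0)
        assert survival_at(model, 10.0) == pytest.approx(np.exp(-1))

    def test_survival_at_zero_is_one(self):
        for model in (make_model("gamma", shape=2.0, rate=0.3),
                      make_model("gamma+weibull", mix_weight=0.4, c1_shape=2.0,
                                 c1_rate=0.3, c2_shape=1.3, c2_scale=20.0)):
            assert survival_at(model, 0.0) == pytest.approx(1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(InputError):
            survival_at(make_model("exponential", rate=0.1), -1.0)

    def test_exponential_median(self):
        model = make_model("exponential", rate=np.log(2) / 12.0)
        assert quantile(model, 0.5) == pytest.approx(12.0)

    def test_mixture_quantile_inverse_contract(self):
        model = make_model("gamma+weibull", mix_weight=0.35, c1_shape=2.2,
                           c1_rate=0.28, c2_shape=1.3, c2_scale=40.0)
        for p in (0.1, 0.3, 0.5, 0.7, 0.9):
            t = quantile(model, p)
            assert survival_at(model, t) == pytest.approx(1.0 - p, abs=1e-8)

    def test_improper_gompertz_quantile_non_evaluable(self):
        model = make_model("gompertz", shape=-0.05, rate=0.01)
        assert np.isnan(quantile(model, 0.5))

    def test_probability_domain_enforced(self):
        model = make_model("exponential", rate=0.1)
        for p in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(InputError):
                quantile(model, p)


class TestAICAndCovariance:
    def test_aic_definition(self):
        model = make_model("exponential", rate=0.1)
        model.loglik = -330.2585092994046  # 100·ln(0.1) − 100
        assert model.aic == pytest.approx(662.5170185988092)

    def test_exponential_log_rate_variance_is_one_over_n(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(8.0, 100)
        ipd = PseudoIPD.from_records(t, np.ones(100, dtype=int))
        fit = fit_parametric(ipd, "exponential")
        cov = parameter_covariance(fit, ipd)
        assert cov[0, 0] == pytest.approx(0.01, rel=1e-3)

    def test_covariance_shrinks_like_one_over_n(self):
        rng = np.random.default_rng(8)
        t = rng.weibull(1.5, 4000) * 10.0
        small = PseudoIPD.from_records(t[:1000], np.ones(1000, dtype=int))
        large = PseudoIPD.from_records(t, np.ones(4000, dtype=int))
        cov_small = parameter_covariance(fit_parametric(small, "weibull"), small)
        cov_large = parameter_covariance(fit_parametric(large, "weibull"), large)
        ratio = np.diag(cov_small) / np.diag(cov_large)
        assert np.all(ratio > 2.5) and np.all(ratio < 6.0)

    def test_covariance_symmetric(self, weibull_trial):
        fit = fit_parametric(weibull_trial, "gamma")
        cov = parameter_covariance(fit, weibull_trial)
        np.testing.assert_allclose(cov, cov.T, atol=1e-10)

    def test_model_json_round_trip(self, tmp_path, weibull_trial):
        from survineq.io import read_model, write_model

        fit = fit_parametric(weibull_trial, "weibull")
        parameter_covariance(fit, weibull_trial)
        write_model(fit, tmp_path / "m.json")
        back = read_model(tmp_path / "m.json")
        assert back.family == fit.family
        assert back.params_natural == pytest.approx(fit.params_natural)
        np.testing.assert_allclose(back.cov_transformed, fit.cov_transformed)
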