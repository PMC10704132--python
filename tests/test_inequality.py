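"""Health distributions, inequality metrics and impact arithmetic."""

import numpy as np
import pytest

from survineq import (
    HealthDistribution,
    InequalitySummary,
    health_distribution,
    inequality_absolute,
    inequality_gradient,
    inequality_impact,
    inequality_summary,
)
from survineq.exceptions import InputError
from tests.conftest import make_model

EXP_MODEL = make_model("exponential", rate=0.1)


class TestHealthDistribution:
    def test_exponential_five_groups_closed_form(self):
        """Group medians are -ln(1-p)/λ at p = .1,.3,.5,.7,.9."""
        hd = health_distribution(EXP_MODEL, 5)
        np.testing.assert_allclose(
            hd.medians, [1.05361, 3.56675, 6.93147, 12.03973, 23.02585], atol=1e-5
        )
        assert np.all(hd.evaluable)

    def test_exponential_two_groups_closed_form(self):
        hd = health_distribution(EXP_MODEL, 2)
        np.testing.assert_allclose(hd.medians, [2.87682, 13.86294], atol=1e-5)

    def test_middle_group_is_overall_median(self):
        for model in (EXP_MODEL,
                      make_model("weibull", shape=1.7, scale=14.0),
                      make_model("gamma+weibull", mix_weight=0.6, c1_shape=2.0,
                                 c1_rate=0.25, c2_shape=1.3, c2_scale=30.0)):
            hd = health_distribution(model, 5)
            from survineq import quantile

            assert hd.medians[2] == pytest.approx(quantile(model, 0.5), rel=1e-8)

    def test_improper_model_flags_not_fabricates(self):
        hd = health_distribution(make_model("gompertz", shape=-0.05, rate=0.01), 5)
        assert not np.all(hd.evaluable)
        assert np.isnan(hd.medians[~hd.evaluable]).all()

    def test_too_few_groups_rejected(self):
        with pytest.raises(InputError):
            health_distribution(EXP_MODEL, 1)

    def test_empirical_block_median_oracle(self):
        """Sorted simulated times split into G blocks reproduce the medians."""
        rng = np.random.default_rng(99)
        t = np.sort(rng.exponential(10.0, 100_000))
        for g in (2, 5):
            blocks = np.array_split(t, g)
            empirical = np.array([np.median(b) for b in blocks])
            hd = health_distribution(EXP_MODEL, g)
            np.testing.assert_allclose(empirical, hd.medians, rtol=0.01)


class TestInequalityMetrics:
    def test_absolute_five_group_ln9(self):
        hd = health_distribution(EXP_MODEL, 5)
        assert inequality_absolute(hd) == pytest.approx(np.log(9) / 0.1, abs=1e-5)

    def test_absolute_two_group_ln3(self):
        hd = health_distribution(EXP_MODEL, 2)
        assert inequality_absolute(hd) == pytest.approx(np.log(3) / 0.1, abs=1e-5)

    def test_degenerate_distribution_zero(self):
        hd = HealthDistribution(n_groups=5, medians=np.full(5, 7.0),
                                evaluable=np.ones(5, dtype=bool))
        assert inequality_absolute(hd) == 0.0
        assert inequality_gradient(hd) == 0.0

    def test_gradient_exact_linear(self):
        hd = HealthDistribution(n_groups=5, medians=np.array([1., 2., 3., 4., 5.]),
                                evaluable=np.ones(5, dtype=bool))
        assert inequality_gradient(hd) == pytest.approx(1.0)

    def test_gradient_exponential_closed_form(self):
        hd = health_distribution(EXP_MODEL, 5)
        assert inequality_gradient(hd) == pytest.approx(5.24175, abs=1e-5)

    def test_gradient_requires_five_groups(self):
        with pytest.raises(InputError):
            inequality_gradient(health_distribution(EXP_MODEL, 2))

    def test_non_evaluable_propagates(self):
        hd = HealthDistribution(
            n_groups=5,
            medians=np.array([1.0, 2.0, 3.0, 4.0, np.nan]),
            evaluable=np.array([True, True, True, True, False]),
        )
        assert np.isnan(inequality_absolute(hd))
        assert np.isnan(inequality_gradient(hd))

    def test_scale_equivariance(self):
        """Times in weeks instead of months scale every metric by the same c."""
        base = make_model("weibull", shape=1.6, scale=12.0)
        scaled = make_model("weibull", shape=1.6, scale=12.0 * 4.345)
        for g in (2, 5):
            hd0 = health_distribution(base, g)
            hd1 = health_distribution(scaled, g)
            np.testing.assert_allclose(hd1.medians, 4.345 * hd0.medians, rtol=1e-8)
        assert inequality_gradient(health_distribution(scaled, 5)) == pytest.approx(
            4.345 * inequality_gradient(health_distribution(base, 5)), rel=1e-8
        )

    def test_uniform_hazard_ratio_widens_inequality(self):
        """A uniform HR<1 on a Weibull baseline strictly raises the 5-group
        inequality — the rationale for not modeling relative effects."""
        shape, scale = 1.4, 15.0
        baseline = make_model("weibull", shape=shape, scale=scale)
        hr = 0.7  # S_new = S^hr → Weibull scale divided by hr^{1/shape}
        treated = make_model("weibull", shape=shape,
                             scale=scale / hr ** (1.0 / shape))
        base_ineq = inequality_absolute(health_distribution(baseline, 5))
        new_ineq = inequality_absolute(health_distribution(treated, 5))
        assert new_ineq > base_ineq

    def test_gradient_bounded_by_half_range_for_convex_quantiles(self):
        """IG ≤ (5-group inequality)/2 when the quantile function is convex."""
        for model in (EXP_MODEL,
                      make_model("weibull", shape=1.2, scale=10.0),
                      make_model("loglogistic", shape=1.8, scale=9.0)):
            hd = health_distribution(model, 5)
            assert inequality_gradient(hd) <= inequality_absolute(hd) / 2 + 1e-9


class TestImpact:
    def test_five_group_worked_example(self):
        """23.7 vs 17.0 months → +6.7 absolute, +39.4% relative."""
        s_int = InequalitySummary(absolute_inequality=23.7, n_groups=5, gradient=5.5)
        s_comp = InequalitySummary(absolute_inequality=17.0, n_groups=5, gradient=3.9)
        impacts = inequality_impact(s_int, s_comp)
        assert impacts["5-group"].absolute_change == pytest.approx(6.7)
        assert impacts["5-group"].relative_change == pytest.approx(100 * 6.7 / 17.0)
        assert impacts["IG"].absolute_change == pytest.approx(1.6)

    def test_self_comparison_is_zero(self):
        s = inequality_summary(health_distribution(EXP_MODEL, 5))
        impacts = inequality_impact(s, s)
        assert impacts["5-group"].absolute_change == 0.0
        assert impacts["5-group"].relative_change == 0.0
        assert impacts["IG"].absolute_change == 0.0

    def test_zero_comparator_relative_non_evaluable(self):
        s_int = InequalitySummary(absolute_inequality=3.0, n_groups=2)
        s_comp = InequalitySummary(absolute_inequality=0.0, n_groups=2)
        impact = inequality_impact(s_int, s_comp)["2-group"]
        assert impact.absolute_change == pytest.approx(3.0)
        assert np.isnan(impact.relative_change)

    def test_mismatched_groups_rejected(self):
        with pytest.raises(InputError):
            inequality_impact(
                InequalitySummary(absolute_inequality=1.0, n_groups=2),
                InequalitySummary(absolute_inequality=1.0, n_groups=5),
            )
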