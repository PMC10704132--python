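"""Threshold gate, combined-AIC ranking and selection determinism."""

import numpy as np
import pytest

from survineq import SelectionConfig, extrapolation_threshold, select_family
from survineq.exceptions import InputError, NoAdmissibleFamily
from tests.conftest import make_model


def fake_fit(family, aic_value, **params):
    model = make_model(family, **params)
    model.loglik = (2 * model.k - aic_value) / 2.0  # so model.aic == aic_value
    return model


class TestThreshold:
    def test_breast_cancer_threshold(self):
        cfg = SelectionConfig(seer_rate=0.148, uplift=0.10)
        assert extrapolation_threshold(cfg) == pytest.approx(0.1628)

    def test_lung_cancer_threshold(self):
        cfg = SelectionConfig(seer_rate=0.033, uplift=0.10)
        assert extrapolation_threshold(cfg) == pytest.approx(0.0363)

    def test_zero_uplift_identity(self):
        cfg = SelectionConfig(seer_rate=0.2, uplift=0.0)
        assert extrapolation_threshold(cfg) == pytest.approx(0.2)

    def test_threshold_above_one_rejected(self):
        with pytest.raises(InputError):
            SelectionConfig(seer_rate=0.95, uplift=0.10)


class TestSelectFamily:
    def exp_with_s120(self, s120, aic_value):
        rate = -np.log(s120) / 120.0
        return fake_fit("exponential", aic_value, rate=rate)

    def test_exceeding_threshold_excluded(self):
        """S(120)=0.20 > 0.1628 is excluded; S(120)=0.10 is admissible."""
        cfg = SelectionConfig(seer_rate=0.148, uplift=0.10)
        fits_int = {"exponential": self.exp_with_s120(0.20, 1000.0),
                    "weibull": fake_fit("weibull", 1010.0, shape=1.5, scale=25.0)}
        fits_comp = {"exponential": self.exp_with_s120(0.10, 1000.0),
                     "weibull": fake_fit("weibull", 1010.0, shape=1.5, scale=22.0)}
        result = select_family(fits_int, fits_comp, cfg)
        audit = result.audit_for("exponential")
        assert not audit.admissible
        assert "threshold" in audit.reason
        assert result.selected == "weibull"

    def test_lowest_combined_aic_wins(self):
        cfg = SelectionConfig(seer_rate=0.148)
        fits_int = {"weibull": fake_fit("weibull", 645.0, shape=1.5, scale=20.0),
                    "lognormal": fake_fit("lognormal", 650.0, meanlog=2.5, sdlog=0.8)}
        fits_comp = {"weibull": fake_fit("weibull", 645.0, shape=1.5, scale=18.0),
                     "lognormal": fake_fit("lognormal", 645.0, meanlog=2.4, sdlog=0.8)}
        result = select_family(fits_int, fits_comp, cfg)
        assert result.selected == "weibull"  # combined 1290 < 1295

    def test_tie_breaks_by_parameter_count_then_name(self):
        cfg = SelectionConfig(seer_rate=0.148)
        fits_int = {"exponential": self.exp_with_s120(0.05, 500.0),
                    "weibull": fake_fit("weibull", 500.0, shape=1.2, scale=15.0)}
        fits_comp = {"exponential": self.exp_with_s120(0.05, 500.0),
                     "weibull": fake_fit("weibull", 500.0, shape=1.2, scale=15.0)}
        assert select_family(fits_int, fits_comp, cfg).selected == "exponential"

    def test_no_admissible_family_lists_reasons(self):
        cfg = SelectionConfig(seer_rate=0.033, uplift=0.10)
        fits = {"exponential": self.exp_with_s120(0.30, 100.0)}
        with pytest.raises(NoAdmissibleFamily) as err:
            select_family(fits, fits, cfg)
        assert "exponential" in err.value.reasons

    def test_improper_extrapolation_gated(self):
        """A plateau above a required group median is inadmissible."""
        cfg = SelectionConfig(seer_rate=0.148, groups=(2, 5),
                              require_evaluable_quantiles=True)
        # plateau e^{-2.04} ≈ 0.130: clears the 0.1628 threshold but sits
        # above the 0.1 survival level of the top-quintile median
        improper = fake_fit("gompertz", 400.0, shape=-0.05, rate=0.102)
        proper = fake_fit("weibull", 500.0, shape=1.4, scale=16.0)
        result = select_family(
            {"gompertz": improper, "weibull": proper},
            {"gompertz": improper, "weibull": proper},
            cfg,
        )
        assert result.selected == "weibull"
        assert "not evaluable" in result.audit_for("gompertz").reason

    def test_uplift_monotonicity(self):
        """Raising the uplift never shrinks the admissible set."""
        fits = {"exponential": self.exp_with_s120(0.17, 100.0),
                "weibull": fake_fit("weibull", 120.0, shape=1.5, scale=25.0)}
        admissible = {}
        for uplift in (0.0, 0.10, 0.20, 0.40):
            cfg = SelectionConfig(seer_rate=0.148, uplift=uplift)
            try:
                result = select_family(fits, fits, cfg)
                admissible[uplift] = {a.family for a in result.audits if a.admissible}
            except NoAdmissibleFamily:
                admissible[uplift] = set()
        uplifts = sorted(admissible)
        for lo, hi in zip(uplifts, uplifts[1:]):
            assert admissible[lo] <= admissible[hi]

    def test_deterministic(self):
        cfg = SelectionConfig(seer_rate=0.148)
        fits_int = {"weibull": fake_fit("weibull", 645.0, shape=1.5, scale=20.0),
                    "lognormal": fake_fit("lognormal", 650.0, meanlog=2.5, sdlog=0.8)}
        fits_comp = {"weibull": fake_fit("weibull", 644.0, shape=1.5, scale=18.0),
                     "lognormal": fake_fit("lognormal", 646.0, meanlog=2.4, sdlog=0.8)}
        first = select_family(fits_int, fits_comp, cfg)
        second = select_family(fits_int, fits_comp, cfg)
        assert first.to_dict() == second.to_dict()

    def test_mismatched_candidate_sets_rejected(self):
        cfg = SelectionConfig(seer_rate=0.148)
        with pytest.raises(InputError, match="same families"):
            select_family(
                {"weibull": fake_fit("weibull", 10.0, shape=1.0, scale=10.0)},
                {"exponential": fake_fit("exponential", 10.0, rate=0.1)},
                cfg,
            )

    def test_veto_list_excludes(self):
        cfg = SelectionConfig(seer_rate=0.148, veto=("weibull",))
        fits = {"weibull": fake_fit("weibull", 100.0, shape=1.5, scale=20.0),
                "lognormal": fake_fit("lognormal", 200.0, meanlog=2.5, sdlog=0.8)}
        assert select_family(fits, fits, cfg).selected == "lognormal"
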