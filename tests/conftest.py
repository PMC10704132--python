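import numpy as np
import pytest

from survineq import FittedModel, PseudoIPD, TruthSpec, simulate_trial
from survineq.families import get_family


def make_model(family: str, cov_scale: float | None = None, **params) -> FittedModel:
    """Build a FittedModel directly from known parameters (no fitting)."""
    fam = get_family(family)
    values = tuple(params[name] for name in fam.param_names)
    transformed = fam.to_transformed(values)
    cov = None
    if cov_scale is not None:
        cov = np.eye(fam.n_params) * cov_scale
    return FittedModel(
        family=family,
        params_natural={n: float(v) for n, v in zip(fam.param_names, values)},
        params_transformed=transformed,
        loglik=0.0,
        k=fam.n_params,
        cov_transformed=cov,
    )


@pytest.fixture
def toy_curve():
    """Five subjects, all events: KM (0,1)→(1,.8)→(2,.4)→(3,0)."""
    from survineq.pseudo_ipd import DigitizedCurve

    return DigitizedCurve(
        coordinates=[[0, 1.0], [1, 0.8], [2, 0.4], [3, 0.0]],
        risk_table=[[0, 5]],
        study_label="toy",
    )


@pytest.fixture(scope="session")
def weibull_trial():
    """A censored Weibull trial with known truth (shape 1.4, scale 14, n=300)."""
    spec = TruthSpec(
        family="weibull",
        params={"shape": 1.4, "scale": 14.0},
        n=300,
        accrual_months=12.0,
        followup_months=36.0,
        dropout_rate=0.012,
        seed=20240915,
        study_label="weib_trial",
    )
    return simulate_trial(spec)


@pytest.fixture(scope="session")
def exp_ipd():
    """Large uncensored exponential sample, rate 0.1."""
    rng = np.random.default_rng(11)
    t = rng.exponential(10.0, size=10_000)
    return PseudoIPD.from_records(time=t, event=np.ones(t.size, dtype=int))
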