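"""Trial-like synthetic survival data with known truth.

Emulates the inputs the pipeline normally gets from published trial
figures: right-censored time-to-event records drawn from a known parametric
(or two-component mixture) model, subject to uniform-accrual administrative
censoring plus exponential dropout, and "digitized" KM curves with a
numbers-at-risk table at regular intervals. Because the generating model is
known, every downstream stage can be validated against exact truth.

What this generator does *not* emulate: digitization pixel noise (curve
coordinates are exact step values) and covariate-dependent censoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError
from .families import get_family
from .pseudo_ipd import DigitizedCurve, PseudoIPD, km_estimate

__all__ = ["TruthSpec", "simulate_trial", "digitize"]


@dataclass(frozen=True)
class TruthSpec:
    """Generating model and trial design for one simulated arm.

    ``accrual_months`` is the uniform enrolment window; a subject accrued at
    a is administratively censored at ``followup_months`` - a after
    randomization. ``dropout_rate`` is an exponential loss-to-follow-up
    hazard per month (0 disables dropout).
    """

    family: str
    params: dict[str, float]
    n: int
    accrual_months: float = 12.0
    followup_months: float = float("inf")
    dropout_rate: float = 0.0
    seed: int = 0
    study_label: str = "sim"
    arm_label: str = "intervention"
    outcome_label: str = "OS"

    def __post_init__(self):
        if self.n < 1:
            raise InputError("n must be ≥ 1")
        if self.followup_months <= 0:
            raise InputError("follow-up end must be positive")
        if self.dropout_rate < 0:
            raise InputError("dropout rate must be nonnegative")
        if self.accrual_months < 0:
            raise InputError("accrual window must be nonnegative")
        if np.isfinite(self.followup_months) and self.accrual_months >= self.followup_months:
            raise InputError("accrual window must end before follow-up ends")

    @property
    def param_values(self) -> tuple[float, ...]:
        fam = get_family(self.family)
        return tuple(self.params[name] for name in fam.param_names)


def simulate_trial(spec: TruthSpec) -> PseudoIPD:
    """Draw one arm of right-censored records from a truth specification.

    Event times come from the truth model by inversion (uniform draws
    through the quantile function; draws beyond an improper plateau never
    fail, they are censored). Censoring is the minimum of the
    administrative time implied by uniform accrual and an exponential
    dropout time; the observed time is the smaller of event and censoring,
    with ties resolved as events.
    """
    fam = get_family(spec.family)
    params = spec.param_values
    rng = np.random.default_rng(spec.seed)

    u = rng.uniform(size=spec.n)
    with np.errstate(all="ignore"):
        t_event = np.asarray(fam.ppf(u, params), dtype=float)
    t_event = np.where(np.isfinite(t_event), t_event, np.inf)  # improper plateau

    if spec.accrual_months > 0:
        accrual = rng.uniform(0.0, spec.accrual_months, size=spec.n)
    else:
        accrual = np.zeros(spec.n)
    if np.isfinite(spec.followup_months):
        admin = spec.followup_months - accrual
    else:
        admin = np.full(spec.n, np.inf)
    if spec.dropout_rate > 0:
        dropout = rng.exponential(1.0 / spec.dropout_rate, size=spec.n)
    else:
        dropout = np.full(spec.n, np.inf)
    censor = np.minimum(admin, dropout)

    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    if np.any(~np.isfinite(time)):
        raise InputError(
            "some subjects have neither an event nor a censoring time; "
            "set a finite follow-up or a positive dropout rate"
        )
    time = np.maximum(time, 1e-9)
    return PseudoIPD.from_records(
        time=time,
        event=event,
        study=spec.study_label,
        arm=spec.arm_label,
    )


def digitize(ipd: PseudoIPD, risk_interval: float = 6.0,
             outcome_label: str = "OS") -> DigitizedCurve:
    """Turn simulated records into the published-figure representation.

    Coordinates are the exact KM step values at every event time; the
    numbers-at-risk table is read off at multiples of ``risk_interval``
    (the at-risk count at τ is the number of records with time ≥ τ);
    ``total_events`` is recorded as published articles often do.
    """
    if risk_interval <= 0:
        raise InputError("risk interval must be positive")
    studies = set(ipd.study.tolist())
    arms = set(ipd.arm.tolist())
    if len(studies) != 1 or len(arms) != 1:
        raise InputError("digitize expects records from a single study and arm")
    if not np.allclose(ipd.weight, 1.0):
        raise InputError("digitize expects unit weights")

    km = km_estimate(ipd)
    coords = np.vstack(
        [np.array([[0.0, 1.0]]), np.column_stack([km.times, km.survival])]
    )
    max_time = float(np.max(ipd.time))
    n_ticks = int(np.floor(max_time / risk_interval + 1e-9)) + 1
    tick_times = np.arange(n_ticks) * risk_interval
    at_risk = np.array([np.sum(ipd.time >= tau) for tau in tick_times])
    keep = at_risk > 0
    keep[0] = True
    risk_table = np.column_stack([tick_times[keep], at_risk[keep]])
    return DigitizedCurve(
        coordinates=coords,
        risk_table=risk_table,
        total_events=int(np.sum(ipd.event)),
        study_label=str(studies.pop()),
        arm_label=str(arms.pop()),
        outcome_label=outcome_label,
    )
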