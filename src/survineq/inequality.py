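"""Health distributions and survival-inequality metrics.

A fitted survival curve for one arm is stratified into G equally sized
patient groups, ordered from lowest to highest survival. For a continuous
distribution, the median survival of the k-th group (the patients between
the (k-1)/G and k/G event-time quantiles) is exactly the event-time
quantile at probability (2k-1)/(2G); the ordered group medians form the
arm's *health distribution*. Three summary metrics follow:

- **absolute inequality** — highest minus lowest group median (for the
  2-group and 5-group stratifications);
- **inequality gradient (IG)** — the ordinary-least-squares slope of the
  five group medians against the group index 1…5, in months per group;
- **impact** — intervention minus comparator for each metric, in absolute
  months and as a percentage of the comparator.

Group medians are read from the fitted parametric model, not from the
within-follow-up KM curve: the top group's median typically lies beyond
observed follow-up, which is the reason parametric extrapolation is needed
in the first place. Non-evaluable quantiles (improper extrapolations)
propagate as NaN and are flagged, never capped at a horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InputError
from .survival_models import FittedModel, quantile

__all__ = [
    "HealthDistribution",
    "InequalitySummary",
    "ImpactResult",
    "health_distribution",
    "inequality_absolute",
    "inequality_gradient",
    "inequality_summary",
    "inequality_impact",
    "group_probabilities",
]


def group_probabilities(n_groups: int) -> np.ndarray:
    """Event-time probabilities (2k-1)/(2G) of the G group medians."""
    if n_groups < 2:
        raise InputError("need at least 2 groups")
    k = np.arange(1, n_groups + 1)
    return (2 * k - 1) / (2 * n_groups)


@dataclass
class HealthDistribution:
    """Ordered group medians for a G-group stratification of one arm."""

    n_groups: int
    medians: np.ndarray
    evaluable: np.ndarray

    def __post_init__(self):
        self.medians = np.asarray(self.medians, dtype=float)
        self.evaluable = np.asarray(self.evaluable, dtype=bool)
        if self.medians.shape != (self.n_groups,):
            raise InputError("medians must have one entry per group")
        finite = self.medians[self.evaluable]
        if finite.size > 1 and np.any(np.diff(finite) < -1e-9):
            raise InputError("group medians must be non-decreasing")

    def to_dict(self) -> dict:
        return {
            "n_groups": self.n_groups,
            "medians": [None if not ok else float(m)
                        for m, ok in zip(self.medians, self.evaluable)],
        }


@dataclass
class InequalitySummary:
    """Absolute inequality (and, for G=5, the IG) of one health distribution."""

    absolute_inequality: float
    n_groups: int
    gradient: float | None = None

    def to_dict(self) -> dict:
        return {
            "absolute_inequality": self.absolute_inequality,
            "n_groups": self.n_groups,
            "gradient": self.gradient,
        }


@dataclass
class ImpactResult:
    """Intervention-vs-comparator change in one inequality metric."""

    metric: str
    intervention: float
    comparator: float

    @property
    def absolute_change(self) -> float:
        return self.intervention - self.comparator

    @property
    def relative_change(self) -> float:
        """Percent change relative to the comparator; NaN if comparator is 0."""
        if self.comparator == 0:
            return math.nan
        return 100.0 * self.absolute_change / self.comparator

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "intervention": self.intervention,
            "comparator": self.comparator,
            "absolute_change": self.absolute_change,
            "relative_change": self.relative_change,
        }


def health_distribution(model: FittedModel, n_groups: int) -> HealthDistribution:
    """Group medians of a fitted model for a G-group stratification.

    Group 1 holds the patients with the lowest survival; its median is the
    1/(2G) event-time quantile. Non-evaluable quantiles are flagged.
    """
    probs = group_probabilities(n_groups)
    medians = np.asarray(quantile(model, probs), dtype=float)
    evaluable = np.isfinite(medians)
    return HealthDistribution(n_groups=n_groups, medians=medians, evaluable=evaluable)


def inequality_absolute(hd: HealthDistribution) -> float:
    """Highest minus lowest group median; NaN if either is non-evaluable."""
    if not (hd.evaluable[0] and hd.evaluable[-1]):
        return math.nan
    return float(hd.medians[-1] - hd.medians[0])


def inequality_gradient(hd: HealthDistribution) -> float:
    """OLS slope of the five group medians on the group index 1…5.

    Equal to Σ_k (k-3)·median_k / 10 in months per group step. Defined only
    for the 5-group stratification; NaN if any group is non-evaluable.
    """
    if hd.n_groups != 5:
        raise InputError("the inequality gradient is defined for 5 groups")
    if not np.all(hd.evaluable):
        return math.nan
    k = np.arange(1, 6)
    return float(np.sum((k - 3) * hd.medians) / 10.0)


def inequality_summary(hd: HealthDistribution) -> InequalitySummary:
    """Absolute inequality plus, for G=5, the inequality gradient."""
    gradient = inequality_gradient(hd) if hd.n_groups == 5 else None
    return InequalitySummary(
        absolute_inequality=inequality_absolute(hd),
        n_groups=hd.n_groups,
        gradient=gradient,
    )


def inequality_impact(
    summary_int: InequalitySummary, summary_comp: InequalitySummary
) -> dict[str, ImpactResult]:
    """Intervention-vs-comparator impact for each metric both sides carry.

    Returns a mapping with key ``"{G}-group"`` for the absolute inequality
    and, when both summaries are 5-group with gradients, key ``"IG"``.
    """
    if summary_int.n_groups != summary_comp.n_groups:
        raise InputError("summaries must use the same number of groups")
    g = summary_int.n_groups
    impacts = {
        f"{g}-group": ImpactResult(
            metric=f"{g}-group",
            intervention=summary_int.absolute_inequality,
            comparator=summary_comp.absolute_inequality,
        )
    }
    if summary_int.gradient is not None and summary_comp.gradient is not None:
        impacts["IG"] = ImpactResult(
            metric="IG",
            intervention=summary_int.gradient,
            comparator=summary_comp.gradient,
        )
    return impacts
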