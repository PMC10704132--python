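"""Pseudo individual-patient data from published Kaplan-Meier curves.

Published trial reports rarely ship patient-level time-to-event data, but
they do ship the KM curve and a numbers-at-risk table. This module inverts
the product-limit recursion interval by interval (the standard
curve-reconstruction approach): within each risk-table interval a censoring
count is proposed, censoring times are spread uniformly over the interval,
event counts at each digitized step are recovered from the survival drops,
and the censoring count is adjusted until the reconstructed at-risk count
matches the published one at the next risk-table time. The result is one
(time, event) record per original subject.

Conventions:

- ties at identical times are resolved events-before-censorings, matching
  the product-limit estimator itself (required for exact round trips);
- the numbers-at-risk count at time τ means subjects with observed time ≥ τ;
- when the risk table has a single entry (initial sample size only), no
  dropout censoring is assumed before the last digitized coordinate and the
  remaining subjects are administratively censored there, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InconsistentRiskTable, InputError

__all__ = [
    "DigitizedCurve",
    "PseudoIPD",
    "StepEstimate",
    "ValidationReport",
    "km_estimate",
    "reconstruct_ipd",
    "validate_reconstruction",
]


@dataclass(frozen=True)
class DigitizedCurve:
    """Published KM coordinates plus numbers-at-risk for one arm/outcome.

    ``coordinates`` is an (K+1, 2) array of (time, survival) starting at
    (0, 1); ``risk_table`` is an (I, 2) array of (time, at-risk count).
    """

    coordinates: np.ndarray
    risk_table: np.ndarray
    total_events: int | None = None
    study_label: str = "study"
    arm_label: str = "intervention"
    outcome_label: str = "OS"

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        risk = np.atleast_2d(np.asarray(self.risk_table, dtype=float))
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "risk_table", risk)
        if coords.shape[1] != 2 or risk.shape[1] != 2:
            raise InputError("coordinates and risk_table must be two-column arrays")
        t, s = coords[:, 0], coords[:, 1]
        if not (t[0] == 0.0 and abs(s[0] - 1.0) < 1e-12):
            raise InputError("first coordinate must be (0, 1)")
        if np.any(np.diff(t) <= 0):
            raise InputError("coordinate times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise InputError("survival coordinates must be non-increasing")
        if np.any((s < -1e-12) | (s > 1 + 1e-12)):
            bad = int(np.argmax((s < -1e-12) | (s > 1 + 1e-12)))
            raise InputError(
                f"survival must lie in [0, 1]; row {bad} has survival {s[bad]}"
            )
        if risk.shape[0] < 1:
            raise InputError("risk table needs at least one entry")
        if np.any(np.diff(risk[:, 0]) <= 0):
            raise InputError("risk-table times must be strictly increasing")
        if np.any(np.diff(risk[:, 1]) > 0):
            raise InputError("risk-table counts must be non-increasing")
        if risk[0, 0] != 0.0:
            raise InputError("risk table must start at time 0")
        if risk[0, 1] < 1:
            raise InputError("initial at-risk count must be ≥ 1")
        if self.total_events is not None and self.total_events < 0:
            raise InputError("total_events must be nonnegative")

    @property
    def n_initial(self) -> int:
        return int(round(self.risk_table[0, 1]))


@dataclass
class PseudoIPD:
    """Weighted right-censored records, possibly pooled across studies."""

    time: np.ndarray
    event: np.ndarray
    weight: np.ndarray
    study: np.ndarray
    arm: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.weight = np.asarray(self.weight, dtype=float)
        self.study = np.asarray(self.study, dtype=object)
        self.arm = np.asarray(self.arm, dtype=object)
        n = self.time.shape[0]
        if n == 0:
            raise InputError("pseudo-IPD must contain at least one record")
        for name, arr in (("event", self.event), ("weight", self.weight),
                          ("study", self.study), ("arm", self.arm)):
            if arr.shape[0] != n:
                raise InputError(f"field {name!r} has length {arr.shape[0]}, expected {n}")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise InputError("times must be finite and positive")
        if np.any((self.event != 0) & (self.event != 1)):
            raise InputError("event indicator must be 0 or 1")
        if np.any(self.weight <= 0):
            raise InputError("weights must be positive")

    @classmethod
    def from_records(cls, time, event, study="study", arm="intervention", weight=None):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        n = time.shape[0]
        if weight is None:
            weight = np.ones(n)
        study = np.full(n, study, dtype=object) if np.isscalar(study) or isinstance(study, str) else np.asarray(study, dtype=object)
        arm = np.full(n, arm, dtype=object) if np.isscalar(arm) or isinstance(arm, str) else np.asarray(arm, dtype=object)
        return cls(time=time, event=event, weight=np.asarray(weight, dtype=float),
                   study=study, arm=arm)

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def total_weight(self) -> float:
        return float(np.sum(self.weight))

    @property
    def n_events(self) -> float:
        return float(np.sum(self.weight * self.event))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.time,
                "event": self.event,
                "weight": self.weight,
                "study": self.study.astype(str),
                "arm": self.arm.astype(str),
            }
        )


@dataclass
class StepEstimate:
    """Product-limit estimate: survival steps at distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    variance: np.ndarray | None = None

    def survival_at(self, t):
        """Step-function evaluation; S(t) = 1 before the first event."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        if out.ndim == 0:
            return float(out)
        return out

    @property
    def median(self) -> float:
        """First time at which survival drops to 0.5 or below; NaN if never."""
        below = self.survival <= 0.5 + 1e-12
        if not np.any(below):
            return float("nan")
        return float(self.times[int(np.argmax(below))])


@dataclass
class ValidationReport:
    """Comparison of a reconstruction against its published summaries."""

    max_abs_deviation: float
    median_reconstructed: float
    median_published: float | None = None
    events_reconstructed: int = 0
    events_published: int | None = None

    @property
    def events_match(self) -> bool | None:
        if self.events_published is None:
            return None
        return self.events_reconstructed == self.events_published

    def to_dict(self) -> dict:
        return {
            "max_abs_deviation": self.max_abs_deviation,
            "median_reconstructed": self.median_reconstructed,
            "median_published": self.median_published,
            "events_reconstructed": self.events_reconstructed,
            "events_published": self.events_published,
            "events_match": self.events_match,
        }


def km_estimate(ipd: PseudoIPD) -> StepEstimate:
    """Weighted Kaplan-Meier product-limit estimate.

    Weights enter multiplicatively in both the risk set and the event count,
    so the estimator is invariant to rescaling all weights by a constant.
    Greenwood's formula (on the weighted counts) supplies the variance.
    """
    order = np.argsort(ipd.time, kind="stable")
    t = ipd.time[order]
    e = ipd.event[order]
    w = ipd.weight[order]
    # weighted at-risk just before each time = reverse cumulative weight
    rev_cum = np.cumsum(w[::-1])[::-1]
    distinct, first_idx = np.unique(t, return_index=True)
    times, survival, at_risk, variance = [], [], [], []
    s = 1.0
    greenwood = 0.0
    for j, tau in enumerate(distinct):
        lo = first_idx[j]
        hi = first_idx[j + 1] if j + 1 < len(distinct) else len(t)
        n_at_risk = rev_cum[lo]
        d = float(np.sum(w[lo:hi] * e[lo:hi]))
        if d <= 0.0:
            continue
        s *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            greenwood += d / (n_at_risk * (n_at_risk - d))
        else:
            greenwood = np.inf
        times.append(tau)
        survival.append(max(s, 0.0))
        at_risk.append(n_at_risk)
        variance.append(max(s, 0.0) ** 2 * greenwood if np.isfinite(greenwood) else 0.0)
    return StepEstimate(
        times=np.asarray(times),
        survival=np.asarray(survival),
        at_risk=np.asarray(at_risk),
        variance=np.asarray(variance),
    )


def _simulate_interval(n_start, km_start, step_times, step_surv, censor_times,
                       interval_start):
    """Run the product-limit inversion through one risk-table interval.

    Returns (event times, event counts, censor times kept, n_end, km_end,
    max deviation of the reconstructed KM from the input coordinates within
    the interval). Censorings at a coordinate time are processed after
    events at that time.
    """
    censor_times = np.sort(np.asarray(censor_times, dtype=float))
    events_t, events_d, events_n, events_s = [], [], [], []
    kept_censor = []
    n = float(n_start)
    km = km_start
    deviation = 0.0
    ci = 0
    for t_k, s_k in zip(step_times, step_surv):
        while ci < len(censor_times) and censor_times[ci] < t_k - 1e-12:
            if n >= 1.0:
                kept_censor.append(censor_times[ci])
                n -= 1.0
            ci += 1
        if km > 0.0 and n >= 1.0:
            d = int(np.floor(n * (1.0 - s_k / km) + 0.5))
            d = max(0, min(d, int(round(n))))
            if d > 0:
                km *= 1.0 - d / n
                events_t.append(t_k)
                events_d.append(d)
                events_n.append(n)
                events_s.append(s_k)
                n -= d
        deviation = max(deviation, abs(km - s_k))
    while ci < len(censor_times):
        if n >= 1.0:
            kept_censor.append(censor_times[ci])
            n -= 1.0
        ci += 1
    return events_t, events_d, kept_censor, n, km, deviation, events_n, events_s


def _uniform_censor_times(start: float, end: float, count: int) -> np.ndarray:
    if count <= 0:
        return np.empty(0)
    j = np.arange(1, count + 1)
    return start + (j - 0.5) * (end - start) / count


def reconstruct_ipd(curve: DigitizedCurve) -> PseudoIPD:
    """Reconstruct pseudo-IPD from a digitized KM curve and its risk table.

    Each risk-table interval is solved by fixed-point iteration on its
    censoring count; the final interval's censoring count is chosen to best
    reproduce the digitized steps (seeded from the average censoring rate of
    earlier intervals). When ``total_events`` is known, a final adjustment
    reconciles the reconstructed event count with it by swapping an event
    and a censoring at the coordinate where the survival perturbation
    (about S/n) is smallest, so the published count is matched at the least
    possible cost to the curve fit.
    """
    coords = curve.coordinates
    risk_t = curve.risk_table[:, 0]
    risk_n = np.round(curve.risk_table[:, 1]).astype(int)
    n_intervals = len(risk_t)
    if n_intervals == 1:
        warnings.warn(
            "risk table has a single entry; assuming no dropout censoring "
            "before the last coordinate (administrative censoring only)",
            stacklevel=2,
        )

    t_coord, s_coord = coords[:, 0], coords[:, 1]
    last_time = t_coord[-1]

    all_event_t: list[float] = []
    all_event_d: list[int] = []
    all_event_n: list[float] = []
    all_event_s: list[float] = []
    all_censor_t: list[float] = []
    n_current = float(risk_n[0])
    km_run = 1.0
    person_time = 0.0
    censored_so_far = 0.0

    for i in range(n_intervals):
        start = risk_t[i]
        end = risk_t[i + 1] if i + 1 < n_intervals else max(last_time, start)
        mask = t_coord > max(start - 1e-12, 0.0)
        if i + 1 < n_intervals:
            mask &= t_coord < end - 1e-12
        step_times = t_coord[mask]
        step_surv = s_coord[mask]

        is_last = i + 1 == n_intervals
        if is_last:
            # seed guess from the average censoring rate seen so far
            if person_time > 0 and censored_so_far > 0:
                rate = censored_so_far / person_time
                guess = int(round(rate * 0.5 * n_current * max(end - start, 0.0)))
            else:
                guess = 0
            guess = max(0, min(guess, int(n_current)))
            target_events = curve.total_events
            prior_events = int(np.sum(all_event_d))
            if n_intervals == 1 and target_events is None:
                candidates = [0]  # no-risk-table mode: no dropout assumed
            elif target_events is None:
                candidates = [guess]
            else:
                candidates = range(int(n_current) + 1)
            best = None
            for ncen in candidates:
                cens = _uniform_censor_times(start, end, ncen)
                ev_t, ev_d, kept_c, n_end, km_end, dev, ev_n, ev_s = (
                    _simulate_interval(
                        n_current, km_run, step_times, step_surv, cens, start
                    )
                )
                if target_events is None:
                    mismatch = 0
                else:
                    mismatch = abs(prior_events + int(np.sum(ev_d)) - target_events)
                key = (round(dev, 9), mismatch, abs(ncen - guess))
                if best is None or key < best[0]:
                    best = (key, ev_t, ev_d, kept_c, n_end, km_end, ev_n, ev_s)
            _, ev_t, ev_d, kept_c, n_end, km_end, ev_n, ev_s = best
            all_event_t.extend(ev_t)
            all_event_d.extend(ev_d)
            all_event_n.extend(ev_n)
            all_event_s.extend(ev_s)
            all_censor_t.extend(kept_c)
            n_current, km_run = n_end, km_end
        else:
            target_n = risk_n[i + 1]
            ncen = 0
            converged = False
            best = None
            for _ in range(400):
                cens = _uniform_censor_times(start, end, ncen)
                ev_t, ev_d, kept_c, n_end, km_end, _dev, ev_n, ev_s = (
                    _simulate_interval(
                        n_current, km_run, step_times, step_surv, cens, start
                    )
                )
                diff = int(round(n_end)) - target_n
                if best is None or abs(diff) < abs(best[0]):
                    best = (diff, ev_t, ev_d, kept_c, n_end, km_end, ncen, ev_n, ev_s)
                if diff == 0:
                    converged = True
                    break
                new_ncen = ncen + diff
                if new_ncen < 0:
                    raise InconsistentRiskTable(
                        f"interval [{start}, {end}) implies a negative censoring "
                        f"count: reconstruction reaches {int(round(n_end))} at-risk "
                        f"with no censoring but the table reports {target_n}"
                    )
                if new_ncen > int(n_current):
                    break
                ncen = new_ncen
            if not converged and best is not None and best[0] < 0:
                raise InconsistentRiskTable(
                    f"interval [{start}, {end}) implies a negative censoring count"
                )
            _, ev_t, ev_d, kept_c, n_end, km_end, ncen, ev_n, ev_s = best
            all_event_t.extend(ev_t)
            all_event_d.extend(ev_d)
            all_event_n.extend(ev_n)
            all_event_s.extend(ev_s)
            all_censor_t.extend(kept_c)
            person_time += 0.5 * (n_current + n_end) * (end - start)
            censored_so_far += len(kept_c)
            n_current, km_run = n_end, km_end

    # subjects still at risk after the last coordinate: administrative censoring
    n_remaining = int(round(n_current))
    admin_time = max(last_time, risk_t[-1])

    # final adjustment: reconcile the event total with the published count by
    # event<->censoring swaps at the same time (at-risk counts are unchanged),
    # picking the coordinate where the KM perturbation (~S/n) is smallest
    if curve.total_events is not None:
        delta = int(np.sum(all_event_d)) - int(curve.total_events)
        while delta > 0:
            costs = [
                all_event_s[j] / max(all_event_n[j] - all_event_d[j], 1.0)
                if all_event_d[j] >= 1 else np.inf
                for j in range(len(all_event_d))
            ]
            if not costs or not np.isfinite(np.min(costs)):
                break
            j = int(np.argmin(costs))
            all_event_d[j] -= 1
            all_censor_t.append(all_event_t[j])
            delta -= 1
        while delta < 0:
            def _s_at(tau):
                idx = int(np.searchsorted(t_coord, tau, side="right")) - 1
                return float(s_coord[idx]) if idx >= 0 else 1.0

            def _at_risk(tau):
                n_at = sum(d for t, d in zip(all_event_t, all_event_d) if t >= tau)
                n_at += sum(1 for c in all_censor_t if c >= tau)
                if admin_time >= tau:
                    n_at += n_remaining
                return max(n_at, 1)

            pool = list(all_censor_t) + ([admin_time] if n_remaining > 0 else [])
            if not pool:
                break
            costs = [_s_at(c) / _at_risk(c) for c in pool]
            j = int(np.argmin(costs))
            chosen = pool[j]
            if j < len(all_censor_t):
                all_censor_t.pop(j)
            else:
                n_remaining -= 1
            all_event_t.append(chosen)
            all_event_d.append(1)
            all_event_n.append(float(_at_risk(chosen)))
            all_event_s.append(_s_at(chosen))
            delta += 1

    times = []
    events = []
    for t_k, d in zip(all_event_t, all_event_d):
        times.extend([t_k] * d)
        events.extend([1] * d)
    for c in all_censor_t:
        times.append(c)
        events.append(0)
    times.extend([admin_time] * n_remaining)
    events.extend([0] * n_remaining)

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) != curve.n_initial:
        raise InconsistentRiskTable(
            f"reconstruction produced {len(times)} subjects but the risk table "
            f"starts at {curve.n_initial}"
        )
    order = np.lexsort((1 - events, times))
    return PseudoIPD.from_records(
        time=times[order],
        event=events[order],
        study=curve.study_label,
        arm=curve.arm_label,
    )


def validate_reconstruction(
    ipd: PseudoIPD,
    curve: DigitizedCurve,
    published_median: float | None = None,
    published_events: int | None = None,
) -> ValidationReport:
    """Compare the KM of a reconstruction against the digitized coordinates."""
    km = km_estimate(ipd)
    t = curve.coordinates[:, 0]
    s = curve.coordinates[:, 1]
    deviation = float(np.max(np.abs(km.survival_at(t) - s)))
    events = int(round(float(np.sum(ipd.weight * ipd.event))))
    return ValidationReport(
        max_abs_deviation=deviation,
        median_reconstructed=km.median,
        median_published=published_median,
        events_reconstructed=events,
        events_published=published_events,
    )
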