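"""Distribution selection: extrapolation-threshold gate plus combined AIC.

An extrapolated survival model can look excellent within follow-up and be
wildly implausible beyond it. The selection algorithm therefore gates every
candidate family on external registry evidence before ranking by fit: a
family is admissible only if the modeled survival of *both* arms at the
horizon (default 10 years) stays at or below a registry-derived threshold —
the 10-year relative survival rate for the cancer type, inflated by a
relative allowance (default 10%) for the possibility that novel therapies
beat the registry era. Admissible families are ranked by the combined AIC
of the two arms (the same family is used for both arms to keep structural
assumptions symmetric), and the lowest combined AIC wins; ties break toward
fewer parameters, then lexicographic family name.

The original procedure also included a visual plausibility inspection. That
step is operationalized here as machine-checkable gates: every group median
needed downstream must be evaluable for both arms (no improper plateaus
above the required levels), the extrapolated survival must be monotone
non-increasing on a grid, and a config-level veto list allows an explicit
analyst override.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, NoAdmissibleFamily
from .families import canonical_name, get_family
from .survival_models import FittedModel, survival_at

__all__ = [
    "SelectionConfig",
    "FamilyAudit",
    "SelectionResult",
    "extrapolation_threshold",
    "select_family",
    "default_candidates",
]


def default_candidates(include_mixtures: bool = True) -> tuple[str, ...]:
    """The six standard families plus, optionally, all 21 unordered pairs."""
    from .families import FAMILY_NAMES

    names = list(FAMILY_NAMES)
    if include_mixtures:
        for i, a in enumerate(FAMILY_NAMES):
            for b in FAMILY_NAMES[i:]:
                names.append(f"{a}+{b}")
    return tuple(names)


@dataclass(frozen=True)
class SelectionConfig:
    """Gate parameters for the selection algorithm.

    ``seer_rate`` is the registry 10-year survival probability for the
    cancer type (for example 0.148 for metastatic breast cancer), ``uplift``
    the relative allowance on top of it, and ``horizon`` the extrapolation
    horizon in months.
    """

    seer_rate: float
    uplift: float = 0.10
    horizon: float = 120.0
    groups: tuple[int, ...] = (2, 5)
    require_evaluable_quantiles: bool = True
    veto: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.seer_rate <= 1.0:
            raise InputError("seer_rate must be a probability")
        if self.uplift < 0:
            raise InputError("uplift must be nonnegative")
        if self.seer_rate * (1.0 + self.uplift) > 1.0:
            raise InputError("seer_rate·(1+uplift) exceeds 1")
        if self.horizon <= 0:
            raise InputError("horizon must be positive")
        object.__setattr__(self, "veto", tuple(canonical_name(v) for v in self.veto))


@dataclass
class FamilyAudit:
    """Per-family audit record of the selection decision."""

    family: str
    aic_intervention: float
    aic_comparator: float
    combined_aic: float
    survival_horizon_intervention: float
    survival_horizon_comparator: float
    admissible: bool
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "aic_intervention": self.aic_intervention,
            "aic_comparator": self.aic_comparator,
            "combined_aic": self.combined_aic,
            "survival_horizon_intervention": self.survival_horizon_intervention,
            "survival_horizon_comparator": self.survival_horizon_comparator,
            "admissible": self.admissible,
            "reason": self.reason,
        }


@dataclass
class SelectionResult:
    """Outcome of the selection algorithm with a full audit trail."""

    selected: str
    threshold: float
    audits: list[FamilyAudit] = field(default_factory=list)

    def audit_for(self, family: str) -> FamilyAudit:
        family = canonical_name(family)
        for audit in self.audits:
            if audit.family == family:
                return audit
        raise KeyError(family)

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "threshold": self.threshold,
            "audits": [a.to_dict() for a in self.audits],
        }


def extrapolation_threshold(config: SelectionConfig) -> float:
    """Upper bound on modeled survival at the horizon: seer_rate·(1+uplift)."""
    threshold = config.seer_rate * (1.0 + config.uplift)
    if threshold > 1.0:
        raise InputError("extrapolation threshold exceeds 1")
    return threshold


def _plausibility_reason(model: FittedModel, config: SelectionConfig) -> str | None:
    """Machine-checkable stand-in for the visual inspection; None if fine."""
    fam = model.family_obj
    grid = np.linspace(0.0, config.horizon, 121)
    s = np.asarray(fam.sf(grid, model.param_values), dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s < -1e-9) or np.any(np.diff(s) > 1e-9):
        return "extrapolated survival not a proper non-increasing curve"
    if config.require_evaluable_quantiles:
        probs = sorted(
            {(2 * k - 1) / (2 * g) for g in config.groups for k in range(1, g + 1)}
        )
        q = np.asarray(fam.ppf(np.array(probs), model.param_values), dtype=float)
        if np.any(~np.isfinite(q)):
            return "required group medians not evaluable (improper extrapolation)"
    return None


def select_family(
    fits_int: dict[str, FittedModel],
    fits_comp: dict[str, FittedModel],
    config: SelectionConfig,
) -> SelectionResult:
    """Apply the threshold gate and combined-AIC ranking across candidates.

    ``fits_int`` and ``fits_comp`` map family identifiers to fitted models
    for the pooled intervention and comparator arms; the two collections
    must cover the same identifiers.
    """
    keys_int = {canonical_name(k) for k in fits_int}
    keys_comp = {canonical_name(k) for k in fits_comp}
    if keys_int != keys_comp:
        raise InputError(
            "intervention and comparator fits must cover the same families; "
            f"difference: {sorted(keys_int ^ keys_comp)}"
        )
    fits_int = {canonical_name(k): v for k, v in fits_int.items()}
    fits_comp = {canonical_name(k): v for k, v in fits_comp.items()}
    threshold = extrapolation_threshold(config)

    audits: list[FamilyAudit] = []
    for family in sorted(fits_int):
        model_int = fits_int[family]
        model_comp = fits_comp[family]
        s_int = float(survival_at(model_int, config.horizon))
        s_comp = float(survival_at(model_comp, config.horizon))
        reason = ""
        admissible = True
        if family in config.veto:
            admissible, reason = False, "vetoed by configuration"
        elif s_int > threshold or s_comp > threshold:
            admissible = False
            reason = (
                f"survival at {config.horizon:g} months exceeds threshold "
                f"{threshold:.4f} (intervention {s_int:.4f}, comparator {s_comp:.4f})"
            )
        else:
            for label, model in (("intervention", model_int), ("comparator", model_comp)):
                why = _plausibility_reason(model, config)
                if why is not None:
                    admissible, reason = False, f"{label}: {why}"
                    break
        audits.append(
            FamilyAudit(
                family=family,
                aic_intervention=model_int.aic,
                aic_comparator=model_comp.aic,
                combined_aic=model_int.aic + model_comp.aic,
                survival_horizon_intervention=s_int,
                survival_horizon_comparator=s_comp,
                admissible=admissible,
                reason=reason,
            )
        )

    admissible = [a for a in audits if a.admissible]
    if not admissible:
        raise NoAdmissibleFamily({a.family: a.reason for a in audits})
    admissible.sort(
        key=lambda a: (a.combined_aic, fits_int[a.family].k, a.family)
    )
    return SelectionResult(
        selected=admissible[0].family, threshold=threshold, audits=audits
    )
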