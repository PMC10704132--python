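"""Exception types shared across the package."""


class SurvIneqError(Exception):
    """Base class for all package-specific errors."""


class InputError(SurvIneqError):
    """Malformed or invariant-violating input data."""


class InconsistentRiskTable(InputError):
    """A numbers-at-risk table implies a negative censoring count."""


class AllCensoredError(InputError):
    """A likelihood cannot be maximized when every record is censored."""


class FitError(SurvIneqError):
    """Optimization failed to produce a usable maximum-likelihood fit."""


class SingularCovariance(SurvIneqError):
    """The observed information matrix is singular beyond repair."""


class NoAdmissibleFamily(SurvIneqError):
    """Every candidate family was excluded by the selection gates."""

    def __init__(self, reasons: dict):
        self.reasons = dict(reasons)
        lines = "; ".join(f"{fam}: {why}" for fam, why in self.reasons.items())
        super().__init__(f"no admissible survival family ({lines})")


class UnstableExtrapolation(SurvIneqError):
    """Too many probabilistic draws produced non-evaluable quantiles."""
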