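"""Parametric survival families and two-component mixtures.

Parameterizations follow the conventions of the dominant parametric-survival
ecosystem (flexsurv-style):

========== =================== ============================================
family     parameters          survival function
========== =================== ============================================
exponential rate λ>0           S(t) = exp(-λt)
gamma       shape a>0, rate r>0 S(t) = Γ_upper(a, rt)/Γ(a)
gompertz    shape γ∈ℝ, rate λ>0 S(t) = exp(-λ/γ (e^{γt}-1)); γ<0 improper
loglogistic shape a>0, scale b>0 S(t) = 1/(1+(t/b)^a)
lognormal   meanlog μ∈ℝ, sdlog σ>0 S(t) = 1-Φ((log t-μ)/σ)
weibull     shape a>0, scale b>0 S(t) = exp(-(t/b)^a)
========== =================== ============================================

A mixture ``f1+f2`` has survival π·S₁ + (1-π)·S₂ with mixing weight π∈(0,1)
as its first parameter (``mix_weight``); mixture names are canonicalized to
alphabetical component order.

Parameters are passed as a tuple of scalars or broadcastable arrays, which
lets the probabilistic layer evaluate a quantile across thousands of
parameter draws in one vectorized call. Every family also exposes the
transform that maps each parameter to an unconstrained scale (log for
positive parameters, identity for the Gompertz shape, logit for the mixing
weight); optimization, Hessians and multivariate-normal sampling all live on
that transformed scale so that back-transformed draws satisfy the domain
constraints by construction.

The Gompertz family with negative shape is *improper*: S(t) plateaus at
exp(rate/shape) > 0, so quantiles beyond the plateau do not exist and are
returned as NaN (the caller treats NaN as "non-evaluable", never as zero).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit, logit, logsumexp

__all__ = [
    "Family",
    "MixtureFamily",
    "get_family",
    "canonical_name",
    "SINGLE_FAMILIES",
    "FAMILY_NAMES",
]

_GOMPERTZ_SHAPE_EPS = 1e-12


def _asarrays(params):
    return tuple(np.asarray(p, dtype=float) for p in params)


class Family:
    """A single parametric survival family.

    Subclasses implement ``logpdf``, ``logsf`` and ``ppf`` on the natural
    scale; ``sf`` and ``plateau`` have generic defaults.
    """

    name: str
    param_names: tuple[str, ...]
    transforms: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- natural <-> transformed -------------------------------------------
    def to_transformed(self, params) -> np.ndarray:
        out = []
        for value, transform in zip(params, self.transforms):
            value = np.asarray(value, dtype=float)
            if transform == "log":
                out.append(np.log(value))
            elif transform == "logit":
                out.append(logit(value))
            else:
                out.append(value)
        return np.array(out)

    def to_natural(self, transformed):
        out = []
        for value, transform in zip(transformed, self.transforms):
            value = np.asarray(value, dtype=float)
            if transform == "log":
                out.append(np.exp(value))
            elif transform == "logit":
                out.append(expit(value))
            else:
                out.append(value)
        return tuple(out)

    # -- distribution surface ----------------------------------------------
    def logpdf(self, t, params):  # pragma: no cover - abstract
        raise NotImplementedError

    def logsf(self, t, params):  # pragma: no cover - abstract
        raise NotImplementedError

    def sf(self, t, params):
        return np.exp(self.logsf(t, params))

    def ppf(self, p, params):  # pragma: no cover - abstract
        raise NotImplementedError

    def plateau(self, params):
        """S(∞); zero for proper distributions."""
        params = _asarrays(params)
        return np.zeros(np.broadcast(*params, np.empty(())).shape)

    def __repr__(self) -> str:
        return f"<Family {self.name}>"


class _Exponential(Family):
    name = "exponential"
    param_names = ("rate",)
    transforms = ("log",)

    def logpdf(self, t, params):
        (rate,) = _asarrays(params)
        t = np.asarray(t, dtype=float)
        return np.log(rate) - rate * t

    def logsf(self, t, params):
        (rate,) = _asarrays(params)
        return -rate * np.asarray(t, dtype=float)

    def ppf(self, p, params):
        (rate,) = _asarrays(params)
        return -np.log1p(-np.asarray(p, dtype=float)) / rate


class _Weibull(Family):
    name = "weibull"
    param_names = ("shape", "scale")
    transforms = ("log", "log")

    def logpdf(self, t, params):
        shape, scale = _asarrays(params)
        return stats.weibull_min.logpdf(t, shape, scale=scale)

    def logsf(self, t, params):
        shape, scale = _asarrays(params)
        t = np.asarray(t, dtype=float)
        return -np.power(t / scale, shape)

    def ppf(self, p, params):
        shape, scale = _asarrays(params)
        p = np.asarray(p, dtype=float)
        return scale * np.power(-np.log1p(-p), 1.0 / shape)


class _Gamma(Family):
    name = "gamma"
    param_names = ("shape", "rate")
    transforms = ("log", "log")

    def logpdf(self, t, params):
        shape, rate = _asarrays(params)
        return stats.gamma.logpdf(t, shape, scale=1.0 / rate)

    def logsf(self, t, params):
        shape, rate = _asarrays(params)
        return stats.gamma.logsf(t, shape, scale=1.0 / rate)

    def ppf(self, p, params):
        shape, rate = _asarrays(params)
        return stats.gamma.ppf(p, shape, scale=1.0 / rate)


class _LogNormal(Family):
    name = "lognormal"
    param_names = ("meanlog", "sdlog")
    transforms = ("identity", "log")

    def logpdf(self, t, params):
        meanlog, sdlog = _asarrays(params)
        return stats.lognorm.logpdf(t, sdlog, scale=np.exp(meanlog))

    def logsf(self, t, params):
        meanlog, sdlog = _asarrays(params)
        return stats.lognorm.logsf(t, sdlog, scale=np.exp(meanlog))

    def ppf(self, p, params):
        meanlog, sdlog = _asarrays(params)
        return np.exp(meanlog + sdlog * stats.norm.ppf(p))


class _LogLogistic(Family):
    name = "loglogistic"
    param_names = ("shape", "scale")
    transforms = ("log", "log")

    def logpdf(self, t, params):
        shape, scale = _asarrays(params)
        return stats.fisk.logpdf(t, shape, scale=scale)

    def logsf(self, t, params):
        shape, scale = _asarrays(params)
        t = np.asarray(t, dtype=float)
        return -np.log1p(np.power(t / scale, shape))

    def ppf(self, p, params):
        shape, scale = _asarrays(params)
        p = np.asarray(p, dtype=float)
        return scale * np.power(p / (1.0 - p), 1.0 / shape)


class _Gompertz(Family):
    """Gompertz with unrestricted shape.

    The hazard is λ·e^{γt}. For γ<0 the cumulative hazard is bounded, the
    survival plateaus at exp(λ/γ) and quantiles beyond the plateau are NaN.
    """

    name = "gompertz"
    param_names = ("shape", "rate")
    transforms = ("identity", "log")

    def _cumhaz(self, t, shape, rate):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            general = rate / shape * np.expm1(shape * t)
        return np.where(np.abs(shape) < _GOMPERTZ_SHAPE_EPS, rate * t, general)

    def logpdf(self, t, params):
        shape, rate = _asarrays(params)
        t = np.asarray(t, dtype=float)
        return np.log(rate) + shape * t - self._cumhaz(t, shape, rate)

    def logsf(self, t, params):
        shape, rate = _asarrays(params)
        return -self._cumhaz(t, shape, rate)

    def ppf(self, p, params):
        shape, rate = _asarrays(params)
        p = np.asarray(p, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            arg = 1.0 - shape / rate * np.log1p(-p)
            general = np.where(arg > 0.0, np.log(np.maximum(arg, 1e-300)) / shape, np.nan)
        exponential = -np.log1p(-p) / rate
        return np.where(np.abs(shape) < _GOMPERTZ_SHAPE_EPS, exponential, general)

    def plateau(self, params):
        shape, rate = _asarrays(params)
        with np.errstate(divide="ignore", over="ignore"):
            plateau = np.exp(rate / shape)
        return np.where(shape < -_GOMPERTZ_SHAPE_EPS, plateau, 0.0)


class MixtureFamily(Family):
    """Two-component mixture: S = π·S₁ + (1-π)·S₂, f = π·f₁ + (1-π)·f₂."""

    def __init__(self, comp1: Family, comp2: Family):
        self.components = (comp1, comp2)
        self.name = f"{comp1.name}+{comp2.name}"
        self.param_names = (
            ("mix_weight",)
            + tuple(f"c1_{p}" for p in comp1.param_names)
            + tuple(f"c2_{p}" for p in comp2.param_names)
        )
        self.transforms = ("logit",) + comp1.transforms + comp2.transforms

    def split_params(self, params):
        comp1, comp2 = self.components
        k1 = comp1.n_params
        pi = np.asarray(params[0], dtype=float)
        return pi, tuple(params[1 : 1 + k1]), tuple(params[1 + k1 :])

    def logpdf(self, t, params):
        pi, p1, p2 = self.split_params(params)
        comp1, comp2 = self.components
        with np.errstate(divide="ignore"):
            parts = np.stack(
                np.broadcast_arrays(
                    np.log(pi) + comp1.logpdf(t, p1),
                    np.log1p(-pi) + comp2.logpdf(t, p2),
                )
            )
        return logsumexp(parts, axis=0)

    def logsf(self, t, params):
        pi, p1, p2 = self.split_params(params)
        comp1, comp2 = self.components
        with np.errstate(divide="ignore"):
            parts = np.stack(
                np.broadcast_arrays(
                    np.log(pi) + comp1.logsf(t, p1),
                    np.log1p(-pi) + comp2.logsf(t, p2),
                )
            )
        return logsumexp(parts, axis=0)

    def plateau(self, params):
        pi, p1, p2 = self.split_params(params)
        comp1, comp2 = self.components
        return pi * comp1.plateau(p1) + (1.0 - pi) * comp2.plateau(p2)

    def ppf(self, p, params, tol: float = 1e-10, max_doublings: int = 60):
        """Invert the mixture survival by vectorized bisection.

        Returns NaN where the target survival level lies at or below the
        mixture plateau (non-evaluable quantile).
        """
        p = np.asarray(p, dtype=float)
        pi, p1, p2 = self.split_params(params)
        comp1, comp2 = self.components
        target = 1.0 - p  # survival level to hit
        shape = np.broadcast(p, pi, *p1, *p2).shape
        target = np.broadcast_to(target, shape).astype(float)
        evaluable = target > self.plateau(params) + 1e-15
        evaluable = np.broadcast_to(evaluable, shape)

        # component quantiles give a generous initial upper bracket
        with np.errstate(invalid="ignore"):
            guess1 = comp1.ppf(np.clip(p, 1e-12, 1 - 1e-12), p1)
            guess2 = comp2.ppf(np.clip(p, 1e-12, 1 - 1e-12), p2)
        hi = np.fmax(np.nan_to_num(guess1, nan=1.0), np.nan_to_num(guess2, nan=1.0))
        hi = np.broadcast_to(np.maximum(hi, 1.0), shape).copy()
        for _ in range(max_doublings):
            need = evaluable & (self.sf(hi, params) > target)
            if not np.any(need):
                break
            hi = np.where(need, hi * 2.0, hi)
        lo = np.zeros(shape)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            below = self.sf(mid, params) > target
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
            if np.max(hi - lo) < tol * max(1.0, np.max(hi)):
                break
        result = 0.5 * (lo + hi)
        result = np.where(evaluable, result, np.nan)
        if result.ndim == 0:
            return float(result)
        return result


SINGLE_FAMILIES: dict[str, Family] = {
    f.name: f
    for f in (
        _Exponential(),
        _Gamma(),
        _Gompertz(),
        _LogLogistic(),
        _LogNormal(),
        _Weibull(),
    )
}

FAMILY_NAMES = tuple(sorted(SINGLE_FAMILIES))

_MIXTURE_CACHE: dict[str, MixtureFamily] = {}


def canonical_name(name: str) -> str:
    """Canonical family identifier; mixture components in alphabetical order."""
    if "+" not in name:
        return name
    a, b = (part.strip() for part in name.split("+"))
    return "+".join(sorted((a, b)))


def get_family(name: str) -> Family:
    """Look up a family by identifier, e.g. ``"weibull"`` or ``"gamma+weibull"``."""
    name = canonical_name(name)
    if "+" in name:
        if name not in _MIXTURE_CACHE:
            a, b = name.split("+")
            if a not in SINGLE_FAMILIES or b not in SINGLE_FAMILIES:
                raise KeyError(f"unknown mixture components in {name!r}")
            _MIXTURE_CACHE[name] = MixtureFamily(SINGLE_FAMILIES[a], SINGLE_FAMILIES[b])
        return _MIXTURE_CACHE[name]
    try:
        return SINGLE_FAMILIES[name]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; choose from {', '.join(FAMILY_NAMES)}"
        ) from None
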