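"""Maximum-likelihood parametric and mixture survival models.

Fits any of the six standard families (exponential, gamma, Gompertz,
log-logistic, log-normal, Weibull) or a two-component mixture to weighted
right-censored data by direct maximization of the weighted log-likelihood

    ℓ(θ) = Σ_i w_i [ δ_i log f(t_i; θ) + (1-δ_i) log S(t_i; θ) ],

with δ_i the event indicator. Optimization runs on the unconstrained
transformed scale (log for positive parameters, logit for the mixing
weight, identity for the Gompertz shape); the parameter covariance is the
inverse observed information on that same scale, which is also where the
probabilistic layer draws its multivariate-normal samples so that every
draw respects the domain constraints.

Mixtures are maximized directly (multi-start, seeded) rather than by EM:
with arbitrary censored component families, direct maximization is simpler
and equally accurate at trial-size data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from statsmodels.tools import numdiff

from .exceptions import AllCensoredError, FitError, InputError, SingularCovariance
from .families import Family, MixtureFamily, canonical_name, get_family
from .pseudo_ipd import PseudoIPD

__all__ = [
    "FittedModel",
    "log_likelihood",
    "fit_parametric",
    "fit_mixture",
    "survival_at",
    "quantile",
    "aic",
    "parameter_covariance",
]

logger = logging.getLogger(__name__)

_PENALTY = 1e12
_MIX_EPS = 1e-6


@dataclass
class FittedModel:
    """A fitted parametric or two-component mixture survival model."""

    family: str
    params_natural: dict[str, float]
    params_transformed: np.ndarray
    loglik: float
    k: int
    cov_transformed: np.ndarray | None = None
    converged: bool = True
    grad_norm: float = math.nan
    message: str = ""

    def __post_init__(self):
        self.family = canonical_name(self.family)
        self.params_transformed = np.asarray(self.params_transformed, dtype=float)

    @property
    def family_obj(self) -> Family:
        return get_family(self.family)

    @property
    def param_values(self) -> tuple[float, ...]:
        fam = self.family_obj
        return tuple(self.params_natural[name] for name in fam.param_names)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params_natural": dict(self.params_natural),
            "params_transformed": self.params_transformed.tolist(),
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "cov_transformed": None
            if self.cov_transformed is None
            else np.asarray(self.cov_transformed).tolist(),
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "message": self.message,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FittedModel":
        cov = payload.get("cov_transformed")
        return cls(
            family=payload["family"],
            params_natural={k: float(v) for k, v in payload["params_natural"].items()},
            params_transformed=np.asarray(payload["params_transformed"], dtype=float),
            loglik=float(payload["loglik"]),
            k=int(payload["k"]),
            cov_transformed=None if cov is None else np.asarray(cov, dtype=float),
            converged=bool(payload.get("converged", True)),
            grad_norm=float(payload.get("grad_norm", math.nan)),
            message=str(payload.get("message", "")),
        )


def log_likelihood(family: str | Family, params, ipd: PseudoIPD) -> float:
    """Weighted censored-data log-likelihood; -inf for invalid parameters."""
    fam = family if isinstance(family, Family) else get_family(family)
    with np.errstate(all="ignore"):
        lp = fam.logpdf(ipd.time, params)
        ls = fam.logsf(ipd.time, params)
        contrib = np.where(ipd.event == 1, lp, ls)
    if not np.all(np.isfinite(contrib)):
        return -math.inf
    return float(np.sum(ipd.weight * contrib))


def survival_at(model: FittedModel, t) -> float | np.ndarray:
    """Model survival S(t); errors on negative t."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InputError("survival_at requires t ≥ 0")
    out = model.family_obj.sf(t_arr, model.param_values)
    if out.ndim == 0:
        return float(out)
    return out


def quantile(model: FittedModel, p) -> float | np.ndarray:
    """Event-time quantile: the t with S(t) = 1-p; NaN when non-evaluable.

    Quantiles beyond the plateau of an improper distribution (for example a
    negative-shape Gompertz) do not exist and are reported as NaN so the
    caller can flag rather than fabricate them.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise InputError("quantile probability must lie in (0, 1)")
    out = model.family_obj.ppf(p_arr, model.param_values)
    out = np.asarray(out, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out


def aic(model: FittedModel) -> float:
    """Akaike information criterion, 2k - 2·loglik (lower is better)."""
    return model.aic


def _check_fittable(ipd: PseudoIPD):
    if np.sum(ipd.event) < 1:
        raise AllCensoredError("cannot fit a survival model with no events")
    if len(np.unique(ipd.time)) < 2:
        raise InputError("need at least two distinct observation times")


def _initial_natural(family: Family, ipd: PseudoIPD) -> tuple[float, ...]:
    """Moment-style starting values on the natural scale."""
    w = ipd.weight
    events = ipd.event == 1
    t_ev = ipd.time[events]
    w_ev = w[events]
    if t_ev.size == 0:  # pragma: no cover - guarded by _check_fittable
        t_ev, w_ev = ipd.time, w
    total_time = float(np.sum(w * ipd.time))
    n_events = float(np.sum(w_ev))
    rate = max(n_events / max(total_time, 1e-12), 1e-8)
    logs = np.log(t_ev)
    mu = float(np.average(logs, weights=w_ev))
    sd = float(np.sqrt(max(np.average((logs - mu) ** 2, weights=w_ev), 1e-4)))
    mean_t = float(np.average(t_ev, weights=w_ev))
    var_t = float(np.average((t_ev - mean_t) ** 2, weights=w_ev)) + 1e-8
    name = family.name
    if name == "exponential":
        return (rate,)
    if name == "weibull":
        shape = min(max(1.2 / sd, 0.3), 10.0)
        return (shape, float(np.exp(mu + 0.5 * sd)))
    if name == "gamma":
        shape = min(max(mean_t**2 / var_t, 0.1), 50.0)
        return (shape, shape / mean_t)
    if name == "lognormal":
        return (mu, sd)
    if name == "loglogistic":
        shape = min(max(1.6 / sd, 0.3), 10.0)
        return (shape, float(np.exp(mu)))
    if name == "gompertz":
        return (1e-3, rate)
    raise KeyError(name)  # pragma: no cover


def _maximize(family: Family, ipd: PseudoIPD, x0: np.ndarray):
    """Minimize the negative weighted log-likelihood on the transformed scale."""

    def nll(x):
        value = log_likelihood(family, family.to_natural(x), ipd)
        if not np.isfinite(value):
            return _PENALTY
        return -value

    best = None
    for method in ("L-BFGS-B", "Nelder-Mead"):
        try:
            res = optimize.minimize(
                nll,
                x0,
                method=method,
                options={"maxiter": 2000}
                if method == "Nelder-Mead"
                else {"maxiter": 500},
            )
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if best is None or res.fun < best.fun:
            best = res
        if np.isfinite(res.fun) and res.fun < _PENALTY / 2:
            break
    if best is None or not np.isfinite(best.fun) or best.fun >= _PENALTY / 2:
        raise FitError(f"likelihood maximization failed for family {family.name!r}")
    # polish with Nelder-Mead if L-BFGS-B stopped on a rough finite-difference
    res = optimize.minimize(nll, best.x, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
    if res.fun <= best.fun:
        best = res
    grad = optimize.approx_fprime(best.x, nll, 1.49e-8)
    return best, float(np.linalg.norm(grad))


def fit_parametric(ipd: PseudoIPD, family: str) -> FittedModel:
    """Fit one of the six standard families by weighted maximum likelihood."""
    fam = get_family(family)
    if isinstance(fam, MixtureFamily):
        raise InputError("use fit_mixture for mixture families")
    _check_fittable(ipd)
    x0 = fam.to_transformed(_initial_natural(fam, ipd))
    best, grad_norm = _maximize(fam, ipd, x0)
    natural = fam.to_natural(best.x)
    converged = grad_norm < 1e-3 * max(1.0, abs(best.fun))
    if not converged:
        logger.warning(
            "fit for %s did not reach a small gradient (|g|=%.3g)", fam.name, grad_norm
        )
    return FittedModel(
        family=fam.name,
        params_natural={n: float(v) for n, v in zip(fam.param_names, natural)},
        params_transformed=np.asarray(best.x, dtype=float),
        loglik=-float(best.fun),
        k=fam.n_params,
        converged=bool(converged),
        grad_norm=grad_norm,
        message=str(getattr(best, "message", "")),
    )


def _mixture_starts(fam: MixtureFamily, ipd: PseudoIPD, n_starts: int, seed: int):
    """Seeded starting points: a split-at-the-median start plus jitters."""
    rng = np.random.default_rng(seed)
    comp1, comp2 = fam.components
    order = np.argsort(ipd.time)
    cum_w = np.cumsum(ipd.weight[order])
    split = ipd.time[order][np.searchsorted(cum_w, 0.5 * cum_w[-1])]
    lower = ipd.time <= split
    upper = ~lower

    def subset(mask):
        if np.sum(mask) < 2 or np.sum(ipd.event[mask]) < 1:
            return ipd
        return PseudoIPD(
            time=ipd.time[mask],
            event=ipd.event[mask],
            weight=ipd.weight[mask],
            study=ipd.study[mask],
            arm=ipd.arm[mask],
        )

    base1 = comp1.to_transformed(_initial_natural(comp1, subset(lower)))
    base2 = comp2.to_transformed(_initial_natural(comp2, subset(upper)))
    first = np.concatenate(([0.0], base1, base2))  # logit(0.5) = 0
    starts = [first]
    for _ in range(max(n_starts - 1, 0)):
        pi0 = rng.uniform(0.2, 0.8)
        jitter1 = base1 + rng.normal(0.0, 0.5, size=base1.size)
        jitter2 = base2 + rng.normal(0.0, 0.5, size=base2.size)
        starts.append(
            np.concatenate(([np.log(pi0 / (1 - pi0))], jitter1, jitter2))
        )
    return starts


def fit_mixture(
    ipd: PseudoIPD,
    families: str | tuple[str, str],
    n_starts: int = 10,
    seed: int = 0,
) -> FittedModel:
    """Fit a two-component mixture by seeded multi-start maximization.

    The mixing weight is clamped to (1e-6, 1-1e-6). For a same-family
    mixture the components are ordered by ascending component median to
    resolve label switching.
    """
    if isinstance(families, str):
        name = canonical_name(families)
    else:
        name = canonical_name("+".join(families))
    fam = get_family(name)
    if not isinstance(fam, MixtureFamily):
        raise InputError(f"{name!r} is not a mixture identifier")
    if n_starts < 1:
        raise InputError("n_starts must be ≥ 1")
    _check_fittable(ipd)

    best = None
    best_grad = math.inf
    failures = []
    for x0 in _mixture_starts(fam, ipd, n_starts, seed):
        try:
            res, grad_norm = _maximize(fam, ipd, x0)
        except FitError as exc:
            failures.append(str(exc))
            continue
        if best is None or res.fun < best.fun:
            best, best_grad = res, grad_norm
    if best is None:
        raise FitError(
            f"all {n_starts} mixture starts failed for {name!r}: {failures[:3]}"
        )

    x = np.asarray(best.x, dtype=float)
    # clamp the mixing weight away from the boundary
    from scipy.special import expit, logit

    pi = float(np.clip(expit(x[0]), _MIX_EPS, 1 - _MIX_EPS))
    x[0] = logit(pi)
    comp1, comp2 = fam.components
    k1 = comp1.n_params
    if comp1.name == comp2.name:
        theta1 = comp1.to_natural(x[1 : 1 + k1])
        theta2 = comp2.to_natural(x[1 + k1 :])
        med1 = float(np.asarray(comp1.ppf(0.5, theta1)))
        med2 = float(np.asarray(comp2.ppf(0.5, theta2)))
        if (math.isnan(med1) and not math.isnan(med2)) or (
            not math.isnan(med1) and not math.isnan(med2) and med1 > med2
        ):
            x = np.concatenate(([-x[0]], x[1 + k1 :], x[1 : 1 + k1]))

    natural = fam.to_natural(x)
    loglik = log_likelihood(fam, natural, ipd)
    converged = best_grad < 1e-3 * max(1.0, abs(loglik))
    return FittedModel(
        family=fam.name,
        params_natural={n: float(v) for n, v in zip(fam.param_names, natural)},
        params_transformed=x,
        loglik=float(loglik),
        k=fam.n_params,
        converged=bool(converged),
        grad_norm=best_grad,
        message=str(getattr(best, "message", "")),
    )


def parameter_covariance(model: FittedModel, ipd: PseudoIPD) -> np.ndarray:
    """Observed-information covariance of the transformed parameters.

    Numerically differentiates the negative weighted log-likelihood at the
    MLE and inverts it. A non-positive-definite result has its eigenvalues
    floored at 1e-10 (with a logged warning); a singular Hessian raises.
    """
    fam = model.family_obj

    def nll(x):
        value = log_likelihood(fam, fam.to_natural(x), ipd)
        if not np.isfinite(value):
            return _PENALTY
        return -value

    hess = numdiff.approx_hess2(np.asarray(model.params_transformed, dtype=float), nll)
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        raise SingularCovariance(
            f"singular observed information for {model.family!r}; "
            "consider a simpler family"
        ) from None
    if not np.all(np.isfinite(cov)):
        raise SingularCovariance(
            f"non-finite covariance for {model.family!r}; consider a simpler family"
        )
    cov = 0.5 * (cov + cov.T)
    eigval, eigvec = np.linalg.eigh(cov)
    if np.any(eigval < 1e-10):
        logger.warning(
            "covariance for %s not positive definite; flooring eigenvalues at 1e-10",
            model.family,
        )
        eigval = np.maximum(eigval, 1e-10)
        cov = eigvec @ np.diag(eigval) @ eigvec.T
        cov = 0.5 * (cov + cov.T)
    model.cov_transformed = cov
    return cov
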