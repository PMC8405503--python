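"""Covariate machinery, TSH feedback forms, and daily interpolation.

Continuous covariates act on a parameter through the power model
``theta_i = theta_pop * (Cov_i / Cov_Ref) ** beta``; categorical covariates
act multiplicatively as ``exp(beta_category)`` on the (log-normally
distributed) parameter, with the reference category at beta = 0.

TSH can feed back on the endogenous production rate ``kendo`` in four ways:
two categorical groupings (cut point 3 mU/l, or cut points 1 and 10 mU/l)
with additive shifts per category, a multiplicative coupling
``kendo * f(TSH)`` and an additive coupling ``kendo + beta3 * f(TSH)``,
where ``f`` is the identity, a power of TSH / TSH_Ref, log(TSH), or a power
of log(TSH) / log(TSH_Ref).  Every form reduces to plain ``kendo`` when its
coefficients are zero, which makes the feedback models properly nested for
likelihood-ratio testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "CovariateEffect",
    "TSHFeedbackSpec",
    "TSH_LOG_FLOOR",
    "apply_power_covariate",
    "apply_categorical_covariate",
    "tsh_category",
    "tsh_function",
    "kendo_with_feedback",
    "interpolate_daily",
    "Trajectory",
    "trajectory",
]

#: floor applied to TSH before taking logs: the limit of quantification
#: observed in the study population (mU/l)
TSH_LOG_FLOOR = 0.005


@dataclass(frozen=True)
class CovariateEffect:
    """A covariate effect on one structural parameter.

    ``kind`` is ``"power"`` (continuous; needs ``cov_ref`` and scalar
    ``beta``) or ``"categorical"`` (needs a ``betas`` mapping with the
    reference category absent or at 0).
    """

    target: str
    kind: str
    cov_ref: float = 1.0
    beta: float = 0.0
    betas: dict = field(default_factory=dict)
    reference: str | None = None  # categorical reference label (beta = 0)

    def __post_init__(self) -> None:
        if self.kind not in ("power", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "power" and self.cov_ref <= 0:
            raise ValueError("cov_ref must be > 0 for the power model")


def apply_power_covariate(theta_pop: float, cov_value, effect: CovariateEffect):
    """Power model: ``theta_pop * (cov / cov_ref) ** beta``."""
    cov_value = np.asarray(cov_value, float)
    if np.any(cov_value <= 0):
        raise ValueError("power-model covariate must be > 0")
    out = theta_pop * (cov_value / effect.cov_ref) ** effect.beta
    return float(out) if out.ndim == 0 else out


def apply_categorical_covariate(
    theta_pop: float, category, effect: CovariateEffect
) -> float:
    """Multiplicative categorical effect ``theta_pop * exp(beta_category)``.

    The reference category maps to ``theta_pop`` (beta = 0); unknown
    categories are an error.
    """
    if category in effect.betas:
        return theta_pop * float(np.exp(effect.betas[category]))
    if category == effect.reference or not effect.betas:
        return theta_pop
    raise ValueError(f"unknown category {category!r}")


def tsh_category(tsh: float, scheme: str = "two") -> int:
    """Categorize a TSH value (mU/l).

    ``scheme="two"``: category 1 for TSH < 3, category 2 for TSH >= 3.
    ``scheme="three"``: 1 for TSH < 1, 2 for 1 <= TSH < 10, 3 for TSH >= 10.
    """
    if tsh < 0:
        raise ValueError("TSH must be >= 0")
    if scheme == "two":
        return 1 if tsh < 3.0 else 2
    if scheme == "three":
        if tsh < 1.0:
            return 1
        return 2 if tsh < 10.0 else 3
    raise ValueError(f"unknown TSH grouping scheme {scheme!r}")


@dataclass(frozen=True)
class TSHFeedbackSpec:
    """Specification of a TSH feedback on the endogenous production rate.

    coupling: "categorical-2", "categorical-3", "multiplicative" or
    "additive".  For the continuous couplings ``f_form`` selects the
    function of TSH: "identity", "power-ratio", "log" or
    "log-power-ratio"; ratio forms normalize by ``tsh_ref`` (which has no
    canonical value and must be supplied).  ``beta1``/``beta2`` are the
    categorical shifts (nmol/day), ``beta3`` the additive slope, and
    ``beta_exp`` the exponent of the power forms.  ``log_base`` selects the
    logarithm (natural by default).
    """

    coupling: str = "additive"
    f_form: str = "identity"
    tsh_ref: float = 1.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    beta_exp: float = 1.0
    log_base: float = float(np.e)

    def __post_init__(self) -> None:
        if self.coupling not in (
            "categorical-2",
            "categorical-3",
            "multiplicative",
            "additive",
        ):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.f_form not in ("identity", "power-ratio", "log", "log-power-ratio"):
            raise ValueError(f"unknown f(TSH) form {self.f_form!r}")
        if self.f_form in ("power-ratio", "log-power-ratio") and self.tsh_ref <= 0:
            raise ValueError("tsh_ref must be > 0 for ratio forms")

    @property
    def free_betas(self) -> tuple[str, ...]:
        """Names of the coefficients that a fit would estimate."""
        if self.coupling == "categorical-2":
            return ("beta1",)
        if self.coupling == "categorical-3":
            return ("beta1", "beta2")
        if self.coupling == "multiplicative":
            return ("beta_exp",) if "power" in self.f_form else ()
        names = ["beta3"]
        if "power" in self.f_form:
            names.append("beta_exp")
        return tuple(names)


def _log(x, base: float):
    return np.log(x) / np.log(base)


def tsh_function(tsh, spec: TSHFeedbackSpec):
    """Evaluate f(TSH) for the continuous feedback forms.

    TSH values below the quantification floor (0.005 mU/l) are clamped
    before any logarithm to avoid -inf at the detection limit.
    """
    tsh = np.asarray(tsh, float)
    if spec.f_form == "identity":
        out = tsh.copy()
    elif spec.f_form == "power-ratio":
        out = (tsh / spec.tsh_ref) ** spec.beta_exp
    else:
        clamped = np.maximum(tsh, TSH_LOG_FLOOR)
        if spec.f_form == "log":
            out = _log(clamped, spec.log_base)
        else:  # log-power-ratio
            denom = _log(spec.tsh_ref, spec.log_base)
            if denom == 0:
                raise ValueError("log(tsh_ref) = 0: choose tsh_ref != 1")
            out = (_log(clamped, spec.log_base) / denom) ** spec.beta_exp
    return float(out) if out.ndim == 0 else out


def kendo_with_feedback(kendo, tsh, spec: TSHFeedbackSpec):
    """Endogenous production under TSH feedback, floored at 0.

    Categorical couplings add ``beta1``/``beta2`` in the higher TSH
    categories; "multiplicative" returns ``kendo * f(TSH)``; "additive"
    returns ``kendo + beta3 * f(TSH)``.  A negative result (possible for
    negative additive coefficients) is clipped to 0 with a warning since a
    production rate cannot be negative.
    """
    tsh_arr = np.atleast_1d(np.asarray(tsh, float))
    if spec.coupling == "categorical-2":
        shift = np.where(tsh_arr >= 3.0, spec.beta1, 0.0)
        out = kendo + shift
    elif spec.coupling == "categorical-3":
        shift = np.where(tsh_arr >= 10.0, spec.beta2, np.where(tsh_arr >= 1.0, spec.beta1, 0.0))
        out = kendo + shift
    elif spec.coupling == "multiplicative":
        out = kendo * tsh_function(tsh_arr, spec)
    else:
        out = kendo + spec.beta3 * tsh_function(tsh_arr, spec)
    if np.any(out < 0):
        warnings.warn(
            "TSH feedback drove the production rate negative; floored at 0",
            stacklevel=2,
        )
        out = np.maximum(out, 0.0)
    return float(out[0]) if np.ndim(tsh) == 0 else out


# ---------------------------------------------------------------------------
# interpolation of body weight and TSH over time


class Trajectory:
    """Shape-preserving interpolant with constant extrapolation.

    Monotone piecewise-cubic (PCHIP) through the support points: passes
    through every support exactly, never overshoots, and stays positive
    whenever the supports are positive.  Outside the support range the
    nearest support value is carried forward/backward.
    """

    def __init__(self, times, values):
        t = np.asarray(times, float)
        v = np.asarray(values, float)
        if t.size != v.size or t.size == 0:
            raise ValueError("times and values must be equal-length, non-empty")
        if t.size == 1:
            self._const = float(v[0])
            self._interp = None
        else:
            if np.any(np.diff(t) <= 0):
                raise ValueError("support times must be strictly increasing")
            self._const = None
            self._interp = PchipInterpolator(t, v, extrapolate=False)
        self.t_min = float(t.min())
        self.t_max = float(t.max())
        self.v_first = float(v[0])
        self.v_last = float(v[-1])

    def __call__(self, t):
        t = np.asarray(t, float)
        if self._interp is None:
            out = np.full(t.shape, self._const)
        else:
            out = self._interp(np.clip(t, self.t_min, self.t_max))
        return float(out) if out.ndim == 0 else out


def trajectory(times, values) -> Trajectory:
    """Build a :class:`Trajectory` through the support points."""
    return Trajectory(times, values)


def interpolate_daily(times, values, horizon: float) -> np.ndarray:
    """Impute daily values on days ``0 .. horizon`` from sparse supports.

    Uses the monotone shape-preserving interpolant of :class:`Trajectory`
    with constant extrapolation beyond the supports.  With fewer than two
    support points the series falls back to a constant with a warning.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    keep = ~np.isnan(v)
    t, v = t[keep], v[keep]
    days = np.arange(0.0, float(horizon) + 1.0)
    if t.size == 0:
        raise ValueError("no support points at all")
    if t.size == 1:
        warnings.warn("single support point: falling back to a constant series",
                      stacklevel=2)
        return np.full(days.shape, float(v[0]))
    if np.any(v <= 0):
        raise ValueError("support values must be positive")
    return Trajectory(t, v)(days)
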