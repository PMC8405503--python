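"""Structural PK model of T4 under oral LT4 dosing with endogenous production.

A one-compartment model with first-order absorption and elimination plus a
zero-order endogenous production rate ``kendo`` describing the residual
thyroid function:

.. math::

    dA_B/dt &= In(t_j, dose_j, F) - k_a A_B,      & A_B(0) &= 0 \\
    dA_C/dt &= k_a A_B + k_{endo} - k_{el} A_C,   & A_C(0) &= k_{endo}/k_{el}

``A_B`` and ``A_C`` are amounts (nmol) in the absorption and central
compartments.  The initial condition places the untreated patient at the
endogenous equilibrium; stopping treatment always returns the system there
(the disease cannot be cured).  The observed free fraction is

.. math:: C_{FT4} = 0.3 \\cdot A_C / V(W), \\qquad
          V(W) = f_V (W/W_{Ref})^{\\beta_W}

with FT4 assumed to be 0.03% of total T4 (0.3 = 0.03% x 1000 pmol/nmol);
body weight enters the observation through the volume only, never the
amount kinetics.

The system is linear, so the solver below evaluates the exact analytic
superposition of once-daily bolus inputs; an independent numeric integrator
lives in :mod:`thyropop.pk_numeric` and shares no code with it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DOSE_NMOL_PER_MCG",
    "FT4_FRACTION_CONST",
    "PKParameters",
    "DoseRegimen",
    "convert_dose_mcg_to_nmol",
    "volume_of_distribution",
    "baseline_amount",
    "dose_response",
    "absorption_response",
    "production_response",
    "simulate_amounts",
    "ft4_concentration",
    "simulate_ft4_profile",
]

#: mcg/day -> nmol/day conversion for thyroxine (molecular weight
#: 776.9 g/mol).  The printed two-decimal factor is used, not the exact
#: 1000/776.9 = 1.2872, so that reported amounts match the published
#: arithmetic; the discrepancy is < 0.3%.
DOSE_NMOL_PER_MCG = 1.29

#: pmol/l FT4 per (nmol T4 / l): 0.03% free fraction x 1000 pmol/nmol
FT4_FRACTION_CONST = 0.3


@dataclass(frozen=True)
class PKParameters:
    """Structural parameters.

    ka, kel in 1/day; kendo in nmol/day; fv (volume factor) in liters;
    betaw dimensionless; f_bio the oral bioavailability fraction; wref the
    reference body weight in kg (by convention the cohort's median weight).
    """

    ka: float = 20.0
    kel: float = 0.1
    kendo: float = 3.66
    fv: float = 4.96
    betaw: float = 0.753
    f_bio: float = 0.6
    wref: float = 7.0

    def __post_init__(self) -> None:
        for name in ("ka", "kel", "kendo", "fv", "f_bio", "wref"):
            if getattr(self, name) < 0 or (
                name not in ("kendo",) and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive")
        if not (0 < self.f_bio <= 1):
            raise ValueError("f_bio must be in (0, 1]")

    def with_(self, **kw) -> "PKParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class DoseRegimen:
    """Daily-dose history with last-observation-carried-forward semantics.

    ``rows`` is a sequence of ``(t, dose_mcg_per_day)``: the dose holds
    from its row's time until the next row.  :meth:`expand` turns the
    history into one bolus event per day, the first event of each segment
    falling at the row time exactly.
    """

    rows: tuple[tuple[float, float], ...]

    def __init__(self, rows):
        rows = tuple((float(t), float(d)) for t, d in rows)
        if any(d <= 0 for _, d in rows):
            raise ValueError("doses must be > 0")
        if any(t < 0 for t, _ in rows):
            raise ValueError("dose times must be >= 0")
        if any(rows[i][0] >= rows[i + 1][0] for i in range(len(rows) - 1)):
            raise ValueError("dose rows must have strictly increasing times")
        object.__setattr__(self, "rows", rows)

    def expand(self, t_end: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (event_times, doses_mcg), one event per day up to t_end."""
        times: list[float] = []
        doses: list[float] = []
        for i, (t0, d) in enumerate(self.rows):
            t_next = self.rows[i + 1][0] if i + 1 < len(self.rows) else t_end
            t = t0
            while t < t_next and t <= t_end:
                times.append(t)
                doses.append(d)
                t += 1.0
        return np.asarray(times), np.asarray(doses)

    @property
    def empty(self) -> bool:
        return len(self.rows) == 0


def convert_dose_mcg_to_nmol(dose_mcg) -> float | np.ndarray:
    """Convert an LT4 dose from mcg/day to nmol/day (factor 1.29)."""
    dose_mcg = np.asarray(dose_mcg, float)
    if np.any(dose_mcg < 0):
        raise ValueError("dose must be >= 0")
    out = dose_mcg * DOSE_NMOL_PER_MCG
    return float(out) if out.ndim == 0 else out


def volume_of_distribution(w, params: PKParameters):
    """Allometric volume ``V = fv * (W / wref) ** betaw`` in liters."""
    w = np.asarray(w, float)
    if np.any(w <= 0):
        raise ValueError("body weight must be > 0")
    out = params.fv * (w / params.wref) ** params.betaw
    return float(out) if out.ndim == 0 else out


def baseline_amount(params: PKParameters) -> float:
    """No-treatment equilibrium amount ``kendo / kel`` (nmol)."""
    if params.kel <= 0:
        raise ValueError("kel must be > 0")
    return params.kendo / params.kel


# ---------------------------------------------------------------------------
# analytic superposition pieces


def dose_response(
    times, event_times, event_doses_mcg, ka: float, kel: float, f_bio: float
) -> np.ndarray:
    """Dose-driven central amount (nmol) at ``times``.

    Exact Bateman superposition over bolus events of ``f_bio * 1.29 * dose``
    into the absorption compartment.  The degenerate ka == kel case uses
    the analytic limit ``amt * ka * tau * exp(-ka * tau)``.
    """
    times = np.atleast_1d(np.asarray(times, float))
    event_times = np.asarray(event_times, float)
    if event_times.size == 0:
        return np.zeros(times.shape)
    amt = f_bio * DOSE_NMOL_PER_MCG * np.asarray(event_doses_mcg, float)
    tau = times[:, None] - event_times[None, :]
    active = tau >= 0
    tau = np.where(active, tau, 0.0)
    if abs(ka - kel) > 1e-9 * max(ka, kel):
        shape = ka / (ka - kel) * (np.exp(-kel * tau) - np.exp(-ka * tau))
    else:
        shape = ka * tau * np.exp(-ka * tau)
    return (np.where(active, shape, 0.0) * amt[None, :]).sum(axis=1)


def absorption_response(
    times, event_times, event_doses_mcg, ka: float, f_bio: float
) -> np.ndarray:
    """Absorption-compartment amount (nmol): single-exponential sum."""
    times = np.atleast_1d(np.asarray(times, float))
    event_times = np.asarray(event_times, float)
    if event_times.size == 0:
        return np.zeros(times.shape)
    amt = f_bio * DOSE_NMOL_PER_MCG * np.asarray(event_doses_mcg, float)
    tau = times[:, None] - event_times[None, :]
    active = tau >= 0
    return (np.where(active, np.exp(-ka * np.where(active, tau, 0.0)), 0.0)
            * amt[None, :]).sum(axis=1)


def production_response(times, prod_daily, kel: float) -> np.ndarray:
    """Central amount driven by a piecewise-constant daily production rate.

    ``prod_daily[d]`` is the zero-order production (nmol/day) on day
    ``[d, d+1)``; the initial condition is the equilibrium of the first
    day's rate, ``prod_daily[0] / kel``.  For a constant rate this returns
    ``rate / kel`` everywhere.  Used for time-varying TSH feedback on the
    endogenous production.
    """
    times = np.atleast_1d(np.asarray(times, float))
    g = np.asarray(prod_daily, float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("prod_daily must be a non-empty 1-d array")
    out = np.empty(times.shape)
    edges = np.arange(g.size + 1, dtype=float)
    for i, t in enumerate(times):
        # initial equilibrium decays; each completed/partial segment adds
        acc = g[0] / kel * np.exp(-kel * t)
        a = edges[:-1]
        b = np.minimum(edges[1:], t)
        seg = b > a
        if np.any(seg):
            acc += np.sum(
                g[seg] / kel
                * (np.exp(-kel * (t - b[seg])) - np.exp(-kel * (t - a[seg])))
            )
        # beyond the last defined day, carry the last rate forward
        if t > edges[-1]:
            a_last, g_last = edges[-1], g[-1]
            acc += g_last / kel * (1.0 - np.exp(-kel * (t - a_last)))
        out[i] = acc
    return out


def simulate_amounts(
    params: PKParameters,
    regimen: DoseRegimen | None,
    times,
    kendo_daily=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact (A_B, A_C) at the requested times.

    ``kendo_daily`` optionally replaces the constant ``params.kendo`` by a
    piecewise-constant daily production series (nmol/day), e.g. when a TSH
    feedback modulates the endogenous rate.
    """
    times = np.atleast_1d(np.asarray(times, float))
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted and >= 0")
    if regimen is None or regimen.empty:
        ev_t = np.empty(0)
        ev_d = np.empty(0)
    else:
        ev_t, ev_d = regimen.expand(float(times.max()) if times.size else 0.0)
    a_b = absorption_response(times, ev_t, ev_d, params.ka, params.f_bio)
    a_c = dose_response(times, ev_t, ev_d, params.ka, params.kel, params.f_bio)
    if kendo_daily is None:
        a_c = a_c + params.kendo / params.kel
    else:
        a_c = a_c + production_response(times, kendo_daily, params.kel)
    return a_b, a_c


def ft4_concentration(a_c, w, params: PKParameters):
    """FT4 concentration (pmol/l): ``0.3 * A_C / V(W)``."""
    a_c = np.asarray(a_c, float)
    if np.any(a_c < 0):
        raise ValueError("central amount must be >= 0")
    out = FT4_FRACTION_CONST * a_c / volume_of_distribution(w, params)
    return float(out) if out.ndim == 0 else out


def simulate_ft4_profile(
    params: PKParameters,
    regimen: DoseRegimen | None,
    weight,
    times,
    kendo_daily=None,
) -> np.ndarray:
    """FT4 series at ``times`` under a dosing regimen and weight course.

    ``weight`` may be a scalar (kg), an array aligned with ``times`` or a
    callable ``W(t)``.  Weight affects only the observed concentration,
    never the amount kinetics.
    """
    times = np.atleast_1d(np.asarray(times, float))
    _, a_c = simulate_amounts(params, regimen, times, kendo_daily=kendo_daily)
    if callable(weight):
        w = np.asarray([float(weight(t)) for t in times])
    else:
        w = np.broadcast_to(np.asarray(weight, float), times.shape)
    return ft4_concentration(a_c, w, params)
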