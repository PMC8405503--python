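"""Independent numeric integrator for the T4 amount system.

Verification path for the analytic solver in :mod:`thyropop.pk`: the two
ODEs are integrated with an adaptive-step Runge-Kutta scheme, restarting at
every bolus event (instantaneous addition of ``f_bio * 1.29 * dose`` to the
absorption compartment).  Deliberately shares no exponential-superposition
code with the analytic path.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .pk import DOSE_NMOL_PER_MCG, DoseRegimen, PKParameters

__all__ = ["numeric_oracle"]


def numeric_oracle(
    params: PKParameters,
    regimen: DoseRegimen | None,
    times,
    kendo_daily=None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the amount ODEs numerically; returns (A_B, A_C) at times.

    Raises ``RuntimeError`` if the integrator fails to meet its tolerance.
    """
    times = np.atleast_1d(np.asarray(times, float))
    if times.size == 0:
        return np.empty(0), np.empty(0)
    t_end = float(times.max())
    if regimen is None or regimen.empty:
        ev_t = np.empty(0)
        ev_amt = np.empty(0)
    else:
        ev_t, ev_d = regimen.expand(t_end)
        ev_amt = params.f_bio * DOSE_NMOL_PER_MCG * ev_d

    if kendo_daily is None:
        def prod(t: float) -> float:
            return params.kendo
        a_c0 = params.kendo / params.kel
    else:
        g = np.asarray(kendo_daily, float)

        def prod(t: float) -> float:
            return float(g[min(int(t), g.size - 1)])
        a_c0 = float(g[0]) / params.kel

    def rhs(t, y):
        a_b, a_c = y
        return [
            -params.ka * a_b,
            params.ka * a_b + prod(t) - params.kel * a_c,
        ]

    # breakpoints: bolus events, (for time-varying production) day edges,
    # and the requested output times.  Exact float equality is safe here:
    # keys and checkpoints come from the very same arrays.
    bolus_at: dict[float, float] = {}
    for t, a in zip(ev_t, ev_amt):
        bolus_at[float(t)] = bolus_at.get(float(t), 0.0) + a
    breaks = set(bolus_at)
    if kendo_daily is not None:
        breaks.update(float(d) for d in range(1, int(np.ceil(t_end)) + 1))
    checkpoints = sorted(
        {0.0, t_end, *(b for b in breaks if 0.0 <= b <= t_end),
         *(float(t) for t in times)}
    )

    y = np.array([0.0, a_c0])
    out = {}
    t_cur = 0.0
    if t_cur in bolus_at:
        y[0] += bolus_at[t_cur]
    if 0.0 in times:
        out[0.0] = y.copy()
    for t_next in checkpoints:
        if t_next <= t_cur:
            continue
        sol = solve_ivp(
            rhs, (t_cur, t_next), y, method="DOP853", rtol=rtol, atol=atol
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"integration failed at t={t_next}: {sol.message}")
        y = sol.y[:, -1].copy()
        t_cur = t_next
        if t_cur != 0.0 and t_cur in bolus_at:
            y[0] += bolus_at[t_cur]
        if t_cur in times:
            out[t_cur] = y.copy()

    res = np.array([out[float(t)] for t in times])
    return res[:, 0], res[:, 1]
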