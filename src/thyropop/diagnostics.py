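"""Model diagnostics: visual predictive check and goodness-of-fit tables.

The VPC simulates replicate cohorts at the observed design (same subjects,
visit times, doses and weights), summarizes observed and simulated FT4 as
percentiles per time bin, and wraps each simulated percentile in a
confidence band across replicates.  Bins hold (approximately) equal
observation counts because visit density is strongly front-loaded in this
population; percentile convention is linear interpolation (numpy default,
"type 7").  Acceptance of a model is judged on these tables — plots are
optional renderings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimate import (
    FT4_FRACTION_CONST,
    FT4PopulationModel,
    PopulationFit,
    PopulationParameters,
    build_designs,
    empirical_bayes_estimates,
)
from .io import Dataset

__all__ = ["VPCResult", "visual_predictive_check", "goodness_of_fit"]


@dataclass
class VPCResult:
    """Percentile table of a visual predictive check.

    ``observed`` has one row per time bin with the observed percentiles;
    ``simulated`` has, for every percentile, the lower / median / upper
    band across replicates.  Bands are ordered within every bin.
    """

    bin_edges: np.ndarray
    table: pd.DataFrame
    n_replicates: int
    seed: int

    def band_ordering_ok(self) -> bool:
        t = self.table
        lo = t.columns.str.startswith
        ok = True
        for stat in ("obs", "sim_med", "sim_lo", "sim_hi"):
            cols = [c for c in t.columns if c.startswith(stat + "_p")]
            cols = sorted(cols, key=lambda c: float(c.rsplit("p", 1)[1]))
            vals = t[cols].to_numpy(float)
            ok &= bool(np.all(np.diff(vals, axis=1) >= -1e-9))
        return ok


def _resolve_params(fit) -> PopulationParameters:
    if isinstance(fit, PopulationParameters):
        return fit
    if isinstance(fit, PopulationFit):
        return fit.params
    if isinstance(fit, FT4PopulationModel):
        return fit.params_
    raise TypeError("fit must be PopulationParameters, PopulationFit or estimator")


def visual_predictive_check(
    fit,
    dataset: Dataset,
    n_replicates: int = 200,
    n_bins: int = 8,
    percentiles: tuple = (5.0, 50.0, 95.0),
    ci: float = 95.0,
    seed: int = 0,
    ft4_col: str = "auto",
) -> VPCResult:
    """Simulate replicates at the observed design and tabulate percentiles.

    Deterministic under ``seed``.  Empty bins (possible with coarse visit
    grids) are dropped with a warning.
    """
    params = _resolve_params(fit)
    designs, _ = build_designs(
        dataset, params.ka, params.kel, params.f_bio, params.wref,
        params.feedback, ft4_col,
    )
    rng = np.random.default_rng(seed)

    t_all = np.concatenate([d.t for d in designs])
    y_all = np.concatenate([d.y for d in designs])

    # simulate: per subject, all replicates at once
    mu, omega, sigma = params.mu, params.omega, params.sigma_prop
    sims = []
    for d in designs:
        phi = mu[None, :] + omega[None, :] * rng.standard_normal((n_replicates, 3))
        kendo = np.exp(phi[:, 0])[:, None]
        fv = np.exp(phi[:, 1])[:, None]
        bw = np.exp(phi[:, 2])[:, None]
        b_term, a_term = d.terms(params.feedback_betas)
        f = FT4_FRACTION_CONST * (kendo * b_term + a_term + d.d[None, :]) / (
            fv * np.exp(bw * d.lw[None, :])
        )
        eps = rng.standard_normal((n_replicates, d.n))
        sims.append(f * (1.0 + sigma * eps))
    sim = np.concatenate(sims, axis=1)  # (R, N)

    # equal-count time bins (numpy linear-interpolation quantiles)
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(t_all, qs))
    if len(edges) - 1 < n_bins:
        warnings.warn("tied visit times reduced the number of bins", stacklevel=2)
    which = np.clip(np.searchsorted(edges, t_all, side="right") - 1, 0,
                    len(edges) - 2)

    rows = []
    a_lo, a_hi = (100 - ci) / 2.0, 100 - (100 - ci) / 2.0
    for b in range(len(edges) - 1):
        m = which == b
        if m.sum() == 0:
            warnings.warn(f"empty VPC bin {b}; dropped", stacklevel=2)
            continue
        row = {
            "bin": b,
            "t_lo": edges[b],
            "t_hi": edges[b + 1],
            "t_mid": float(np.median(t_all[m])),
            "n": int(m.sum()),
        }
        for p in percentiles:
            row[f"obs_p{p:g}"] = float(np.percentile(y_all[m], p))
            per_rep = np.percentile(sim[:, m], p, axis=1)  # (R,)
            row[f"sim_lo_p{p:g}"] = float(np.percentile(per_rep, a_lo))
            row[f"sim_med_p{p:g}"] = float(np.percentile(per_rep, 50))
            row[f"sim_hi_p{p:g}"] = float(np.percentile(per_rep, a_hi))
        rows.append(row)
    return VPCResult(edges, pd.DataFrame(rows), n_replicates, seed)


def goodness_of_fit(fit, dataset: Dataset, ft4_col: str = "auto") -> tuple[pd.DataFrame, dict]:
    """Observation vs population/individual predictions with weighted residuals.

    Residuals are standardized under the proportional-error model:
    ``iwres = (y - f_ind) / (sigma * f_ind)``; the summary reports their
    mean and variance (a well-calibrated fit has variance near 1).
    """
    params = _resolve_params(fit)
    designs, _ = build_designs(
        dataset, params.ka, params.kel, params.f_bio, params.wref,
        params.feedback, ft4_col,
    )
    if isinstance(fit, (PopulationFit, FT4PopulationModel)):
        ebes = fit.ebes if isinstance(fit, PopulationFit) else fit.ebes_
    else:
        ebes, _ = empirical_bayes_estimates(params, designs=designs)
    ebe_idx = ebes.set_index("subject_id")

    rows = []
    mu = params.mu
    for d in designs:
        f_pop = d.predict(mu, params.feedback_betas)
        if d.subject_id in ebe_idx.index:
            phi_i = ebe_idx.loc[
                d.subject_id, ["phi_kendo", "phi_fv", "phi_betaw"]
            ].to_numpy(float)
        else:
            phi_i = mu
        f_ind = d.predict(phi_i, params.feedback_betas)
        iwres = (d.y - f_ind) / (params.sigma_prop * f_ind)
        for j in range(d.n):
            rows.append(
                {
                    "subject_id": d.subject_id,
                    "t": d.t[j],
                    "observation": d.y[j],
                    "pred_population": f_pop[j],
                    "pred_individual": f_ind[j],
                    "iwres": iwres[j],
                }
            )
    table = pd.DataFrame(rows)
    summary = {
        "iwres_mean": float(table["iwres"].mean()),
        "iwres_var": float(table["iwres"].var(ddof=1)),
        "n_obs": len(table),
    }
    return table, summary
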