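"""Nonlinear mixed-effects estimation of the FT4 population model.

The structural model of :mod:`thyropop.pk` is embedded in a population
model with log-normal inter-individual variability on the endogenous
production rate ``kendo``, the volume factor ``fv`` and the allometric
exponent ``betaw`` (``theta_i = theta_pop * exp(eta_i)``, diagonal
``Omega``), a proportional residual error ``y = f * (1 + sigma * eps)``,
and fixed ``ka``, ``kel`` and bioavailability.

Estimation uses stochastic-approximation EM (SAEM): a Metropolis-Hastings
kernel samples the individual log-parameters, and the sufficient statistics
of the complete-data model (which is exponential-family here) are updated
with decreasing step sizes.  The marginal -2 log-likelihood is computed by
importance sampling around each subject's conditional mode (Laplace-matched
multivariate-t proposal); a pure Laplace approximation is available as a
deterministic fallback and is used for finite-difference Fisher standard
errors.

Because ``ka``, ``kel`` and ``F`` are fixed and the system is linear, the
dose-driven central amount of each subject is precomputed once; evaluating
an individual prediction then costs a handful of vectorized operations,
which keeps SAEM fast enough for simulation studies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

from .covariates import TSHFeedbackSpec, interpolate_daily, trajectory, tsh_function
from .io import Dataset, log
from .pk import FT4_FRACTION_CONST, DoseRegimen, dose_response, production_response

__all__ = [
    "PopulationParameters",
    "PopulationFit",
    "LRTResult",
    "FT4PopulationModel",
    "build_designs",
    "fit_population",
    "minus2_log_likelihood",
    "empirical_bayes_estimates",
    "individual_prediction",
    "compare_models",
    "standard_errors",
]

_LOG2PI = math.log(2.0 * math.pi)
_OMEGA_FLOOR = 1e-8
_RANDOM_EFFECTS = ("kendo", "fv", "betaw")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class PopulationParameters:
    """Population-level parameters of the final model.

    Typical values (``kendo`` nmol/day, ``fv`` l, ``betaw`` unitless),
    log-scale IIV standard deviations, the proportional residual error
    magnitude ``sigma_prop``, the fixed constants, and an optional TSH
    feedback specification with its coefficient values.
    """

    kendo: float = 3.66
    fv: float = 4.96
    betaw: float = 0.753
    omega_kendo: float = 1.12
    omega_fv: float = 0.249
    omega_betaw: float = 0.404
    sigma_prop: float = 0.228
    ka: float = 20.0
    kel: float = 0.1
    f_bio: float = 0.6
    wref: float = 7.0
    feedback: TSHFeedbackSpec | None = None
    feedback_betas: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("kendo", "fv", "betaw", "sigma_prop", "ka", "kel", "wref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("omega_kendo", "omega_fv", "omega_betaw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def mu(self) -> np.ndarray:
        return np.log([self.kendo, self.fv, self.betaw])

    @property
    def omega(self) -> np.ndarray:
        return np.array([self.omega_kendo, self.omega_fv, self.omega_betaw])


@dataclass
class PopulationFit:
    """Result of a population fit."""

    params: PopulationParameters
    minus2ll: float
    converged: bool
    ebes: pd.DataFrame  # per-subject phi (log params) and eta columns
    shrinkage: dict  # percent per random effect
    rse: dict | None = None  # percent, if standard errors were computed
    n_subjects: int = 0
    n_obs: int = 0

    @property
    def minus2ll_(self) -> float:  # uniform access for compare_models
        return self.minus2ll


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of two nested fits."""

    delta_ofv: float
    df: int
    p_value: float
    significant: bool
    negative_delta: bool  # approximation/convergence artifact flag


# ---------------------------------------------------------------------------
# per-subject design


class _SubjectFeedback:
    """Precomputed production-response bases for one subject's TSH series."""

    def __init__(self, spec: TSHFeedbackSpec, tsh_daily: np.ndarray,
                 t_obs: np.ndarray, kel: float):
        self.spec = spec
        self.kel = kel
        self.t_obs = t_obs
        self.tsh_daily = tsh_daily
        self._cache_exp: float | None = None
        self._cache_g: np.ndarray | None = None
        if spec.coupling == "categorical-2":
            self.g_cat = [
                production_response(t_obs, (tsh_daily >= 3.0).astype(float), kel)
            ]
        elif spec.coupling == "categorical-3":
            self.g_cat = [
                production_response(
                    t_obs,
                    ((tsh_daily >= 1.0) & (tsh_daily < 10.0)).astype(float),
                    kel,
                ),
                production_response(t_obs, (tsh_daily >= 10.0).astype(float), kel),
            ]
        elif "power" not in spec.f_form:
            self._cache_g = production_response(
                t_obs, tsh_function(tsh_daily, spec), kel
            )
            self._cache_exp = spec.beta_exp

    def _g(self, beta_exp: float) -> np.ndarray:
        if "power" not in self.spec.f_form:
            return self._cache_g
        if self._cache_exp is None or beta_exp != self._cache_exp:
            spec = replace(self.spec, beta_exp=beta_exp)
            self._cache_g = production_response(
                self.t_obs, tsh_function(self.tsh_daily, spec), self.kel
            )
            self._cache_exp = beta_exp
        return self._cache_g

    def terms(self, betas: dict) -> tuple[np.ndarray | float, np.ndarray | float]:
        """Return (kendo multiplier B, additive production amount A)."""
        spec = self.spec
        if spec.coupling == "categorical-2":
            return 1.0 / self.kel, betas.get("beta1", 0.0) * self.g_cat[0]
        if spec.coupling == "categorical-3":
            return (
                1.0 / self.kel,
                betas.get("beta1", 0.0) * self.g_cat[0]
                + betas.get("beta2", 0.0) * self.g_cat[1],
            )
        if spec.coupling == "multiplicative":
            return self._g(betas.get("beta_exp", spec.beta_exp)), 0.0
        # additive
        return (
            1.0 / self.kel,
            betas.get("beta3", 0.0) * self._g(betas.get("beta_exp", spec.beta_exp)),
        )


@dataclass
class SubjectDesign:
    """Everything needed to predict one subject at its observation times."""

    subject_id: str
    t: np.ndarray
    y: np.ndarray
    lw: np.ndarray  # log(W(t) / wref)
    d: np.ndarray  # dose-driven central amount (nmol)
    inv_kel: float
    fb: _SubjectFeedback | None = None

    @property
    def n(self) -> int:
        return self.t.size

    def terms(self, betas: dict | None):
        if self.fb is None:
            return self.inv_kel, 0.0
        return self.fb.terms(betas or {})

    def predict(self, phi: np.ndarray, betas: dict | None = None) -> np.ndarray:
        kendo, fv, betaw = np.exp(phi)
        b_term, a_term = self.terms(betas)
        a_c = kendo * b_term + a_term + self.d
        return FT4_FRACTION_CONST * a_c / (fv * np.exp(betaw * self.lw))


def build_designs(
    dataset: Dataset,
    ka: float = 20.0,
    kel: float = 0.1,
    f_bio: float = 0.6,
    wref: float | None = None,
    feedback: TSHFeedbackSpec | None = None,
    ft4_col: str = "auto",
) -> tuple[list[SubjectDesign], float]:
    """Assemble per-subject fitting designs from a dataset.

    ``wref=None`` uses the median of all observed body weights, the
    conventional reference for the allometric volume.  ``ft4_col="auto"``
    fits ``ft4_norm`` when normalization has been run, raw ``ft4``
    otherwise.
    """
    obs = dataset.observations
    if ft4_col == "auto":
        ft4_col = "ft4_norm" if "ft4_norm" in obs.columns else "ft4"
    if ft4_col not in obs.columns:
        raise ValueError(f"no column {ft4_col!r} in observations")
    weights_all = obs["weight"].dropna()
    if wref is None:
        if weights_all.empty:
            raise ValueError("cannot infer wref: no weights in dataset")
        wref = float(weights_all.median())

    designs = []
    for sid, g in obs.groupby("subject_id", sort=True):
        y_mask = g[ft4_col].notna()
        if y_mask.sum() == 0:
            continue
        t_obs = g.loc[y_mask, "t"].to_numpy(float)
        y = g.loc[y_mask, ft4_col].to_numpy(float)
        if y_mask.sum() < 2:
            log(f"subject {sid!r} has a single FT4 observation", "WARNING")

        w_rows = g["weight"].notna()
        if w_rows.sum() == 0:
            raise ValueError(f"subject {sid!r} has no body weights")
        w_traj = trajectory(
            g.loc[w_rows, "t"].to_numpy(float), g.loc[w_rows, "weight"].to_numpy(float)
        )
        lw = np.log(np.asarray(w_traj(t_obs), float) / wref)

        dose_rows = g["dose_daily"].notna()
        if dose_rows.sum():
            regimen = DoseRegimen(
                list(
                    zip(
                        g.loc[dose_rows, "t"].to_numpy(float),
                        g.loc[dose_rows, "dose_daily"].to_numpy(float),
                    )
                )
            )
            ev_t, ev_d = regimen.expand(float(t_obs.max()))
            d = dose_response(t_obs, ev_t, ev_d, ka, kel, f_bio)
        else:
            d = np.zeros_like(t_obs)

        fb = None
        if feedback is not None:
            tsh_rows = g["tsh"].notna()
            if tsh_rows.sum() == 0:
                raise ValueError(
                    f"subject {sid!r} has no TSH values but a feedback is requested"
                )
            tsh_daily = interpolate_daily(
                g.loc[tsh_rows, "t"].to_numpy(float),
                g.loc[tsh_rows, "tsh"].to_numpy(float),
                horizon=float(np.ceil(t_obs.max())) + 1,
            )
            fb = _SubjectFeedback(feedback, tsh_daily, t_obs, kel)

        designs.append(SubjectDesign(str(sid), t_obs, y, lw, d, 1.0 / kel, fb))
    if not designs:
        raise ValueError("no usable FT4 observations in dataset")
    return designs, wref


# ---------------------------------------------------------------------------
# likelihood pieces


def _cond_m2ll(design: SubjectDesign, phi: np.ndarray, sigma: float,
               betas: dict | None) -> float:
    """Conditional -2 log-likelihood of one subject given its parameters."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        f = design.predict(phi, betas)
    if not np.all(np.isfinite(f)) or np.any(f <= 0):
        return np.inf
    r = (design.y - f) / (sigma * f)
    return float(r @ r + 2.0 * np.sum(np.log(sigma * f)) + design.n * _LOG2PI)


def _prior_m2ll(phi: np.ndarray, mu: np.ndarray, omega: np.ndarray,
                free: np.ndarray) -> float:
    z = (phi[free] - mu[free]) / omega[free]
    return float(z @ z + 2.0 * np.sum(np.log(omega[free])) + free.sum() * _LOG2PI)


def _joint_m2ll(design, phi, mu, omega, sigma, betas, free):
    return _cond_m2ll(design, phi, sigma, betas) + _prior_m2ll(phi, mu, omega, free)


def _conditional_mode(design, mu, omega, sigma, betas, free, x0=None):
    """Minimize the joint -2LL over the free components of phi."""
    idx = np.nonzero(free)[0]

    def h(x):
        phi = mu.copy()
        phi[idx] = x
        return _joint_m2ll(design, phi, mu, omega, sigma, betas, free)

    x0 = (mu[idx] if x0 is None else np.asarray(x0)[idx]).astype(float)
    res = optimize.minimize(h, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 600})
    res2 = optimize.minimize(h, res.x, method="BFGS",
                             options={"gtol": 1e-7, "maxiter": 200})
    if res2.fun <= res.fun:
        res = res2
    phi = mu.copy()
    phi[idx] = res.x
    return phi, float(res.fun)


def _hessian_fd(fun, x, step=1e-4):
    """Central finite-difference Hessian of a scalar function."""
    k = x.size
    h = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = step
            ej = np.zeros(k); ej[j] = step
            if i == j:
                h[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / step**2
            else:
                h[i, j] = h[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * step**2)
    return h


def _spd(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.maximum(vals, floor)
    return vecs @ np.diag(vals) @ vecs.T


def _subject_m2ll(design, params: PopulationParameters, method, n_draws, rng,
                  x0=None):
    mu, omega, sigma = params.mu, params.omega, params.sigma_prop
    betas = params.feedback_betas
    free = omega > _OMEGA_FLOOR
    if not free.any():
        return _cond_m2ll(design, mu, sigma, betas), mu
    phi_hat, h_min = _conditional_mode(design, mu, omega, sigma, betas, free, x0)
    idx = np.nonzero(free)[0]
    k = idx.size

    def h_free(x):
        phi = phi_hat.copy()
        phi[idx] = x
        return _joint_m2ll(design, phi, mu, omega, sigma, betas, free)

    hess = _hessian_fd(lambda x: 0.5 * h_free(x), phi_hat[idx])
    hess = _spd(hess)
    if method == "laplace":
        sign, logdet = np.linalg.slogdet(hess)
        return h_min - k * _LOG2PI + logdet, phi_hat

    # importance sampling with a multivariate-t proposal (df=4)
    df = 4.0
    cov = _spd(np.linalg.inv(hess))
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_draws, k))
    chi = rng.chisquare(df, size=n_draws)
    x = phi_hat[idx][None, :] + (z @ chol.T) * np.sqrt(df / chi)[:, None]

    # vectorized joint -2LL over draws
    phi_mat = np.tile(phi_hat, (n_draws, 1))
    phi_mat[:, idx] = x
    kendo = np.exp(phi_mat[:, 0])[:, None]
    fv = np.exp(phi_mat[:, 1])[:, None]
    bw = np.exp(phi_mat[:, 2])[:, None]
    b_term, a_term = design.terms(betas)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        a_c = kendo * b_term + a_term + design.d[None, :]
        f = FT4_FRACTION_CONST * a_c / (fv * np.exp(bw * design.lw[None, :]))
        ok = np.all(np.isfinite(f) & (f > 0), axis=1)
        f = np.where(np.isfinite(f) & (f > 0), f, 1.0)
        r = (design.y[None, :] - f) / (sigma * f)
        cond = (r * r).sum(axis=1) + 2.0 * np.log(sigma * f).sum(axis=1) \
            + design.n * _LOG2PI
    zp = (x - params.mu[idx][None, :]) / omega[idx][None, :]
    prior = (zp * zp).sum(axis=1) + 2.0 * np.sum(np.log(omega[idx])) + k * _LOG2PI
    joint = np.where(ok, cond + prior, np.inf)

    # log t-density
    diff = x - phi_hat[idx][None, :]
    sol = np.linalg.solve(chol, diff.T).T
    maha = (sol * sol).sum(axis=1)
    _, logdet_cov = np.linalg.slogdet(cov)
    logq = (
        gammaln((df + k) / 2.0) - gammaln(df / 2.0)
        - 0.5 * k * math.log(df * math.pi) - 0.5 * logdet_cov
        - (df + k) / 2.0 * np.log1p(maha / df)
    )
    logw = -0.5 * joint - logq
    ln_li = logsumexp(logw) - math.log(n_draws)
    return -2.0 * ln_li, phi_hat


def minus2_log_likelihood(
    params: PopulationParameters,
    dataset: Dataset | None = None,
    designs: list[SubjectDesign] | None = None,
    method: str = "importance",
    n_draws: int = 5000,
    seed: int = 0,
    warm_start: np.ndarray | None = None,
) -> float:
    """Marginal -2 log-likelihood of the population model.

    ``method="importance"`` (default) integrates each subject's random
    effects by importance sampling with a Laplace-matched multivariate-t
    proposal; ``method="laplace"`` is the deterministic Laplace
    approximation.  With all omegas at 0 the integral degenerates and the
    closed-form Gaussian sum is returned.  Deterministic given ``seed``.
    """
    if designs is None:
        if dataset is None:
            raise ValueError("either dataset or designs must be given")
        designs, _ = build_designs(
            dataset, params.ka, params.kel, params.f_bio, params.wref,
            params.feedback,
        )
    rng = np.random.default_rng(seed)
    total = 0.0
    for i, design in enumerate(designs):
        x0 = warm_start[i] if warm_start is not None else None
        val, _ = _subject_m2ll(design, params, method, n_draws, rng, x0)
        if not np.isfinite(val):
            warnings.warn(
                f"subject {design.subject_id!r}: non-finite likelihood contribution",
                stacklevel=2,
            )
        total += val
    return float(total)


# ---------------------------------------------------------------------------
# SAEM


class _Stack:
    """Padded across-subject arrays for vectorized SAEM updates."""

    def __init__(self, designs: list[SubjectDesign], betas: dict | None):
        n = len(designs)
        j = max(d.n for d in designs)
        self.n, self.j = n, j
        self.y = np.zeros((n, j))
        self.d = np.zeros((n, j))
        self.lw = np.zeros((n, j))
        self.mask = np.zeros((n, j), dtype=bool)
        self.nobs = np.array([d.n for d in designs])
        self.b = np.full((n, j), designs[0].inv_kel)
        self.a = np.zeros((n, j))
        for i, des in enumerate(designs):
            sl = slice(0, des.n)
            self.y[i, sl] = des.y
            self.d[i, sl] = des.d
            self.lw[i, sl] = des.lw
            self.mask[i, sl] = True
        self.designs = designs
        self.update_feedback(betas)

    def update_feedback(self, betas: dict | None) -> None:
        if self.designs[0].fb is None:
            return
        for i, des in enumerate(self.designs):
            b_term, a_term = des.terms(betas)
            self.b[i, : des.n] = b_term
            self.a[i, : des.n] = a_term

    def cond_m2ll(self, phi: np.ndarray, sigma: float):
        """Vector of conditional -2LL per subject; also returns residual stat."""
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            kendo = np.exp(phi[:, 0])[:, None]
            fv = np.exp(phi[:, 1])[:, None]
            bw = np.exp(phi[:, 2])[:, None]
            a_c = kendo * self.b + self.a + self.d
            f = FT4_FRACTION_CONST * a_c / (fv * np.exp(bw * self.lw))
        bad = np.any((~np.isfinite(f) | (f <= 0)) & self.mask, axis=1)
        f = np.where(np.isfinite(f) & (f > 0), f, 1.0)
        r = np.where(self.mask, (self.y - f) / (sigma * f), 0.0)
        val = (r * r).sum(axis=1) + 2.0 * np.where(
            self.mask, np.log(sigma * f), 0.0
        ).sum(axis=1) + self.nobs * _LOG2PI
        val = np.where(bad, np.inf, val)
        rel2 = np.where(self.mask, ((self.y - f) / f) ** 2, 0.0).sum(axis=1)
        return val, np.where(bad, np.nan, rel2)


def _saem(designs, mu0, omega0, sigma0, feedback, betas0, n_burnin, n_iter, rng):
    """Run SAEM; returns (mu, omega, sigma, betas, phi, converged, history)."""
    n = len(designs)
    n_total = sum(d.n for d in designs)
    mu = mu0.copy()
    omega = np.maximum(omega0.copy(), 0.05)
    sigma = float(sigma0)
    betas = dict(betas0)
    free_names = feedback.free_betas if feedback is not None else ()

    stack = _Stack(designs, betas)
    phi = mu[None, :] + 0.5 * rng.standard_normal((n, 3))
    cur, _ = stack.cond_m2ll(phi, sigma)
    step = np.full(3, 0.4)
    acc_count = np.zeros(3)
    prop_count = np.zeros(3)

    s1 = np.zeros(3)
    s2 = np.zeros(3)
    s3 = 0.0
    history = []

    def prior_vec(p):
        z = (p - mu[None, :]) / omega[None, :]
        return (z * z).sum(axis=1)

    for k in range(n_burnin + n_iter):
        gamma = 1.0 if k < n_burnin else 1.0 / (k - n_burnin + 1)

        # --- simulation step: MH kernels -------------------------------
        # kernel 1: independent proposal from the current prior
        prop = mu[None, :] + omega[None, :] * rng.standard_normal((n, 3))
        cand, _ = stack.cond_m2ll(prop, sigma)
        accept = np.log(rng.uniform(size=n)) < 0.5 * (cur - cand)
        phi[accept] = prop[accept]
        cur[accept] = cand[accept]

        # kernel 2: componentwise random walk on the joint
        for c in range(3):
            prop = phi.copy()
            prop[:, c] += step[c] * rng.standard_normal(n)
            cand, _ = stack.cond_m2ll(prop, sigma)
            dj = (cur + prior_vec(phi)) - (cand + prior_vec(prop))
            accept = np.log(rng.uniform(size=n)) < 0.5 * dj
            phi[accept] = prop[accept]
            cur[accept] = cand[accept]
            acc_count[c] += accept.sum()
            prop_count[c] += n
        if k < n_burnin and (k + 1) % 20 == 0:
            rate = acc_count / np.maximum(prop_count, 1)
            step *= np.exp(0.6 * (rate - 0.35))
            step = np.clip(step, 0.01, 2.0)
            acc_count[:] = 0
            prop_count[:] = 0

        # --- feedback-coefficient update (no IIV on betas) --------------
        # delayed and damped during burn-in: an undamped per-iteration
        # argmax chases the Monte-Carlo noise of the chain and can drag
        # the population parameters into a biased quasi-mode
        if free_names and k >= n_burnin // 3:
            def beta_obj(x):
                trial = dict(betas)
                for name, v in zip(free_names, x):
                    trial[name] = float(v)
                stack.update_feedback(trial)
                vals, _ = stack.cond_m2ll(phi, sigma)
                return vals.sum() if np.all(np.isfinite(vals)) else 1e12

            x0 = np.array([betas.get(nm, 0.0) for nm in free_names])
            res = optimize.minimize(
                beta_obj, x0, method="Nelder-Mead",
                options={"maxiter": 40, "xatol": 1e-5, "fatol": 1e-6},
            )
            damp = 0.3 if k < n_burnin else gamma
            new = x0 + damp * (res.x - x0)
            for name, v in zip(free_names, new):
                betas[name] = float(v)
            stack.update_feedback(betas)
            cur, _ = stack.cond_m2ll(phi, sigma)

        # --- stochastic approximation of sufficient statistics ----------
        _, rel2 = stack.cond_m2ll(phi, sigma)
        s1 = s1 + gamma * (phi.sum(axis=0) - s1)
        s2 = s2 + gamma * ((phi**2).sum(axis=0) - s2)
        s3 = s3 + gamma * (np.nansum(rel2) - s3)

        mu = s1 / n
        var = np.maximum(s2 / n - mu**2, 1e-6)
        new_omega = np.sqrt(var)
        if k < n_burnin:
            new_omega = np.maximum(new_omega, 0.90 * omega)
        omega = new_omega
        sigma = max(math.sqrt(s3 / n_total), 1e-4)
        cur, _ = stack.cond_m2ll(phi, sigma)
        history.append(np.concatenate([mu, omega, [sigma]]))

    history = np.asarray(history)
    tail = history[-min(50, len(history)):]
    drift = np.abs(tail[-1] - tail[0]) / np.maximum(np.abs(tail[-1]), 1e-6)
    converged = bool(np.all(drift < 0.05))
    return mu, omega, sigma, betas, phi, converged, history


# ---------------------------------------------------------------------------
# estimator


class FT4PopulationModel(BaseEstimator):
    """Population PK model of FT4 under LT4 therapy (SAEM estimator).

    scikit-learn style: ``fit(dataset)`` estimates the typical values of
    ``kendo`` (nmol/day), ``fv`` (l) and ``betaw``, their log-normal IIV
    standard deviations, the proportional error magnitude, and any TSH
    feedback coefficients; fitted values land in trailing-underscore
    attributes.  ``ka``, ``kel`` and ``f_bio`` are fixed by default
    (estimating them is a sensitivity-analysis switch handled upstream by
    passing different fixed values).

    Parameters
    ----------
    ka, kel, f_bio : fixed structural constants (1/day, 1/day, fraction).
    wref : reference weight (kg); None uses the dataset median.
    kendo0, fv0, betaw0, omega0, sigma0 : initial estimates.
    feedback : optional :class:`~thyropop.covariates.TSHFeedbackSpec`.
    ft4_col : observation column; ``"auto"`` prefers ``ft4_norm``.
    n_burnin, n_iter : SAEM exploration / smoothing iteration counts.
    ll_method, ll_draws : how ``minus2ll_`` is computed after the fit.
    random_state : seed for the SAEM chain and likelihood evaluation.
    """

    def __init__(
        self,
        ka: float = 20.0,
        kel: float = 0.1,
        f_bio: float = 0.6,
        wref: float | None = None,
        kendo0: float = 2.0,
        fv0: float = 3.0,
        betaw0: float = 0.8,
        omega0: tuple = (0.5, 0.3, 0.3),
        sigma0: float = 0.3,
        feedback: TSHFeedbackSpec | None = None,
        ft4_col: str = "auto",
        n_burnin: int = 400,
        n_iter: int = 200,
        ll_method: str = "importance",
        ll_draws: int = 5000,
        compute_ll: bool = True,
        random_state: int = 0,
    ):
        self.ka = ka
        self.kel = kel
        self.f_bio = f_bio
        self.wref = wref
        self.kendo0 = kendo0
        self.fv0 = fv0
        self.betaw0 = betaw0
        self.omega0 = omega0
        self.sigma0 = sigma0
        self.feedback = feedback
        self.ft4_col = ft4_col
        self.n_burnin = n_burnin
        self.n_iter = n_iter
        self.ll_method = ll_method
        self.ll_draws = ll_draws
        self.compute_ll = compute_ll
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X: Dataset, y=None):
        designs, wref = build_designs(
            X, self.ka, self.kel, self.f_bio, self.wref, self.feedback,
            self.ft4_col,
        )
        rng = np.random.default_rng(self.random_state)
        mu0 = np.log([self.kendo0, self.fv0, self.betaw0])
        betas0 = {name: 0.0 for name in
                  (self.feedback.free_betas if self.feedback else ())}
        mu, omega, sigma, betas, phi, converged, history = _saem(
            designs, mu0, np.asarray(self.omega0, float), self.sigma0,
            self.feedback, betas0, self.n_burnin, self.n_iter, rng,
        )
        self.kendo_, self.fv_, self.betaw_ = np.exp(mu)
        self.omega_ = dict(zip(_RANDOM_EFFECTS, omega))
        self.sigma_prop_ = sigma
        self.feedback_betas_ = betas
        self.converged_ = converged
        self.history_ = history
        self.wref_ = wref
        self.n_subjects_ = len(designs)
        self.n_obs_ = int(sum(d.n for d in designs))
        self._designs = designs
        self._phi_chain = phi

        params = self.params_
        ebes, shrink = empirical_bayes_estimates(params, designs=designs,
                                                 warm_start=phi)
        self.ebes_ = ebes
        self.shrinkage_ = shrink
        if self.compute_ll:
            self.minus2ll_ = minus2_log_likelihood(
                params, designs=designs, method=self.ll_method,
                n_draws=self.ll_draws, seed=self.random_state,
                warm_start=ebes[["phi_kendo", "phi_fv", "phi_betaw"]].to_numpy(),
            )
        else:
            self.minus2ll_ = math.nan
        if not converged:
            log("SAEM did not meet the drift criterion; fit flagged "
                "non-converged", "WARNING")
        return self

    @property
    def params_(self) -> PopulationParameters:
        return PopulationParameters(
            kendo=float(self.kendo_), fv=float(self.fv_), betaw=float(self.betaw_),
            omega_kendo=float(self.omega_["kendo"]),
            omega_fv=float(self.omega_["fv"]),
            omega_betaw=float(self.omega_["betaw"]),
            sigma_prop=float(self.sigma_prop_),
            ka=self.ka, kel=self.kel, f_bio=self.f_bio, wref=float(self.wref_),
            feedback=self.feedback, feedback_betas=dict(self.feedback_betas_),
        )

    # -- prediction --------------------------------------------------------

    def predict(self, X: Dataset, individual: bool = False) -> pd.DataFrame:
        """Predicted FT4 at each subject's observation times.

        ``individual=True`` uses the empirical-Bayes etas of the fitted
        subjects (unknown subjects fall back to the typical profile).
        """
        designs, _ = build_designs(
            X, self.ka, self.kel, self.f_bio, self.wref_, self.feedback,
            self.ft4_col,
        )
        mu = self.params_.mu
        ebe = self.ebes_.set_index("subject_id") if individual else None
        rows = []
        for d in designs:
            phi = mu
            if individual and ebe is not None and d.subject_id in ebe.index:
                phi = ebe.loc[
                    d.subject_id, ["phi_kendo", "phi_fv", "phi_betaw"]
                ].to_numpy(float)
            f = d.predict(phi, self.feedback_betas_)
            for t, pred in zip(d.t, f):
                rows.append({"subject_id": d.subject_id, "t": t, "pred": pred})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# module-level operations


def individual_prediction(
    params: PopulationParameters, eta: np.ndarray, dataset: Dataset,
    subject_id: str,
) -> np.ndarray:
    """Deterministic FT4 profile of one subject for a given eta vector."""
    designs, _ = build_designs(
        dataset, params.ka, params.kel, params.f_bio, params.wref,
        params.feedback,
    )
    for d in designs:
        if d.subject_id == str(subject_id):
            return d.predict(params.mu + np.asarray(eta, float),
                             params.feedback_betas)
    raise KeyError(f"subject {subject_id!r} not in dataset")


def empirical_bayes_estimates(
    params: PopulationParameters,
    dataset: Dataset | None = None,
    designs: list[SubjectDesign] | None = None,
    warm_start: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Conditional modes of the individual parameters plus shrinkage.

    Shrinkage per random effect is ``(1 - sd(eta_hat) / omega) * 100``
    (capped into [0, 100] for reporting); an omega of 0 makes it undefined
    and it is reported as NaN.
    """
    if designs is None:
        designs, _ = build_designs(
            dataset, params.ka, params.kel, params.f_bio, params.wref,
            params.feedback,
        )
    mu, omega = params.mu, params.omega
    free = omega > _OMEGA_FLOOR
    rows = []
    for i, d in enumerate(designs):
        x0 = warm_start[i] if warm_start is not None else None
        phi_hat, _ = _conditional_mode(
            d, mu, omega, params.sigma_prop, params.feedback_betas, free, x0
        )
        eta = phi_hat - mu
        rows.append(
            {
                "subject_id": d.subject_id,
                "phi_kendo": phi_hat[0], "phi_fv": phi_hat[1],
                "phi_betaw": phi_hat[2],
                "eta_kendo": eta[0], "eta_fv": eta[1], "eta_betaw": eta[2],
                "kendo_i": math.exp(phi_hat[0]), "fv_i": math.exp(phi_hat[1]),
                "betaw_i": math.exp(phi_hat[2]),
            }
        )
    ebes = pd.DataFrame(rows)
    shrink = {}
    for j, name in enumerate(_RANDOM_EFFECTS):
        if omega[j] <= _OMEGA_FLOOR:
            shrink[name] = math.nan
        else:
            sd = float(ebes[f"eta_{name}"].std(ddof=0))
            shrink[name] = float(np.clip((1.0 - sd / omega[j]) * 100.0, 0.0, 100.0))
    return ebes, shrink


def fit_population(
    dataset: Dataset,
    start: PopulationParameters | None = None,
    feedback: TSHFeedbackSpec | None = None,
    wref: float | None = None,
    n_burnin: int = 400,
    n_iter: int = 200,
    ll_method: str = "importance",
    ll_draws: int = 5000,
    compute_rse: bool = False,
    seed: int = 0,
) -> PopulationFit:
    """Fit the population model; functional wrapper over the estimator.

    ``start`` supplies initial estimates and the fixed constants; by
    default generic initial values are used.  Returns a
    :class:`PopulationFit` with estimates, -2LL, EBEs, shrinkage and
    (optionally) Fisher-information RSEs.
    """
    kw = {}
    if start is not None:
        kw = dict(
            ka=start.ka, kel=start.kel, f_bio=start.f_bio,
            kendo0=start.kendo, fv0=start.fv, betaw0=start.betaw,
            omega0=(start.omega_kendo or 0.3, start.omega_fv or 0.3,
                    start.omega_betaw or 0.3),
            sigma0=start.sigma_prop,
        )
        feedback = feedback or start.feedback
    est = FT4PopulationModel(
        wref=wref, feedback=feedback, n_burnin=n_burnin, n_iter=n_iter,
        ll_method=ll_method, ll_draws=ll_draws, random_state=seed, **kw,
    ).fit(dataset)
    params = est.params_
    rse = None
    if compute_rse:
        rse = standard_errors(params, designs=est._designs)
    return PopulationFit(
        params=params,
        minus2ll=est.minus2ll_,
        converged=est.converged_,
        ebes=est.ebes_,
        shrinkage=est.shrinkage_,
        rse=rse,
        n_subjects=est.n_subjects_,
        n_obs=est.n_obs_,
    )


def standard_errors(
    params: PopulationParameters,
    dataset: Dataset | None = None,
    designs: list[SubjectDesign] | None = None,
    step: float = 0.02,
) -> dict:
    """Relative standard errors (%) from the observed Fisher information.

    Finite-difference Hessian of the Laplace -2LL with respect to the
    log-transformed population parameters; the SE of a log-parameter is
    itself (approximately) the relative SE of the parameter.
    """
    if designs is None:
        designs, _ = build_designs(
            dataset, params.ka, params.kel, params.f_bio, params.wref,
            params.feedback,
        )
    names = ["kendo", "fv", "betaw", "omega_kendo", "omega_fv", "omega_betaw",
             "sigma_prop"]
    beta_names = list(params.feedback.free_betas) if params.feedback else []
    x0 = np.array(
        [math.log(getattr(params, nm)) for nm in names]
        + [params.feedback_betas.get(nm, 0.0) for nm in beta_names]
    )

    def obj(x):
        p = replace(
            params,
            **{nm: math.exp(v) for nm, v in zip(names, x[: len(names)])},
            feedback_betas={
                **params.feedback_betas,
                **{nm: v for nm, v in zip(beta_names, x[len(names):])},
            },
        )
        return minus2_log_likelihood(p, designs=designs, method="laplace")

    hess = _hessian_fd(obj, x0, step=step)
    cov = 2.0 * np.linalg.inv(_spd(hess, floor=1e-10))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    out = {nm: float(se[i] * 100.0) for i, nm in enumerate(names)}
    for j, nm in enumerate(beta_names):
        out[nm] = float(se[len(names) + j])  # absolute SE for raw coefficients
    return out


def compare_models(
    fit_reduced, fit_full, df: int | None = None, alpha: float = 0.05
) -> LRTResult:
    """Likelihood-ratio test between nested population fits.

    ``delta_ofv = -2LL_reduced - (-2LL_full)`` compared against a
    chi-square with ``df`` degrees of freedom (default: the number of extra
    feedback coefficients in the full model).  A negative delta beyond
    numerical tolerance is flagged as an approximation or convergence
    artifact and treated as no improvement.
    """
    m2_red = getattr(fit_reduced, "minus2ll_", None)
    m2_full = getattr(fit_full, "minus2ll_", None)
    if m2_red is None or m2_full is None:
        raise ValueError("both fits must carry a minus2ll_ value")
    if df is None:
        fb_r = getattr(getattr(fit_reduced, "params", fit_reduced), "feedback", None)
        fb_f = getattr(getattr(fit_full, "params", fit_full), "feedback", None)
        n_r = len(fb_r.free_betas) if fb_r is not None else 0
        n_f = len(fb_f.free_betas) if fb_f is not None else 0
        df = max(n_f - n_r, 1)
    delta = float(m2_red - m2_full)
    negative = delta < -1e-6
    stat = max(delta, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(
        delta_ofv=delta, df=df, p_value=p,
        significant=bool(p < alpha and not negative), negative_delta=negative,
    )
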