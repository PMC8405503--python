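"""Mixed-effects estimation: likelihood, SAEM recovery, EBEs, LRT."""

import math

import numpy as np
import pandas as pd
import pytest

import thyropop as tp
from thyropop.estimate import build_designs, minus2_log_likelihood

_LOG2PI = math.log(2 * math.pi)


def _no_dose_dataset(y_values, weight=5.0, pna=7.0):
    obs = [
        tp.LabObservation("A", float(10 * i), ft4=float(y), weight=weight)
        for i, y in enumerate(y_values)
    ]
    return tp.Dataset.from_records(
        [tp.SubjectRecord("A", pna_start_days=pna)], obs
    )


@pytest.fixture(scope="module")
def fitted_small(identity_cohort):
    ds, truth = identity_cohort
    est = tp.FT4PopulationModel(
        wref=truth.population.wref, n_burnin=250, n_iter=120,
        ll_draws=2000, random_state=0,
    ).fit(ds)
    return ds, truth, est


class TestLikelihood:
    def test_degenerate_no_iiv_closed_form(self):
        params = tp.PopulationParameters(
            omega_kendo=0.0, omega_fv=0.0, omega_betaw=0.0, sigma_prop=0.2,
            wref=5.0,
        )
        y = [6.0, 7.5, 8.0]
        ds = _no_dose_dataset(y)
        f = 0.3 * params.kendo / params.kel / params.fv  # weight == wref
        expected = sum(
            ((yi - f) / (0.2 * f)) ** 2 + 2 * math.log(0.2 * f) + _LOG2PI
            for yi in y
        )
        got = minus2_log_likelihood(params, dataset=ds)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_single_exact_observation_closed_form(self):
        params = tp.PopulationParameters(
            omega_kendo=0.0, omega_fv=0.0, omega_betaw=0.0, sigma_prop=0.15,
            wref=5.0,
        )
        f = 0.3 * params.kendo / params.kel / params.fv
        ds = _no_dose_dataset([f])
        got = minus2_log_likelihood(params, dataset=ds)
        assert got == pytest.approx(2 * math.log(0.15 * f) + _LOG2PI, rel=1e-12)

    def test_importance_close_to_laplace(self, identity_cohort):
        ds, truth = identity_cohort
        p = truth.population
        imp = minus2_log_likelihood(p, dataset=ds, n_draws=4000, seed=0)
        lap = minus2_log_likelihood(p, dataset=ds, method="laplace")
        assert imp == pytest.approx(lap, abs=3.0)

    def test_deterministic_given_seed(self, identity_cohort):
        ds, truth = identity_cohort
        p = truth.population
        a = minus2_log_likelihood(p, dataset=ds, n_draws=1000, seed=5)
        b = minus2_log_likelihood(p, dataset=ds, n_draws=1000, seed=5)
        assert a == b


class TestIndividualPrediction:
    def test_zero_eta_is_typical_profile(self):
        params = tp.PopulationParameters(wref=5.0)
        ds = _no_dose_dataset([5.0, 6.0])
        pred = tp.individual_prediction(params, np.zeros(3), ds, "A")
        f = 0.3 * params.kendo / params.kel / params.fv
        np.testing.assert_allclose(pred, f)

    def test_log2_eta_on_kendo_doubles_baseline(self):
        params = tp.PopulationParameters(wref=5.0)
        ds = _no_dose_dataset([5.0, 6.0])
        base = tp.individual_prediction(params, np.zeros(3), ds, "A")
        doubled = tp.individual_prediction(
            params, np.array([math.log(2), 0.0, 0.0]), ds, "A"
        )
        np.testing.assert_allclose(doubled, 2 * base)

    def test_predictions_strictly_positive(self, identity_cohort):
        ds, truth = identity_cohort
        rng = np.random.default_rng(0)
        for _ in range(5):
            eta = rng.normal(0, 1, 3)
            pred = tp.individual_prediction(
                truth.population, eta, ds, ds.subjects["subject_id"].iloc[0]
            )
            assert (pred > 0).all()


class TestFitPopulation:
    def test_near_noiseless_identifiability(self):
        truth = tp.PopulationParameters(
            omega_kendo=0.0, omega_fv=0.0, omega_betaw=0.0, sigma_prop=0.02,
        )
        cfg = tp.CohortConfig(
            n_subjects=20, truth=truth, n_missing_baseline=0,
            assay_jitter_sigma=0, assay_up_bias=0, assay_anomaly_frac=0,
            missing_range_frac=0,
        )
        ds, _ = tp.generate_cohort(cfg, seed=3)
        est = tp.FT4PopulationModel(
            wref=truth.wref, n_burnin=250, n_iter=150, compute_ll=False,
            random_state=3,
        ).fit(ds)
        # close to the generating truth ...
        assert est.kendo_ == pytest.approx(truth.kendo, rel=0.02)
        assert est.fv_ == pytest.approx(truth.fv, rel=0.02)
        assert est.betaw_ == pytest.approx(truth.betaw, rel=0.02)
        # ... and, more stringently, to the exact no-IIV maximum-likelihood
        # solution for this dataset (deterministic closed-form objective)
        from scipy.optimize import minimize

        designs, _ = build_designs(ds, 20.0, 0.1, 0.6, truth.wref)

        def obj(x):
            p = tp.PopulationParameters(
                kendo=math.exp(x[0]), fv=math.exp(x[1]), betaw=math.exp(x[2]),
                omega_kendo=0.0, omega_fv=0.0, omega_betaw=0.0,
                sigma_prop=math.exp(x[3]), wref=truth.wref,
            )
            return minus2_log_likelihood(p, designs=designs)

        x0 = np.log([truth.kendo, truth.fv, truth.betaw, truth.sigma_prop])
        mle = np.exp(minimize(obj, x0, method="Nelder-Mead",
                              options={"xatol": 1e-8, "fatol": 1e-10,
                                       "maxiter": 2000}).x)
        assert est.kendo_ == pytest.approx(mle[0], rel=0.005)
        assert est.fv_ == pytest.approx(mle[1], rel=0.005)
        assert est.betaw_ == pytest.approx(mle[2], rel=0.01)

    def test_deterministic_replay(self, identity_cohort):
        ds, truth = identity_cohort
        kw = dict(wref=truth.population.wref, n_burnin=120, n_iter=60,
                  ll_draws=500, random_state=9)
        a = tp.FT4PopulationModel(**kw).fit(ds)
        b = tp.FT4PopulationModel(**kw).fit(ds)
        assert a.kendo_ == b.kendo_
        assert a.minus2ll_ == b.minus2ll_
        pd.testing.assert_frame_equal(a.ebes_, b.ebes_)

    def test_seed_stability_of_fixed_effects(self, fitted_small):
        ds, truth, est = fitted_small
        other = tp.FT4PopulationModel(
            wref=truth.population.wref, n_burnin=250, n_iter=120,
            compute_ll=False, random_state=77,
        ).fit(ds)
        assert other.kendo_ == pytest.approx(est.kendo_, rel=0.15)
        assert other.fv_ == pytest.approx(est.fv_, rel=0.10)
        assert other.betaw_ == pytest.approx(est.betaw_, rel=0.15)

    def test_estimator_api(self, fitted_small):
        ds, truth, est = fitted_small
        params = est.get_params()
        assert params["random_state"] == 0
        preds = est.predict(ds)
        assert (preds["pred"] > 0).all()
        ind = est.predict(ds, individual=True)
        assert len(ind) == len(preds)

    def test_fit_population_wrapper(self, identity_cohort):
        ds, truth = identity_cohort
        fit = tp.fit_population(ds, wref=truth.population.wref,
                                n_burnin=100, n_iter=50, ll_draws=500, seed=2)
        assert isinstance(fit, tp.PopulationFit)
        assert np.isfinite(fit.minus2ll)
        assert fit.n_subjects == ds.n_subjects


class TestEmpiricalBayes:
    def test_shrinkage_bounds_and_sd_inequality(self, fitted_small):
        ds, truth, est = fitted_small
        for name, val in est.shrinkage_.items():
            assert 0.0 <= val <= 100.0
            sd = est.ebes_[f"eta_{name}"].std(ddof=0)
            assert sd <= est.omega_[name] + 1e-9

    def test_sparse_subject_shrinks_toward_zero(self):
        # a subject with one observation gets a MAP eta smaller than the
        # unpenalized (data-only) eta
        params = tp.PopulationParameters(wref=5.0, omega_fv=0.0, omega_betaw=0.0)
        f_typ = 0.3 * params.kendo / params.kel / params.fv
        ds = _no_dose_dataset([2.0 * f_typ])
        ebes, _ = tp.empirical_bayes_estimates(params, dataset=ds)
        eta_map = float(ebes["eta_kendo"].iloc[0])
        assert 0.0 < eta_map < math.log(2.0)

    def test_zero_omega_shrinkage_is_nan(self):
        params = tp.PopulationParameters(wref=5.0, omega_fv=0.0, omega_betaw=0.0)
        ds = _no_dose_dataset([5.0, 6.0])
        _, shrink = tp.empirical_bayes_estimates(params, dataset=ds)
        assert math.isnan(shrink["fv"])
        assert not math.isnan(shrink["kendo"])


class TestModelComparison:
    def test_identical_fits_not_significant(self, fitted_small):
        _, _, est = fitted_small
        res = tp.compare_models(est, est, df=1)
        assert res.delta_ofv == 0.0
        assert not res.significant

    def test_negative_delta_flagged(self):
        class Dummy:
            def __init__(self, m2):
                self.minus2ll_ = m2

        res = tp.compare_models(Dummy(100.0), Dummy(105.0), df=1)
        assert res.negative_delta
        assert not res.significant

    def test_large_delta_significant(self):
        class Dummy:
            def __init__(self, m2):
                self.minus2ll_ = m2

        res = tp.compare_models(Dummy(100.0), Dummy(80.0), df=1)
        assert res.significant
        assert res.p_value < 1e-4


class TestStandardErrors:
    def test_fisher_rse_finite_and_positive(self):
        cfg = tp.CohortConfig(
            n_subjects=6, n_missing_baseline=0, assay_jitter_sigma=0,
            assay_up_bias=0, assay_anomaly_frac=0, missing_range_frac=0,
        )
        ds, truth = tp.generate_cohort(cfg, seed=11)
        rse = tp.standard_errors(truth.population, dataset=ds)
        for name in ("kendo", "fv", "betaw", "sigma_prop"):
            assert np.isfinite(rse[name])
            assert rse[name] > 0
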