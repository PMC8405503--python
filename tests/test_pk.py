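"""Structural PK model: conversions, analytic solver, numeric agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thyropop as tp
from thyropop.pk import DoseRegimen, absorption_response


class TestDoseConversion:
    @pytest.mark.parametrize("mcg, nmol", [(25.0, 32.25), (0.0, 0.0), (50.0, 64.5)])
    def test_printed_factor(self, mcg, nmol):
        assert tp.convert_dose_mcg_to_nmol(mcg) == pytest.approx(nmol)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            tp.convert_dose_mcg_to_nmol(-1.0)

    def test_factor_close_to_exact_molecular_weight_value(self):
        assert tp.DOSE_NMOL_PER_MCG == pytest.approx(1000.0 / 776.9, rel=3e-3)


class TestVolume:
    def test_reference_weight_gives_fv(self, default_params):
        assert tp.volume_of_distribution(default_params.wref, default_params) == (
            pytest.approx(default_params.fv)
        )

    def test_double_reference_weight(self, default_params):
        v = tp.volume_of_distribution(2 * default_params.wref, default_params)
        assert v == pytest.approx(4.96 * 2 ** 0.753)
        assert v == pytest.approx(8.36, abs=0.01)

    def test_zero_exponent_degenerates_to_fv(self, default_params):
        p = default_params.with_(betaw=1e-300)  # effectively zero
        assert tp.volume_of_distribution(3.0, p) == pytest.approx(p.fv)

    def test_nonpositive_weight_rejected(self, default_params):
        with pytest.raises(ValueError):
            tp.volume_of_distribution(0.0, default_params)


class TestBaseline:
    def test_published_equilibrium(self, default_params):
        assert tp.baseline_amount(default_params) == pytest.approx(36.6)

    def test_no_production_no_amount(self, default_params):
        assert tp.baseline_amount(default_params.with_(kendo=0.0)) == 0.0

    def test_equal_rates_unit_amount(self, default_params):
        p = default_params.with_(kendo=0.1, kel=0.1)
        assert tp.baseline_amount(p) == pytest.approx(1.0)


class TestAnalyticSolver:
    def test_no_doses_stay_at_equilibrium(self, default_params):
        t = np.array([0.0, 5.0, 100.0, 700.0])
        _, a_c = tp.simulate_amounts(default_params, None, t)
        np.testing.assert_allclose(a_c, 36.6)

    def test_single_dose_returns_to_equilibrium(self, default_params):
        # one bolus: excess over kendo/kel decays with half-life ln2/kel ~ 7 d
        excess = tp.dose_response(
            np.array([50.0, 50.0 + math.log(2) / 0.1, 400.0]),
            np.array([0.0]), np.array([50.0]), 20.0, 0.1, 0.6,
        )
        assert excess[1] == pytest.approx(excess[0] / 2, rel=1e-3)
        assert excess[2] == pytest.approx(0.0, abs=1e-10)

    def test_peak_time_of_central_compartment(self, default_params):
        # t_max = ln(ka/kel)/(ka - kel) for a single bolus
        t_max = math.log(200.0) / 19.9
        assert t_max == pytest.approx(0.266, abs=5e-4)
        t = np.linspace(0.0, 1.5, 3001)
        resp = tp.dose_response(t, np.array([0.0]), np.array([25.0]),
                                20.0, 0.1, 0.6)
        assert t[np.argmax(resp)] == pytest.approx(t_max, abs=2e-3)

    def test_absorption_compartment_peaks_at_bolus(self):
        t = np.linspace(0.0, 1.0, 101)
        a_b = absorption_response(t, np.array([0.0]), np.array([25.0]), 20.0, 0.6)
        assert np.argmax(a_b) == 0
        assert np.all(np.diff(a_b) <= 0)

    def test_superposition(self, default_params):
        t = np.linspace(0.0, 30.0, 7)
        r1 = DoseRegimen([(0.0, 25.0)])
        r2 = DoseRegimen([(10.0, 37.5)])
        both = DoseRegimen([(0.0, 25.0)])  # 25 until day 10, then 62.5
        _, a1 = tp.simulate_amounts(default_params, r1, t)
        d2 = tp.dose_response(t, *r2.expand(30.0), default_params.ka,
                              default_params.kel, default_params.f_bio)
        combined = DoseRegimen([(0.0, 25.0), (10.0, 62.5)])
        _, a_both = tp.simulate_amounts(default_params, combined, t)
        # a regimen that adds 37.5 on top of 25 from day 10 equals the sum
        # of the single-dose responses (minus one duplicated baseline)
        np.testing.assert_allclose(a_both, a1 + d2, rtol=1e-10)

    def test_steady_state_daily_average(self, default_params):
        # closed-form mean of the linear system under 25 mcg/day
        expected = 0.3 * (3.66 + 0.6 * 1.29 * 25.0) / (0.1 * 4.96)
        assert expected == pytest.approx(13.92, abs=5e-3)
        t = np.linspace(300.0, 301.0, 25)
        prof = tp.simulate_ft4_profile(
            default_params, DoseRegimen([(0.0, 25.0)]), default_params.wref, t
        )
        assert np.trapezoid(prof, t) == pytest.approx(expected, rel=1e-3)

    def test_equal_rates_limit_is_finite_and_matches_oracle(self, default_params):
        p = default_params.with_(ka=0.1, kel=0.1)
        reg = DoseRegimen([(0.0, 25.0)])
        t = np.array([0.5, 3.0, 10.0])
        _, a_c = tp.simulate_amounts(p, reg, t)
        _, a_num = tp.numeric_oracle(p, reg, t)
        np.testing.assert_allclose(a_c, a_num, rtol=1e-7)

    def test_nonnegative_amounts(self, default_params):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 90, 20))
        reg = DoseRegimen([(0.0, 12.5), (30.0, 50.0)])
        a_b, a_c = tp.simulate_amounts(default_params, reg, t)
        assert (a_b >= 0).all() and (a_c >= 0).all()


class TestFT4Observation:
    def test_published_arithmetic(self, default_params):
        assert tp.ft4_concentration(36.6, default_params.wref, default_params) == (
            pytest.approx(0.3 * 36.6 / 4.96)
        )

    def test_zero_amount_zero_concentration(self, default_params):
        assert tp.ft4_concentration(0.0, 5.0, default_params) == 0.0

    def test_doubling_volume_halves_concentration(self, default_params):
        c1 = tp.ft4_concentration(36.6, default_params.wref, default_params)
        c2 = tp.ft4_concentration(
            36.6, default_params.wref, default_params.with_(fv=2 * 4.96)
        )
        assert c2 == pytest.approx(c1 / 2)

    def test_free_fraction_constant_consistency(self):
        # 0.3 pmol/l per nmol = 0.03% free fraction x 1000 pmol/nmol
        assert tp.pk.FT4_FRACTION_CONST == pytest.approx(0.0003 * 1000.0)

    def test_flat_profile_without_doses(self, default_params):
        t = np.array([0.0, 50.0, 500.0])
        prof = tp.simulate_ft4_profile(default_params, None, 5.0, t)
        assert np.ptp(prof) == 0.0

    def test_growing_weight_decreasing_ft4(self, default_params):
        t = np.linspace(0.0, 600.0, 13)
        prof = tp.simulate_ft4_profile(
            default_params, None, lambda tt: 3.3 + 0.013 * tt, t
        )
        assert np.all(np.diff(prof) < 0)


class TestDoseRegimen:
    def test_locf_expansion(self):
        reg = DoseRegimen([(0.0, 25.0), (2.5, 37.5)])
        ev_t, ev_d = reg.expand(5.0)
        np.testing.assert_allclose(ev_t, [0.0, 1.0, 2.0, 2.5, 3.5, 4.5])
        np.testing.assert_allclose(ev_d, [25.0, 25.0, 25.0, 37.5, 37.5, 37.5])

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            DoseRegimen([(0.0, -5.0)])
        with pytest.raises(ValueError):
            DoseRegimen([(5.0, 25.0), (5.0, 30.0)])


@settings(max_examples=5)
@given(seed=st.integers(0, 10_000))
def test_analytic_matches_numeric_oracle(seed, default_params):
    """Random regimens: exact superposition vs independent integrator."""
    rng = np.random.default_rng(seed)
    n_seg = rng.integers(1, 4)
    starts = np.sort(rng.uniform(0, 40, n_seg))
    starts[0] = 0.0
    rows = [(float(t), float(rng.choice([12.5, 25.0, 37.5, 50.0])))
            for t in np.unique(starts)]
    reg = DoseRegimen(rows)
    t = np.sort(rng.uniform(0, 60, 6))
    _, a_c = tp.simulate_amounts(default_params, reg, t)
    _, a_num = tp.numeric_oracle(default_params, reg, t)
    np.testing.assert_allclose(a_c, a_num, rtol=1e-6)
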