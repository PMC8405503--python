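"""Reference-range normalization: formulas, age lookup, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import thyropop as tp
from thyropop.normalize import (
    NormalizationSettings,
    Window,
    default_windows,
)

positive = st.floats(0.1, 50, allow_nan=False)


class TestTargetLookup:
    @pytest.mark.parametrize(
        "pna, expected",
        [
            (15.0, (8.50, 30.50)),
            (200.0, (9.17, 25.28)),
            (400.0, (10.45, 22.35)),
            (0.0, (8.50, 30.50)),
            (30.0, (8.50, 30.50)),  # closed-above bracket bound
            (31.0, (9.17, 25.28)),
            (1826.0, (10.45, 22.35)),
        ],
    )
    def test_ft4_brackets(self, pna, expected):
        assert tp.lookup_target_range(pna) == expected

    def test_outside_coverage_is_domain_error(self):
        with pytest.raises(ValueError):
            tp.lookup_target_range(1827.0)
        with pytest.raises(ValueError):
            tp.lookup_target_range(-1.0)

    @given(pna=st.floats(0, 1826, allow_nan=False))
    def test_lookup_total_on_age_axis(self, pna):
        lo, up = tp.lookup_target_range(pna)
        assert lo < up


class TestFormulas:
    def test_scale_examples(self):
        assert tp.scale_normalize(10.0, 20.0, 30.5) == pytest.approx(15.25)
        assert tp.scale_normalize(7.7, 13.0, 13.0) == pytest.approx(7.7)
        assert tp.scale_normalize(0.0, 20.0, 30.5) == 0.0

    def test_scale_rejects_bad_range(self):
        with pytest.raises(ValueError):
            tp.scale_normalize(5.0, 0.0, 30.5)

    def test_location_scale_maps_limits_to_limits(self):
        assert tp.location_scale_normalize(10.0, 10.0, 30.0, 8.5, 30.5) == 8.5
        assert tp.location_scale_normalize(30.0, 10.0, 30.0, 8.5, 30.5) == 30.5

    def test_location_scale_negative_output_preserved(self):
        # a measurement far below the assay lower limit maps below zero
        assert tp.location_scale_normalize(2.0, 10.0, 30.0, 8.5, 30.5) == (
            pytest.approx(-0.3)
        )

    def test_location_scale_degenerate_range(self):
        with pytest.raises(ValueError):
            tp.location_scale_normalize(5.0, 10.0, 10.0, 8.5, 30.5)

    def test_blend_endpoints(self):
        args = (10.0, 9.0, 29.0, 8.5, 30.5)
        s = tp.scale_normalize(10.0, 29.0, 30.5)
        ls = tp.location_scale_normalize(*args)
        assert tp.blended_normalize(*args, t=0.0) == pytest.approx(s)
        assert tp.blended_normalize(*args, t=150.0) == pytest.approx(ls)
        assert tp.blended_normalize(*args, t=600.0) == pytest.approx(ls)

    def test_blend_midpoint_hand_computed(self):
        # halfway blend of 9.6 (location-scale) and 10*30.5/29 (scale)
        out = tp.blended_normalize(10.0, 9.0, 29.0, 8.5, 30.5, t=75.0)
        assert out == pytest.approx(0.5 * 9.6 + 0.5 * (10.0 * 30.5 / 29.0))
        assert out == pytest.approx(10.0586, abs=1e-4)

    @given(x=positive, t=st.floats(0, 300, allow_nan=False))
    def test_blend_continuous_and_piecewise_linear(self, x, t):
        args = (x, 9.0, 29.0, 8.5, 30.5)
        s = tp.scale_normalize(x, 29.0, 30.5)
        ls = tp.location_scale_normalize(*args)
        w = min(t / 150.0, 1.0)
        assert tp.blended_normalize(*args, t=t) == pytest.approx(
            w * ls + (1 - w) * s
        )

    @given(x=positive, lo=st.floats(5, 12), width=st.floats(5, 30),
           t=st.floats(0, 400))
    def test_fixed_point_when_ranges_coincide(self, x, lo, width, t):
        up = lo + width
        assert tp.scale_normalize(x, up, up) == pytest.approx(x)
        assert tp.location_scale_normalize(x, lo, up, lo, up) == pytest.approx(x)
        assert tp.blended_normalize(x, lo, up, lo, up, t=t) == pytest.approx(x)

    @given(x1=positive, x2=positive, t=st.floats(0, 400))
    def test_strictly_increasing_in_measurement(self, x1, x2, t):
        if x1 == x2:
            return
        lo_x, hi_x = sorted((x1, x2))
        args = (9.0, 29.0, 8.5, 30.5)
        assert tp.blended_normalize(lo_x, *args, t=t) < tp.blended_normalize(
            hi_x, *args, t=t
        )

    @given(x=st.floats(0, 60, allow_nan=False))
    def test_scale_never_negative(self, x):
        assert tp.scale_normalize(x, 20.0, 30.5) >= 0.0


class TestSeverity:
    @pytest.mark.parametrize(
        "value, expected",
        [(4.9, "severe"), (0.1, "severe"), (5.0, "moderate"), (9.99, "moderate"),
         (10.0, "mild"), (25.0, "mild"), (None, "unknown"),
         (float("nan"), "unknown")],
    )
    def test_thresholds(self, value, expected):
        assert tp.classify_severity(value) == expected

    def test_negative_is_domain_error(self):
        with pytest.raises(ValueError):
            tp.classify_severity(-0.1)


class TestNormalizeDataset:
    def test_identity_ranges_give_identity(self, identity_cohort):
        ds, _ = identity_cohort
        out, tr = tp.normalize_dataset(ds)
        obs = out.observations
        measured = ~obs["ft4"].isna()
        np.testing.assert_allclose(
            obs.loc[measured, "ft4_norm"], obs.loc[measured, "ft4"], rtol=1e-12
        )
        assert tr.n_skipped_ == 0

    def test_rows_without_range_are_flagged_not_normalized(self, tiny_dataset):
        out, tr = tp.normalize_dataset(tiny_dataset)
        obs = out.observations
        row = obs[(obs["subject_id"] == "B") & (obs["t"] == 45.0)].iloc[0]
        assert bool(row["ft4_norm_skipped"])
        assert math.isnan(row["ft4_norm"])
        assert tr.n_skipped_ == 1

    def test_default_cohort_fully_processed(self, small_cohort):
        ds, _ = small_cohort
        out, tr = tp.normalize_dataset(ds)
        obs = out.observations
        measured = ~obs["ft4"].isna()
        assert tr.n_normalized_ + tr.n_skipped_ == int(measured.sum())
        late = obs["t"] > 150.0
        done = measured & late & ~obs["ft4_norm_skipped"]
        assert (obs.loc[done, "ft4_norm"] > 0).all()

    def test_clamp_negative_floors_at_zero(self):
        subj = [tp.SubjectRecord("A", pna_start_days=7.0)]
        obs = [tp.LabObservation("A", 0.0, ft4=1.0, ft4_ref_low=10.0,
                                 ft4_ref_up=30.0, weight=3.3),
               tp.LabObservation("A", 200.0, ft4=2.0, ft4_ref_low=15.0,
                                 ft4_ref_up=25.0, weight=6.0)]
        ds = tp.Dataset.from_records(subj, obs)
        raw, tr_raw = tp.normalize_dataset(ds)
        assert tr_raw.n_negative_ >= 1
        assert (raw.observations["ft4_norm"] < 0).any()
        clamped, _ = tp.normalize_dataset(ds, clamp_negative=True)
        assert (clamped.observations["ft4_norm"].dropna() >= 0).all()

    def test_transformer_is_sklearn_compatible(self):
        tr = tp.ReferenceRangeNormalizer(ts=100.0)
        assert tr.get_params()["ts"] == 100.0
        tr.set_params(ts=150.0)
        assert tr.ts == 150.0


class TestSummaries:
    def test_identity_dataset_identical_medians(self, identity_cohort):
        ds, _ = identity_cohort
        out, _ = tp.normalize_dataset(ds)
        tab = tp.summarize_comparison(out)
        row = tab[tab["window"] == "last"].iloc[0]
        assert row["median_raw"] == pytest.approx(row["median_norm"])
        assert not row["significant"]

    def test_single_value_window_degenerate_iqr(self, tiny_dataset):
        out, _ = tp.normalize_dataset(tiny_dataset)
        tab = tp.summarize_comparison(
            out, windows=[Window("one", "point", 30.0)]
        )
        row = tab.iloc[0]
        assert row["median_raw"] == row["q25_raw"] == row["q75_raw"]
        assert math.isnan(row["p_value"])

    def test_empty_window_yields_nan_row(self, tiny_dataset):
        out, _ = tp.normalize_dataset(tiny_dataset)
        tab = tp.summarize_comparison(
            out, windows=[Window("none", "interval", 900.0, 950.0)]
        )
        assert math.isnan(tab.iloc[0]["median_raw"])

    def test_normalized_not_above_raw_when_assay_uppers_inflated(self):
        # generator draws assay upper limits above the target on average
        ds, _ = tp.generate_cohort(tp.CohortConfig(), seed=0)
        out, _ = tp.normalize_dataset(ds)
        tab = tp.summarize_comparison(out)
        lower = (tab["median_norm"] <= tab["median_raw"]).sum()
        assert lower >= 3

    def test_skewness_known_signs(self):
        rng = np.random.default_rng(0)
        sym = rng.normal(10, 1, 200)
        expo = rng.exponential(5, 200) + 1
        subj = [tp.SubjectRecord("A", pna_start_days=7.0)]
        obs = [tp.LabObservation("A", float(i), ft4=float(v))
               for i, v in enumerate(np.concatenate([sym, expo]))]
        ds = tp.Dataset.from_records(subj, obs)
        tab = tp.skewness_diagnostic(
            ds,
            windows=[Window("sym", "interval", 0, 200),
                     Window("exp", "interval", 200, 400)],
        )
        assert abs(tab.iloc[0]["skewness"]) < 0.4
        assert tab.iloc[1]["skewness"] > 1.0

    def test_undersized_window_gives_nan(self, tiny_dataset):
        tab = tp.skewness_diagnostic(
            tiny_dataset, windows=[Window("t=0", "point", 0.0)]
        )
        assert math.isnan(tab.iloc[0]["skewness"])

    def test_cohort_skewness_decreases_under_treatment(self, small_cohort):
        ds, _ = small_cohort
        tab = tp.skewness_diagnostic(ds, windows=default_windows())
        first = tab[tab["window"] == "t=0"].iloc[0]["skewness"]
        last = tab[tab["window"] == "last"].iloc[0]["skewness"]
        assert first > last


def test_settings_validation():
    with pytest.raises(ValueError):
        NormalizationSettings(ts=0.0)
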