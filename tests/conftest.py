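import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thyropop as tp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params() -> tp.PKParameters:
    """Published final-model structural parameters."""
    return tp.PKParameters()


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject default-settings cohort plus its truth (shared, read-only)."""
    cfg = tp.CohortConfig(n_subjects=12, n_missing_baseline=1)
    return tp.generate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def identity_cohort():
    """A cohort whose assay ranges equal the target range everywhere."""
    cfg = tp.CohortConfig(
        n_subjects=10,
        n_missing_baseline=1,
        assay_jitter_sigma=0.0,
        assay_up_bias=0.0,
        assay_anomaly_frac=0.0,
        missing_range_frac=0.0,
    )
    return tp.generate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def recovery_fit():
    """Full-size recovery experiment: published-truth cohort, fitted.

    The cohort's assay ranges equal the target range, so the fit runs on
    raw FT4 (normalization would be the identity).  Shared across test
    modules to avoid refitting.
    """
    cfg = tp.CohortConfig(
        assay_jitter_sigma=0.0,
        assay_up_bias=0.0,
        assay_anomaly_frac=0.0,
        missing_range_frac=0.0,
    )
    ds, truth = tp.generate_cohort(cfg, seed=1)
    est = tp.FT4PopulationModel(
        wref=truth.population.wref, random_state=1
    ).fit(ds)
    return ds, truth, est


@pytest.fixture()
def tiny_dataset() -> tp.Dataset:
    """Two subjects, hand-built, with assorted missing cells."""
    subjects = [
        tp.SubjectRecord("A", sex="female", ga_weeks=39.0, pna_start_days=7.0,
                         severity="severe"),
        tp.SubjectRecord("B", sex="male", pna_start_days=10.0,
                         severity="unknown"),
    ]
    observations = [
        tp.LabObservation("A", 0.0, ft4=3.2, ft4_ref_low=9.0, ft4_ref_up=29.0,
                          tsh=300.0, weight=3.4, dose_daily=25.0),
        tp.LabObservation("A", 30.0, ft4=18.0, ft4_ref_low=9.0, ft4_ref_up=29.0,
                          tsh=5.0, weight=4.2),
        tp.LabObservation("B", 0.0, tsh=120.0, weight=3.0, dose_daily=37.5),
        tp.LabObservation("B", 45.0, ft4=22.0, tsh=2.0, weight=4.9),
    ]
    return tp.Dataset.from_records(subjects, observations)
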