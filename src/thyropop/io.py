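"""Long-format dataset I/O and validation.

The analysis operates on a single long-format CSV: one row per subject and
time point, carrying the laboratory observations (FT4 with its assay
reference range, TSH, body weight, daily levothyroxine dose) together with
the per-subject demographics repeated on every row.  Time ``t`` is measured
in days since the start of LT4 treatment (t = 0 is the first dose); the
postnatal age at any time is ``pna_start_days + t``.

Doses follow last-observation-carried-forward semantics: a ``dose_daily``
value holds from its row's ``t`` until the next row that carries a dose.
Missing values are first-class (empty CSV cells, ``NaN`` in memory); nothing
is imputed at this layer.
"""

from __future__ import annotations

import dataclasses
import math
import sys
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LabObservation",
    "SubjectRecord",
    "Dataset",
    "DatasetParseError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "load_config",
    "SEVERITY_LEVELS",
    "OBS_COLUMNS",
    "SUBJECT_COLUMNS",
]

SEVERITY_LEVELS = ("severe", "moderate", "mild", "unknown")

#: canonical observation-level columns, in on-disk order
OBS_COLUMNS = [
    "subject_id",
    "t",
    "ft4",
    "ft4_ref_low",
    "ft4_ref_up",
    "tsh",
    "weight",
    "dose_daily",
]

#: canonical subject-level columns (repeated on each CSV row)
SUBJECT_COLUMNS = ["subject_id", "sex", "ga_weeks", "pna_start_days", "severity"]

_NUMERIC_OBS = ["t", "ft4", "ft4_ref_low", "ft4_ref_up", "tsh", "weight", "dose_daily"]
_POSITIVE_OBS = ["ft4", "ft4_ref_low", "ft4_ref_up", "tsh", "weight", "dose_daily"]


class DatasetParseError(ValueError):
    """A cell could not be parsed; the message names row and column."""


class DatasetValidationError(ValueError):
    """The dataset violates a documented structural invariant."""


@dataclass
class LabObservation:
    """One time-stamped laboratory record.

    All concentrations are in pmol/l (FT4) or mU/l (TSH); weight in kg;
    ``dose_daily`` in mcg/day.  ``None`` marks an absent value.
    """

    subject_id: str
    t: float
    ft4: float | None = None
    ft4_ref_low: float | None = None
    ft4_ref_up: float | None = None
    tsh: float | None = None
    weight: float | None = None
    dose_daily: float | None = None


@dataclass
class SubjectRecord:
    """Per-subject demographics and the baseline severity label."""

    subject_id: str
    sex: str = "female"
    ga_weeks: float | None = None
    pna_start_days: float = 0.0
    severity: str = "unknown"


def _isnan(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class Dataset:
    """A validated cohort: subject table plus observation table.

    ``subjects`` has columns :data:`SUBJECT_COLUMNS`; ``observations`` has
    columns :data:`OBS_COLUMNS` (plus any derived columns such as
    ``ft4_norm``).  Observations are kept sorted by ``(subject_id, t)``.
    """

    subjects: pd.DataFrame
    observations: pd.DataFrame

    def __post_init__(self) -> None:
        self.subjects = self.subjects.reset_index(drop=True)
        self.observations = (
            self.observations.sort_values(["subject_id", "t"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        subjects: list[SubjectRecord],
        observations: list[LabObservation],
    ) -> "Dataset":
        subj = pd.DataFrame(
            [dataclasses.asdict(s) for s in subjects], columns=SUBJECT_COLUMNS
        )
        obs = pd.DataFrame(
            [dataclasses.asdict(o) for o in observations], columns=OBS_COLUMNS
        )
        for c in _NUMERIC_OBS:
            obs[c] = pd.to_numeric(obs[c])
        subj["ga_weeks"] = pd.to_numeric(subj["ga_weeks"])
        subj["pna_start_days"] = pd.to_numeric(subj["pna_start_days"])
        return cls(subj, obs)

    # -- basic properties --------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def subject_observations(self, subject_id: str) -> pd.DataFrame:
        return self.observations[self.observations["subject_id"] == subject_id]

    def copy(self) -> "Dataset":
        return Dataset(self.subjects.copy(), self.observations.copy())

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        subj, obs = self.subjects, self.observations
        for c in SUBJECT_COLUMNS:
            if c not in subj.columns:
                raise DatasetValidationError(f"subject table misses column {c!r}")
        for c in OBS_COLUMNS:
            if c not in obs.columns:
                raise DatasetValidationError(f"observation table misses column {c!r}")

        if subj["subject_id"].duplicated().any():
            dup = subj.loc[subj["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise DatasetValidationError(f"duplicated subject record {dup!r}")
        bad_sev = ~subj["severity"].isin(SEVERITY_LEVELS)
        if bad_sev.any():
            raise DatasetValidationError(
                f"unknown severity label {subj.loc[bad_sev, 'severity'].iloc[0]!r}"
            )
        if (pd.to_numeric(subj["pna_start_days"]) < 0).any():
            raise DatasetValidationError("pna_start_days must be >= 0")

        known = set(subj["subject_id"])
        orphan = ~obs["subject_id"].isin(known)
        if orphan.any():
            raise DatasetValidationError(
                f"observation references unknown subject "
                f"{obs.loc[orphan, 'subject_id'].iloc[0]!r}"
            )

        t = obs["t"].to_numpy(float)
        if np.isnan(t).any():
            raise DatasetValidationError("observation time t is mandatory")
        if (t < 0).any():
            raise DatasetValidationError("observation times must satisfy t >= 0")
        if obs.duplicated(subset=["subject_id", "t"]).any():
            row = obs[obs.duplicated(subset=["subject_id", "t"])].iloc[0]
            raise DatasetValidationError(
                f"duplicated record for subject {row['subject_id']!r} at t={row['t']}"
            )

        for c in _POSITIVE_OBS:
            v = obs[c].to_numpy(float)
            bad = v <= 0
            if np.any(bad & ~np.isnan(v)):
                i = int(np.nonzero(bad & ~np.isnan(v))[0][0])
                raise DatasetValidationError(
                    f"column {c!r} must be > 0 when present "
                    f"(row {i}, value {v[i]!r})"
                )

        low = obs["ft4_ref_low"].to_numpy(float)
        up = obs["ft4_ref_up"].to_numpy(float)
        both = ~np.isnan(low) & ~np.isnan(up)
        if np.any(both & (low >= up)):
            i = int(np.nonzero(both & (low >= up))[0][0])
            raise DatasetValidationError(
                f"inverted reference range at row {i}: "
                f"ft4_ref_low={low[i]} >= ft4_ref_up={up[i]}"
            )


# ---------------------------------------------------------------------------
# CSV reader / writer


def _parse_numeric(raw: pd.Series, column: str) -> pd.Series:
    """Parse a string column to float, naming the offending row on failure."""
    out = np.full(len(raw), np.nan)
    for i, cell in enumerate(raw.to_numpy()):
        s = str(cell).strip()
        if s == "" or s.lower() in ("na", "nan", "none"):
            continue
        try:
            out[i] = float(s)
        except ValueError as exc:
            raise DatasetParseError(
                f"cannot parse {s!r} in column {column!r}, data row {i + 1}"
            ) from exc
    return pd.Series(out, index=raw.index)


def read_dataset(path, schema: Mapping[str, str] | None = None) -> Dataset:
    """Read a long-format CSV into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file (RFC-4180, '.' decimal separator, UTF-8).
    schema
        Optional mapping from file column names to canonical names, so
        NONMEM-style headers can be aliased, e.g.
        ``{"ID": "subject_id", "TIME": "t", "DV": "ft4"}``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        raw = raw.rename(columns=dict(schema))
    for required in ("subject_id", "t"):
        if required not in raw.columns:
            raise DatasetValidationError(f"required column {required!r} not found")

    obs = pd.DataFrame({"subject_id": raw["subject_id"].astype(str)})
    for c in _NUMERIC_OBS:
        obs[c] = _parse_numeric(raw[c], c) if c in raw.columns else np.nan
    obs = obs[OBS_COLUMNS]
    # derived columns (e.g. from a previous normalization run) survive I/O
    if "ft4_norm" in raw.columns:
        obs["ft4_norm"] = _parse_numeric(raw["ft4_norm"], "ft4_norm")
    if "ft4_norm_skipped" in raw.columns:
        obs["ft4_norm_skipped"] = raw["ft4_norm_skipped"].str.lower() == "true"

    # subject-level columns: first non-empty cell per subject
    sub_cols: dict[str, pd.Series] = {}
    for c in ("sex", "severity"):
        if c in raw.columns:
            sub_cols[c] = raw[c].replace("", np.nan)
    for c in ("ga_weeks", "pna_start_days"):
        if c in raw.columns:
            sub_cols[c] = _parse_numeric(raw[c], c)
    aux = pd.DataFrame({"subject_id": obs["subject_id"], **sub_cols})
    first = aux.groupby("subject_id", sort=True).first().reset_index()
    subj = pd.DataFrame({"subject_id": first["subject_id"]})
    subj["sex"] = first["sex"] if "sex" in first else "unknown"
    subj["ga_weeks"] = first["ga_weeks"] if "ga_weeks" in first else np.nan
    subj["pna_start_days"] = (
        first["pna_start_days"] if "pna_start_days" in first else 0.0
    )
    subj["severity"] = (
        first["severity"].fillna("unknown") if "severity" in first else "unknown"
    )
    subj["sex"] = subj["sex"].fillna("unknown")
    subj["pna_start_days"] = subj["pna_start_days"].fillna(0.0)
    return Dataset(subj, obs)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a :class:`Dataset` back to long-format CSV.

    Values round-trip bit-identically through :func:`read_dataset` for
    decimal text of up to 10 significant digits; absent cells are written
    as empty fields.
    """
    merged = dataset.observations.merge(
        dataset.subjects, on="subject_id", how="left", validate="many_to_one"
    )
    extra = [c for c in dataset.observations.columns if c not in OBS_COLUMNS]
    cols = OBS_COLUMNS + extra + [c for c in SUBJECT_COLUMNS if c != "subject_id"]
    merged = merged[cols]
    merged.to_csv(path, index=False, float_format="%.10g", na_rep="")


def load_config(path) -> dict:
    """Load a TOML run-configuration file into a plain dict."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def log(message: str, level: str = "INFO") -> None:
    """Minimal severity-tagged logging to stderr."""
    print(f"[{level}] {message}", file=sys.stderr)
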