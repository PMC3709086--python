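"""Cohort data model, CSV ingest and the study's patient-level filters.

A cohort is a collection of ward patients, each with a time-ordered series
of five-variable vital-sign observations (heart rate, respiratory rate,
SpO2, systolic blood pressure, tympanic temperature).  Patients are
labelled ``normal`` (discharged home) or ``abnormal`` (re-admitted to the
ICU or died on the ward); for abnormal patients the time of the first such
event replaces discharge in all length-of-stay arithmetic.

Filtering mirrors the study flow: observations with any missing vital are
removed first, then patients whose stay falls outside the 4--29 day window
are excluded.  A :class:`FilterReport` carries the counts of every stage.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical ordering of the five vital signs used for every vector in the package.
VITALS = ("hr", "rr", "spo2", "sysbp", "temp")

#: Default CSV schema: data-model field -> column name.
DEFAULT_SCHEMA = {
    "patient_id": "patient_id",
    "time": "time_h",
    "hr": "hr",
    "rr": "rr",
    "spo2": "spo2",
    "sysbp": "sysbp",
    "temp": "temp",
    "outcome": "outcome",
    "event_time": "event_time_h",
}

NORMAL = "normal"
ABNORMAL = "abnormal"


class SchemaError(ValueError):
    """A mandatory column is missing from an input file."""


def day_index(time_h: float) -> int:
    """Calendar day touched by an observation, with admission day = day 1."""
    return int(time_h // 24.0) + 1


@dataclass
class VitalSignObservation:
    """One timestamped five-variable measurement for one patient.

    ``time`` is hours since ward admission.  Values may be NaN before the
    completeness filter runs; an observation that survives the filter has
    all five vitals present.
    """

    patient_id: str
    time: float
    hr: float
    rr: float
    spo2: float
    sysbp: float
    temp: float

    def values(self) -> np.ndarray:
        """The observation as a vector in :data:`VITALS` order."""
        return np.array([getattr(self, v) for v in VITALS], dtype=float)

    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values())))


@dataclass
class PatientRecord:
    """A labelled patient: time-ordered observations plus outcome metadata."""

    patient_id: str
    observations: list[VitalSignObservation]
    outcome: str | None = None
    event_time: float | None = None

    def __post_init__(self) -> None:
        self.observations.sort(key=lambda o: o.time)
        if self.outcome == ABNORMAL and self.event_time is None:
            raise ValueError(
                f"patient {self.patient_id}: abnormal outcome requires an event time"
            )

    @property
    def length_of_stay_days(self) -> int:
        """Stay length in whole days.

        Normal patients: number of distinct calendar days touched by their
        observations (admission day = day 1).  Abnormal patients: days from
        admission to the first event (ICU re-admission or death).
        """
        if self.outcome == ABNORMAL:
            return day_index(self.event_time)
        return len({day_index(o.time) for o in self.observations})

    @property
    def last_day(self) -> int:
        """Day index of the latest observation (the discharge day for normals)."""
        return day_index(self.observations[-1].time)

    def observations_on_day(self, day: int) -> list[VitalSignObservation]:
        return [o for o in self.observations if day_index(o.time) == day]

    def matrix(self) -> np.ndarray:
        """All observations stacked as an (n_obs, 5) array in VITALS order."""
        return np.array([o.values() for o in self.observations], dtype=float)

    def times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations], dtype=float)


@dataclass
class FilterReport:
    """Patient/observation counts across the filtering stages."""

    n_input_patients: int = 0
    n_after_completeness: int = 0
    n_after_stay_filter: int = 0
    n_observations_dropped: int = 0
    n_normal: int = 0
    n_abnormal: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    def validate(self) -> None:
        counts = (self.n_input_patients, self.n_after_completeness, self.n_after_stay_filter)
        if any(c < 0 for c in self.__dict__.values()):
            raise ValueError("filter report counts must be non-negative")
        if not (counts[0] >= counts[1] >= counts[2]):
            raise ValueError(f"filter report counts must be non-increasing: {counts}")


@dataclass
class Cohort:
    """A collection of patient records with filtering provenance."""

    patients: list[PatientRecord] = field(default_factory=list)
    filter_report: FilterReport = field(default_factory=FilterReport)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("patient ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    @property
    def n_observations(self) -> int:
        return sum(len(p.observations) for p in self.patients)

    def to_frame(self) -> pd.DataFrame:
        """Long-format observation table with outcome metadata repeated per row."""
        rows = []
        for p in self.patients:
            for o in p.observations:
                rows.append(
                    {
                        "patient_id": p.patient_id,
                        "time_h": o.time,
                        "hr": o.hr,
                        "rr": o.rr,
                        "spo2": o.spo2,
                        "sysbp": o.sysbp,
                        "temp": o.temp,
                        "outcome": p.outcome,
                        "event_time_h": p.event_time,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id", "time_h", "hr", "rr", "spo2", "sysbp", "temp",
                "outcome", "event_time_h",
            ],
        )

    def all_observations(self, complete_only: bool = True) -> np.ndarray:
        """Stacked (n, 5) matrix of every observation in the cohort."""
        mats = []
        for p in self.patients:
            for o in p.observations:
                if not complete_only or o.is_complete():
                    mats.append(o.values())
        return np.array(mats, dtype=float).reshape(-1, len(VITALS))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the observation CSV; missing values become empty strings."""
    frame = cohort.to_frame()
    frame.to_csv(path, index=False, na_rep="")


def read_cohort(path: str | Path, schema: dict[str, str] | None = None) -> Cohort:
    """Read an observation CSV into a :class:`Cohort`.

    One :class:`PatientRecord` per distinct patient id, observations sorted
    by time.  Cells that fail numeric parsing become NaN (a warning reports
    how many) so the completeness filter can account for them; duplicate
    (patient_id, time) rows are kept with a warning.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema.values() if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    numeric_fields = ["time", *VITALS, "event_time"]
    frame = pd.DataFrame({"patient_id": raw[schema["patient_id"]]})
    n_bad = 0
    for f in numeric_fields:
        col = raw[schema[f]]
        parsed = pd.to_numeric(col, errors="coerce")
        n_bad += int((parsed.isna() & (col != "")).sum())
        frame[f] = parsed
    frame["outcome"] = raw[schema["outcome"]].where(raw[schema["outcome"]] != "", np.nan)
    if n_bad:
        warnings.warn(f"{n_bad} unparseable numeric value(s) set to missing")

    dup = frame.duplicated(subset=["patient_id", "time"], keep=False)
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} rows share a (patient_id, time) stamp; keeping all"
        )

    patients: list[PatientRecord] = []
    for pid, grp in frame.groupby("patient_id", sort=True):
        outcome = grp["outcome"].dropna().iloc[0] if grp["outcome"].notna().any() else None
        event = grp["event_time"].dropna().iloc[0] if grp["event_time"].notna().any() else None
        obs = [
            VitalSignObservation(
                patient_id=str(pid),
                time=float(r.time),
                hr=float(r.hr), rr=float(r.rr), spo2=float(r.spo2),
                sysbp=float(r.sysbp), temp=float(r.temp),
            )
            for r in grp.itertuples()
            if math.isfinite(r.time)
        ]
        patients.append(
            PatientRecord(str(pid), obs, outcome=outcome,
                          event_time=float(event) if event is not None else None)
        )

    n = len(patients)
    report = FilterReport(n_input_patients=n, n_after_completeness=n, n_after_stay_filter=n)
    return Cohort(patients=patients, filter_report=report)


# ---------------------------------------------------------------------------
# Filters


def drop_incomplete(cohort: Cohort) -> Cohort:
    """Remove every observation with a missing vital sign.

    Patients left with no observations are removed entirely.  The filter
    report's completeness-stage counts are updated.
    """
    kept: list[PatientRecord] = []
    n_dropped = 0
    for p in cohort.patients:
        complete = [o for o in p.observations if o.is_complete()]
        n_dropped += len(p.observations) - len(complete)
        if complete:
            kept.append(replace(p, observations=complete))
    report = replace(
        cohort.filter_report,
        n_after_completeness=len(kept),
        n_after_stay_filter=len(kept),
        n_observations_dropped=cohort.filter_report.n_observations_dropped + n_dropped,
    )
    return Cohort(patients=kept, filter_report=report)


def filter_by_stay(cohort: Cohort, min_days: int = 4, max_days: int = 29) -> Cohort:
    """Keep patients whose stay (or time to event) is within [min_days, max_days]."""
    if min_days > max_days:
        raise ValueError("min_days must not exceed max_days")
    kept = [p for p in cohort.patients
            if min_days <= p.length_of_stay_days <= max_days]
    report = replace(cohort.filter_report, n_after_stay_filter=len(kept))
    return Cohort(patients=kept, filter_report=report)


def split_by_outcome(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition into (normal, abnormal) sub-cohorts; union reconstructs the input."""
    unlabelled = [p.patient_id for p in cohort.patients if p.outcome not in (NORMAL, ABNORMAL)]
    if unlabelled:
        raise ValueError(f"unlabelled patient(s): {unlabelled[:5]}")
    normal = [p for p in cohort.patients if p.outcome == NORMAL]
    abnormal = [p for p in cohort.patients if p.outcome == ABNORMAL]
    base = replace(cohort.filter_report, n_normal=len(normal), n_abnormal=len(abnormal))
    return (
        Cohort(patients=normal, filter_report=replace(base)),
        Cohort(patients=abnormal, filter_report=replace(base)),
    )


def preprocess(cohort: Cohort, min_days: int = 4, max_days: int = 29) -> Cohort:
    """Apply the full filter chain (completeness, then stay window) and label counts."""
    out = filter_by_stay(drop_incomplete(cohort), min_days, max_days)
    n_normal = sum(1 for p in out.patients if p.outcome == NORMAL)
    n_abnormal = sum(1 for p in out.patients if p.outcome == ABNORMAL)
    out.filter_report.n_normal = n_normal
    out.filter_report.n_abnormal = n_abnormal
    out.filter_report.validate()
    return out
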