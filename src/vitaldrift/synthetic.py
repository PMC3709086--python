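"""Synthetic post-operative cohort generator.

Emulates the statistical structure of an upper-GI surgical ward cohort:

* Admission-day and discharge-day marginal means/SDs per vital sign
  (heart rate in bpm, respiratory rate in brpm, SpO2 in %, systolic blood
  pressure in mmHg, tympanic temperature in °C).
* Exponential recovery of each vital's mean (and noise SD) from its
  admission value toward its discharge value, stabilising after roughly
  four days.
* Length of stay drawn from a discretised log-normal matched to the ward's
  median/IQR and clipped to the 4--28 day range; for deteriorating
  ("abnormal") patients the analogous time-to-event distribution.
* Charting cadence of 1--2 h early in the stay and 4 h later on.
* Pre-event deterioration episodes for abnormal patients: tachycardia
  (HR -> ~150 bpm), tachypnea (RR -> ~40 brpm), or bradycardia with
  hypertension (HR -> ~45 bpm, SysBP -> ~190 mmHg), ramped linearly over
  a window before the event.

Everything is driven by a single integer seed and is bit-for-bit
reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cohort import (
    ABNORMAL,
    NORMAL,
    VITALS,
    Cohort,
    FilterReport,
    PatientRecord,
    VitalSignObservation,
)

# Admission/discharge marginals per vital, VITALS order: hr, rr, spo2, sysbp, temp.
_ADMISSION_MEAN = (80.6, 16.7, 97.0, 115.7, 36.6)
_ADMISSION_SD = (12.8, 2.5, 1.3, 16.0, 0.5)
_DISCHARGE_MEAN = (81.2, 15.7, 96.3, 132.1, 36.4)
_DISCHARGE_SD = (11.7, 1.0, 1.5, 16.6, 0.4)

#: Deterioration episode types: vital index -> extreme target, natural units.
EPISODE_TYPES = {
    "hr_high": {"hr": 150.0},
    "hr_low_sysbp_high": {"hr": 45.0, "sysbp": 190.0},
    "rr_high": {"rr": 40.0},
}

_Q75 = 0.6744897501960817  # standard-normal 75th-percentile quantile


@dataclass
class SyntheticParams:
    """Generator configuration; defaults encode the study-scale conditions."""

    n_normal: int = 154
    n_abnormal: int = 17
    admission_mean: tuple[float, ...] = _ADMISSION_MEAN
    admission_sd: tuple[float, ...] = _ADMISSION_SD
    discharge_mean: tuple[float, ...] = _DISCHARGE_MEAN
    discharge_sd: tuple[float, ...] = _DISCHARGE_SD
    recovery_tau_days: float = 1.5
    stay_median_days: float = 9.0
    stay_iqr_days: float = 5.0
    event_median_days: float = 5.0
    event_iqr_days: float = 4.0
    stay_min_days: int = 4
    stay_max_days: int = 28
    episode_window_h: float = 24.0
    obs_interval_early_h: tuple[float, float] = (1.0, 2.0)
    obs_interval_late_h: float = 4.0
    early_fraction: float = 0.4
    noise_scale: float = 1.0
    drift_scale: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValueError("patient counts must be non-negative")
        for sd in (*self.admission_sd, *self.discharge_sd):
            if sd <= 0:
                raise ValueError("marginal SDs must be positive")
        if self.recovery_tau_days <= 0:
            raise ValueError("recovery_tau_days must be positive")
        if not (1 <= self.stay_min_days <= self.stay_max_days):
            raise ValueError("invalid stay bounds")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticParams":
        data = yaml.safe_load(text) or {}
        for key in ("admission_mean", "admission_sd", "discharge_mean", "discharge_sd",
                    "obs_interval_early_h"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _lognormal_sigma(median: float, iqr: float) -> float:
    # For log-normal with median m, quartiles are m*exp(+-q75*s); solve IQR = 2m*sinh(q75*s).
    return float(np.arcsinh(iqr / (2.0 * median)) / _Q75)


def _sample_days(median: float, iqr: float, lo: int, hi: int, rng: np.random.Generator) -> int:
    if iqr == 0.0:
        return int(np.clip(round(median), lo, hi))
    s = _lognormal_sigma(median, iqr)
    draw = median * np.exp(s * rng.standard_normal())
    return int(np.clip(round(draw), lo, hi))


def sample_length_of_stay(params: SyntheticParams, rng: np.random.Generator) -> int:
    """Draw a whole-day length of stay for a normal-recovery patient."""
    return _sample_days(params.stay_median_days, params.stay_iqr_days,
                        params.stay_min_days, params.stay_max_days, rng)


def sample_time_to_event(params: SyntheticParams, rng: np.random.Generator) -> int:
    """Draw whole days from admission to the first adverse event."""
    return _sample_days(params.event_median_days, params.event_iqr_days,
                        params.stay_min_days, params.stay_max_days, rng)


def recovery_mean(params: SyntheticParams, t_hours: float) -> np.ndarray:
    """Expected vital-sign vector at ``t_hours`` after admission (no noise)."""
    w = np.exp(-t_hours / (24.0 * params.recovery_tau_days))
    adm = np.asarray(params.admission_mean)
    dis = np.asarray(params.discharge_mean)
    return dis + params.drift_scale * (adm - dis) * w


def recovery_sd(params: SyntheticParams, t_hours: float) -> np.ndarray:
    """Noise SD vector at ``t_hours``, interpolating admission -> discharge SDs."""
    w = np.exp(-t_hours / (24.0 * params.recovery_tau_days))
    adm = np.asarray(params.admission_sd)
    dis = np.asarray(params.discharge_sd)
    return params.noise_scale * (dis + (adm - dis) * w)


def _charting_times(params: SyntheticParams, end_h: float, rng: np.random.Generator) -> list[float]:
    times, t = [], 0.0
    early_end = params.early_fraction * end_h
    lo, hi = params.obs_interval_early_h
    while t < end_h:
        times.append(t)
        t += rng.uniform(lo, hi) if t < early_end else params.obs_interval_late_h
    return times


def episode_ramp(baseline: float, target: float, t: float,
                 event_time: float, window: float) -> float:
    """Linear ramp from ``baseline`` toward ``target`` inside the pre-event window.

    Outside the window the baseline is returned unchanged; at the event time
    the target is reached exactly.
    """
    start = event_time - window
    if t <= start:
        return baseline
    frac = min((t - start) / window, 1.0)
    return baseline * (1.0 - frac) + target * frac


def simulate_patient(
    params: SyntheticParams,
    outcome: str,
    rng: np.random.Generator,
    patient_id: str = "P0",
) -> PatientRecord:
    """Simulate one patient's observation series.

    Normal patients follow the exponential recovery curve with Gaussian
    observation noise.  Abnormal patients additionally receive one or two
    deterioration episodes whose affected vitals ramp linearly toward their
    extreme targets during the pre-event window; their series stops at the
    event.
    """
    if outcome not in (NORMAL, ABNORMAL):
        raise ValueError(f"unknown outcome label: {outcome!r}")

    if outcome == NORMAL:
        stay_days = sample_length_of_stay(params, rng)
        end_h = 24.0 * stay_days
        event_time = None
        episodes: dict[str, float] = {}
    else:
        event_days = sample_time_to_event(params, rng)
        # Event lands inside its calendar day so day_index(event) == event_days.
        event_time = 24.0 * event_days - rng.uniform(0.0, 12.0)
        end_h = event_time
        n_ep = int(rng.integers(1, 3))
        chosen = rng.choice(list(EPISODE_TYPES), size=n_ep, replace=False)
        episodes = {}
        for name in chosen:
            episodes.update(EPISODE_TYPES[name])

    window_start = (event_time - params.episode_window_h) if event_time is not None else None
    base_at_window = (recovery_mean(params, max(window_start, 0.0))
                      if window_start is not None else None)

    times = _charting_times(params, end_h, rng)
    if event_time is not None:
        # The deterioration that triggers the event is itself charted: the
        # series ends with an observation at the event showing the extreme.
        times.append(event_time)

    observations = []
    for t in times:
        mean = recovery_mean(params, t)
        sd = recovery_sd(params, t)
        if episodes:
            for vital, target in episodes.items():
                i = VITALS.index(vital)
                mean[i] = episode_ramp(base_at_window[i], target, t,
                                       event_time, params.episode_window_h)
        values = mean + sd * rng.standard_normal(len(VITALS))
        values = np.maximum(values, 1e-3)           # vitals are strictly positive
        values[VITALS.index("spo2")] = min(values[VITALS.index("spo2")], 100.0)
        if params.missing_rate > 0.0:
            mask = rng.random(len(VITALS)) < params.missing_rate
            values = np.where(mask, np.nan, values)
        observations.append(VitalSignObservation(
            patient_id, float(t),
            **{v: float(values[i]) for i, v in enumerate(VITALS)},
        ))
    return PatientRecord(patient_id, observations, outcome=outcome, event_time=event_time)


def generate_cohort(params: SyntheticParams | None = None, seed: int | None = None) -> Cohort:
    """Generate a full labelled cohort; identical seeds give identical cohorts."""
    params = params or SyntheticParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    patients = []
    for i in range(params.n_normal):
        patients.append(simulate_patient(params, NORMAL, rng, patient_id=f"N{i + 1:03d}"))
    for i in range(params.n_abnormal):
        patients.append(simulate_patient(params, ABNORMAL, rng, patient_id=f"A{i + 1:03d}"))
    n = len(patients)
    report = FilterReport(n_input_patients=n, n_after_completeness=n, n_after_stay_filter=n,
                          n_normal=params.n_normal, n_abnormal=params.n_abnormal)
    return Cohort(patients=patients, filter_report=report)
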