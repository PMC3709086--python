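"""Kernel-density model of normality and novelty scoring.

The model is a kernel density estimate over the normalised vital-sign
vectors charted on each normal patient's discharge day — the most
physiologically stable period of the stay:

    p(x) = 1 / (N (2 pi)^(D/2) sigma^D) * sum_i exp(-||x - x_i||^2 / (2 sigma^2))

with D = 5 and a single isotropic kernel width sigma chosen by the
nearest-neighbour rule: for every training point, the mean Euclidean
distance to its k = 10 nearest other points is computed, and sigma is the
grand mean of those per-point averages.

Abnormality of a query vector is its novelty score z(x) = -ln p(x),
evaluated in the log domain (log-sum-exp) so extreme vitals never overflow
to infinity.  An alarm threshold k = mu + 3 sd is derived from the
per-observation scores of the normal group.  Per-day patient trajectories
and per-group mean trajectories (with standard errors across patients)
summarise recovery and deterioration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import logsumexp

from .cohort import ABNORMAL, Cohort, PatientRecord, day_index
from .sammon import NormalizationParams, normalize


def training_set(normal_cohort: Cohort, params: NormalizationParams) -> np.ndarray:
    """Normalised last-day (pre-discharge) observations of all normal patients."""
    if len(normal_cohort) == 0:
        raise ValueError("empty cohort")
    vecs = []
    for p in normal_cohort.patients:
        for o in p.observations_on_day(p.last_day):
            vecs.append(o.values())
    return normalize(np.array(vecs, dtype=float), params)


@dataclass
class BandwidthEstimate:
    """Per-point k-NN average distances and their grand mean."""

    deltas: np.ndarray
    k: int
    sigma: float


def estimate_bandwidth(X, k: int = 10) -> BandwidthEstimate:
    """Nearest-neighbour kernel width.

    For each point: the mean Euclidean distance to its ``k`` nearest *other*
    points (ties at the k-th distance broken by index order); sigma is the
    mean of those per-point averages.  ``k`` is reduced to N - 1 with a
    warning when the sample is too small.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    if k > n - 1:
        warnings.warn(f"k={k} reduced to {n - 1} for a sample of {n} points")
        k = n - 1
    tree = cKDTree(X)
    dists, _ = tree.query(X, k=k + 1)  # nearest neighbour of each point is itself
    deltas = dists[:, 1:].mean(axis=1)
    sigma = float(deltas.mean())
    if sigma == 0.0:
        raise ValueError("all points identical: kernel width would be zero")
    return BandwidthEstimate(deltas=deltas, k=k, sigma=sigma)


@dataclass
class NormalityModel:
    """Isotropic-Gaussian KDE over normalised training vectors."""

    training_vectors: np.ndarray
    sigma: float
    dims: int = 5

    def __post_init__(self) -> None:
        self.training_vectors = np.atleast_2d(np.asarray(self.training_vectors, dtype=float))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self.dims = self.training_vectors.shape[1]

    @property
    def n_training(self) -> int:
        return self.training_vectors.shape[0]

    @classmethod
    def fit(cls, normal_cohort: Cohort, params: NormalizationParams,
            k: int = 10) -> "NormalityModel":
        X = training_set(normal_cohort, params)
        bw = estimate_bandwidth(X, k=k)
        return cls(training_vectors=X, sigma=bw.sigma)


def log_likelihood(model: NormalityModel, x) -> np.ndarray:
    """ln p(x) under the KDE, via log-sum-exp; accepts a vector or (m, D) matrix."""
    X = model.training_vectors
    q = np.atleast_2d(np.asarray(x, dtype=float))
    out = np.empty(q.shape[0])
    const = (np.log(model.n_training)
             + 0.5 * model.dims * np.log(2.0 * np.pi)
             + model.dims * np.log(model.sigma))
    chunk = 2048
    for s in range(0, q.shape[0], chunk):
        block = q[s:s + chunk]
        sq = np.sum((block[:, None, :] - X[None, :, :]) ** 2, axis=2)
        out[s:s + chunk] = logsumexp(-sq / (2.0 * model.sigma ** 2), axis=1) - const
    return out if np.ndim(x) == 2 else float(out[0])


def likelihood(model: NormalityModel, x):
    """p(x) under the KDE (may underflow to 0 for extreme queries)."""
    return np.exp(log_likelihood(model, x))


def novelty_score(model: NormalityModel, x):
    """z(x) = -ln p(x); high scores mean abnormal. Finite for any finite x."""
    return -log_likelihood(model, x)


@dataclass
class NoveltyThreshold:
    """Alarm level k = mu + multiplier * sd over the normal reference scores."""

    mu_z: float
    sd_z: float
    multiplier: float = 3.0

    @property
    def k_threshold(self) -> float:
        return self.mu_z + self.multiplier * self.sd_z


def compute_threshold(model: NormalityModel, normal_cohort: Cohort,
                      params: NormalizationParams,
                      multiplier: float = 3.0,
                      per_patient: bool = False) -> NoveltyThreshold:
    """Derive the alarm threshold from the normal group's novelty scores.

    By default mu and sd are taken over the per-observation scores of every
    normal patient; ``per_patient=True`` averages within patients first.
    Sample (n - 1) SD convention.
    """
    if len(normal_cohort) == 0:
        raise ValueError("empty cohort")
    if per_patient:
        scores = np.array([
            float(np.mean(novelty_score(model, normalize(p.matrix(), params))))
            for p in normal_cohort.patients
        ])
    else:
        Z = novelty_score(model, normalize(normal_cohort.all_observations(), params))
        scores = np.asarray(Z, dtype=float)
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    return NoveltyThreshold(mu_z=float(scores.mean()), sd_z=sd, multiplier=multiplier)


def daily_novelty(model: NormalityModel, patient: PatientRecord,
                  params: NormalizationParams) -> pd.DataFrame:
    """Per-day mean novelty score for one patient.

    Abnormal patients are scored only up to their event time.  Returns a
    frame with columns day, z_mean, n_obs.
    """
    obs = patient.observations
    if patient.outcome == ABNORMAL and patient.event_time is not None:
        obs = [o for o in obs if o.time <= patient.event_time]
    if not obs:
        return pd.DataFrame(columns=["day", "z_mean", "n_obs"])
    days = np.array([day_index(o.time) for o in obs])
    X = normalize(np.array([o.values() for o in obs]), params)
    z = np.asarray(novelty_score(model, X))
    frame = pd.DataFrame({"day": days, "z": z})
    agg = frame.groupby("day")["z"].agg(["mean", "size"]).reset_index()
    return agg.rename(columns={"mean": "z_mean", "size": "n_obs"})


@dataclass
class NoveltyTrajectory:
    """Group-level per-day novelty summary.

    ``per_patient`` holds each patient's daily means; ``summary`` has one
    row per day up to the truncation day with the across-patient mean, the
    standard error (sd / sqrt(n patients contributing), 0 when only one
    contributes) and the contributing count.
    """

    per_patient: pd.DataFrame   # patient_id, day, z_mean, n_obs
    summary: pd.DataFrame       # day, z_mean, z_se, n_patients
    truncation_day: int


def group_trajectory(cohort: Cohort, model: NormalityModel,
                     params: NormalizationParams,
                     truncation_percentile: float = 75.0) -> NoveltyTrajectory:
    """Per-day mean novelty across a patient group, truncated at the group's
    75th-percentile stay (or time-to-event) by default."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    frames = []
    for p in cohort.patients:
        f = daily_novelty(model, p, params)
        f.insert(0, "patient_id", p.patient_id)
        frames.append(f)
    per_patient = pd.concat(frames, ignore_index=True)
    stays = [p.length_of_stay_days for p in cohort.patients]
    trunc = int(np.percentile(stays, truncation_percentile, method="nearest"))
    sel = per_patient[per_patient["day"] <= trunc]
    rows = []
    for day, grp in sel.groupby("day"):
        vals = grp["z_mean"].to_numpy()
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append({"day": int(day), "z_mean": float(vals.mean()),
                     "z_se": se, "n_patients": len(vals)})
    summary = pd.DataFrame(rows, columns=["day", "z_mean", "z_se", "n_patients"])
    return NoveltyTrajectory(per_patient=per_patient, summary=summary, truncation_day=trunc)


def exceedance_table(cohort: Cohort, model: NormalityModel,
                     params: NormalizationParams,
                     threshold: NoveltyThreshold) -> pd.DataFrame:
    """Per patient: maximum daily score and whether it crosses the threshold."""
    rows = []
    for p in cohort.patients:
        f = daily_novelty(model, p, params)
        zmax = float(f["z_mean"].max()) if len(f) else float("nan")
        rows.append({"patient_id": p.patient_id, "outcome": p.outcome,
                     "z_max_daily": zmax,
                     "exceeds_threshold": bool(zmax > threshold.k_threshold)})
    return pd.DataFrame(rows)
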