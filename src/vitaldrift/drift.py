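"""Distribution drift across the ward stay: subgroups and distances.

For each patient, five daily-average vital-sign vectors are formed at fixed
fractions of the stay: G1 = admission day, G2/G3/G4 = days at 25/50/75 % of
the stay, G5 = discharge day (or last pre-event day).  Drift is quantified
by comparing, per vital sign, the G1..G4 samples against G5 with three
distribution distances:

* Kolmogorov–Smirnov: sup-norm difference of the two empirical CDFs,
  computed directly on the samples.
* Symmetric Kullback–Leibler (Jeffreys) divergence: sum over shared
  histogram bins of (p - q) * ln(p / q), in nats.
* Bhattacharyya distance: -ln of the overlap coefficient sum(sqrt(p * q)).

The histogram-based metrics use shared fixed-width bins spanning the pooled
range of the two samples; empty bins are handled by additive smoothing (or
flagged divergent in strict mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord, VITALS

SUBGROUPS = ("G1", "G2", "G3", "G4", "G5")

#: Default histogram bin widths, natural units per vital.
DEFAULT_BIN_WIDTHS = {"hr": 5.0, "rr": 1.0, "spo2": 1.0, "sysbp": 5.0, "temp": 0.2}

METRICS = ("KS", "KL_s", "Bhat")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def subgroup_days(length_of_stay_days: int) -> tuple[int, int, int, int, int]:
    """Day indices at 0/25/50/75/100 % of an L-day stay (day 1 = admission).

    d_q = 1 + round(q * (L - 1)), rounding half away from zero, so the first
    subgroup is always day 1 and the last is always day L.
    """
    L = length_of_stay_days
    if L < 4:
        raise ValueError("length of stay must be at least 4 days")
    return tuple(1 + _round_half_away(q * (L - 1)) for q in (0.0, 0.25, 0.5, 0.75, 1.0))


def daily_average(patient: PatientRecord, day: int) -> np.ndarray | None:
    """Arithmetic mean vector of a patient's observations on a calendar day.

    Returns ``None`` if the day has no observations; the caller decides the
    fallback.
    """
    obs = patient.observations_on_day(day)
    if not obs:
        return None
    return np.mean([o.values() for o in obs], axis=0)


@dataclass
class SubgroupSet:
    """Per-patient daily-average vectors at the five stay fractions.

    ``table`` has columns patient_id, subgroup, and one column per vital.
    """

    table: pd.DataFrame

    def sample(self, subgroup: str, vital: str) -> np.ndarray:
        sel = self.table.loc[self.table["subgroup"] == subgroup, vital]
        return sel.to_numpy(dtype=float)

    def vectors(self, subgroup: str | None = None) -> np.ndarray:
        t = self.table if subgroup is None else self.table[self.table["subgroup"] == subgroup]
        return t[list(VITALS)].to_numpy(dtype=float)


def build_subgroups(cohort: Cohort) -> SubgroupSet:
    """Compute every patient's G1..G5 daily-average vectors.

    A subgroup row is present only when its designated day has at least one
    observation.
    """
    rows = []
    for p in cohort.patients:
        days = subgroup_days(p.length_of_stay_days)
        for label, day in zip(SUBGROUPS, days):
            vec = daily_average(p, day)
            if vec is None:
                continue
            rows.append({"patient_id": p.patient_id, "subgroup": label, "day": day,
                         **dict(zip(VITALS, vec))})
    return SubgroupSet(pd.DataFrame(rows, columns=["patient_id", "subgroup", "day", *VITALS]))


# ---------------------------------------------------------------------------
# Distribution containers


class EmpiricalCDF:
    """Right-continuous empirical CDF of a sample, evaluable at any real."""

    def __init__(self, sample):
        sample = np.asarray(sample, dtype=float)
        if sample.size == 0:
            raise ValueError("empty sample")
        self.sorted = np.sort(sample)
        self.n = sample.size

    def __call__(self, x) -> np.ndarray | float:
        return np.searchsorted(self.sorted, np.asarray(x), side="right") / self.n


@dataclass
class DiscreteDistribution:
    """Histogram-style discrete distribution on shared bin edges."""

    bin_edges: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if len(self.mass) != len(self.bin_edges) - 1:
            raise ValueError("need len(mass) == len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.mass < 0):
            raise ValueError("mass must be non-negative")
        if abs(self.mass.sum() - 1.0) > 1e-12:
            raise ValueError("mass must sum to 1")

    @classmethod
    def from_sample(cls, sample, bin_edges) -> "DiscreteDistribution":
        counts, _ = np.histogram(np.asarray(sample, dtype=float), bins=bin_edges)
        total = counts.sum()
        if total == 0:
            raise ValueError("no sample points fall within the bin edges")
        return cls(bin_edges=np.asarray(bin_edges, dtype=float), mass=counts / total)


def shared_bin_edges(sample_p, sample_q, width: float) -> np.ndarray:
    """Fixed-width edges spanning the pooled range of two samples."""
    pooled = np.concatenate([np.asarray(sample_p, float), np.asarray(sample_q, float)])
    lo, hi = pooled.min(), pooled.max()
    n_bins = max(int(np.ceil((hi - lo) / width)), 1)
    return lo + width * np.arange(n_bins + 1)


# ---------------------------------------------------------------------------
# The three distances


def ks_distance(sample_p, sample_q) -> float:
    """Two-sample Kolmogorov–Smirnov statistic: sup |P(x) - Q(x)|, in [0, 1]."""
    p = np.asarray(sample_p, dtype=float)
    q = np.asarray(sample_q, dtype=float)
    if p.size == 0 or q.size == 0:
        raise ValueError("both samples must be non-empty")
    P, Q = EmpiricalCDF(p), EmpiricalCDF(q)
    pooled = np.concatenate([P.sorted, Q.sorted])
    return float(np.max(np.abs(P(pooled) - Q(pooled))))


def _check_shared(p: DiscreteDistribution, q: DiscreteDistribution) -> None:
    if len(p.bin_edges) != len(q.bin_edges) or not np.allclose(p.bin_edges, q.bin_edges):
        raise ValueError("distributions must share bin edges")


def kl_symmetric(
    p: DiscreteDistribution,
    q: DiscreteDistribution,
    smoothing: float = 1e-10,
    strict: bool = False,
) -> float:
    """Symmetric Kullback–Leibler (Jeffreys) divergence in nats.

    sum over bins of (p - q) * ln(p / q).  Bins empty in one distribution
    make the sum divergent; by default a small additive smoothing (followed
    by renormalisation) keeps it finite, while ``strict=True`` returns
    ``inf`` as the divergent flag.
    """
    _check_shared(p, q)
    pm, qm = p.mass, q.mass
    divergent = bool(np.any((pm == 0) ^ (qm == 0)))
    if strict:
        if divergent:
            return float("inf")
        both = pm > 0
        return float(np.sum((pm[both] - qm[both]) * np.log(pm[both] / qm[both])))
    pm = (pm + smoothing) / (pm + smoothing).sum()
    qm = (qm + smoothing) / (qm + smoothing).sum()
    return float(np.sum((pm - qm) * np.log(pm / qm)))


def bhattacharyya(p: DiscreteDistribution, q: DiscreteDistribution) -> float:
    """Bhattacharyya distance -ln(BC) with BC = sum(sqrt(p * q)); inf if BC = 0."""
    _check_shared(p, q)
    bc = float(np.sum(np.sqrt(p.mass * q.mass)))
    if bc == 0.0:
        return float("inf")
    return max(0.0, -np.log(bc))  # clip the (tiny) negative rounding case


# ---------------------------------------------------------------------------
# Distance maps


@dataclass
class DistanceMap:
    """5 (vitals) x 4 (G1..G4 vs G5) matrix of one metric's distances."""

    metric: str
    values: pd.DataFrame  # index VITALS, columns G1..G4

    def to_long(self) -> pd.DataFrame:
        long = self.values.reset_index(names="vital").melt(
            id_vars="vital", var_name="comparison", value_name="distance")
        long.insert(0, "metric", self.metric)
        return long


def distance_map(
    subgroups: SubgroupSet,
    metric: str,
    bin_widths: dict[str, float] | None = None,
) -> DistanceMap:
    """Compare each vital's G1..G4 sample with its G5 sample under one metric.

    KS works on the raw daily-average samples; KL_s and Bhat on shared-edge
    histograms of those samples.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    widths = {**DEFAULT_BIN_WIDTHS, **(bin_widths or {})}
    mat = np.zeros((len(VITALS), 4))
    for i, vital in enumerate(VITALS):
        ref = subgroups.sample("G5", vital)
        for j, label in enumerate(SUBGROUPS[:4]):
            sam = subgroups.sample(label, vital)
            if metric == "KS":
                mat[i, j] = ks_distance(sam, ref)
            else:
                edges = shared_bin_edges(sam, ref, widths[vital])
                p = DiscreteDistribution.from_sample(sam, edges)
                q = DiscreteDistribution.from_sample(ref, edges)
                mat[i, j] = kl_symmetric(p, q) if metric == "KL_s" else bhattacharyya(p, q)
    values = pd.DataFrame(mat, index=list(VITALS), columns=list(SUBGROUPS[:4]))
    return DistanceMap(metric=metric, values=values)


def all_distance_maps(subgroups: SubgroupSet,
                      bin_widths: dict[str, float] | None = None) -> dict[str, DistanceMap]:
    return {m: distance_map(subgroups, m, bin_widths) for m in METRICS}
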