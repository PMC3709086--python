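"""End-to-end orchestration: simulate/load -> filter -> distances -> Sammon
-> model of normality -> scoring -> report bundle.

A single global seed deterministically derives an independent sub-seed for
every stage (splitmix-style mixing), so stages can be rerun in isolation
and identical configurations yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import drift, normality, sammon
from .cohort import Cohort, preprocess, read_cohort, split_by_outcome, write_cohort
from .synthetic import SyntheticParams, generate_cohort


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31, mixed from the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything needed to run the full analysis reproducibly."""

    input_csv: str | None = None            # if None, a synthetic cohort is generated
    synthetic: SyntheticParams = field(default_factory=SyntheticParams)
    min_stay_days: int = 4
    max_stay_days: int = 29
    bin_widths: dict[str, float] = field(default_factory=dict)
    sammon_max_iter: int = 200
    sammon_tol: float = 1e-7
    sammon_step: float = 0.3
    sammon_max_points: int = 900            # subsample cap for the embedding stage
    bandwidth_k: int = 10
    threshold_multiplier: float = 3.0
    seed: int = 0

    def to_yaml(self) -> str:
        data = dataclasses.asdict(self)
        return yaml.safe_dump(data, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        if "synthetic" in data and isinstance(data["synthetic"], dict):
            syn = dict(data["synthetic"])
            for key in ("admission_mean", "admission_sd", "discharge_mean",
                        "discharge_sd", "obs_interval_early_h"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            data["synthetic"] = SyntheticParams(**syn)
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All pipeline artifacts plus the config hash that produced them."""

    config_hash: str
    filter_report: dict
    distance_maps: dict[str, pd.DataFrame]
    embedding: pd.DataFrame
    embedding_stress: float
    model_summary: dict
    trajectories: dict[str, pd.DataFrame]
    exceedance: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": self.config_hash,
                "filter_report": self.filter_report,
                "model_summary": self.model_summary,
                "embedding_stress": self.embedding_stress}
        (out / "report.json").write_text(json.dumps(meta, indent=2) + "\n")
        long = pd.concat(
            [drift.DistanceMap(m, df).to_long() for m, df in self.distance_maps.items()],
            ignore_index=True)
        long.to_csv(out / "distances.csv", index=False, float_format="%.10g")
        self.embedding.to_csv(out / "sammon.csv", index=False, float_format="%.10g")
        for name, traj in self.trajectories.items():
            traj.to_csv(out / f"trajectory_{name}.csv", index=False, float_format="%.10g")
        self.exceedance.to_csv(out / "exceedance.csv", index=False)


def load_or_generate(config: PipelineConfig) -> Cohort:
    if config.input_csv is not None:
        return read_cohort(config.input_csv)
    return generate_cohort(config.synthetic, seed=derive_seed(config.seed, "simulate"))


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages in order and assemble the report bundle."""
    cohort = load_or_generate(config)
    cohort = preprocess(cohort, config.min_stay_days, config.max_stay_days)
    normal, abnormal = split_by_outcome(cohort)

    subgroups = drift.build_subgroups(normal)
    maps = drift.all_distance_maps(subgroups, config.bin_widths or None)

    norm_params = sammon.fit_normalization(cohort)
    vectors = subgroups.vectors()
    labels = subgroups.table[["patient_id", "subgroup"]].reset_index(drop=True)
    emb_seed = derive_seed(config.seed, "sammon")
    if vectors.shape[0] > config.sammon_max_points:
        rng = np.random.default_rng(emb_seed)
        idx = np.sort(rng.choice(vectors.shape[0], config.sammon_max_points, replace=False))
        vectors, labels = vectors[idx], labels.iloc[idx].reset_index(drop=True)
    emb = sammon.sammon_embed(sammon.normalize(vectors, norm_params),
                              seed=emb_seed,
                              max_iter=config.sammon_max_iter,
                              tol=config.sammon_tol,
                              step=config.sammon_step)
    embedding = labels.copy()
    embedding["y1"] = emb.points[:, 0]
    embedding["y2"] = emb.points[:, 1]

    model = normality.NormalityModel.fit(normal, norm_params, k=config.bandwidth_k)
    threshold = normality.compute_threshold(model, normal, norm_params,
                                            multiplier=config.threshold_multiplier)
    trajectories = {
        "normal": normality.group_trajectory(normal, model, norm_params).summary,
        "abnormal": normality.group_trajectory(abnormal, model, norm_params).summary
        if len(abnormal) else pd.DataFrame(),
    }
    exceed = normality.exceedance_table(abnormal, model, norm_params, threshold) \
        if len(abnormal) else pd.DataFrame()

    return ReportBundle(
        config_hash=config.config_hash(),
        filter_report=dict(cohort.filter_report.__dict__),
        distance_maps={m: dm.values for m, dm in maps.items()},
        embedding=embedding,
        embedding_stress=emb.stress,
        model_summary={
            "n_training": model.n_training,
            "sigma": model.sigma,
            "mu_z": threshold.mu_z,
            "sd_z": threshold.sd_z,
            "k_threshold": threshold.k_threshold,
        },
        trajectories=trajectories,
        exceedance=exceed,
    )
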