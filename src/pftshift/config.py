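"""Run configuration: one structured file drives the whole pipeline."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .sdm_ensemble import LearnerSpec, default_learners
from .synthetic_landscape import ClimateDelta, GridSpec, NicheSpec

__all__ = ["RunConfig", "ScenarioSpec", "load_config", "derive_seed"]

KNOWN_LEARNERS = {"gam", "mars", "maxent", "rf"}


@dataclass(frozen=True)
class ScenarioSpec:
    label: str
    rcp: str
    gcm: str
    delta: ClimateDelta


@dataclass
class RunConfig:
    seed: int
    grid: GridSpec
    landscape: dict
    niches: dict[str, NicheSpec]  # species id -> niche
    n_records: dict[str, int]  # species id -> occurrence sample size
    pfts: dict[str, list[str]]  # pft -> member species
    scenarios: list[ScenarioSpec]
    learners: list[LearnerSpec]
    thresholds: dict = field(default_factory=dict)
    modelling: dict = field(default_factory=dict)

    def threshold(self, key: str):
        defaults = {
            "vif": 10.0,
            "filter": 0.7,
            "min_agree": 3,
            "presence_min": 2,
            "quantile": 0.05,
            "min_records": 200,
        }
        return self.thresholds.get(key, defaults[key])

    def model_param(self, key: str):
        defaults = {
            "n_replicates": 100,
            "train_frac": 0.7,
            "k_projection": 10,
            "anova_cells": 200,
            "n_background_vif": 5000,
            "allow_below_min": False,
        }
        return self.modelling.get(key, defaults[key])

    def validate(self) -> None:
        for spec in self.learners:
            if spec.name not in KNOWN_LEARNERS:
                raise ValueError(f"unknown learner name {spec.name!r}")
        labels = [s.label for s in self.scenarios]
        if len(set(labels)) != len(labels):
            raise ValueError("scenario labels must be unique")
        for pft, members in self.pfts.items():
            unknown = [m for m in members if m not in self.niches]
            if unknown:
                raise ValueError(f"PFT {pft!r} references unknown species {unknown}")


def derive_seed(base: int, *names: str) -> int:
    """Stable sub-seed (< 2^31) derived from the run seed and a name path."""
    h = base & 0x7FFFFFFF
    for name in names:
        h = zlib.crc32(f"{h}:{name}".encode()) & 0x7FFFFFFF
    return h


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    grid = GridSpec(**raw["grid"])
    niches = {}
    n_records = {}
    for sid, nd in raw["species"].items():
        niches[sid] = NicheSpec(
            species_id=sid,
            optima=dict(nd["optima"]),
            breadths=dict(nd["breadths"]),
            max_prob=float(nd.get("max_prob", 1.0)),
        )
        n_records[sid] = int(nd.get("n_records", 500))
    scenarios = [
        ScenarioSpec(
            label=sd["label"],
            rcp=sd.get("rcp", sd["label"]),
            gcm=sd.get("gcm", "gcm0"),
            delta=ClimateDelta(
                label=sd["label"],
                offsets=dict(sd.get("offsets", {})),
                factors=dict(sd.get("factors", {})),
            ),
        )
        for sd in raw.get("scenarios", [])
    ]
    learners_raw = raw.get("learners", "default")
    if learners_raw == "default":
        learners = default_learners()
    else:
        learners = [
            LearnerSpec(
                name=ld["name"],
                pa_strategy=ld.get("pa_strategy", "random"),
                pa_count=ld.get("pa_count", 10_000),
                hyperparams=dict(ld.get("hyperparams", {})),
                presence_only=bool(ld.get("presence_only", ld["name"] == "maxent")),
            )
            for ld in learners_raw
        ]
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        grid=grid,
        landscape=dict(raw.get("landscape", {})),
        niches=niches,
        n_records=n_records,
        pfts={k: list(v) for k, v in raw.get("pfts", {}).items()},
        scenarios=scenarios,
        learners=learners,
        thresholds=dict(raw.get("thresholds", {})),
        modelling=dict(raw.get("modelling", {})),
    )
    cfg.validate()
    return cfg
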