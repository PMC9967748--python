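"""Pipeline configuration: one YAML document drives every stage.

Thresholds default to the analysis' standard calls: differential abundance
at adjusted p < 0.05 with |logFC| > 1, clinical association at adjusted
p < 0.05, enrichment reported at permutation p < 0.05 and FDR q < 0.25.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .diff_abund import CohortSpec, default_cohorts
from .io_formats import CLINICAL_VARIABLES
from .synthetic_data import (
    ClinicalEffect,
    DAEffect,
    ExpressionBlock,
    SimulationConfig,
)


class ConfigError(ValueError):
    """The YAML configuration contains unknown or invalid keys."""


@dataclass
class DecontamConfig:
    margin: float = 0.1
    min_prevalence: float = 0.1
    share_threshold: float = 0.9
    max_plates: int = 2
    slope_scale: str = "log"


@dataclass
class TransformConfig:
    pseudocount: float = 1.0


@dataclass
class DAConfig:
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    bonferroni: bool = True
    use_adjusted: bool = True
    cohorts: list[CohortSpec] = field(default_factory=default_cohorts)


@dataclass
class ClinicalConfig:
    alpha: float = 0.05
    collapse_stages: bool = True
    variables: tuple[str, ...] = CLINICAL_VARIABLES


@dataclass
class EnrichmentConfig:
    n_perm: int = 1000
    weight: float = 1.0
    metric: str = "pearson"
    alpha: float = 0.05
    fdr_threshold: float = 0.25


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "mycoarch_out"
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    transform: TransformConfig = field(default_factory=TransformConfig)
    decontam: DecontamConfig = field(default_factory=DecontamConfig)
    da: DAConfig = field(default_factory=DAConfig)
    clinical: ClinicalConfig = field(default_factory=ClinicalConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def __post_init__(self) -> None:
        for name, value in (
            ("da.alpha", self.da.alpha),
            ("da.lfc_threshold", self.da.lfc_threshold),
            ("clinical.alpha", self.clinical.alpha),
            ("enrichment.alpha", self.enrichment.alpha),
            ("enrichment.fdr_threshold", self.enrichment.fdr_threshold),
        ):
            if value <= 0:
                raise ConfigError(f"{name} must be positive")


def _build(cls, data: Mapping[str, Any], context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> PipelineConfig:
    """Load a PipelineConfig from YAML, applying flat dotted overrides
    (e.g. ``{"da.alpha": 0.01, "seed": 7}``)."""
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    for key, value in (overrides or {}).items():
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value

    sim_data = dict(data.pop("simulate", {}))
    if "da_effects" in sim_data:
        sim_data["da_effects"] = [
            _build(DAEffect, e, "simulate.da_effects") for e in sim_data["da_effects"]
        ]
    if "clinical_effect" in sim_data and sim_data["clinical_effect"] is not None:
        ce = dict(sim_data["clinical_effect"])
        if "levels" in ce:
            ce["levels"] = tuple(ce["levels"])
        sim_data["clinical_effect"] = _build(ClinicalEffect, ce,
                                             "simulate.clinical_effect")
    if "expression" in sim_data and sim_data["expression"] is not None:
        sim_data["expression"] = _build(ExpressionBlock, sim_data["expression"],
                                        "simulate.expression")
    for tuple_key in ("subtype_weights", "gender_weights"):
        if tuple_key in sim_data:
            sim_data[tuple_key] = tuple(sim_data[tuple_key])

    da_data = dict(data.pop("da", {}))
    if "cohorts" in da_data:
        da_data["cohorts"] = [
            CohortSpec(c["name"], c["group_a"], c["group_b"])
            for c in da_data["cohorts"]
        ]
    clin_data = dict(data.pop("clinical", {}))
    if "variables" in clin_data:
        clin_data["variables"] = tuple(clin_data["variables"])

    cfg = PipelineConfig(
        seed=int(data.pop("seed", 0)),
        out_dir=str(data.pop("out_dir", "mycoarch_out")),
        simulate=_build(SimulationConfig, sim_data, "simulate"),
        transform=_build(TransformConfig, dict(data.pop("transform", {})),
                         "transform"),
        decontam=_build(DecontamConfig, dict(data.pop("decontam", {})), "decontam"),
        da=_build(DAConfig, da_data, "da"),
        clinical=_build(ClinicalConfig, clin_data, "clinical"),
        enrichment=_build(EnrichmentConfig, dict(data.pop("enrichment", {})),
                          "enrichment"),
    )
    if data:
        raise ConfigError(f"unknown top-level config keys: {sorted(data)}")
    # the simulation inherits the run seed unless set explicitly
    if "seed" not in sim_data:
        cfg.simulate.seed = cfg.seed
    return cfg
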