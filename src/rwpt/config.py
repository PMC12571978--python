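"""Run configuration: validated YAML schema for geometry, scoring, simulation and statistics.

Unknown keys are rejected everywhere (``extra="forbid"``) so typos in a config
file fail loudly instead of silently falling back to defaults.  The matching
JSON schema is shipped at ``configs/config.schema.json``.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Dict, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .geometry import TargetGrid
from .scoring import DEFAULT_AGGREGATE_MAP, ParadigmID
from .simulate import DEFAULT_GROUP_PRESETS, SimulationConfig
from .stats import StatisticsPlan, default_plan

__all__ = ["GeometryConfig", "ScoringConfig", "SimulationBlock", "StatisticsBlock",
           "PathsConfig", "RunConfig", "load_config", "export_schema"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    wall_distance_cm: float = Field(192.0, gt=0)
    horizontal_spacing_cm: float = Field(51.4, gt=0)
    vertical_spacing_cm: float = Field(51.4, gt=0)

    def to_grid(self) -> TargetGrid:
        return TargetGrid(self.wall_distance_cm, self.horizontal_spacing_cm,
                          self.vertical_spacing_cm)


class ScoringConfig(_Strict):
    calibration_threshold_deg: float = Field(10.0, gt=0)
    aggregate_map: Dict[str, list[str]] = Field(
        default_factory=lambda: {k: [p.value for p in v]
                                 for k, v in DEFAULT_AGGREGATE_MAP.items()})

    def to_aggregate_map(self):
        return {name: tuple(ParadigmID(p) for p in paradigms)
                for name, paradigms in self.aggregate_map.items()}


class SimulationBlock(_Strict):
    group_sizes: Dict[str, int] = Field(
        default_factory=lambda: {"BVP": 32, "PPPD": 43, "HC": 32})
    repeats: int = Field(1, ge=1)
    master_seed: int = 0
    # optional per-group overrides of the preset generative means
    parameters: Dict[str, Dict[str, float]] = Field(default_factory=dict)

    def to_simulation_config(self) -> SimulationConfig:
        presets = dict(DEFAULT_GROUP_PRESETS)
        for group, overrides in self.parameters.items():
            if group not in presets:
                raise ValueError(f"no preset for group {group!r}")
            preset = presets[group]
            presets[group] = replace(preset, model=replace(preset.model, **overrides))
        return SimulationConfig(group_sizes=dict(self.group_sizes), presets=presets,
                                repeats=self.repeats, master_seed=self.master_seed)


class StatisticsBlock(_Strict):
    alpha: float = Field(0.05, gt=0, lt=1)
    levene_alpha: float = Field(0.05, gt=0, lt=1)
    posthoc: str = "bootstrap-tukey"
    n_boot: int = Field(1000, ge=1)
    seed: int = 0

    def to_plan(self) -> StatisticsPlan:
        base = default_plan(seed=self.seed)
        return replace(base, alpha=self.alpha, levene_alpha=self.levene_alpha,
                       posthoc=self.posthoc, n_boot=self.n_boot, seed=self.seed)


class PathsConfig(_Strict):
    trials_csv: Optional[str] = None      # input; None => simulate
    metadata_csv: Optional[str] = None
    output_dir: str = "rwpt_output"


class RunConfig(_Strict):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    scoring: ScoringConfig = Field(default_factory=ScoringConfig)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    statistics: StatisticsBlock = Field(default_factory=StatisticsBlock)
    paths: PathsConfig = Field(default_factory=PathsConfig)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)


def export_schema(path) -> None:
    """Write the JSON schema for RunConfig (shipped in configs/)."""
    import json

    Path(path).write_text(json.dumps(RunConfig.model_json_schema(), indent=2) + "\n")
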