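"""Run configuration: YAML loading with itemized validation.

One config file fully describes a run; defaults mirror the analysis
conventions used throughout (alpha 0.05, effect-size gate 0.5, Tukey
fence multiplier 1.5, circadian period window 18-30 h, AC bound 0.15/h,
index->PS offset 16 h, PS->CT offset -12 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .image import SegmentationConfig
from .rhythm import RhythmCriteria

__all__ = ["PipelineConfig", "ConfigError", "load_config"]

WORKFLOWS = ("simulate", "phagocytosis", "proteoglycan")


class ConfigError(ValueError):
    """Carries an itemized list of validation problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" +
                         "\n".join(f"  - {p}" for p in problems))


@dataclass
class PipelineConfig:
    workflow: str = "simulate"
    input_dir: str | None = None
    pg_table: str | None = None
    standard_curve: str | None = None
    output_dir: str = "results"
    seed: int = 0
    alpha: float = 0.05
    g_min: float = 0.5
    iqr_multiplier: float = 1.5
    background_signal: float = 0.0
    period_min: float = 18.0
    period_max: float = 30.0
    ac_bound: float = 0.15
    index_to_ps: float = 16.0
    ps_to_ct: float = -12.0
    area_min: float = 150.0
    area_max: float = 450.0
    max_clump_size: int = 4
    edge_threshold_rel: float = 0.25
    smooth: bool = True
    detrend: bool = True
    collapse_replicates: bool = True
    # simulate-workflow knobs
    start: float = 16.0
    interval: float = 4.0
    span: float = 24.0
    replicates: int = 3
    cells_per_image: int = 20

    def criteria(self) -> RhythmCriteria:
        return RhythmCriteria(period_min=self.period_min,
                              period_max=self.period_max,
                              ac_bound=self.ac_bound, alpha=self.alpha)

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(area_min=self.area_min, area_max=self.area_max,
                                  max_clump_size=self.max_clump_size,
                                  edge_threshold_rel=self.edge_threshold_rel)


def _validate(raw: dict) -> PipelineConfig:
    problems: list[str] = []
    known = {f.name: f for f in fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            problems.append(f"unknown key {key!r}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    if cfg.workflow not in WORKFLOWS:
        problems.append(f"workflow must be one of {WORKFLOWS}, got {cfg.workflow!r}")
    if not (0 < cfg.alpha < 1):
        problems.append("alpha must be in (0, 1)")
    if cfg.g_min < 0:
        problems.append("g_min must be >= 0")
    if cfg.iqr_multiplier <= 0:
        problems.append("iqr_multiplier must be > 0")
    if not (0 < cfg.period_min < cfg.period_max):
        problems.append("need 0 < period_min < period_max")
    if cfg.ac_bound <= 0:
        problems.append("ac_bound must be > 0")
    if not (0 < cfg.area_min < cfg.area_max):
        problems.append("need 0 < area_min < area_max")
    if cfg.max_clump_size < 1:
        problems.append("max_clump_size must be >= 1")
    if cfg.interval <= 0 or cfg.span < cfg.interval:
        problems.append("need interval > 0 and span >= interval")
    if cfg.replicates < 1:
        problems.append("replicates must be >= 1")
    if cfg.workflow == "phagocytosis" and not cfg.input_dir:
        problems.append("phagocytosis workflow requires input_dir")
    if cfg.workflow == "proteoglycan" and not (cfg.pg_table and cfg.standard_curve):
        problems.append("proteoglycan workflow requires pg_table and standard_curve")
    if problems:
        raise ConfigError(problems)
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; all defaults materialized."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["top level of the config must be a mapping"])
    cfg = _validate(raw)
    for p_key in ("input_dir", "pg_table", "standard_curve"):
        p = getattr(cfg, p_key)
        if p is not None and not Path(p).exists():
            raise ConfigError([f"{p_key} path does not exist: {p}"])
    return cfg
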