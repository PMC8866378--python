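"""Run configuration: YAML schema, defaults and validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .designcv import DEFAULT_DENSITY_GRID, DEFAULT_DILUTION_LEVELS


@dataclass
class FilterSettings:
    maf_min: float = 0.05
    depth_q90_min: float = 10.0
    depth_q90_max: float = 500.0
    biallelic_only: bool = True


@dataclass
class GwasSettings:
    enabled: bool = True
    n_perm: int = 1000
    alpha: float = 0.05
    merge_window_bp: int = 1_000_000
    n_pcs: int = 1
    coding: str = "additive"
    seed: Optional[int] = None


@dataclass
class PredictionSettings:
    enabled: bool = True
    vp_fraction: float = 0.10
    n_reps: int = 100
    kinship: str = "shrunk"  # shrunk | vanraden
    thin_window_bp: int = 1000
    seed: Optional[int] = None


@dataclass
class ExperimentSettings:
    density: bool = False
    density_grid: tuple = DEFAULT_DENSITY_GRID
    relatedness: bool = False
    dilution_levels: tuple = DEFAULT_DILUTION_LEVELS
    reps_per_level: int = 50
    vp_size: int = 60
    size_modes: tuple = ()
    size_grid: tuple = ()
    size_reps: int = 50
    n_reps: int = 100
    seed: Optional[int] = None


@dataclass
class RunConfig:
    vcf: str = ""
    phenotypes: str = ""
    output_dir: str = "qgpanel_run"
    traits: tuple = ()  # empty = all traits in the phenotype file
    filter: FilterSettings = field(default_factory=FilterSettings)
    ld_neighbors: int = 100
    gwas: GwasSettings = field(default_factory=GwasSettings)
    prediction: PredictionSettings = field(default_factory=PredictionSettings)
    experiments: ExperimentSettings = field(default_factory=ExperimentSettings)


def _build(cls, data: dict):
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        sub = cls.__dataclass_fields__[k].type
        if isinstance(v, dict):
            kwargs[k] = _build(
                {"filter": FilterSettings, "gwas": GwasSettings,
                 "prediction": PredictionSettings,
                 "experiments": ExperimentSettings}[k], v)
        elif isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(RunConfig, data)


def validate(config: RunConfig) -> list[str]:
    """Schema and cross-field checks; returns issues, raises nothing."""
    issues: list[str] = []
    if not config.vcf:
        issues.append("vcf path is required")
    elif not Path(config.vcf).exists():
        issues.append(f"vcf path does not exist: {config.vcf}")
    if not config.phenotypes:
        issues.append("phenotypes path is required")
    elif not Path(config.phenotypes).exists():
        issues.append(f"phenotypes path does not exist: {config.phenotypes}")
    if not (0.0 <= config.filter.maf_min < 0.5):
        issues.append(f"filter.maf_min must be in [0, 0.5): {config.filter.maf_min}")
    g = config.gwas
    if g.enabled:
        if not (0.0 < g.alpha < 1.0):
            issues.append(f"gwas.alpha must be in (0, 1): {g.alpha}")
        if g.n_perm < 20:
            issues.append(f"gwas.n_perm must be >= 20: {g.n_perm}")
        if g.merge_window_bp < 1:
            issues.append(f"gwas.merge_window_bp must be >= 1: {g.merge_window_bp}")
        if g.coding not in ("additive", "dominance"):
            issues.append(f"gwas.coding unknown: {g.coding}")
        if g.seed is None:
            issues.append("gwas.seed is required (stochastic stage)")
    p = config.prediction
    if p.enabled:
        if not (0.0 < p.vp_fraction < 1.0):
            issues.append(f"prediction.vp_fraction must be in (0, 1): {p.vp_fraction}")
        if p.n_reps < 1:
            issues.append("prediction.n_reps must be >= 1")
        if p.kinship not in ("shrunk", "vanraden"):
            issues.append(f"prediction.kinship unknown: {p.kinship}")
        if p.seed is None:
            issues.append("prediction.seed is required (stochastic stage)")
    e = config.experiments
    if (e.density or e.relatedness or e.size_modes) and e.seed is None:
        issues.append("experiments.seed is required (stochastic stage)")
    for mode in e.size_modes:
        if mode not in ("absolute", "fixed_vp", "fixed_total"):
            issues.append(f"experiments.size_modes unknown mode: {mode}")
    return issues
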