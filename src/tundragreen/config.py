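"""Run configuration: defaults, YAML loading, and schema validation.

Defaults follow the analysis constants used throughout the package:
spar in [0.68, 0.72], 1000 Monte-Carlo draws, alpha 0.10 (0.05 also
reported), 17-year phenology windows, barren threshold 0.10, 10-year
minimum record, |r| > 0.75 predictor screening, 2/3 training split,
90% year subsampling, and per-sensor reflectance bounds of 7/5/3%.
All schema violations are collected and reported at once.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields

import yaml

__all__ = ["GeneratorConfig", "AnalysisConfig", "RunConfig", "load_config",
           "ConfigError"]


class ConfigError(ValueError):
    """Raised with every schema violation enumerated."""


@dataclass
class GeneratorConfig:
    n_sites: int = 300
    year_start: int = 1985
    year_end: int = 2016
    frac_greening: float = 0.37
    frac_browning: float = 0.05
    frac_barren: float = 0.05
    noise_sd: float = 0.02
    interannual_sd: float = 0.01
    n_temperature_datasets: int = 5
    temperature_cells: int = 10
    warming_rate: float = 1.5625      # degC SWI per decade (5.0 degC over 32 yr)
    n_predictors: int = 20
    field_coupling: float = 0.5


@dataclass
class AnalysisConfig:
    spar_low: float = 0.68
    spar_high: float = 0.72
    n_sims: int = 1000
    alpha: float = 0.10
    window_years: int = 17
    min_obs: int = 10
    min_doy_span: float = 30.0
    barren_threshold: float = 0.10
    min_record_years: int = 10
    corr_threshold: float = 0.75
    train_fraction: float = 2.0 / 3.0
    subsample_fraction: float = 0.9
    reference_sensor: str = "L7"
    prewhiten: str = "yuepilon"       # "yuepilon", "zhang", or "" (plain MK)
    calibrate: bool = True
    rf_trees: int = 500
    swi_per_year_choice: bool = False


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/latest"
    stages: tuple = ("simulate", "calibrate", "ndvimax", "run-ensemble",
                     "trends", "correlate", "drivers", "validate", "report")
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self):
        errs = []
        g, a = self.generator, self.analysis
        if g.n_sites < 1:
            errs.append(f"generator.n_sites must be >= 1, got {g.n_sites}")
        if g.year_end < g.year_start:
            errs.append("generator.year_end must be >= generator.year_start")
        for name in ("frac_greening", "frac_browning", "frac_barren"):
            v = getattr(g, name)
            if not 0 <= v <= 1:
                errs.append(f"generator.{name} must be in [0, 1], got {v}")
        if g.frac_greening + g.frac_browning > 1:
            errs.append("generator.frac_greening + frac_browning must be <= 1")
        if not -1 <= g.field_coupling <= 1:
            errs.append(f"generator.field_coupling must be in [-1, 1], got {g.field_coupling}")
        if not 0 < a.spar_low <= a.spar_high:
            errs.append("analysis.spar bounds must satisfy 0 < spar_low <= spar_high")
        if a.n_sims < 2:
            errs.append(f"analysis.n_sims must be >= 2, got {a.n_sims}")
        if not 0 < a.alpha < 1:
            errs.append(f"analysis.alpha must be in (0, 1), got {a.alpha}")
        if a.window_years < 1:
            errs.append(f"analysis.window_years must be >= 1, got {a.window_years}")
        if not 0 < a.train_fraction < 1:
            errs.append("analysis.train_fraction must be in (0, 1)")
        if not 0 < a.subsample_fraction <= 1:
            errs.append("analysis.subsample_fraction must be in (0, 1]")
        if a.prewhiten not in ("", "yuepilon", "zhang"):
            errs.append(f"analysis.prewhiten must be '', 'yuepilon', or 'zhang', "
                        f"got {a.prewhiten!r}")
        if errs:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errs))
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _build(cls, data: dict, prefix: str, errs: list):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        errs.append(f"unknown key {prefix}{key}")
    return cls(**{k: v for k, v in data.items() if k in known})


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML (nested sections: generator, analysis)."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = {**data, **overrides}
    errs = []
    gen = _build(GeneratorConfig, data.pop("generator", {}) or {}, "generator.", errs)
    ana = _build(AnalysisConfig, data.pop("analysis", {}) or {}, "analysis.", errs)
    top = {k: v for k, v in data.items()}
    if "stages" in top:
        top["stages"] = tuple(top["stages"])
    known = {f.name for f in fields(RunConfig)}
    for key in sorted(set(top) - known):
        errs.append(f"unknown key {key}")
    cfg = RunConfig(**{k: v for k, v in top.items() if k in known},
                    generator=gen, analysis=ana)
    if errs:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errs))
    return cfg.validate()
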