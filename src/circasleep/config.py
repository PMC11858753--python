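"""Run configuration: a single structured file with CLI overrides.

Precedence is flags > file > defaults. Every result file written by the
CLI embeds the resolved config, so any output is regenerable from its
own echo plus the seed.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class NpcraConfig(BaseModel):
    bins_per_day: int = 24
    min_nights: int = 6
    allow_short: bool = False
    max_missing_fraction: float = 0.2
    missing_policy: str = "error"


class McmcSettings(BaseModel):
    n_chains: int = 4
    n_walkers: int = 32
    n_warmup: int = 1200
    n_keep: int = 400
    seed: int = 0


class PriorOverrides(BaseModel):
    intercept_mean: float | None = None
    intercept_sd: float | None = None
    slope_scale: float | None = None
    group_sd_scale: float | None = None
    resid_sd_scale: float | None = None


class MoranConfig(BaseModel):
    weight_scheme: str = "inverse_distance"
    n_permutations: int = 9999
    min_distance_km: float = 1.0


class RunConfig(BaseModel):
    """Top-level run configuration for the CLI."""

    npcra: NpcraConfig = Field(default_factory=NpcraConfig)
    mcmc: McmcSettings = Field(default_factory=McmcSettings)
    priors: PriorOverrides = Field(default_factory=PriorOverrides)
    moran: MoranConfig = Field(default_factory=MoranConfig)
    preset: str = "industrial"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        cfg = cls.model_validate(data)
        if overrides:
            merged = cfg.model_dump()
            for key, value in overrides.items():
                if value is None:
                    continue
                section, _, leaf = key.partition(".")
                if leaf:
                    merged[section][leaf] = value
                else:
                    merged[section] = value
            cfg = cls.model_validate(merged)
        return cfg

    def echo(self) -> dict:
        return self.model_dump()
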