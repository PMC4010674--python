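"""Run configuration: schema-validated settings for reproducible runs.

A single YAML document drives every command; unknown keys are rejected, and
the fully resolved configuration (including the connection-amplitude prior
table, whose published source is ambiguous) is archived next to every run's
outputs so any artefact can be regenerated from config + seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .core import SpectralGrid
from .priors import ALPHA_PRIOR_MEANS, PriorSet, default_priors

__all__ = ["RunConfig", "load_config", "archive_config"]


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    f_min: float = 4.0
    f_max: float = 90.0
    n_freqs: int = 24
    n_modes: int = 32


class InversionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_iter: int = 64
    f_tol: float = 0.01
    tol_hits: int = 4
    lam_var: float = 1.0 / 16.0
    free: list[str] | None = None  # None: every free-by-default parameter


class PriorOverride(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mean: float | None = None
    logvar: float | None = None
    free: bool | None = None


class RunConfig(BaseModel):
    """Top-level configuration for simulate / fit / compare / maps."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    output_dir: str = "runs"
    grid: GridConfig = Field(default_factory=GridConfig)
    inversion: InversionConfig = Field(default_factory=InversionConfig)
    contrast_coding: str = "linear"
    n_epochs: int = 256
    model: int = 7
    mass: bool = False
    alpha_means: dict[str, float] | None = None
    prior_overrides: dict[str, PriorOverride] = Field(default_factory=dict)

    @field_validator("contrast_coding")
    @classmethod
    def _coding(cls, v):
        if v not in ("linear", "log"):
            raise ValueError("contrast_coding must be 'linear' or 'log'")
        return v

    @field_validator("model")
    @classmethod
    def _model(cls, v):
        if not 1 <= v <= 8:
            raise ValueError("model must be an id in 1..8")
        return v

    def spectral_grid(self) -> SpectralGrid:
        g = self.grid
        return SpectralGrid.default(
            freqs=np.linspace(g.f_min, g.f_max, g.n_freqs), n_modes=g.n_modes
        )

    def priors(self) -> PriorSet:
        pr = default_priors(alpha_means=self.alpha_means)
        for name, ov in self.prior_overrides.items():
            if name not in pr:
                raise KeyError(f"prior override for unknown parameter {name!r}")
            p = pr[name]
            if ov.mean is not None:
                p.mean = ov.mean
            if ov.logvar is not None:
                p.logvar = ov.logvar
            if ov.free is not None:
                p.free = ov.free
        return pr


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig(**raw)


def archive_config(cfg: RunConfig, out_dir: Path) -> Path:
    """Write the fully resolved configuration (and the alpha table) to disk."""
    out_dir.mkdir(parents=True, exist_ok=True)
    resolved = cfg.model_dump()
    resolved["resolved_alpha_prior_means"] = dict(
        cfg.alpha_means or ALPHA_PRIOR_MEANS
    )
    path = out_dir / "config.resolved.json"
    path.write_text(json.dumps(resolved, indent=2, sort_keys=True))
    return path
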