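"""Experiment configuration: schema, YAML/JSON loading, hashing.

Configs round-trip losslessly and unknown keys are rejected, so a run is
fully reproducible from the logged config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .params import LigandParams, ModelKind, ReceptorConfig
from .population import PopulationSpec

__all__ = ["ExperimentConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LigandConfig(_Strict):
    name: Optional[str] = None
    concentration: float
    partial_affinity: float
    full_affinity: float = 1.0
    activity_rate: float = 1.0

    def to_params(self) -> LigandParams:
        return LigandParams(
            concentration=self.concentration,
            partial_affinity=self.partial_affinity,
            full_affinity=self.full_affinity,
            activity_rate=self.activity_rate,
            name=self.name,
        )


class ReceptorsConfig(_Strict):
    a_total: float = 1.0
    b_total: Optional[float] = None

    def to_config(self) -> ReceptorConfig:
        return ReceptorConfig(a_total=self.a_total, b_total=self.b_total)


class PopulationConfig(_Strict):
    n_cells: int = 100_000
    mean_a: float = 1.0
    sd_a: float = 0.5
    mean_b: Optional[float] = None
    sd_b: Optional[float] = None
    correlation: float = 0.0

    def to_spec(self, seed: int) -> PopulationSpec:
        return PopulationSpec(
            n_cells=self.n_cells,
            mean_a=self.mean_a,
            sd_a=self.sd_a,
            mean_b=self.mean_b,
            sd_b=self.sd_b,
            seed=seed,
            correlation=self.correlation,
        )


class GridAxis(_Strict):
    start: float = 1e-4
    stop: float = 1e4
    num: int = 41

    def points(self):
        import numpy as np

        if self.num < 1 or self.start <= 0 or self.stop <= 0:
            raise ConfigError("grid axes need positive bounds and num >= 1")
        return np.logspace(np.log10(self.start), np.log10(self.stop), self.num)


class ScanConfig(_Strict):
    kp_c: GridAxis = Field(default_factory=GridAxis)
    kf_a0: GridAxis = Field(default_factory=GridAxis)
    ratios: Optional[List[float]] = None
    exponent: float = 1.0


class ExperimentConfig(_Strict):
    """Top-level experiment description (YAML or JSON)."""

    model: ModelKind = ModelKind.ALA
    seed: int = 0
    target_mean: float = 1.0
    exponent: float = 1.0
    ligands: List[LigandConfig] = Field(default_factory=list)
    inhibitor: Optional[LigandConfig] = None
    receptors: ReceptorsConfig = Field(default_factory=ReceptorsConfig)
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    scan: ScanConfig = Field(default_factory=ScanConfig)

    @field_validator("model", mode="before")
    @classmethod
    def _coerce_model(cls, v):
        if isinstance(v, str):
            try:
                return ModelKind(v.upper())
            except ValueError as exc:
                raise ValueError(
                    f"unknown model {v!r}; choose from "
                    + ", ".join(m.value for m in ModelKind)
                ) from exc
        return v

    def ligand_params(self) -> List[LigandParams]:
        return [lig.to_params() for lig in self.ligands]

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:12]


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML or JSON experiment config."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return ExperimentConfig.model_validate(doc)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigError(f"{path}: {exc}") from exc
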