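"""Pipeline configuration: schema-validated blocks for every stage.

Unknown keys are rejected so a typo in a config file fails loudly rather
than silently running defaults.  The fully serialized config (plus its
hash) is stamped into every output's provenance header.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["PipelineConfig", "load_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScenarioBlock(_Block):
    name: str = "binding_landscape"
    seed: int = 0
    n_trajs: int = 20
    n_steps: int = 2000
    params: dict = Field(default_factory=dict)
    adaptive: bool = False
    n_rounds: int = 5
    trajs_per_round: int = 4
    adaptive_clusters: int = 8
    input_path: str | None = None  # load instead of simulate


class FeaturizationBlock(_Block):
    tica_lag: int = 5
    variance_fraction: float = 0.95
    k: int = 30
    kmeans_seed: int = 0

    @field_validator("variance_fraction")
    @classmethod
    def _vf(cls, v):
        if not 0 < v <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")
        return v


class MsmBlock(_Block):
    lag: int = 5
    mode: str = "sliding"
    temperature: float = 300.0

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("sliding", "strided"):
            raise ValueError("mode must be 'sliding' or 'strided'")
        return v


class MacrostateRegion(_Block):
    name: str
    feature: str
    min: float = float("-inf")
    max: float = float("inf")


class KineticsBlock(_Block):
    macrostates: list[MacrostateRegion] = Field(default_factory=list)
    n_top: int = 5
    tpt_pairs: list[tuple[str, str]] = Field(default_factory=list)
    kmc_steps: int = 0
    kmc_start_macrostate: str | None = None


class CompareBlock(_Block):
    enabled: bool = False
    n_residues: int = 12
    path_spec: list[int] = Field(default_factory=lambda: [0, 3, 5, 8, 11])
    coupling_strength: float = 0.85
    n_frames: int = 5000
    kl_bins: int = 30
    mi_bins: int = 24
    distance_cutoff: float = 6.0
    mi_null_shuffles: int = 20


class BootstrapBlock(_Block):
    enabled: bool = False
    n_rounds: int = 200
    fraction: float = 0.8
    mode: str = "resample"
    statistic: str = "stationary_distribution"


class PipelineConfig(_Block):
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    featurization: FeaturizationBlock = Field(default_factory=FeaturizationBlock)
    msm: MsmBlock = Field(default_factory=MsmBlock)
    kinetics: KineticsBlock = Field(default_factory=KineticsBlock)
    compare: CompareBlock = Field(default_factory=CompareBlock)
    bootstrap: BootstrapBlock = Field(default_factory=BootstrapBlock)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config": self.model_dump(), "config_hash": self.config_hash()}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML/JSON config file (defaults when path is None) and apply
    nested-dict overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    for key, val in (overrides or {}).items():
        node = data
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = val
    return PipelineConfig.model_validate(data)
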