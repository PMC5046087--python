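"""Pipeline configuration: every stage parameter with its default, YAML
round-trip, and a provenance hash embedded in each artifact's report."""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field


def package_version() -> str:
    try:
        return version("cemsnorm")
    except PackageNotFoundError:
        return "unknown"


class PipelineConfig(BaseModel):
    """All stage parameters; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # reference building
    ref_mt_lo: float = 520.0
    ref_mt_hi: float = 3650.0
    ref_min_presence: float = Field(0.5, gt=0, le=1)
    mz_group_tol: float = Field(0.01, gt=0)
    mt_group_tol: float = Field(20.0, gt=0)
    # stable selection
    stable_method: str = "hyperline"
    n_candidates: int = Field(1000, ge=10)
    start_size: int = Field(10, ge=2)
    # new-sample processing
    new_mt_lo: float = 840.0
    new_mt_hi: float = 3000.0
    mass_tol: float = Field(0.01, gt=0)
    mt_gate: Optional[float] = 60.0
    alignment_iterations: int = Field(5, ge=1)
    loess_span: float = Field(0.75, gt=0, le=1)
    # statistics
    group_min_presence: float = Field(0.75, gt=0, le=1)
    bh_alpha: float = Field(0.05, gt=0, lt=1)
    svm_c: float = Field(1.0, gt=0)
    svm_gamma: float = Field(0.03125, gt=0)
    # randomness
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config": self.model_dump(),
                "config_hash": self.config_hash(),
                "package_version": package_version()}

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(),
                                             sort_keys=True))
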