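"""Run configuration: YAML in, validated model out, provenance hash.

Defaults equal the analysis constants used throughout the package: 3/10 mm
band thresholds, 4/8 mm penumbra radii (cumulative), 26-connectivity,
10 mm^3 lesion floor, 10% growth threshold, and the consensus PASL
quantification constants.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator


class ASLConstants(BaseModel):
    t1_blood_ms: float = 1650.0
    label_efficiency: float = 0.98
    partition_coefficient: float = 0.9
    ti_ms: float = 1800.0
    ti1_ms: float = 1650.0


class ModelOptions(BaseModel):
    correction: str = "bh"  # bh | holm | bonferroni
    tissue_ref: str = "NAWM"
    location_ref: str = "JV"
    volume_location_ref: str = "D"


class RunConfig(BaseModel):
    cohort_dir: str = "scratch/cohort"
    results_dir: str = "results"
    band_thresholds_mm: tuple[float, float] = (3.0, 10.0)
    penumbra_radii_mm: tuple[float, float] = (4.0, 8.0)
    penumbra_mode: str = "cumulative"
    connectivity: int = 26
    min_lesion_volume_mm3: float = 10.0
    growth_threshold: float = 0.10
    asl: ASLConstants = Field(default_factory=ASLConstants)
    models: ModelOptions = Field(default_factory=ModelOptions)
    n_subjects: int = 20
    n_longitudinal: int = 10
    grid_shape: tuple[int, int, int] = (96, 96, 48)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    voxel_noise_cv: float = 0.05
    seed: int = 0

    @field_validator("band_thresholds_mm", "penumbra_radii_mm")
    @classmethod
    def _increasing_positive(cls, v):
        if not (0 < v[0] < v[1]):
            raise ValueError(f"thresholds must be positive and increasing, got {v}")
        return v

    @field_validator("connectivity")
    @classmethod
    def _connectivity(cls, v):
        if v not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {v}")
        return v

    @field_validator("min_lesion_volume_mm3", "growth_threshold")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError(f"threshold must be positive, got {v}")
        return v

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed, "package": "wmhperf"}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
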