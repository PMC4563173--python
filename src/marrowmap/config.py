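"""Validated pipeline configuration covering every tunable."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class PipelineConfig(BaseModel):
    """All tunables of the quantification pipeline, schema-validated.

    Defaults mirror the reference protocol: equal class priors, a 2.5-SD
    vertebral threshold, 26-connectivity islanding, and 50 LOOCV repetitions
    of 1000 training samples.
    """

    model_config = ConfigDict(extra="forbid")

    hu_threshold: float = Field(100.0, ge=-1024.0, le=3071.0,
                                description="bone-extraction HU threshold")
    closing_radius_mm: float = Field(3.0, ge=0.0,
                                     description="morphological closing radius, mm")
    min_island: int = Field(10, ge=1, description="minimum trabecular island size P, voxels")
    connectivity: Literal[6, 18, 26] = Field(26, description="3-D neighbourhood definition")
    k: float = Field(2.5, gt=0.0, description="threshold multiplier: mean - k*SD")
    prior: float = Field(0.5, gt=0.0, lt=1.0, description="cortical class prior")
    training_size: int = Field(1000, ge=4, description="labelled voxels per training set")
    loocv_repetitions: int = Field(50, ge=1, description="LOOCV repetitions")
    seed: int = Field(17, ge=0, description="master random seed")
    decay_correct: bool = Field(True, description="decay-correct injected activity to scan time")
    exclude_skull: bool = Field(False, description="omit the skull ROI from quantification")
    resample: Literal["pet_to_ct"] = Field(
        "pet_to_ct", description="resampling direction; masks live on the CT grid"
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)
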