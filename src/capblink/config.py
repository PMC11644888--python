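"""Pipeline configuration: validated JSON blocks and deterministic seeding.

All defaults match the published operating point of the method: passband
[2.0, 5.5] Hz, filter order 128, detection threshold 4.0, 40 s windows with
2 s step, 80/20 train/test split, >= 1500 training iterations.

A single global seed fans out into independent per-stage integer sub-seeds
through ``numpy.random.SeedSequence`` so that re-ordering or skipping stages
never silently shifts another stage's random stream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .capacitance import ELECTROSTATIC_K

__all__ = ["PipelineConfig", "load_config", "stage_seed"]

#: Stage names with a reserved sub-seed slot, in fixed order.
_STAGES = ("synth", "noise", "dataset", "split", "train")


class CapacitanceConfig(BaseModel):
    L: float = 18e-6
    C: float = 33e-12
    eps: tuple[float, float, float] = (1.0, 100.0, 100.0)
    d: tuple[float, float, float] = (5e-3, 1e-3, 50e-3)
    S: float = 25e-3 * 8e-3
    k: float = ELECTROSTATIC_K


class SynthConfig(BaseModel):
    fs: float = Field(default=100.0, ge=20.0)
    duration: float = Field(default=40.0, gt=0)
    onsets: list[float] = Field(
        default_factory=lambda: [2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0, 34.0, 38.0]
    )
    closing: float = Field(default=0.15, gt=0)
    hold: float = Field(default=0.08, gt=0)
    opening: float = Field(default=0.25, gt=0)
    noise_preset: str = "bench"


class InterpConfig(BaseModel):
    T: float = Field(default=0.01, gt=0)
    sigma: float | None = None
    half_width: float = Field(default=3.0, gt=0)
    unnormalized: bool = False


class FilterConfig(BaseModel):
    order: int = Field(default=128, ge=2)
    band: tuple[float, float] = (2.0, 5.5)

    @model_validator(mode="after")
    def _check_band(self) -> "FilterConfig":
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"need 0 < low < high, got {self.band}")
        return self


class DetectorBlock(BaseModel):
    threshold: float = Field(default=4.0, gt=0)
    min_exceed_duration: float = Field(default=0.05, ge=0)
    refractory: float = Field(default=0.45, ge=0)
    scale_window: float = Field(default=10.0, gt=0)
    raw_units: bool = False


class WindowConfig(BaseModel):
    length: float = Field(default=40.0, gt=0)
    step: float = Field(default=2.0, gt=0)


class TrainBlock(BaseModel):
    iterations: int = Field(default=2000, ge=1)
    learning_rate: float = Field(default=0.5, gt=0)
    train_fraction: float = Field(default=0.8, gt=0, lt=1)
    dataset_size: int = Field(default=2000, ge=10)
    noise_sd: float = Field(default=1.5, ge=0)


class PipelineConfig(BaseModel):
    """Validated nested configuration for the full pipeline."""

    capacitance: CapacitanceConfig = Field(default_factory=CapacitanceConfig)
    synth: SynthConfig = Field(default_factory=SynthConfig)
    interp: InterpConfig = Field(default_factory=InterpConfig)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    detector: DetectorBlock = Field(default_factory=DetectorBlock)
    window: WindowConfig = Field(default_factory=WindowConfig)
    train: TrainBlock = Field(default_factory=TrainBlock)
    seed: int = 0


def load_config(path: "str | Path | None") -> PipelineConfig:
    """Load and validate a JSON config file; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    payload = json.loads(Path(path).read_text())
    return PipelineConfig.model_validate(payload)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) derived from the global seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; known: {_STAGES}")
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGES))
    state = children[_STAGES.index(stage)].generate_state(1)[0]
    return int(state % (2**31))
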