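"""Run configuration: one validated document covering every tunable default.

Unknown keys are rejected so a typo in a YAML file fails loudly, and every
report embeds the resolved configuration for auditability.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PeakConfig(_Strict):
    min_separation: int = Field(5, ge=1)
    min_prominence: float = Field(0.3, ge=0.0)
    smooth_window: int = Field(3, ge=1)
    # learned mode only: exclude this many frames at each end of a predicted
    # curve from keyframe candidacy.  0 is safe when the phase regressor is
    # trained with extrapolated targets (its edges stay monotone); raise it
    # if edge transients fabricate keyframes
    edge_guard: int = Field(0, ge=0)


class DepthConfig(_Strict):
    lo: float = 0.5
    hi: float = 0.75
    h2_mode: Literal["union", "max_single"] = "union"


class CaaConfig(_Strict):
    lo: float = 75.0
    hi: float = 95.0


class DetectionConfig(_Strict):
    conf_thresh: float = Field(0.25, ge=0.0, le=1.0)
    nms_iou: float = Field(0.5, gt=0.0, le=1.0)
    csl_window_radius: int = Field(6, ge=0)
    csl_bins: int = 180


class ModelConfig(_Strict):
    image_size: int = 128
    segment_length: int = Field(60, ge=3)
    backbone_channels: tuple[int, int, int] = (10, 20, 24)
    rnn_hidden: int = 24
    rnn_layers: int = 2
    detector_epochs: int = 12
    phase_epochs: int = 30
    gain_epochs: int = 40
    # supervise frames outside the labeled span with the periodic
    # continuation of the volume curve (exact for phantom labels; disable
    # for annotations where periodicity is uncertain)
    extrapolate_phase_targets: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 4


class RunConfig(_Strict):
    seed: int = 0
    peaks: PeakConfig = PeakConfig()
    depth: DepthConfig = DepthConfig()
    caa: CaaConfig = CaaConfig()
    detection: DetectionConfig = DetectionConfig()
    model: ModelConfig = ModelConfig()
    aggregation: Literal["max", "min", "first"] = "max"

    def echo(self) -> dict:
        """Flat dict embedded into reports."""
        return self.model_dump(mode="json")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return RunConfig(**data)
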