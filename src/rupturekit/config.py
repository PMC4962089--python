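"""Validated pipeline configuration (YAML-backed, schema-checked).

Every stage parameter lives here with its canonical default: dH/N threshold
1.2, minimum track duration 60 min, temporal-smoothing cap 10 min,
fast/slow halftime boundary 30 min, 2-min frame interval. Unknown keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .segment import MAX_SIGMA_T_MIN

__all__ = ["PipelineConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class RuptureScriptConfig(_Strict):
    nucleus_id: int
    onset_frame: int
    drop_fraction: float = Field(gt=0, lt=1)
    recovery_tau: float = Field(gt=0)
    contraction_fraction: float = Field(default=0.0, ge=0, lt=1)
    h2b_focal_gain: float = Field(default=1.0, ge=1)


class SimulateConfig(_Strict):
    n_nuclei: int = Field(default=10, ge=1)
    frame_count: int = Field(default=150, ge=2)
    frame_interval: float = Field(default=2.0, gt=0)
    image_size: tuple[int, int] = (256, 256)
    nucleus_radius_range: tuple[float, float] = (10.0, 16.0)
    motion_step_sd: float = Field(default=2.0, ge=0)
    deformation_amplitude: float = Field(default=0.0, ge=0)
    expression_cv: float = Field(default=0.2, ge=0)
    signal_level: float = Field(default=1000.0, gt=0)
    background_level: float = Field(default=100.0, ge=0)
    noise_gaussian_sd: float = Field(default=100.0, ge=0)
    noise_poisson: bool = False
    rupture_script: list[RuptureScriptConfig] = Field(default_factory=list)


class SegmentConfig(_Strict):
    channel: str = "reference"
    log_sigma: float = Field(default=8.0, gt=0)
    min_area: int = Field(default=120, ge=1)
    max_area: int | None = None
    sigma_xy: float = Field(default=1.5, ge=0)
    sigma_t_min: float = Field(default=0.0, ge=0)
    clahe_clip: float = Field(default=0.01, ge=0)
    peak_snr: float = Field(default=5.0, ge=0)
    watershed_enabled: bool = True

    @field_validator("sigma_t_min")
    @classmethod
    def _cap_sigma_t(cls, v: float) -> float:
        if v > MAX_SIGMA_T_MIN:
            raise ValueError(
                f"sigma_t_min={v} min exceeds the {MAX_SIGMA_T_MIN}-min cap "
                "on temporal smoothing"
            )
        return v


class TrackConfig(_Strict):
    max_displacement: float = Field(default=40.0, gt=0)
    max_gap: int = Field(default=5, ge=0)
    min_duration: float = Field(default=60.0, ge=0)  # minutes, strict '<'


class AnalysisConfig(_Strict):
    threshold: float = Field(default=1.2, gt=1)
    baseline_window: int = Field(default=5, ge=2)
    completeness_level: float = Field(default=0.95, gt=0, le=1)
    fast_slow_boundary_min: float = Field(default=30.0, gt=0)
    pre_frames: int = Field(default=5, ge=1)
    post_frames: int = Field(default=60, ge=1)
    detection_sigma_t: float = Field(default=0.0, ge=0)


class StatsConfig(_Strict):
    n_boot: int = Field(default=2000, ge=10)
    n_starts: int = Field(default=10, ge=1)
    min_halftimes: int = Field(default=10, ge=10)


class PipelineConfig(_Strict):
    """Full end-to-end configuration; see section models for the knobs."""

    input_path: str | None = None  # TIFF stack; exclusive with simulate
    single_marker: bool = False  # NLS-only mode: mandatory temporal smoothing
    seed: int = 0
    simulate: SimulateConfig | None = None
    segmentation: SegmentConfig = Field(default_factory=SegmentConfig)
    tracking: TrackConfig = Field(default_factory=TrackConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    def validate_ready(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of input_path or simulate must be configured"
            )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(payload)


def dump_config(config: PipelineConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(
        config.model_dump(mode="json"), sort_keys=True, default_flow_style=False
    )
    if path is not None:
        Path(path).write_text(text)
    return text
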