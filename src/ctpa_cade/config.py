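"""Run configuration: every tunable of the segmentation chain as a named,
range-checked key with its default.

All geometric defaults follow adult thoracic anatomy at typical CTPA
acquisition settings (2.0 mm axial slices, ~0.7 mm pixels). Unknown keys are
rejected at load time so that config files cannot silently misspell a key.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=False)


class IOConfig(_Section):
    target_slice_thickness_mm: float = 2.0
    orientation_tolerance_deg: float = 5.0

    @model_validator(mode="after")
    def _check(self) -> "IOConfig":
        if self.target_slice_thickness_mm <= 0:
            raise ValueError("target_slice_thickness_mm must be positive")
        if not (0 < self.orientation_tolerance_deg <= 45):
            raise ValueError("orientation_tolerance_deg must be in (0, 45]")
        return self


class PreprocessConfig(_Section):
    enabled: bool = True
    max_angle_deg: float = 25.0
    min_angle_deg: float = 1.0
    body_threshold_hu: float = -500.0

    @model_validator(mode="after")
    def _check(self) -> "PreprocessConfig":
        if not (0 < self.max_angle_deg <= 45):
            raise ValueError("max_angle_deg must be in (0, 45]")
        return self


class AirwayConfig(_Section):
    air_threshold_hu: float = -800.0
    diameter_range_mm: Tuple[float, float] = (8.0, 30.0)
    volume_range_cm3: Tuple[float, float] = (2.0, 60.0)
    carina_gap_mm: float = 7.5
    max_caudal_search_mm: float = 40.0
    gap_metric: Literal["edge", "centroid"] = "edge"
    voi_fractions: Tuple[float, float] = (0.15, 0.35)
    join_max_shift_mm: float = 10.0

    @model_validator(mode="after")
    def _check(self) -> "AirwayConfig":
        for lo, hi in (self.diameter_range_mm, self.volume_range_cm3):
            if not (0 < lo < hi):
                raise ValueError("ranges must satisfy 0 < lo < hi")
        if self.carina_gap_mm <= 0:
            raise ValueError("carina_gap_mm must be positive")
        f0, f1 = self.voi_fractions
        if not (0 < f0 < f1 <= 1):
            raise ValueError("voi_fractions must satisfy 0 < f0 < f1 <= 1")
        return self


class VesselConfig(_Section):
    hu_range: Tuple[float, float] = (150.0, 1200.0)
    region_tolerance_hu: float = 100.0
    max_region_area_mm2: float = 4000.0
    smoothing_sigma_px: float = 1.0
    edge_percentiles: Tuple[float, float] = (70.0, 90.0)
    pt_hough_radius_range_mm: Tuple[float, float] = (8.0, 20.0)
    dao_circularity_floor: float = 0.7
    aao_circularity_floor: float = 0.8
    pv_circularity_floor: float = 0.85

    @model_validator(mode="after")
    def _check(self) -> "VesselConfig":
        lo, hi = self.hu_range
        if lo >= hi:
            raise ValueError("hu_range lo must be < hi")
        if self.region_tolerance_hu <= 0:
            raise ValueError("region_tolerance_hu must be positive")
        rlo, rhi = self.pt_hough_radius_range_mm
        if not (0 < rlo < rhi):
            raise ValueError("pt_hough_radius_range_mm must satisfy 0 < lo < hi")
        for f in (self.dao_circularity_floor, self.aao_circularity_floor,
                  self.pv_circularity_floor):
            if not (0 <= f <= 1):
                raise ValueError("circularity floors must be in [0, 1]")
        return self


class PipelineConfig(_Section):
    ray_fan_deg: float = 45.0
    ray_step_deg: float = 5.0
    ray_length_mm: float = 50.0
    ray_min_connected_mm: float = 10.0
    refine_fan_deg: float = 10.0
    refine_step_deg: float = 2.0
    dao_track_mm: float = 30.0
    dao_area_band: Tuple[float, float] = (0.5, 1.5)
    arch_area_factor: float = 1.8
    arch_circularity_floor: float = 0.6
    arch_search_mm: float = 80.0
    aao_search_mm: float = 30.0
    pt_search_mm: float = 20.0
    pt_box_mm: Tuple[float, float] = (40.0, 40.0)
    pt_track_mm: float = 50.0
    pv_transition: Literal["rising", "falling"] = "rising"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if not (0 < self.ray_fan_deg <= 90):
            raise ValueError("ray_fan_deg must be in (0, 90]")
        if self.ray_length_mm <= 0 or self.ray_min_connected_mm <= 0:
            raise ValueError("ray lengths must be positive")
        lo, hi = self.dao_area_band
        if not (0 < lo < 1 < hi):
            raise ValueError("dao_area_band must bracket 1.0")
        if self.arch_area_factor <= 1:
            raise ValueError("arch_area_factor must exceed 1")
        return self


class MeasureConfig(_Section):
    noise_roi_cm2: float = 1.0
    contrast_roi_cm2: float = 2.0
    measurement_slice: Literal["pt_optimal", "carina"] = "pt_optimal"
    low_contrast_hu: float = 200.0

    @model_validator(mode="after")
    def _check(self) -> "MeasureConfig":
        if self.noise_roi_cm2 <= 0 or self.contrast_roi_cm2 <= 0:
            raise ValueError("ROI areas must be positive")
        return self


class EvalConfig(_Section):
    bf_tolerance_vox: float = 2.0

    @model_validator(mode="after")
    def _check(self) -> "EvalConfig":
        if self.bf_tolerance_vox <= 0:
            raise ValueError("bf_tolerance_vox must be positive")
        return self


class RunConfig(_Section):
    """Top-level configuration for the whole chain."""

    io: IOConfig = IOConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    airway: AirwayConfig = AirwayConfig()
    vessel: VesselConfig = VesselConfig()
    pipeline: PipelineConfig = PipelineConfig()
    measure: MeasureConfig = MeasureConfig()
    evalmetrics: EvalConfig = EvalConfig()
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a YAML or JSON file; unknown keys are rejected."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        return cls.model_validate(data)
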