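"""Report quantities computed from the segmentations.

Image noise (SD of HU in a 1 cm² circular ROI in the descending aorta),
intravenous contrast level (mean HU in a 2 cm² circular ROI in the
pulmonary trunk), vessel diameters, and the exam quality classification
from component scores (good 0–3, acceptable 4–7, inferior ≥ 8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import ndimage

from ctpa_cade.volume_io import CTVolume

QUALITY_CLASSES = ("good", "acceptable", "inferior")


@dataclass
class MeasurementReport:
    """Per-exam measurements with per-compartment detection accounting.

    Every measurement is ``None`` exactly when its prerequisite compartment
    was not detected (soft failure)."""

    noise_sd_hu: Optional[float] = None
    pt_contrast_mean_hu: Optional[float] = None
    aao_diameter_mm: Optional[float] = None
    pt_diameter_mm: Optional[float] = None
    detection_flags: Dict[str, bool] = field(default_factory=dict)
    failure_stages: Dict[str, str] = field(default_factory=dict)
    quality_class: Optional[str] = None
    low_contrast: Optional[bool] = None


def circular_roi(center: Tuple[float, float], area_cm2: float,
                 spacing: Tuple[float, float],
                 shape: Tuple[int, int]) -> np.ndarray:
    """Pixel mask of a circular ROI of the given physical area.

    The disc has radius sqrt(area/π) mm around ``center`` (row, col pixels);
    anisotropic pixels are handled so the realized area stays within 5% of
    target. Raises when the circle does not fit inside the image.
    """
    if area_cm2 <= 0:
        raise ValueError("ROI area must be positive")
    radius_mm = math.sqrt(area_cm2 * 100.0 / math.pi)
    r0, c0 = center
    rad_r = radius_mm / spacing[0]
    rad_c = radius_mm / spacing[1]
    if (r0 - rad_r < -0.5 or c0 - rad_c < -0.5
            or r0 + rad_r > shape[0] - 0.5 or c0 + rad_c > shape[1] - 0.5):
        raise ValueError("circular ROI exceeds image bounds")
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    mask = (((rr - r0) * spacing[0]) ** 2
            + ((cc - c0) * spacing[1]) ** 2) <= radius_mm ** 2
    return mask


def _roi_in_region(region_mask: np.ndarray, area_cm2: float,
                   spacing: Tuple[float, float]) -> Optional[np.ndarray]:
    """A circular ROI fully inside a region, or None if it cannot fit.

    First tries the region's mass center; if the disc is not contained, it
    is recentered at the region's inscribed-circle center (the maximum of
    the interior distance transform)."""
    if not region_mask.any():
        return None
    rows, cols = np.nonzero(region_mask)
    radius_mm = math.sqrt(area_cm2 * 100.0 / math.pi)
    for attempt in ("mass_center", "inscribed"):
        if attempt == "mass_center":
            center = (float(rows.mean()), float(cols.mean()))
        else:
            dist = ndimage.distance_transform_edt(region_mask,
                                                  sampling=spacing)
            center = tuple(float(v) for v in
                           np.unravel_index(int(dist.argmax()), dist.shape))
        try:
            roi = circular_roi(center, area_cm2, spacing, region_mask.shape)
        except ValueError:
            continue
        if bool((roi & ~region_mask).sum() == 0):
            return roi
    return None


def measure_noise(vol: CTVolume, dao_mask: np.ndarray,
                  measurement_slice: int, area_cm2: float = 1.0
                  ) -> Optional[float]:
    """SD of HU in a circular ROI at the DAo mass center on one slice.

    Returns None (soft failure) when the DAo is absent at that slice or no
    contained disc can be placed."""
    if not (0 <= measurement_slice < vol.n_slices):
        return None
    region = dao_mask[measurement_slice]
    roi = _roi_in_region(region, area_cm2, vol.in_plane_spacing_mm)
    if roi is None:
        return None
    return float(vol.hu[measurement_slice][roi].std())


def measure_pt_contrast(vol: CTVolume, pt_mask: np.ndarray,
                        measurement_slice: int, area_cm2: float = 2.0
                        ) -> Optional[float]:
    """Mean HU in a circular ROI at the PT mass center on one slice."""
    if not (0 <= measurement_slice < vol.n_slices):
        return None
    region = pt_mask[measurement_slice]
    roi = _roi_in_region(region, area_cm2, vol.in_plane_spacing_mm)
    if roi is None:
        return None
    return float(vol.hu[measurement_slice][roi].mean())


def classify_quality(component_scores: Mapping[str, int]) -> str:
    """Exam quality from summed component scores.

    Total 0–3 → good, 4–7 → acceptable, ≥ 8 → inferior. Scores must be
    non-negative integers (visual sub-scores are inputs, not computed)."""
    total = 0
    for name, score in component_scores.items():
        if int(score) != score or score < 0:
            raise ValueError(f"component score {name}={score!r} must be a "
                             "non-negative integer")
        total += int(score)
    if total <= 3:
        return "good"
    if total <= 7:
        return "acceptable"
    return "inferior"
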