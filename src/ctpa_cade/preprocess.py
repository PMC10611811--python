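"""Orientation normalization of the thorax prior to segmentation.

Patient orientation can vary along the cranio-caudal direction (scoliosis,
movement, positioning). The in-plane rotation of the body is estimated
separately in the cranial and caudal parts of the exam from the principal
axes of the thresholded body mask, and the correction angle is interpolated
linearly along the slice axis. Estimates beyond a validity bound (default
±25°) are considered unreliable: the volume is passed through unrotated
with a warning flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from ctpa_cade.volume_io import CTVolume
from ctpa_cade.config import PreprocessConfig

log = logging.getLogger(__name__)


@dataclass
class AlignmentInfo:
    """In-plane rotation estimates for the cranial and caudal thorax."""

    cranial_angle_deg: float
    caudal_angle_deg: float
    applied: bool = False
    reliable: bool = True


def body_mask_slice(slice_hu: np.ndarray, threshold_hu: float = -500.0
                    ) -> np.ndarray:
    """Largest above-threshold component of a slice, excluding the table.

    Components touching the bottom image edge with width > 80% of the image
    are removed (patient-table heuristic) before the largest remaining
    component is selected.
    """
    fg = slice_hu > threshold_hu
    if not fg.any():
        return np.zeros_like(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        return np.zeros_like(fg)
    bottom = labels[-1]
    for lbl in np.unique(bottom[bottom > 0]):
        cols = np.nonzero(labels == lbl)[1]
        if (cols.max() - cols.min() + 1) > 0.8 * fg.shape[1]:
            labels[labels == lbl] = 0
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    if counts.max() == 0:
        return np.zeros_like(fg)
    # Fill interior holes (lungs, airway) so shape moments reflect the
    # body outline rather than the parenchymal anatomy.
    return ndimage.binary_fill_holes(labels == counts.argmax())


def _symmetry_axis_angle(mask: np.ndarray) -> Optional[float]:
    """Angle (deg) between the body's bilateral symmetry axis and the image
    y-axis (rows); positive = clockwise in display convention.

    The symmetry axis is the principal axis perpendicular to the body's
    elongation (the anteroposterior axis of a thorax wider than deep).
    """
    n = mask.sum()
    if n < 50:
        return None
    rows, cols = np.nonzero(mask)
    r0, c0 = rows.mean(), cols.mean()
    dr, dc = rows - r0, cols - c0
    mu20 = float((dr * dr).mean())
    mu02 = float((dc * dc).mean())
    mu11 = float((dr * dc).mean())
    # Major-axis angle from the column (x) axis, in (-pi/2, pi/2]; the
    # symmetry (minor) axis deviates from the row (y) axis by the same
    # amount. The display-convention sign flips once because row indices
    # grow downward.
    theta = 0.5 * math.atan2(2 * mu11, mu02 - mu20)
    return -math.degrees(theta)


def estimate_body_axis(vol: CTVolume, region: str,
                       config: Optional[PreprocessConfig] = None) -> float:
    """Estimate the body's in-plane rotation in the cranial or caudal thorax.

    ``region`` selects the top or bottom 25% of slices containing body
    foreground. The per-slice symmetry-axis angles are averaged. Raises if
    the region contains no foreground.
    """
    config = config or PreprocessConfig()
    if region not in ("cranial", "caudal"):
        raise ValueError("region must be 'cranial' or 'caudal'")
    has_body = [bool((vol.hu[z] > config.body_threshold_hu).any())
                for z in range(vol.n_slices)]
    body_slices = [z for z, ok in enumerate(has_body) if ok]
    if not body_slices:
        raise ValueError("empty thorax region: no body foreground in volume")
    quarter = max(1, len(body_slices) // 4)
    selected = body_slices[:quarter] if region == "cranial" \
        else body_slices[-quarter:]
    angles = []
    for z in selected:
        mask = body_mask_slice(vol.hu[z], config.body_threshold_hu)
        ang = _symmetry_axis_angle(mask)
        if ang is not None:
            angles.append(ang)
    if not angles:
        raise ValueError(f"empty thorax region: no usable body mask ({region})")
    return float(np.mean(angles))


def estimate_alignment(vol: CTVolume,
                       config: Optional[PreprocessConfig] = None
                       ) -> AlignmentInfo:
    """Estimate cranial and caudal rotation; flag unreliable estimates."""
    config = config or PreprocessConfig()
    cranial = estimate_body_axis(vol, "cranial", config)
    caudal = estimate_body_axis(vol, "caudal", config)
    reliable = (abs(cranial) <= config.max_angle_deg
                and abs(caudal) <= config.max_angle_deg)
    if not reliable:
        log.warning("alignment estimate out of validity bound "
                    "(cranial %.1f°, caudal %.1f°); volume left unrotated",
                    cranial, caudal)
    return AlignmentInfo(cranial_angle_deg=cranial, caudal_angle_deg=caudal,
                         reliable=reliable)


def align_volume(vol: CTVolume, info: AlignmentInfo,
                 min_angle_deg: float = 1.0) -> Tuple[CTVolume, AlignmentInfo]:
    """Rotate each slice by the negated (interpolated) estimated angle.

    The correction angle varies linearly from the cranial to the caudal
    estimate. Bilinear interpolation on HU, background filled with
    −1000 HU. Identity angles return the input unchanged (bit-identical);
    estimates below ``min_angle_deg`` are treated as identity, because
    interpolating a sub-degree rotation would blur the noise texture the
    measurement stage must preserve, for no geometric benefit.
    """
    if not info.reliable:
        return vol, replace(info, applied=False)
    if abs(info.cranial_angle_deg) < min_angle_deg \
            and abs(info.caudal_angle_deg) < min_angle_deg:
        return vol, replace(info, applied=True)
    angles = np.linspace(info.cranial_angle_deg, info.caudal_angle_deg,
                         vol.n_slices)
    out = np.empty_like(vol.hu, dtype=np.float32)
    for z in range(vol.n_slices):
        if angles[z] == 0.0:
            out[z] = vol.hu[z]
        else:
            out[z] = _rotate_slice(vol.hu[z], -angles[z])
    return replace(vol, hu=out), replace(info, applied=True)


def _rotate_slice(slice_hu: np.ndarray, angle_deg: float,
                  order: int = 1) -> np.ndarray:
    """Rotate about the image center; display-clockwise positive angle."""
    a = math.radians(angle_deg)
    ca, sa = math.cos(a), math.sin(a)
    nrows, ncols = slice_hu.shape
    r0, c0 = (nrows - 1) / 2.0, (ncols - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(nrows) - r0, np.arange(ncols) - c0,
                         indexing="ij")
    src_r = ca * rr + sa * cc + r0
    src_c = -sa * rr + ca * cc + c0
    return ndimage.map_coordinates(
        slice_hu.astype(np.float32), [src_r, src_c],
        order=order, cval=-1000.0).astype(np.float32)


def preprocess_volume(vol: CTVolume,
                      config: Optional[PreprocessConfig] = None
                      ) -> Tuple[CTVolume, AlignmentInfo]:
    """Estimate and apply orientation normalization (the full stage)."""
    config = config or PreprocessConfig()
    if not config.enabled:
        return vol, AlignmentInfo(0.0, 0.0, applied=False)
    info = estimate_alignment(vol, config)
    return align_volume(vol, info, config.min_angle_deg)
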