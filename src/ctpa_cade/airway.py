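"""Trachea detection, bifurcation tracking and carina localization.

The trachea is found in the superior thorax by thresholding air, removing
exterior air by border flood fill, and filtering connected components by
tracheal size; it is then tracked slice by slice to the bifurcation where
the left and right main bronchi appear as two distinct segments. The carina
level is the first slice where the bronchus-to-bronchus gap strictly
exceeds 0.75 cm — the anatomical anchor for all vessel detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from ctpa_cade.volume_io import CTVolume
from ctpa_cade.config import AirwayConfig

_STRUCT_2D = np.ones((3, 3), dtype=bool)
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


@dataclass
class AirwayResult:
    """Outcome of the airway stage (soft failures carry detected=False)."""

    trachea_mask: np.ndarray
    bifurcation_slice: Optional[int] = None
    carina_slice: Optional[int] = None
    left_bronchus_centroid: Optional[Tuple[float, float]] = None
    right_bronchus_centroid: Optional[Tuple[float, float]] = None
    detected: bool = False
    failure_stage: Optional[str] = None


@dataclass
class SubVolume:
    """A sub-volume of interest with its placement in the parent volume."""

    vol: CTVolume
    slice_start: int
    row_start: int
    col_start: int
    parent_shape: Tuple[int, int, int]


def _body_bbox(vol: CTVolume, threshold_hu: float = -500.0
               ) -> Tuple[int, int, int, int]:
    fg = (vol.hu > threshold_hu).any(axis=0)
    if not fg.any():
        raise ValueError("empty body bounding box: no body voxels in volume")
    rows = np.nonzero(fg.any(axis=1))[0]
    cols = np.nonzero(fg.any(axis=0))[0]
    return int(rows[0]), int(rows[-1] + 1), int(cols[0]), int(cols[-1] + 1)


def extract_candidate_volumes(
    vol: CTVolume, config: Optional[AirwayConfig] = None
) -> Tuple[SubVolume, SubVolume]:
    """Two adjoined VOIs from the superior thorax sharing the body bbox.

    Defaults cover slices [0, 15%) and [15%, 35%) of the stack.
    """
    from dataclasses import replace

    config = config or AirwayConfig()
    f0, f1 = config.voi_fractions
    n = vol.n_slices
    z_split, z_end = int(math.floor(n * f0)), int(math.floor(n * f1))
    z_split, z_end = max(1, z_split), max(2, z_end)
    r0, r1, c0, c1 = _body_bbox(vol)
    out = []
    for zs, ze in ((0, z_split), (z_split, z_end)):
        crop = replace(vol, hu=vol.hu[zs:ze, r0:r1, c0:c1])
        out.append(SubVolume(vol=crop, slice_start=zs, row_start=r0,
                             col_start=c0, parent_shape=vol.hu.shape))
    return out[0], out[1]


def interior_air_mask(hu: np.ndarray, air_threshold_hu: float) -> np.ndarray:
    """Air-range voxels with exterior air removed.

    Exterior air is every air component reaching an in-plane border of any
    slice (the cranial/caudal faces are deliberately not used as seeds: an
    open trachea lumen in the first slice must survive).
    """
    air = hu < air_threshold_hu
    labels, n = ndimage.label(air, structure=_STRUCT_3D)
    if n == 0:
        return air
    border_labels = np.unique(np.concatenate([
        labels[:, 0, :].ravel(), labels[:, -1, :].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
    border_labels = border_labels[border_labels > 0]
    return air & ~np.isin(labels, border_labels)


@dataclass
class _Candidate:
    mask: np.ndarray                  # 3D bool, full parent shape
    slices: Tuple[int, int]           # [first, last] slice indices
    volume_cm3: float
    median_diameter_mm: float
    face_centroids: Dict[int, Tuple[float, float]]  # slice -> (row, col)

    @property
    def length(self) -> int:
        return self.slices[1] - self.slices[0] + 1


def _component_candidates(air: np.ndarray, zs: int, ze: int,
                          vol: CTVolume, config: AirwayConfig
                          ) -> List[_Candidate]:
    """Size-filtered connected air components within slice range [zs, ze)."""
    sub = air[zs:ze]
    labels, n = ndimage.label(sub, structure=_STRUCT_3D)
    pixel_area = vol.pixel_area_mm2
    voxel_cm3 = pixel_area * vol.slice_thickness_mm / 1000.0
    out = []
    for lbl in range(1, n + 1):
        comp = labels == lbl
        counts = comp.sum(axis=(1, 2))
        zidx = np.nonzero(counts)[0]
        diameters = 2.0 * np.sqrt(counts[zidx] * pixel_area / math.pi)
        med_d = float(np.median(diameters))
        volume = float(comp.sum() * voxel_cm3)
        dlo, dhi = config.diameter_range_mm
        vlo, vhi = config.volume_range_cm3
        if not (dlo <= med_d <= dhi and vlo <= volume <= vhi):
            continue
        full = np.zeros(vol.hu.shape, dtype=bool)
        full[zs:ze] = comp
        faces = {}
        for z_local in (zidx[0], zidx[-1]):
            rows, cols = np.nonzero(comp[z_local])
            faces[zs + int(z_local)] = (float(rows.mean()), float(cols.mean()))
        out.append(_Candidate(
            mask=full,
            slices=(zs + int(zidx[0]), zs + int(zidx[-1])),
            volume_cm3=volume,
            median_diameter_mm=med_d,
            face_centroids=faces,
        ))
    return out


def find_trachea(upper: SubVolume, lower: SubVolume,
                 config: Optional[AirwayConfig] = None
                 ) -> Optional[np.ndarray]:
    """Select the trachea among air components of the two VOIs.

    Candidates within tracheal diameter/volume range are joined across the
    VOI boundary by centroid continuity; the longest surviving candidate is
    the trachea. Returns a full-volume boolean mask, or None when no
    candidate survives (soft failure).
    """
    config = config or AirwayConfig()
    # Work on the stacked VOIs in the body-bbox frame so that exterior air
    # touching the bbox border is flood-filled away correctly.
    r0, c0 = upper.row_start, upper.col_start
    hu_crop = np.concatenate([upper.vol.hu, lower.vol.hu], axis=0)
    z_end = hu_crop.shape[0]
    air = interior_air_mask(hu_crop, config.air_threshold_hu)

    pseudo = CTVolume(hu=hu_crop, spacing_mm=upper.vol.spacing_mm)
    n_upper = upper.vol.n_slices
    upper_c = _component_candidates(air, 0, n_upper, pseudo, config)
    lower_c = _component_candidates(air, n_upper, z_end, pseudo, config)

    # Join across the VOI boundary by centroid continuity.
    joined: List[_Candidate] = []
    used_lower = set()
    boundary = n_upper
    px = np.asarray(pseudo.in_plane_spacing_mm)
    for uc in upper_c:
        match = None
        if uc.slices[1] == boundary - 1:
            top_c = np.asarray(uc.face_centroids[uc.slices[1]])
            for i, lc in enumerate(lower_c):
                if i in used_lower or lc.slices[0] != boundary:
                    continue
                bot_c = np.asarray(lc.face_centroids[lc.slices[0]])
                shift = float(np.linalg.norm((top_c - bot_c) * px))
                if shift <= config.join_max_shift_mm:
                    match = i
                    break
        if match is not None:
            lc = lower_c[match]
            used_lower.add(match)
            joined.append(_Candidate(
                mask=uc.mask | lc.mask,
                slices=(uc.slices[0], lc.slices[1]),
                volume_cm3=uc.volume_cm3 + lc.volume_cm3,
                median_diameter_mm=(uc.median_diameter_mm
                                    + lc.median_diameter_mm) / 2,
                face_centroids={**uc.face_centroids, **lc.face_centroids},
            ))
        else:
            joined.append(uc)
    joined.extend(lc for i, lc in enumerate(lower_c) if i not in used_lower)
    if not joined:
        return None

    midline_col = hu_crop.shape[2] / 2.0

    def sort_key(c: _Candidate):
        first_face = c.face_centroids[min(c.face_centroids)]
        return (-c.length, -c.volume_cm3, abs(first_face[1] - midline_col))

    best = sorted(joined, key=sort_key)[0]
    # Place the bbox-frame mask back into the parent volume frame.
    full = np.zeros(upper.parent_shape, dtype=bool)
    full[:z_end, r0:r0 + hu_crop.shape[1], c0:c0 + hu_crop.shape[2]] = best.mask
    return full


def track_to_bifurcation(
    vol: CTVolume, trachea_mask: np.ndarray,
    config: Optional[AirwayConfig] = None,
    air: Optional[np.ndarray] = None,
) -> Tuple[Optional[int], np.ndarray]:
    """Track the trachea caudally to the first two-bronchus slice.

    Starting from the trachea's most caudal single-component slice, air
    components 3D-connected to the tracked lumen are followed caudally;
    the first slice presenting ≥ 2 distinct in-plane components is the
    bifurcation. Returns (bifurcation_slice | None, extended mask).
    """
    config = config or AirwayConfig()
    if air is None:
        air = interior_air_mask(vol.hu, config.air_threshold_hu)
    mask = trachea_mask.copy()
    z_idx = np.nonzero(mask.any(axis=(1, 2)))[0]
    if z_idx.size == 0:
        return None, mask
    z = int(z_idx[-1])
    footprint = mask[z]
    for z_next in range(z + 1, vol.n_slices):
        overlap_zone = ndimage.binary_dilation(footprint, structure=_STRUCT_2D)
        slice_air = air[z_next]
        labels, n = ndimage.label(slice_air, structure=_STRUCT_2D)
        touching = np.unique(labels[overlap_zone & slice_air])
        touching = touching[touching > 0]
        if touching.size == 0:
            return None, mask
        if touching.size >= 2:
            return z_next, mask
        comp = labels == touching[0]
        mask[z_next] = comp
        footprint = comp
    return None, mask


def _bronchus_components(slice_air: np.ndarray, prev_union: np.ndarray
                         ) -> List[np.ndarray]:
    labels, n = ndimage.label(slice_air, structure=_STRUCT_2D)
    zone = ndimage.binary_dilation(prev_union, structure=_STRUCT_2D,
                                   iterations=2)
    touching = np.unique(labels[zone & slice_air])
    touching = touching[touching > 0]
    comps = [labels == t for t in touching]
    comps.sort(key=lambda m: -int(m.sum()))
    return comps


def _component_gap_mm(a: np.ndarray, b: np.ndarray,
                      spacing: Tuple[float, float], metric: str) -> float:
    ra, ca = np.nonzero(a)
    rb, cb = np.nonzero(b)
    if metric == "centroid":
        d = (np.array([ra.mean(), ca.mean()])
             - np.array([rb.mean(), cb.mean()])) * np.asarray(spacing)
        return float(np.linalg.norm(d))
    # Edge-to-edge: min pairwise distance between boundary pixel centers,
    # minus one pixel extent (each boundary pixel reaches half a pixel
    # beyond its center toward the gap).
    ba = a & ~ndimage.binary_erosion(a)
    bb = b & ~ndimage.binary_erosion(b)
    pa = np.argwhere(ba) * np.asarray(spacing)
    pb = np.argwhere(bb) * np.asarray(spacing)
    return float(cdist(pa, pb).min()) - float(np.mean(spacing))


def locate_carina(
    vol: CTVolume, bifurcation_slice: int,
    config: Optional[AirwayConfig] = None,
    air: Optional[np.ndarray] = None,
    trachea_footprint: Optional[np.ndarray] = None,
) -> Tuple[Optional[int], Optional[Tuple[float, float]],
           Optional[Tuple[float, float]]]:
    """First slice caudal of the bifurcation with bronchus gap > 0.75 cm.

    The gap is the minimum in-plane edge-to-edge distance between the left
    and right main bronchus components, in mm (strict inequality). Returns
    (carina_slice, left_centroid, right_centroid); all None on soft failure
    (separation never exceeded within the caudal search bound).
    """
    config = config or AirwayConfig()
    if air is None:
        air = interior_air_mask(vol.hu, config.air_threshold_hu)
    spacing = vol.in_plane_spacing_mm
    max_slices = int(config.max_caudal_search_mm / vol.slice_thickness_mm)
    if trachea_footprint is None:
        trachea_footprint = air[max(0, bifurcation_slice - 1)]
    prev_union = trachea_footprint
    for z in range(bifurcation_slice, min(vol.n_slices,
                                          bifurcation_slice + max_slices + 1)):
        comps = _bronchus_components(air[z], prev_union)
        if len(comps) < 2:
            if not comps:
                return None, None, None
            prev_union = comps[0]
            continue
        a, b = comps[0], comps[1]
        prev_union = a | b
        gap = _component_gap_mm(a, b, spacing, config.gap_metric)
        if gap > config.carina_gap_mm:
            cent = []
            for m in (a, b):
                rows, cols = np.nonzero(m)
                cent.append((float(rows.mean()), float(cols.mean())))
            # Patient-left has the larger column index.
            left, right = (cent[0], cent[1]) if cent[0][1] > cent[1][1] \
                else (cent[1], cent[0])
            return z, left, right
    return None, None, None


def detect_airway(vol: CTVolume,
                  config: Optional[AirwayConfig] = None) -> AirwayResult:
    """Run the full airway stage: VOIs → trachea → bifurcation → carina."""
    config = config or AirwayConfig()
    empty = np.zeros(vol.hu.shape, dtype=bool)
    try:
        upper, lower = extract_candidate_volumes(vol, config)
    except ValueError:
        return AirwayResult(trachea_mask=empty, failure_stage="trachea")
    trachea = find_trachea(upper, lower, config)
    if trachea is None:
        return AirwayResult(trachea_mask=empty, failure_stage="trachea")
    air = interior_air_mask(vol.hu, config.air_threshold_hu)
    bifurcation, mask = track_to_bifurcation(vol, trachea, config, air=air)
    if bifurcation is None:
        return AirwayResult(trachea_mask=mask, failure_stage="bifurcation")
    carina, left_c, right_c = locate_carina(
        vol, bifurcation, config, air=air,
        trachea_footprint=mask[bifurcation - 1] if bifurcation > 0 else None)
    if carina is None:
        return AirwayResult(trachea_mask=mask, bifurcation_slice=bifurcation,
                            failure_stage="carina")
    return AirwayResult(
        trachea_mask=mask,
        bifurcation_slice=bifurcation,
        carina_slice=carina,
        left_bronchus_centroid=left_c,
        right_bronchus_centroid=right_c,
        detected=True,
    )
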