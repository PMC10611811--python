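"""The sequential segmentation chain.

Stage order mirrors the anatomical dependency structure: trachea → carina →
descending aorta (ray search posterior to the left main bronchus) → aortic
arch (morphological change while tracking the DAo cranially) → ascending
aorta (first circular object tracking the anterior arch caudally) →
pulmonary trunk (rectangular search space left-lateral to the AAo) →
pulmonary valve (circularity transition while tracking the PT caudally).

Each stage can fail *softly*: the failure is recorded per compartment and
every downstream compartment is marked undetected with an ``upstream:``
failure stage, but the run always completes and returns a full report.
There is no randomness anywhere in the chain: identical volume and
configuration produce identical results.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from ctpa_cade.volume_io import CTVolume, POSTERIOR
from ctpa_cade.config import RunConfig
from ctpa_cade.preprocess import preprocess_volume, body_mask_slice
from ctpa_cade.airway import AirwayResult, detect_airway
from ctpa_cade.measure import MeasurementReport, measure_noise, measure_pt_contrast
from ctpa_cade import vessel_primitives as vp

log = logging.getLogger(__name__)

STAGES = ("trachea", "carina", "dao", "aao", "pt")


@dataclass
class AnatomicalLandmarks:
    """Slice indices and seed points anchoring the vessel detection."""

    bifurcation_slice: Optional[int] = None
    carina_slice: Optional[int] = None
    arch_slice: Optional[int] = None
    pv_slice: Optional[int] = None
    dao_seed: Optional[Tuple[int, int, int]] = None
    aao_seed: Optional[Tuple[int, int, int]] = None
    pt_seed: Optional[Tuple[int, int, int]] = None
    detected: Dict[str, bool] = field(default_factory=dict)


@dataclass
class CompartmentSegmentation:
    """A segmented compartment with per-slice regions and soft-failure state."""

    label: str
    mask: np.ndarray
    per_slice_regions: Dict[int, vp.Region2D] = field(default_factory=dict)
    detected: bool = False
    failure_stage: Optional[str] = None
    diameter_mm: Optional[float] = None


@dataclass
class PipelineResult:
    landmarks: AnatomicalLandmarks
    segmentations: Dict[str, CompartmentSegmentation]
    report: MeasurementReport
    airway: Optional[AirwayResult] = None
    alignment_applied: bool = False
    stage_seconds: Dict[str, float] = field(default_factory=dict)


class _SliceOps:
    """Per-slice smoothed images and edge maps, computed lazily and cached."""

    def __init__(self, vol: CTVolume, config: RunConfig):
        self.vol = vol
        self.config = config
        self._smoothed: Dict[int, np.ndarray] = {}
        self._edges: Dict[int, np.ndarray] = {}

    def smoothed(self, z: int) -> np.ndarray:
        if z not in self._smoothed:
            self._smoothed[z] = ndimage.gaussian_filter(
                self.vol.hu[z].astype(np.float64),
                self.config.vessel.smoothing_sigma_px)
        return self._smoothed[z]

    def edges(self, z: int) -> np.ndarray:
        if z not in self._edges:
            body = body_mask_slice(self.vol.hu[z],
                                   self.config.preprocess.body_threshold_hu)
            _, edges = vp.enhance_and_edge(
                self.vol.hu[z], self.config.vessel.hu_range,
                body_mask=body if body.any() else None,
                sigma_px=self.config.vessel.smoothing_sigma_px,
                percentiles=self.config.vessel.edge_percentiles)
            self._edges[z] = edges
        return self._edges[z]

    def grow(self, z: int, seed: Tuple[int, int],
             search_px: int = 2) -> Optional[vp.Region2D]:
        """Region growing + half-max refinement at a seed; None on failure.

        If the seed pixel itself is out of the contrast range, the brightest
        in-range pixel within ``search_px`` is used instead (propagated
        centroids can land on a partial-volume pixel)."""
        cfg = self.config.vessel
        img = self.smoothed(z)
        spacing = self.vol.in_plane_spacing_mm
        r, c = int(round(seed[0])), int(round(seed[1]))
        nrows, ncols = img.shape
        if not (0 <= r < nrows and 0 <= c < ncols):
            return None
        lo, hi = cfg.hu_range
        edges = self.edges(z)
        if not (lo <= img[r, c] <= hi) or edges[r, c]:
            r0, r1 = max(0, r - search_px), min(nrows, r + search_px + 1)
            c0, c1 = max(0, c - search_px), min(ncols, c + search_px + 1)
            window = img[r0:r1, c0:c1].copy()
            window[(window < lo) | (window > hi)] = -np.inf
            window[edges[r0:r1, c0:c1]] = -np.inf
            if not np.isfinite(window).any():
                return None
            dr, dc = np.unravel_index(int(window.argmax()), window.shape)
            r, c = r0 + dr, c0 + dc
        try:
            region = vp.region_grow_2d(
                img, (r, c), cfg.region_tolerance_hu, cfg.max_region_area_mm2,
                spacing, edges=edges, hu_range=cfg.hu_range, slice_index=z)
        except ValueError:
            return None
        if region.overgrown:
            return region  # caller decides; flagged
        return vp.refine_half_max(img, region, spacing)


def _empty_mask(vol: CTVolume) -> np.ndarray:
    return np.zeros(vol.hu.shape, dtype=bool)


def _upstream(stage: Optional[str]) -> str:
    """Failure tag for a compartment whose prerequisite stage failed."""
    root = (stage or "unknown").split(":")[-1]
    return f"upstream:{root}"


def _failed(vol: CTVolume, label: str, stage: str) -> CompartmentSegmentation:
    return CompartmentSegmentation(label=label, mask=_empty_mask(vol),
                                   detected=False, failure_stage=stage)


# --------------------------------------------------------------------------
# DAo
# --------------------------------------------------------------------------

def detect_dao(vol: CTVolume, airway: AirwayResult, config: RunConfig,
               ops: Optional[_SliceOps] = None
               ) -> Tuple[CompartmentSegmentation, Optional[Tuple[int, int, int]]]:
    """Find and segment the descending aorta around the carina level.

    Two sequential ray fans originate posterior to the left main bronchus:
    a coarse ±45° fan, then a refined fan around the best first-pass hit.
    A confirmed hit seeds 2D region growing; the DAo is propagated to
    adjacent slices (± the tracking bound) by re-seeding at the previous
    slice's centroid, accepting slices that stay circular and of similar
    area."""
    ops = ops or _SliceOps(vol, config)
    pcfg, vcfg = config.pipeline, config.vessel
    if airway.carina_slice is None or airway.left_bronchus_centroid is None:
        return _failed(vol, "dao", _upstream("carina")), None
    z_c = airway.carina_slice
    origin = airway.left_bronchus_centroid
    spacing = vol.in_plane_spacing_mm
    img = ops.smoothed(z_c)

    def best_hit(center_dir, half, step):
        space = vp.RaySearchSpace(
            origin=origin,
            directions=vp.fan_directions(center_dir, half, step),
            max_length_mm=pcfg.ray_length_mm,
            hu_range=vcfg.hu_range,
            min_connected_mm=pcfg.ray_min_connected_mm)
        hits = vp.cast_rays(space, img, spacing)
        if not hits:
            return None
        return max(hits, key=lambda h: h.connected_run_mm)

    hit = best_hit(POSTERIOR, pcfg.ray_fan_deg, pcfg.ray_step_deg)
    if hit is not None:
        refined = best_hit(hit.direction, pcfg.refine_fan_deg,
                           pcfg.refine_step_deg)
        hit = refined or hit
    if hit is None:
        return _failed(vol, "dao", "dao_ray_search"), None

    seed = (int(round(hit.midpoint[0])), int(round(hit.midpoint[1])))
    region = ops.grow(z_c, seed)
    if region is None or region.overgrown:
        return _failed(vol, "dao", "dao_ray_search"), None

    regions: Dict[int, vp.Region2D] = {z_c: region}
    a0 = region.area_mm2
    track = int(pcfg.dao_track_mm / vol.slice_thickness_mm)
    lo_f, hi_f = pcfg.dao_area_band
    for direction in (-1, +1):
        prev = region
        for dz in range(1, track + 1):
            z = z_c + direction * dz
            if not (0 <= z < vol.n_slices):
                break
            cand = ops.grow(z, prev.centroid)
            if cand is None or cand.overgrown:
                break
            if cand.circularity < vcfg.dao_circularity_floor:
                break
            if not (lo_f * a0 <= cand.area_mm2 <= hi_f * a0):
                break
            regions[z] = cand
            prev = cand

    mask = _empty_mask(vol)
    for z, reg in regions.items():
        mask[z] = reg.mask
    seg = CompartmentSegmentation(label="dao", mask=mask,
                                  per_slice_regions=regions, detected=True)
    return seg, (z_c, seed[0], seed[1])


# --------------------------------------------------------------------------
# Arch + AAo
# --------------------------------------------------------------------------

def _anterior_tip_centroid(mask: np.ndarray, spacing: Tuple[float, float],
                           depth_mm: float = 12.0) -> Tuple[float, float]:
    """Centroid of the pixels within ``depth_mm`` of the most anterior row."""
    rows, cols = np.nonzero(mask)
    sel = rows <= rows.min() + depth_mm / spacing[0]
    return float(rows[sel].mean()), float(cols[sel].mean())

def detect_arch_and_aao(
    vol: CTVolume, dao: CompartmentSegmentation, airway: AirwayResult,
    config: RunConfig, ops: Optional[_SliceOps] = None
) -> Tuple[Optional[int], CompartmentSegmentation, Optional[Tuple[int, int, int]]]:
    """Locate the aortic-arch level and segment the ascending aorta.

    The DAo is re-segmented slice by slice in the caudal→cranial direction;
    the arch level is the first slice whose region's area jumps above
    ``arch_area_factor`` times the carina-level area or whose circularity
    drops below the arch floor (the limbs merge into one elongated
    cross-section). From there the anterior third of the arch region is
    tracked caudally and the first sufficiently circular region seeds the
    AAo, which is then segmented on every slice between the arch and the
    carina."""
    ops = ops or _SliceOps(vol, config)
    pcfg, vcfg = config.pipeline, config.vessel
    if not dao.detected or airway.carina_slice is None:
        return None, _failed(vol, "aao", _upstream("dao")), None
    z_c = airway.carina_slice
    carina_region = dao.per_slice_regions[z_c]
    a0 = carina_region.area_mm2

    arch_slice: Optional[int] = None
    arch_region: Optional[vp.Region2D] = None
    max_up = int(pcfg.arch_search_mm / vol.slice_thickness_mm)
    prev = carina_region
    for dz in range(1, max_up + 1):
        z = z_c - dz
        if z < 0:
            break
        cand = ops.grow(z, prev.centroid)
        if cand is None:
            break
        if cand.area_mm2 > pcfg.arch_area_factor * a0 \
                or cand.circularity < pcfg.arch_circularity_floor:
            arch_slice, arch_region = z, cand
            break
        prev = cand
    if arch_slice is None:
        return None, _failed(vol, "aao", "arch_tracking"), None

    # Anterior part of the arch region ("anterior" = smaller row index):
    # the centroid of the pixels near the region's most anterior row sits on
    # the AAo limb regardless of how far the elongated band stretches back.
    centroid = _anterior_tip_centroid(arch_region.mask,
                                      vol.in_plane_spacing_mm)

    max_down = int(pcfg.aao_search_mm / vol.slice_thickness_mm)
    aao_found: Optional[int] = None
    aao_region: Optional[vp.Region2D] = None
    for dz in range(1, max_down + 1):
        z = arch_slice + dz
        if z >= vol.n_slices:
            break
        cand = ops.grow(z, centroid, search_px=4)
        if cand is None:
            continue
        if not cand.overgrown and cand.circularity >= vcfg.aao_circularity_floor:
            aao_found, aao_region = z, cand
            break
        # Still elongated (arch remnant): follow its anterior tip down.
        centroid = _anterior_tip_centroid(cand.mask, vol.in_plane_spacing_mm)
    if aao_found is None or aao_found > z_c:
        return arch_slice, _failed(vol, "aao", "aao_circularity"), None

    # Segment the AAo on every slice between the arch and the carina.
    regions: Dict[int, vp.Region2D] = {aao_found: aao_region}
    for direction, stop in ((-1, arch_slice), (+1, z_c)):
        prev_r = aao_region
        z = aao_found
        while z != stop:
            z += direction
            cand = ops.grow(z, prev_r.centroid)
            if cand is None or cand.overgrown:
                break
            regions[z] = cand
            prev_r = cand

    mask = _empty_mask(vol)
    for z, reg in regions.items():
        mask[z] = reg.mask
    circ_ok = [reg.equivalent_diameter_mm for z, reg in sorted(regions.items())
               if reg.circularity >= vcfg.aao_circularity_floor]
    diameter = float(np.mean(circ_ok)) if circ_ok else None
    seg = CompartmentSegmentation(label="aao", mask=mask,
                                  per_slice_regions=regions, detected=True,
                                  diameter_mm=diameter)
    seed3 = (aao_found, int(round(aao_region.centroid[0])),
             int(round(aao_region.centroid[1])))
    return arch_slice, seg, seed3


# --------------------------------------------------------------------------
# PT
# --------------------------------------------------------------------------

def detect_pt(
    vol: CTVolume, aao: CompartmentSegmentation, airway: AirwayResult,
    config: RunConfig, ops: Optional[_SliceOps] = None
) -> Tuple[CompartmentSegmentation, Optional[int], Optional[Tuple[int, int, int]]]:
    """Segment the pulmonary trunk and locate the pulmonary-valve level.

    A rectangular search space abuts the patient-left boundary of the AAo
    at (and a little caudal of) the carina; the brightest in-range point
    inside it seeds the segmentation chain. The PT is tracked caudally; the
    PV level is the first slice where circularity rises above the PV floor
    after having been below it (elongated outflow → round proximal trunk).
    The PT diameter is the mean of per-slice Hough-circle diameters over
    the tracked planes."""
    ops = ops or _SliceOps(vol, config)
    pcfg, vcfg = config.pipeline, config.vessel
    if not aao.detected or airway.carina_slice is None:
        return _failed(vol, "pt", _upstream("aao")), None, None
    z_c = airway.carina_slice
    spacing = vol.in_plane_spacing_mm
    box_h = int(pcfg.pt_box_mm[0] / spacing[0])
    box_w = int(pcfg.pt_box_mm[1] / spacing[1])
    max_dz = int(pcfg.pt_search_mm / vol.slice_thickness_mm)

    seed_region: Optional[vp.Region2D] = None
    seed_z: Optional[int] = None
    seed_rc: Optional[Tuple[int, int]] = None
    for dz in range(0, max_dz + 1):
        z = z_c + dz
        if z >= vol.n_slices:
            break
        ref_z = z if aao.mask[z].any() else z_c
        if not aao.mask[ref_z].any():
            continue
        rows, cols = np.nonzero(aao.mask[ref_z])
        left_col = int(cols.max()) + 2
        row_center = int(rows.mean())
        r0 = max(0, row_center - box_h // 2)
        r1 = min(vol.hu.shape[1], row_center + box_h // 2)
        c0, c1 = left_col, min(vol.hu.shape[2], left_col + box_w)
        if c1 - c0 < 3 or r1 - r0 < 3:
            continue
        img = ops.smoothed(z)
        window = img[r0:r1, c0:c1].copy()
        lo, hi = vcfg.hu_range
        exclude = ndimage.binary_dilation(aao.mask[ref_z], iterations=3)
        window[(window < lo) | (window > hi)] = -np.inf
        window[exclude[r0:r1, c0:c1]] = -np.inf
        if not np.isfinite(window).any():
            continue
        dr, dc = np.unravel_index(int(window.argmax()), window.shape)
        cand = ops.grow(z, (r0 + dr, c0 + dc))
        if cand is None or cand.overgrown or cand.area_mm2 < 80.0:
            continue
        seed_region, seed_z, seed_rc = cand, z, (r0 + dr, c0 + dc)
        break
    if seed_region is None:
        return _failed(vol, "pt", "pt_search_space"), None, None

    # Track caudally; watch the circularity for the PV transition.
    regions: Dict[int, vp.Region2D] = {seed_z: seed_region}
    track = int(pcfg.pt_track_mm / vol.slice_thickness_mm)
    prev = seed_region
    floor = vcfg.pv_circularity_floor
    pv_slice: Optional[int] = None
    seen_other_side = prev.circularity < floor if pcfg.pv_transition == "rising" \
        else prev.circularity >= floor
    for dz in range(1, track + 1):
        z = seed_z + dz
        if z >= vol.n_slices:
            break
        cand = ops.grow(z, prev.centroid)
        if cand is None or cand.overgrown:
            break
        regions[z] = cand
        if pv_slice is None:
            if pcfg.pv_transition == "rising":
                if cand.circularity >= floor and seen_other_side:
                    pv_slice = z
                seen_other_side = seen_other_side or cand.circularity < floor
            else:
                if cand.circularity < floor and seen_other_side:
                    pv_slice = z
                seen_other_side = seen_other_side or cand.circularity >= floor
        prev = cand

    # Hough diameter on each tracked plane, within the region's neighbourhood.
    diameters = []
    rlo, rhi = vcfg.pt_hough_radius_range_mm
    for z, reg in sorted(regions.items()):
        rows, cols = np.nonzero(reg.mask)
        pad = int(6.0 / min(spacing))
        roi = (max(0, rows.min() - pad), max(0, cols.min() - pad),
               min(vol.hu.shape[1], rows.max() + pad + 1),
               min(vol.hu.shape[2], cols.max() + pad + 1))
        result = vp.hough_circle_diameter(ops.smoothed(z), (rlo, rhi),
                                          spacing, roi=roi)
        if result is not None:
            diameters.append(result[1])
    diameter = float(np.mean(diameters)) if diameters else None

    mask = _empty_mask(vol)
    for z, reg in regions.items():
        mask[z] = reg.mask
    seg = CompartmentSegmentation(label="pt", mask=mask,
                                  per_slice_regions=regions, detected=True,
                                  diameter_mm=diameter)
    return seg, pv_slice, (seed_z, seed_rc[0], seed_rc[1])


# --------------------------------------------------------------------------
# Full chain
# --------------------------------------------------------------------------

def run_pipeline(vol: CTVolume, config: Optional[RunConfig] = None
                 ) -> PipelineResult:
    """Execute the whole chain and return a complete per-exam result.

    Soft failures never raise: each stage marks its compartment and all
    downstream compartments as undetected and the report is still produced.
    Only hard input/geometry errors propagate."""
    config = config or RunConfig()
    vol.check_pipeline_eligible()
    landmarks = AnatomicalLandmarks()
    segmentations: Dict[str, CompartmentSegmentation] = {}
    stage_seconds: Dict[str, float] = {}

    t0 = time.perf_counter()
    vol, align_info = preprocess_volume(vol, config.preprocess)
    stage_seconds["preprocess"] = time.perf_counter() - t0
    ops = _SliceOps(vol, config)

    t0 = time.perf_counter()
    airway = detect_airway(vol, config.airway)
    stage_seconds["airway"] = time.perf_counter() - t0
    landmarks.bifurcation_slice = airway.bifurcation_slice
    landmarks.carina_slice = airway.carina_slice
    landmarks.detected["trachea"] = airway.trachea_mask.any() \
        and airway.failure_stage != "trachea"
    landmarks.detected["bifurcation"] = airway.bifurcation_slice is not None
    landmarks.detected["carina"] = airway.carina_slice is not None
    trachea_seg = CompartmentSegmentation(
        label="trachea", mask=airway.trachea_mask,
        detected=bool(landmarks.detected["trachea"]),
        failure_stage=airway.failure_stage)
    segmentations["trachea"] = trachea_seg

    t0 = time.perf_counter()
    if airway.detected:
        dao, dao_seed = detect_dao(vol, airway, config, ops)
    else:
        dao, dao_seed = _failed(vol, "dao",
                                _upstream(airway.failure_stage)), None
    stage_seconds["dao"] = time.perf_counter() - t0
    segmentations["dao"] = dao
    landmarks.dao_seed = dao_seed
    landmarks.detected["dao"] = dao.detected

    t0 = time.perf_counter()
    if dao.detected:
        arch_slice, aao, aao_seed = detect_arch_and_aao(vol, dao, airway,
                                                        config, ops)
    else:
        arch_slice, aao, aao_seed = None, _failed(
            vol, "aao", _upstream(dao.failure_stage)), None
    stage_seconds["aao"] = time.perf_counter() - t0
    segmentations["aao"] = aao
    landmarks.arch_slice = arch_slice
    landmarks.aao_seed = aao_seed
    landmarks.detected["aao"] = aao.detected

    t0 = time.perf_counter()
    if aao.detected:
        pt, pv_slice, pt_seed = detect_pt(vol, aao, airway, config, ops)
    else:
        pt, pv_slice, pt_seed = _failed(
            vol, "pt", _upstream(aao.failure_stage)), None, None
    stage_seconds["pt"] = time.perf_counter() - t0
    segmentations["pt"] = pt
    landmarks.pv_slice = pv_slice
    landmarks.pt_seed = pt_seed
    landmarks.detected["pt"] = pt.detected
    landmarks.detected["pv"] = pv_slice is not None

    # ---- measurements ------------------------------------------------
    t0 = time.perf_counter()
    report = MeasurementReport()
    report.detection_flags = dict(landmarks.detected)
    report.failure_stages = {
        name: seg.failure_stage for name, seg in segmentations.items()
        if seg.failure_stage}
    if pt.detected and pt.per_slice_regions:
        if config.measure.measurement_slice == "pt_optimal":
            meas_z = max(pt.per_slice_regions,
                         key=lambda z: pt.per_slice_regions[z].area_mm2)
        else:
            meas_z = airway.carina_slice
    else:
        meas_z = airway.carina_slice
    if dao.detected and meas_z is not None:
        z_noise = meas_z if dao.mask[meas_z].any() else airway.carina_slice
        report.noise_sd_hu = measure_noise(
            vol, dao.mask, z_noise, config.measure.noise_roi_cm2)
    if pt.detected and meas_z is not None:
        report.pt_contrast_mean_hu = measure_pt_contrast(
            vol, pt.mask, meas_z, config.measure.contrast_roi_cm2)
        if report.pt_contrast_mean_hu is not None:
            report.low_contrast = bool(report.pt_contrast_mean_hu
                                       < config.measure.low_contrast_hu)
    report.aao_diameter_mm = aao.diameter_mm if aao.detected else None
    report.pt_diameter_mm = pt.diameter_mm if pt.detected else None
    stage_seconds["measure"] = time.perf_counter() - t0

    return PipelineResult(
        landmarks=landmarks,
        segmentations=segmentations,
        report=report,
        airway=airway,
        alignment_applied=align_info.applied,
        stage_seconds=stage_seconds,
    )
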