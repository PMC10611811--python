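"""Deterministic synthetic CTPA phantom generator.

The phantom emulates the mediastinal anatomy the detection chain relies on,
with voxel-accurate ground-truth masks and true measurement values:

* an elliptical soft-tissue thorax (≈40 HU) with a thin high-attenuation
  rind standing in for the bony shell, on an air background (−1000 HU);
* two lung fields (≈−850 HU);
* an air-filled trachea bifurcating into left and right main bronchi that
  diverge slice by slice, so the carina level (bronchus gap > 0.75 cm) is
  analytically known;
* a contrast-filled aorta: vertical descending (DAo) and ascending (AAo)
  limbs joined cranially by a horizontal connecting tube, which produces the
  merged, elongated axial cross-section that marks the aortic-arch level
  while keeping both limbs circular below it;
* a pulmonary trunk (PT) left-lateral to the AAo whose cross-section is an
  elongated stadium (low circularity) above the pulmonary-valve level and a
  circle below it, so the circularity-based PV rule has a defined answer;
* seeded, locally standardized Gaussian noise and optional streak/motion
  degradation.

Default intensity and size parameters follow published population medians
for CT pulmonary angiography: AAo diameter 33 mm, PT diameter 27 mm, PT
contrast 385 HU, image noise SD 20 HU at 2.0 mm slice thickness, ~0.7 mm
pixels. Geometry is rendered at 2× in-plane supersampling and box-averaged
down, so rasterized diameters are accurate to ≤ 0.5 voxel and structure
boundaries carry realistic partial-volume gradients.

Truth values in a bundle are the generator's *inputs* (or analytic
consequences of them), never re-measurements of the rendered volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from ctpa_cade.volume_io import CTVolume, SliceOrder

# Compartment label values used in exported label masks.
LABELS = {"trachea": 1, "dao": 2, "aao": 3, "pt": 4}

# Canonical compartment measurement extents (mm along the slice axis); these
# define which slices belong to each compartment's ground-truth mask and
# mirror the tracking bounds of the detection chain.
DAO_EXTENT_MM = 30.0    # DAo: within ± this of the carina
PT_TRACK_MM = 50.0      # PT: from the carina caudally, at most this far


@dataclass
class TracheaSpec:
    diameter_mm: float = 18.0
    bifurcation_slice: int = 60
    bronchus_diameter_mm: float = 12.0
    bronchus_offset_mm: float = 7.0         # initial lateral offset of each bronchus
    bronchus_divergence_mm_per_slice: float = 1.75
    bronchus_length_slices: int = 12
    center_mm: Tuple[float, float] = (5.0, -18.0)   # (row, col) offset from image center


@dataclass
class AortaSpec:
    aao_diameter_mm: float = 33.0
    dao_diameter_mm: float = 25.0
    arch_apex_slice: int = 38               # slice of the connecting tube's axis
    contrast_hu: float = 385.0
    aao_center_mm: Tuple[float, float] = (-30.0, -5.0)
    dao_center_mm: Tuple[float, float] = (40.0, 18.0)


@dataclass
class PTSpec:
    diameter_mm: float = 27.0
    contrast_hu: float = 385.0
    pv_slice: int = 70
    row_mm: float = -25.0
    elongation: float = 3.0                 # straight length of the stadium, in radii
    clearance_mm: float = 2.0               # gap between AAo edge and PT edge


@dataclass
class BodySpec:
    semi_axes_mm: Tuple[float, float] = (75.0, 100.0)   # (row, col)
    soft_tissue_hu: float = 40.0
    rind_thickness_mm: float = 3.0
    rind_hu: float = 700.0


@dataclass
class LungSpec:
    hu: float = -850.0
    center_col_mm: float = 75.0
    semi_axes_mm: Tuple[float, float] = (48.0, 16.0)


@dataclass
class StreakSpec:
    n_bands: int = 12
    amplitude_hu: float = 200.0


@dataclass
class MotionSpec:
    blur_mm: float = 3.0


@dataclass
class ArtifactSpec:
    streak: Optional[StreakSpec] = None
    motion: Optional[MotionSpec] = None


@dataclass
class PhantomSpec:
    """Geometric and intensity parameters of one synthetic CTPA exam.

    Set ``trachea``, ``aorta`` or ``pt`` to ``None`` to delete that
    structure (for soft-failure robustness fixtures).
    """

    matrix: Tuple[int, int, int] = (100, 320, 320)
    spacing_mm: Tuple[float, float, float] = (2.0, 0.7, 0.7)
    trachea: Optional[TracheaSpec] = field(default_factory=TracheaSpec)
    aorta: Optional[AortaSpec] = field(default_factory=AortaSpec)
    pt: Optional[PTSpec] = field(default_factory=PTSpec)
    body: BodySpec = field(default_factory=BodySpec)
    lungs: LungSpec = field(default_factory=LungSpec)
    noise_sd_hu: float = 20.0
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    rotation_deg: Tuple[float, float] = (0.0, 0.0)   # (cranial, caudal) in-plane
    esophagus_air_diameter_mm: Optional[float] = None
    seed: int = 0

    # ---- analytic truth helpers -------------------------------------

    @property
    def carina_slice(self) -> Optional[int]:
        """First slice where the bronchus edge gap strictly exceeds 7.5 mm."""
        if self.trachea is None:
            return None
        t = self.trachea
        for k in range(t.bronchus_length_slices + 1):
            gap = 2.0 * (t.bronchus_offset_mm
                         + k * t.bronchus_divergence_mm_per_slice) \
                - t.bronchus_diameter_mm
            if gap > 7.5:
                return t.bifurcation_slice + k
        return None

    @property
    def arch_slice(self) -> Optional[int]:
        """Most caudal slice intersected by the arch connecting tube."""
        if self.aorta is None:
            return None
        th = self.spacing_mm[0]
        bar_z = self.aorta.arch_apex_slice * th
        return int(math.floor((bar_z + self.aorta.dao_diameter_mm / 2.0) / th))

    def validate(self) -> None:
        """Reject geometrically inconsistent specs (structure collisions)."""
        n_slices, nrows, ncols = self.matrix
        if n_slices < 20:
            raise ValueError("phantom must have at least 20 slices")
        semi_r, semi_c = self.body.semi_axes_mm
        half_r = (nrows - 1) / 2 * self.spacing_mm[1]
        half_c = (ncols - 1) / 2 * self.spacing_mm[2]
        if semi_r + self.body.rind_thickness_mm > half_r or \
           semi_c + self.body.rind_thickness_mm > half_c:
            raise ValueError("body ellipse does not fit in the matrix")
        if self.aorta is not None and self.pt is not None:
            aao_edge = self.aorta.aao_center_mm[1] + self.aorta.aao_diameter_mm / 2
            pt_col = aao_edge + self.pt.clearance_mm + self.pt.diameter_mm / 2
            pt_right_edge = pt_col - self.pt.diameter_mm / 2
            if pt_right_edge < aao_edge + 0.5:
                raise ValueError("PT overlaps the AAo")
            lung_inner = self.lungs.center_col_mm - self.lungs.semi_axes_mm[1]
            if pt_col + self.pt.diameter_mm / 2 > lung_inner - 0.5:
                raise ValueError("PT overlaps the left lung")
        if self.aorta is not None and self.trachea is not None:
            # DAo must stay clear of (and posterior to) the bronchi.
            dao_row = self.aorta.dao_center_mm[0] - self.aorta.dao_diameter_mm / 2
            tr_row = self.trachea.center_mm[0] + self.trachea.diameter_mm / 2
            if dao_row < tr_row + 1.0:
                raise ValueError("DAo collides with the airway")
        if self.trachea is not None and self.carina_slice is not None:
            if self.carina_slice > self.trachea.bifurcation_slice \
                    + self.trachea.bronchus_length_slices:
                raise ValueError("bronchi too short to reach the carina gap")


@dataclass
class PhantomBundle:
    """A rendered phantom: volume, per-compartment truth masks, true values."""

    volume: CTVolume
    truth_masks: Dict[str, np.ndarray]
    truth: Dict[str, object]
    spec: PhantomSpec


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

_SS = 2  # in-plane supersampling factor


def _fine_grid(nrows: int, ncols: int, spacing: Tuple[float, float]):
    """mm coordinates of supersampled pixel centers, origin at image center."""
    fr = (np.arange(nrows * _SS) + 0.5) / _SS - 0.5 - (nrows - 1) / 2.0
    fc = (np.arange(ncols * _SS) + 0.5) / _SS - 0.5 - (ncols - 1) / 2.0
    rows_mm = fr * spacing[0]
    cols_mm = fc * spacing[1]
    return np.meshgrid(rows_mm, cols_mm, indexing="ij")


def _downsample(fine: np.ndarray) -> np.ndarray:
    """Box-average a supersampled mask to per-pixel coverage in [0, 1]."""
    nr, nc = fine.shape[0] // _SS, fine.shape[1] // _SS
    return fine.reshape(nr, _SS, nc, _SS).mean(axis=(1, 3))


def _disc(rr, cc, center, radius):
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _ellipse(rr, cc, center, semi):
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _capsule(rr, cc, p0, p1, radius):
    """Distance-to-segment disc sweep (stadium shape)."""
    d = np.asarray(p1, float) - np.asarray(p0, float)
    length2 = float(d @ d)
    if length2 == 0:
        return _disc(rr, cc, p0, radius)
    t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / length2
    t = np.clip(t, 0.0, 1.0)
    pr = p0[0] + t * d[0]
    pc = p0[1] + t * d[1]
    return (rr - pr) ** 2 + (cc - pc) ** 2 <= radius ** 2


def _pt_geometry(spec: PhantomSpec) -> Tuple[float, float]:
    """(row, col) center of the PT in mm, derived from the AAo position."""
    assert spec.pt is not None
    if spec.aorta is not None:
        aao_edge = spec.aorta.aao_center_mm[1] + spec.aorta.aao_diameter_mm / 2
    else:
        aao_edge = 11.5  # default AAo left edge when the aorta is deleted
    pt_col = aao_edge + spec.pt.clearance_mm + spec.pt.diameter_mm / 2
    return spec.pt.row_mm, pt_col


def generate(spec: PhantomSpec) -> PhantomBundle:
    """Render a phantom volume with truth masks and true measurement values."""
    spec.validate()
    n_slices, nrows, ncols = spec.matrix
    th, row_sp, col_sp = spec.spacing_mm
    rr, cc = _fine_grid(nrows, ncols, (row_sp, col_sp))

    hu = np.full((n_slices, nrows, ncols), -1000.0, dtype=np.float32)
    masks = {name: np.zeros((n_slices, nrows, ncols), dtype=bool)
             for name in LABELS}

    body = spec.body
    semi_r, semi_c = body.semi_axes_mm
    carina = spec.carina_slice
    arch = spec.arch_slice
    angles = np.linspace(spec.rotation_deg[0], spec.rotation_deg[1], n_slices)

    if spec.pt is not None:
        pt_row, pt_col = _pt_geometry(spec)
        pt_r = spec.pt.diameter_mm / 2.0
        pt_half_len = spec.pt.elongation * pt_r / 2.0
        pt_start = (carina if carina is not None else spec.pt.pv_slice - 8) - 4
        pt_end = spec.pt.pv_slice + 12

    lung_slices = (18, n_slices - 6)

    # Most shapes do not vary along z: cache their fine masks (and binary
    # downsamples) unless a per-slice rotation forces re-evaluation.
    rotated = bool(np.any(angles != 0.0))
    _fine_cache: Dict[str, np.ndarray] = {}
    _bin_cache: Dict[str, np.ndarray] = {}

    for z in range(n_slices):
        z_mm = z * th
        a = math.radians(angles[z])
        if a != 0.0:
            # A rotated patient: evaluate every shape in patient coordinates.
            ca, sa = math.cos(a), math.sin(a)
            pr = ca * rr + sa * cc
            pc = -sa * rr + ca * cc
        else:
            pr, pc = rr, cc

        def shape(key: Optional[str], fn):
            if rotated or key is None:
                return fn()
            if key not in _fine_cache:
                _fine_cache[key] = fn()
            return _fine_cache[key]

        paint: List[Tuple[np.ndarray, float, Optional[str], Optional[str]]] = []
        paint.append((shape("rind", lambda: _ellipse(
            pr, pc, (0, 0), (semi_r + body.rind_thickness_mm,
                             semi_c + body.rind_thickness_mm))),
            body.rind_hu, None, None))
        paint.append((shape("body", lambda: _ellipse(
            pr, pc, (0, 0), (semi_r, semi_c))), body.soft_tissue_hu,
            None, None))

        if lung_slices[0] <= z <= lung_slices[1]:
            # Lungs are clipped to the body interior so parenchymal air can
            # never connect to the exterior air surrounding the patient.
            for side, key in ((-1, "lung_r"), (1, "lung_l")):
                paint.append((shape(key, lambda side=side: _ellipse(
                    pr, pc, (0, side * spec.lungs.center_col_mm),
                    spec.lungs.semi_axes_mm) & _ellipse(
                    pr, pc, (0, 0), (semi_r - 2.0, semi_c - 2.0))),
                    spec.lungs.hu, None, None))

        t = spec.trachea
        if t is not None:
            if z < t.bifurcation_slice:
                paint.append((shape("trachea", lambda: _disc(
                    pr, pc, t.center_mm, t.diameter_mm / 2)),
                    -1000.0, "trachea", "trachea"))
            elif z <= t.bifurcation_slice + t.bronchus_length_slices:
                k = z - t.bifurcation_slice
                off = t.bronchus_offset_mm + k * t.bronchus_divergence_mm_per_slice
                for side in (-1, 1):
                    center = (t.center_mm[0], t.center_mm[1] + side * off)
                    paint.append((_disc(pr, pc, center,
                                        t.bronchus_diameter_mm / 2),
                                  -1000.0, None, None))
        if spec.esophagus_air_diameter_mm is not None and z < 75:
            paint.append((shape("esoph", lambda: _disc(
                pr, pc, (21.0, -18.0), spec.esophagus_air_diameter_mm / 2)),
                -1000.0, None, None))

        ao = spec.aorta
        if ao is not None and arch is not None and z >= ao.arch_apex_slice - 1:
            bar_z = ao.arch_apex_slice * th
            dz = z_mm - bar_z
            bar_r = ao.dao_diameter_mm / 2.0
            dao_name = "dao" if (carina is not None and
                                 abs(z_mm - carina * th) <= DAO_EXTENT_MM) else None
            paint.append((shape("dao", lambda: _disc(
                pr, pc, ao.dao_center_mm, ao.dao_diameter_mm / 2)),
                ao.contrast_hu, dao_name, "dao"))
            if carina is None or z <= carina + 15:
                aao_name = "aao" if (carina is not None and arch <= z <= carina) \
                    else None
                paint.append((shape("aao", lambda: _disc(
                    pr, pc, ao.aao_center_mm, ao.aao_diameter_mm / 2)),
                    ao.contrast_hu, aao_name, "aao"))
            if abs(dz) < bar_r:
                half_w = math.sqrt(bar_r ** 2 - dz ** 2)
                paint.append((_capsule(pr, pc, ao.aao_center_mm,
                                       ao.dao_center_mm, half_w),
                              ao.contrast_hu, None, None))

        if spec.pt is not None and pt_start <= z <= pt_end:
            if z < spec.pt.pv_slice:
                shp = shape("pt_stadium", lambda: _capsule(
                    pr, pc, (pt_row - pt_half_len, pt_col),
                    (pt_row + pt_half_len, pt_col), pt_r))
                cache_key = "pt_stadium"
            else:
                shp = shape("pt_circle", lambda: _disc(
                    pr, pc, (pt_row, pt_col), pt_r))
                cache_key = "pt_circle"
            in_track = (carina is not None
                        and carina <= z <= carina + int(PT_TRACK_MM / th))
            paint.append((shp, spec.pt.contrast_hu,
                          "pt" if in_track else None, cache_key))

        if spec.artifacts.streak is not None and 25 <= z <= 85:
            paint.append((shape("svc", lambda: _disc(
                pr, pc, (-40.0, -40.0), 6.0)), 1200.0, None, None))

        canvas = np.full(rr.shape, -1000.0, dtype=np.float32)
        for fine_mask, value, name, _key in paint:
            canvas[fine_mask] = np.float32(value)
        hu[z] = _downsample_hu(canvas)
        for fine_mask, _value, name, key in paint:
            if name is None:
                continue
            if not rotated and key is not None:
                if key not in _bin_cache:
                    _bin_cache[key] = _downsample(
                        fine_mask.astype(np.float32)) >= 0.5
                masks[name][z] |= _bin_cache[key]
            else:
                masks[name][z] |= _downsample(
                    fine_mask.astype(np.float32)) >= 0.5

    # Degradations (before noise: motion blur; after noise: streaks).
    if spec.artifacts.motion is not None:
        sigma_px = spec.artifacts.motion.blur_mm / row_sp
        for z in range(n_slices):
            hu[z] = ndimage.gaussian_filter1d(hu[z], sigma_px, axis=0)

    if spec.noise_sd_hu > 0:
        hu += _standardized_noise(hu.shape, spec.noise_sd_hu,
                                  (row_sp, col_sp), spec.seed)

    if spec.artifacts.streak is not None:
        hu += _streak_field(hu.shape, (row_sp, col_sp),
                            spec.artifacts.streak, slice_range=(25, 85))

    hu = np.round(hu).astype(np.float32)  # integer HU storage quantization

    vol = CTVolume(hu=hu, spacing_mm=spec.spacing_mm,
                   source_id=f"phantom(seed={spec.seed})")

    truth: Dict[str, object] = {
        "carina_slice": carina,
        "bifurcation_slice": spec.trachea.bifurcation_slice
        if spec.trachea else None,
        "arch_slice": arch,
        "pv_slice": spec.pt.pv_slice if spec.pt else None,
        "aao_diameter_mm": spec.aorta.aao_diameter_mm if spec.aorta else None,
        "dao_diameter_mm": spec.aorta.dao_diameter_mm if spec.aorta else None,
        "pt_diameter_mm": spec.pt.diameter_mm if spec.pt else None,
        "pt_contrast_hu": spec.pt.contrast_hu if spec.pt else None,
        "noise_sd_hu": spec.noise_sd_hu,
        "rotation_deg": spec.rotation_deg,
    }
    return PhantomBundle(volume=vol, truth_masks=masks, truth=truth, spec=spec)


def _downsample_hu(fine_canvas: np.ndarray) -> np.ndarray:
    nr, nc = fine_canvas.shape[0] // _SS, fine_canvas.shape[1] // _SS
    return fine_canvas.reshape(nr, _SS, nc, _SS).mean(axis=(1, 3))


def _standardized_noise(shape, sd_hu: float, spacing: Tuple[float, float],
                        seed: int) -> np.ndarray:
    """Zero-mean noise whose windowed sample SD is uniformly ``sd_hu``.

    White Gaussian noise is standardized per pixel by its local windowed
    mean and SD (window ≈ the diameter of a 1 cm² measurement ROI), so that
    the sample SD inside any ROI-sized neighbourhood matches the nominal
    value closely instead of only in expectation.
    """
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(shape).astype(np.float32)
    k = int(round(11.3 / float(np.mean(spacing))))
    k = max(9, k | 1)
    m = ndimage.uniform_filter(w, size=(1, k, k))
    m2 = ndimage.uniform_filter(w * w, size=(1, k, k))
    s = np.sqrt(np.maximum(m2 - m * m, 1e-12))
    return (sd_hu * (w - m) / s).astype(np.float32)


def _streak_field(shape, spacing, streak: StreakSpec,
                  slice_range: Tuple[int, int],
                  focus_mm: Tuple[float, float] = (-40.0, -40.0)) -> np.ndarray:
    """Alternating bright/dark bands radiating from a dense-contrast focus."""
    n_slices, nrows, ncols = shape
    rows_mm = (np.arange(nrows) - (nrows - 1) / 2.0) * spacing[0]
    cols_mm = (np.arange(ncols) - (ncols - 1) / 2.0) * spacing[1]
    rr, cc = np.meshgrid(rows_mm, cols_mm, indexing="ij")
    dr, dc = rr - focus_mm[0], cc - focus_mm[1]
    phi = np.arctan2(dc, dr)
    dist = np.hypot(dr, dc)
    pattern = (streak.amplitude_hu * np.sign(np.sin(streak.n_bands * phi))
               * np.exp(-dist / 60.0) * (dist > 6.0)).astype(np.float32)
    out = np.zeros(shape, dtype=np.float32)
    out[slice_range[0]:slice_range[1] + 1] = pattern
    return out


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "aao_diameter_mm": (20.0, 40.0),
    "pt_diameter_mm": (18.0, 35.0),
    "contrast_hu": (200.0, 600.0),
    "noise_sd_hu": (5.0, 35.0),
}


def cohort_specs(
    n: int,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    seed: int = 0,
) -> List[PhantomSpec]:
    """``n`` phantom specs Latin-hypercube-sampled over parameter ranges.

    The DAo diameter is tied to the AAo diameter (0.75×, clipped to
    [16, 30] mm) as in adult anatomy. Specs are cheap; render them one at a
    time with :func:`generate` when volumes are only needed transiently.
    """
    from scipy.stats import qmc

    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    keys = sorted(ranges)
    sampler = qmc.LatinHypercube(d=len(keys), seed=seed)
    unit = sampler.random(n)
    lo = np.array([ranges[k][0] for k in keys])
    hi = np.array([ranges[k][1] for k in keys])
    values = lo + unit * (hi - lo)  # degenerate (lo == hi) ranges allowed

    specs = []
    for i in range(n):
        params = dict(zip(keys, values[i]))
        aao = float(params["aao_diameter_mm"])
        dao = float(np.clip(0.75 * aao, 16.0, 30.0))
        specs.append(PhantomSpec(
            aorta=AortaSpec(aao_diameter_mm=aao, dao_diameter_mm=dao,
                            contrast_hu=float(params["contrast_hu"])),
            pt=PTSpec(diameter_mm=float(params["pt_diameter_mm"]),
                      contrast_hu=float(params["contrast_hu"])),
            noise_sd_hu=float(params["noise_sd_hu"]),
            seed=seed + i + 1,
        ))
    return specs


def generate_cohort(
    n: int,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    seed: int = 0,
) -> Tuple[List[PhantomBundle], "pandas.DataFrame"]:
    """Generate ``n`` phantoms over parameter ranges plus a truth manifest."""
    import pandas as pd

    specs = cohort_specs(n, ranges, seed)
    bundles = [generate(spec) for spec in specs]
    rows = []
    for i, (spec, bundle) in enumerate(zip(specs, bundles)):
        rows.append({
            "index": i,
            "aao_diameter_mm": spec.aorta.aao_diameter_mm,
            "dao_diameter_mm": spec.aorta.dao_diameter_mm,
            "pt_diameter_mm": spec.pt.diameter_mm,
            "contrast_hu": spec.pt.contrast_hu,
            "noise_sd_hu": spec.noise_sd_hu,
            "seed": spec.seed,
        })
    return bundles, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def write_bundle(bundle: PhantomBundle, out_dir: str | Path,
                 format: str = "nifti",
                 slice_order: SliceOrder = SliceOrder.cranial_to_caudal
                 ) -> Dict[str, Path]:
    """Serialize a phantom volume (and truth label mask) to disk.

    ``format`` is ``nifti`` or ``dicom_series``. The DICOM writer emits a
    valid axial CT series (MONOCHROME2, explicit little endian) with correct
    RescaleSlope/Intercept, PixelSpacing and ImagePositionPatient so the
    reader round-trips; ``slice_order`` controls the on-disk direction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    if format == "nifti":
        paths["volume"] = _write_nifti_volume(bundle.volume,
                                              out_dir / "volume.nii.gz")
        label = np.zeros(bundle.volume.hu.shape, dtype=np.uint8)
        for name, value in LABELS.items():
            label[bundle.truth_masks[name]] = value
        paths["labels"] = _write_nifti_labels(label, bundle.volume,
                                              out_dir / "labels.nii.gz")
    elif format == "dicom_series":
        paths["series"] = _write_dicom_series(bundle.volume, out_dir,
                                              slice_order, bundle.spec.seed)
    else:
        raise ValueError(f"unknown format {format!r}")
    return paths


def _ras_affine(vol: CTVolume) -> np.ndarray:
    th, row_sp, col_sp = vol.spacing_mm
    return np.diag([col_sp, row_sp, th, 1.0])


def _write_nifti_volume(vol: CTVolume, path: Path) -> Path:
    import nibabel as nib

    data = np.transpose(vol.hu[::-1, ::-1, ::-1], (2, 1, 0)).astype(np.float32)
    img = nib.Nifti1Image(data, _ras_affine(vol))
    nib.save(img, str(path))
    return path


def _write_nifti_labels(label: np.ndarray, vol: CTVolume, path: Path) -> Path:
    import nibabel as nib

    data = np.transpose(label[::-1, ::-1, ::-1], (2, 1, 0)).astype(np.uint8)
    img = nib.Nifti1Image(data, _ras_affine(vol))
    nib.save(img, str(path))
    return path


_UID_ROOT = "1.2.826.0.1.3680043.9.7433"


def _write_dicom_series(vol: CTVolume, out_dir: Path,
                        slice_order: SliceOrder, seed: int) -> Path:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, CTImageStorage

    n = vol.n_slices
    th, row_sp, col_sp = vol.spacing_mm
    indices = range(n) if slice_order == SliceOrder.cranial_to_caudal \
        else range(n - 1, -1, -1)
    series_uid = f"{_UID_ROOT}.{seed}.1"
    study_uid = f"{_UID_ROOT}.{seed}.0"
    for file_idx, z in enumerate(indices):
        # Intercept -2048 leaves headroom for noisy air below -1024 HU.
        stored = np.clip(np.round(vol.hu[z]) + 2048, 0, 65535).astype(np.uint16)
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = f"{series_uid}.{z + 2}"
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = f"{series_uid}.{z + 2}"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = f"phantom-{seed}"
        ds.InstanceNumber = file_idx + 1
        ds.Rows, ds.Columns = vol.hu.shape[1:]
        ds.PixelSpacing = [f"{row_sp:.6f}", f"{col_sp:.6f}"]
        ds.SliceThickness = f"{th:.6f}"
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        # Slice 0 is most cranial: give it the largest patient z.
        ds.ImagePositionPatient = [0.0, 0.0, float((n - 1 - z) * th)]
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "-2048"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = stored.tobytes()
        ds.save_as(str(out_dir / f"slice_{file_idx:04d}.dcm"),
                   enforce_file_format=True)
    return out_dir
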