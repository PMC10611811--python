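"""CT volume reading and geometry.

The single in-memory representation consumed by every later stage is
:class:`CTVolume`: a 3D Hounsfield-unit array indexed ``(slice, row, col)``
with slice 0 the most cranial slice, plus voxel spacing in mm. Axial
radiological display convention applies throughout the package:

* "anterior" is **decreasing** row index,
* "patient-left" is **increasing** column index.

Readers accept DICOM series directories, NIfTI and NRRD; stored values are
converted to HU with the per-slice rescale slope/intercept and slices are
sorted cranial→caudal regardless of on-disk order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Tuple

import numpy as np

log = logging.getLogger(__name__)

#: Physically plausible HU range after conversion.
HU_MIN, HU_MAX = -1500.0, 4000.0

#: Minimum slice count for pipeline eligibility.
MIN_SLICES = 20

# In-plane anatomical direction unit vectors as (d_row, d_col).
POSTERIOR = (1.0, 0.0)
ANTERIOR = (-1.0, 0.0)
PATIENT_LEFT = (0.0, 1.0)
PATIENT_RIGHT = (0.0, -1.0)


class SliceOrder(str, Enum):
    """Slice order of the source data on disk."""

    cranial_to_caudal = "cranial_to_caudal"
    caudal_to_cranial = "caudal_to_cranial"


@dataclass
class CTVolume:
    """A 3D axial CT volume in Hounsfield units.

    Attributes
    ----------
    hu : ndarray, shape (n_slices, n_rows, n_cols)
        HU values, slice 0 most cranial.
    spacing_mm : (slice_thickness, row_spacing, col_spacing)
    slice_order : SliceOrder
        On-disk acquisition direction (the array itself is always stored
        cranial→caudal).
    origin_mm : 3-vector
        Physical position of voxel (0, 0, 0); informational.
    source_id : str
    """

    hu: np.ndarray
    spacing_mm: Tuple[float, float, float]
    slice_order: SliceOrder = SliceOrder.cranial_to_caudal
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise ValueError("hu array must be 3D (slice, row, col)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm components must be strictly positive")

    @property
    def n_slices(self) -> int:
        return self.hu.shape[0]

    @property
    def slice_thickness_mm(self) -> float:
        return float(self.spacing_mm[0])

    @property
    def in_plane_spacing_mm(self) -> Tuple[float, float]:
        return float(self.spacing_mm[1]), float(self.spacing_mm[2])

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.spacing_mm[1] * self.spacing_mm[2])

    def check_pipeline_eligible(self) -> None:
        """Refuse detection on volumes that cannot contain the anatomy."""
        if self.n_slices < MIN_SLICES:
            raise ValueError(
                f"volume has {self.n_slices} slices; "
                f"at least {MIN_SLICES} required for detection"
            )


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_dir"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise ValueError(f"cannot infer volume format from {path}")


def read_volume(path: str | Path, format_hint: str = "auto") -> CTVolume:
    """Read a CT volume and convert it to HU.

    Parameters
    ----------
    path : path to a DICOM series directory or a NIfTI/NRRD file.
    format_hint : one of ``dicom_dir``, ``nifti``, ``nrrd``, ``auto``.

    Returns
    -------
    CTVolume sorted cranial→caudal, HU = stored·slope + intercept applied
    per slice; ``slice_order`` records the on-disk direction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format_hint == "auto" else format_hint
    if fmt == "dicom_dir":
        return _read_dicom_dir(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "nrrd":
        return _read_nrrd(path)
    raise ValueError(f"unknown format hint {fmt!r}")


def _require_tag(ds, tag_name: str, fname: str):
    value = getattr(ds, tag_name, None)
    if value is None:
        raise ValueError(f"missing required DICOM tag {tag_name} in {fname}")
    return value


def _read_dicom_dir(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append((p, ds))
    if not datasets:
        raise ValueError(f"no DICOM image files found in {path}")

    shapes = {(int(ds.Rows), int(ds.Columns)) for _, ds in datasets}
    if len(shapes) != 1:
        raise ValueError("DICOM slices disagree on matrix size")

    first = datasets[0][1]
    pixel_spacing = _require_tag(first, "PixelSpacing", datasets[0][0].name)
    row_sp, col_sp = float(pixel_spacing[0]), float(pixel_spacing[1])
    spacings = {tuple(float(v) for v in ds.PixelSpacing) for _, ds in datasets
                if hasattr(ds, "PixelSpacing")}
    if len(spacings) != 1:
        raise ValueError("DICOM slices disagree on PixelSpacing")

    iop = _require_tag(first, "ImageOrientationPatient", datasets[0][0].name)
    _check_axial_orientation(np.asarray([float(v) for v in iop]))

    # Sort by the patient z coordinate; larger z is more cranial (superior).
    positions = []
    for p, ds in datasets:
        ipp = _require_tag(ds, "ImagePositionPatient", p.name)
        positions.append(float(ipp[2]))
    order = np.argsort(positions)[::-1]  # descending z = cranial first
    on_disk_cranial_first = positions[0] >= positions[-1]
    slice_order = (SliceOrder.cranial_to_caudal if on_disk_cranial_first
                   else SliceOrder.caudal_to_cranial)

    zs = np.sort(np.asarray(positions))
    if len(zs) > 1:
        gaps = np.diff(zs)
        thickness = float(np.median(gaps))
        if thickness <= 0:
            raise ValueError("duplicate or non-monotonic slice positions")
        if np.any(np.abs(gaps - thickness) > 0.10 * thickness):
            raise ValueError(
                "inconsistent inter-slice spacing beyond 10% tolerance")
    else:
        thickness = float(getattr(first, "SliceThickness", 0) or 0)
        if thickness <= 0:
            raise ValueError("missing SliceThickness for single-slice series")

    slices = []
    for idx in order:
        p, ds = datasets[idx]
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = getattr(ds, "RescaleIntercept", None)
        if intercept is None:
            log.warning("RescaleSlope/Intercept missing in %s; assuming 1/0",
                        p.name)
            intercept = 0.0
        arr = ds.pixel_array.astype(np.float32) * slope + float(intercept)
        slices.append(arr)
    hu = np.stack(slices, axis=0)

    top = datasets[order[0]][1]
    ipp = [float(v) for v in top.ImagePositionPatient]
    return CTVolume(
        hu=hu,
        spacing_mm=(thickness, row_sp, col_sp),
        slice_order=slice_order,
        origin_mm=(ipp[0], ipp[1], ipp[2]),
        source_id=str(path),
    )


def _check_axial_orientation(iop: np.ndarray, tolerance_deg: float = 5.0) -> None:
    """Row/col direction cosines must be within tolerance of the axial axes."""
    row_dir, col_dir = iop[:3], iop[3:]
    # Axial: row cosines along ±x, col cosines along ±y (in patient space the
    # DICOM convention stores (col-direction, row-direction); we only require
    # both in-plane axes to be near the patient x/y plane and orthogonal to z.
    for v in (row_dir, col_dir):
        axis = np.zeros(3)
        axis[int(np.argmax(np.abs(v)))] = np.sign(v[int(np.argmax(np.abs(v)))])
        cosang = float(np.clip(np.dot(v, axis) / np.linalg.norm(v), -1, 1))
        ang = np.degrees(np.arccos(abs(cosang)))
        if ang > tolerance_deg or int(np.argmax(np.abs(v))) == 2:
            raise ValueError("unsupported orientation: non-axial DICOM series")


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)  # RAS+: +x right, +y anterior, +z superior
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ValueError("only 3D NIfTI volumes are supported")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError("missing or invalid NIfTI voxel spacing (pixdim)")
    # Our convention flips every RAS axis: slice 0 is cranial (−z), rows
    # increase posteriorly (−y), columns increase toward patient-left (−x).
    hu = np.transpose(data, (2, 1, 0))[::-1, ::-1, ::-1].copy()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(hu=hu, spacing_mm=spacing, source_id=str(path))


def _read_nrrd(path: Path) -> CTVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(np.abs(direction), np.eye(3), atol=0.1):
        raise ValueError("unsupported orientation: non-axial NRRD volume")
    data = sitk.GetArrayFromImage(img).astype(np.float32)  # (z, y, x), LPS
    if data.ndim != 3:
        raise ValueError("only 3D NRRD volumes are supported")
    sp = img.GetSpacing()  # (x, y, z)
    # LPS: x→patient-left, y→posterior, z→superior. Our col/row match L/P
    # directly; slices must be flipped so index 0 is cranial (superior).
    hu = data[::-1].copy()
    return CTVolume(
        hu=hu,
        spacing_mm=(float(sp[2]), float(sp[1]), float(sp[0])),
        source_id=str(path),
    )


def reformat_to_working_thickness(
    vol: CTVolume, target_thickness_mm: float = 2.0
) -> CTVolume:
    """Reformat along the slice axis to the working slice thickness.

    Each output slice averages the input slices overlapping its
    ``target_thickness_mm`` window, weighted by overlap (mean-preserving; at
    integer thickness ratios this is plain block averaging). The in-plane
    grid is unchanged. An input already at target thickness (±1%) is
    returned unchanged; thicker input raises (no upsampling).
    """
    t_in = vol.slice_thickness_mm
    if abs(t_in - target_thickness_mm) <= 0.01 * target_thickness_mm:
        return vol
    if t_in > target_thickness_mm:
        raise ValueError(
            f"input slice thickness {t_in} mm exceeds target "
            f"{target_thickness_mm} mm; upsampling is not supported"
        )
    n_in = vol.n_slices
    n_out = int(np.floor(n_in * t_in / target_thickness_mm))
    if n_out < 1:
        raise ValueError("volume too short to reformat")
    out = np.empty((n_out,) + vol.hu.shape[1:], dtype=np.float32)
    for j in range(n_out):
        z0, z1 = j * target_thickness_mm, (j + 1) * target_thickness_mm
        i0, i1 = int(np.floor(z0 / t_in)), int(np.ceil(z1 / t_in))
        i1 = min(i1, n_in)
        weights = []
        for i in range(i0, i1):
            lo, hi = i * t_in, (i + 1) * t_in
            weights.append(max(0.0, min(hi, z1) - max(lo, z0)))
        w = np.asarray(weights, dtype=np.float64)
        w /= w.sum()
        out[j] = np.tensordot(w, vol.hu[i0:i1].astype(np.float64), axes=1)
    return replace(
        vol,
        hu=out,
        spacing_mm=(target_thickness_mm, vol.spacing_mm[1], vol.spacing_mm[2]),
    )
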