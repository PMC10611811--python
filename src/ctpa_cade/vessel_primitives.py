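"""Reusable 2D operators of the segmentation chain.

These are the building blocks applied slice-by-slice by the pipeline:
windowed enhancement, hysteresis edge detection, homogeneity-based 2D region
growing with half-maximum boundary refinement, circularity scoring, ray
casting for seed search, and Hough-based circle diameter estimation.

All operators are pure functions of their inputs: reruns are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import feature, measure, transform


# --------------------------------------------------------------------------
# Region container
# --------------------------------------------------------------------------

@dataclass
class Region2D:
    """A segmented in-plane region with its shape statistics.

    ``area_mm2`` counts pixels times pixel area; ``equivalent_diameter_mm``
    is the diameter of the circle of equal area; ``circularity`` is
    4π·area/perimeter² computed on the outer contour polygon, clipped to
    [0, 1] (1 = perfect disc).
    """

    mask: np.ndarray
    slice_index: int
    centroid: Tuple[float, float]
    area_mm2: float
    equivalent_diameter_mm: float
    circularity: float
    mean_hu: float
    overgrown: bool = False

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def make_region(
    mask: np.ndarray,
    slice_hu: np.ndarray,
    slice_index: int,
    spacing: Tuple[float, float],
    overgrown: bool = False,
) -> Region2D:
    """Assemble a :class:`Region2D` with statistics from a binary mask."""
    mask = mask.astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty region")
    rows, cols = np.nonzero(mask)
    pixel_area = spacing[0] * spacing[1]
    area = n * pixel_area
    return Region2D(
        mask=mask,
        slice_index=slice_index,
        centroid=(float(rows.mean()), float(cols.mean())),
        area_mm2=float(area),
        equivalent_diameter_mm=float(2.0 * math.sqrt(area / math.pi)),
        circularity=circularity_of_mask(mask, spacing),
        mean_hu=float(slice_hu[mask].mean()),
        overgrown=overgrown,
    )


# --------------------------------------------------------------------------
# Circularity
# --------------------------------------------------------------------------

def circularity_of_mask(mask: np.ndarray, spacing: Tuple[float, float] = (1.0, 1.0)) -> float:
    """Shape compactness 4π·area/perimeter² of the outer contour, in [0, 1].

    Both the perimeter and the area are taken from the marching-squares
    outer contour polygon (sub-pixel, at the 0.5 iso-level), lightly
    smoothed along the contour so pixel staircasing does not inflate the
    perimeter. Using the polygon area rather than the pixel count keeps the
    estimator consistent: a rasterized square scores ≈ π/4 and a large disc
    ≈ 1.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty region")
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return 0.0
    # Outer contour = the longest one; scale vertices to mm.
    scale = np.asarray(spacing, dtype=float)
    best_area, best_perim = 0.0, 0.0
    for contour in contours:
        pts = _smooth_closed_contour(contour) * scale
        d = np.diff(pts, axis=0)
        perim = float(np.sqrt((d ** 2).sum(axis=1)).sum())
        x, y = pts[:, 1], pts[:, 0]
        area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
        if area > best_area:
            best_area, best_perim = area, perim
    if best_perim <= 0:
        return 0.0
    return float(np.clip(4.0 * math.pi * best_area / best_perim ** 2, 0.0, 1.0))


def _smooth_closed_contour(contour: np.ndarray, window: int = 3) -> np.ndarray:
    """Cyclic moving average of a closed marching-squares contour.

    Removes the half-pixel staircase so the polygon length approximates the
    true boundary length; a window of a few vertices barely rounds genuine
    corners (a square keeps ≈ 4s perimeter)."""
    pts = contour[:-1] if len(contour) > 1 \
        and np.allclose(contour[0], contour[-1]) else contour
    n = len(pts)
    if n < window + 2:
        return contour
    kernel = np.ones(window) / window
    smoothed = np.column_stack([
        np.convolve(np.concatenate([pts[-(window // 2):, k], pts[:, k],
                                    pts[:window // 2, k]]),
                    kernel, mode="valid")
        for k in range(2)])
    return np.vstack([smoothed, smoothed[:1]])


def circularity(region: Region2D) -> float:
    """Circularity of a segmented region (see :func:`circularity_of_mask`)."""
    return region.circularity


# --------------------------------------------------------------------------
# Enhancement + edges
# --------------------------------------------------------------------------

def enhance_and_edge(
    slice_hu: np.ndarray,
    contrast_window: Tuple[float, float],
    body_mask: Optional[np.ndarray] = None,
    sigma_px: float = 1.0,
    percentiles: Tuple[float, float] = (70.0, 90.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Window/rescale a slice and detect edges by hysteresis thresholding.

    ``enhanced`` is the HU image clipped to ``contrast_window`` and rescaled
    to [0, 1]. Edges come from a Canny detector (Gaussian-smoothed gradient
    magnitude, non-maximum suppression, hysteresis linking) with the low and
    high thresholds at the given gradient-magnitude quantiles inside
    ``body_mask`` (whole image when no mask is given). A constant slice
    yields an empty edge map.
    """
    lo, hi = contrast_window
    if lo >= hi:
        raise ValueError("contrast window must satisfy lo < hi")
    img = np.clip(slice_hu.astype(np.float64), lo, hi)
    enhanced = (img - lo) / (hi - lo)

    arr = slice_hu.astype(np.float64)
    span = float(arr.max() - arr.min())
    if span <= 0:
        return enhanced, np.zeros(arr.shape, dtype=bool)
    norm = (arr - arr.min()) / span
    mask = body_mask.astype(bool) if body_mask is not None else None
    edges = feature.canny(
        norm, sigma=sigma_px,
        low_threshold=percentiles[0] / 100.0,
        high_threshold=percentiles[1] / 100.0,
        use_quantiles=True, mask=mask)
    return enhanced, edges


# --------------------------------------------------------------------------
# Region growing
# --------------------------------------------------------------------------

def region_grow_2d(
    slice_hu: np.ndarray,
    seed: Tuple[int, int],
    hu_tolerance: float,
    max_area_mm2: float,
    spacing: Tuple[float, float],
    edges: Optional[np.ndarray] = None,
    hu_range: Tuple[float, float] = (150.0, 1200.0),
    slice_index: int = 0,
) -> Region2D:
    """Grow a homogeneous 8-connected region from a seed pixel.

    The growth criterion is |HU − region mean| ≤ ``hu_tolerance``; it is
    evaluated as a deterministic fixed point (the connected component of the
    thresholded homogeneity image containing the seed, with the mean updated
    each iteration), which makes the result independent of any pixel visit
    order. Growth never crosses ``edges`` pixels; interior holes (noise or
    edge pixels) are filled. If the region exceeds ``max_area_mm2`` it is
    returned flagged ``overgrown`` and callers treat it as a failure.
    """
    r, c = int(seed[0]), int(seed[1])
    nrows, ncols = slice_hu.shape
    if not (0 <= r < nrows and 0 <= c < ncols):
        raise ValueError("invalid seed: outside image")
    seed_hu = float(slice_hu[r, c])
    if not (hu_range[0] <= seed_hu <= hu_range[1]):
        raise ValueError(
            f"invalid seed: HU {seed_hu:.0f} outside contrast range {hu_range}")
    if edges is not None and edges[r, c]:
        raise ValueError("invalid seed: on an edge pixel")

    pixel_area = spacing[0] * spacing[1]
    max_px = max(1, int(max_area_mm2 / pixel_area))
    # Crop a window generously larger than the largest admissible region.
    half = int(2.0 * math.sqrt(max_area_mm2 / math.pi) / min(spacing)) + 8
    r0, r1 = max(0, r - half), min(nrows, r + half + 1)
    c0, c1 = max(0, c - half), min(ncols, c + half + 1)
    win = slice_hu[r0:r1, c0:c1].astype(np.float64)
    win_edges = edges[r0:r1, c0:c1] if edges is not None else None
    sr, sc = r - r0, c - c0

    structure = np.ones((3, 3), dtype=bool)
    mean = seed_hu
    region = None
    overgrown = False
    for _ in range(25):
        cand = np.abs(win - mean) <= hu_tolerance
        if win_edges is not None:
            cand &= ~win_edges
        cand[sr, sc] = True
        labels, _ = ndimage.label(cand, structure=structure)
        new_region = labels == labels[sr, sc]
        new_region = ndimage.binary_fill_holes(new_region)
        if new_region.sum() > max_px:
            region = new_region
            overgrown = True
            break
        new_mean = float(win[new_region].mean())
        if region is not None and np.array_equal(new_region, region):
            break
        region, mean = new_region, new_mean

    full = np.zeros_like(slice_hu, dtype=bool)
    full[r0:r1, c0:c1] = region
    return make_region(full, slice_hu, slice_index, spacing, overgrown=overgrown)


def refine_half_max(
    slice_hu: np.ndarray,
    region: Region2D,
    spacing: Tuple[float, float],
    ring_px: int = 9,
    ring_gap_px: int = 4,
    max_shift_px: int = 3,
) -> Region2D:
    """Half-maximum boundary refinement of a grown vessel region.

    Re-thresholds the neighbourhood of a region at the midpoint between the
    region's core mean HU and the median HU of a surrounding background
    ring, then keeps the connected component overlapping the original
    region. This places the boundary at 50% intensity, making area and
    diameter estimates unbiased with respect to the vessel-to-background
    contrast. The ring starts ``ring_gap_px`` outside the grown mask so a
    slightly under-grown boundary (edge-blocked growth) cannot contaminate
    the background estimate; the core mean (eroded mask) symmetrically
    avoids rim dilution.
    """
    mask = region.mask
    dil = ndimage.binary_dilation(mask, iterations=ring_px)
    ring = dil & ~ndimage.binary_dilation(mask, iterations=ring_gap_px)
    if not ring.any():
        return region
    core = ndimage.binary_erosion(mask, iterations=2)
    core_mean = float(slice_hu[core].mean()) if core.any() else region.mean_hu
    background = float(np.median(slice_hu[ring]))
    tau = 0.5 * (core_mean + background)
    allowed = ndimage.binary_dilation(mask, iterations=max_shift_px)
    cand = (slice_hu >= tau) & allowed
    labels, _ = ndimage.label(cand, structure=np.ones((3, 3)))
    overlap = labels[mask]
    overlap = overlap[overlap > 0]
    if overlap.size == 0:
        return region
    keep = np.bincount(overlap).argmax()
    refined = ndimage.binary_fill_holes(labels == keep)
    return make_region(refined, slice_hu, region.slice_index, spacing,
                       overgrown=region.overgrown)


# --------------------------------------------------------------------------
# Ray casting
# --------------------------------------------------------------------------

@dataclass
class RaySearchSpace:
    """A fan of rays probing for a contrast-filled structure.

    ``origin`` is in pixel coordinates (row, col); ``directions`` are unit
    vectors in mm space (d_row, d_col). A direction scores a hit when the
    ray, walked out to ``max_length_mm``, enters ``hu_range`` and stays
    in-range for at least ``min_connected_mm``.
    """

    origin: Tuple[float, float]
    directions: List[Tuple[float, float]]
    max_length_mm: float
    hu_range: Tuple[float, float]
    min_connected_mm: float

    def __post_init__(self) -> None:
        if not self.directions:
            raise ValueError("directions must be non-empty")
        if self.max_length_mm <= 0:
            raise ValueError("max_length_mm must be positive")


@dataclass
class RayHit:
    direction: Tuple[float, float]
    first_hit_point: Tuple[float, float]   # pixel coords (row, col)
    connected_run_mm: float
    midpoint: Tuple[float, float]          # pixel coords of run midpoint


def fan_directions(center_dir: Tuple[float, float], half_angle_deg: float,
                   step_deg: float) -> List[Tuple[float, float]]:
    """Unit directions spanning ±half_angle around a central direction."""
    base = math.atan2(center_dir[1], center_dir[0])
    n = int(round(half_angle_deg / step_deg))
    out = []
    for k in range(-n, n + 1):
        a = base + math.radians(k * step_deg)
        out.append((math.cos(a), math.sin(a)))
    return out


def cast_rays(space: RaySearchSpace, slice_hu: np.ndarray,
              spacing: Tuple[float, float]) -> List[RayHit]:
    """Walk each ray and report first in-range entries with their run length.

    Sampling is bilinear at half-pixel steps; an empty hit list is a valid
    result (nothing in range along any ray).
    """
    lo, hi = space.hu_range
    step_mm = 0.5 * min(spacing)
    # The first hit must occur within max_length_mm, but a run that starts
    # near the end of the ray is allowed to complete: the search length
    # bounds where the structure may begin, not how wide it is.
    n_steps = int((space.max_length_mm + space.min_connected_mm + 5.0)
                  / step_mm)
    hits: List[RayHit] = []
    nrows, ncols = slice_hu.shape
    for d in space.directions:
        t = np.arange(1, n_steps + 1) * step_mm
        rr = space.origin[0] + t * d[0] / spacing[0]
        cc = space.origin[1] + t * d[1] / spacing[1]
        inside = (rr >= 0) & (rr <= nrows - 1) & (cc >= 0) & (cc <= ncols - 1)
        if not inside.any():
            continue
        rr, cc, t = rr[inside], cc[inside], t[inside]
        vals = ndimage.map_coordinates(slice_hu, [rr, cc], order=1)
        in_range = (vals >= lo) & (vals <= hi)
        if not in_range.any() or t[np.argmax(in_range)] > space.max_length_mm:
            continue
        first = int(np.argmax(in_range))
        run_end = first
        while run_end + 1 < len(in_range) and in_range[run_end + 1]:
            run_end += 1
        run_mm = float(t[run_end] - t[first] + step_mm)
        if run_mm >= space.min_connected_mm:
            mid = (first + run_end) // 2
            hits.append(RayHit(
                direction=d,
                first_hit_point=(float(rr[first]), float(cc[first])),
                connected_run_mm=run_mm,
                midpoint=(float(rr[mid]), float(cc[mid])),
            ))
    return hits


# --------------------------------------------------------------------------
# Hough circle diameter
# --------------------------------------------------------------------------

def hough_circle_diameter(
    image: np.ndarray,
    radius_range_mm: Tuple[float, float],
    spacing: Tuple[float, float],
    roi: Optional[Tuple[int, int, int, int]] = None,
    score_floor: float = 0.25,
) -> Optional[Tuple[Tuple[float, float], float, float]]:
    """Estimate a circle diameter by circular Hough transform.

    ``image`` is either an HU slice (edges are computed by a Canny detector
    on the normalized crop) or a boolean edge map. ``roi`` is an optional
    bounding box (r0, c0, r1, c1) restricting the search. Returns
    ``((row, col) center in full-image pixels, diameter_mm, score)`` for the
    best-scoring circle, with parabolic sub-pixel interpolation over the
    radius axis, or ``None`` when no accumulator peak reaches
    ``score_floor`` (soft failure for that slice).
    """
    rmin_mm, rmax_mm = radius_range_mm
    if rmin_mm >= rmax_mm:
        raise ValueError("radius range must satisfy rmin < rmax")
    px = float(np.mean(spacing))
    if roi is not None:
        r0, c0, r1, c1 = roi
        r0, c0 = max(0, r0), max(0, c0)
        crop = image[r0:r1, c0:c1]
    else:
        r0 = c0 = 0
        crop = image
    if crop.size == 0:
        return None
    if crop.dtype == bool:
        edges = crop
    else:
        arr = crop.astype(np.float64)
        span = arr.max() - arr.min()
        if span <= 0:
            return None
        norm = (arr - arr.min()) / span
        edges = feature.canny(norm, sigma=1.0)
    if not edges.any():
        return None
    rmin_px = max(2, int(math.floor(rmin_mm / px)))
    rmax_px = max(rmin_px + 1, int(math.ceil(rmax_mm / px)))
    radii = np.arange(rmin_px, rmax_px + 1)
    # skimage normalizes the accumulator per radius (votes / circumference),
    # so peak values are the fraction of the circle supported by edges.
    scores = transform.hough_circle(edges, radii)
    flat = int(np.argmax(scores))
    ri, rr, cc = np.unravel_index(flat, scores.shape)
    score = float(scores[ri, rr, cc])
    if score < score_floor:
        return None
    # Parabolic interpolation along the radius axis at the peak position.
    r_best = float(radii[ri])
    if 0 < ri < len(radii) - 1:
        y0, y1, y2 = (float(scores[ri - 1, rr, cc]),
                      float(scores[ri, rr, cc]),
                      float(scores[ri + 1, rr, cc]))
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            r_best += 0.5 * (y0 - y2) / denom
    center = (float(rr + r0), float(cc + c0))
    return center, 2.0 * r_best * px, score
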