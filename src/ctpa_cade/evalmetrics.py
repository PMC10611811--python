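"""Segmentation and measurement agreement metrics.

Dice overlap, Boundary F1 (contour matching within a distance tolerance),
Pearson correlation and Bland–Altman limits of agreement (absolute and
percentage), as used to validate segmentations and paired measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage


@dataclass
class AgreementSummary:
    """Bland–Altman / correlation summary of paired measurements.

    ``loa_low``/``loa_high`` are mean difference ± 1.96·SD of differences;
    percentage differences use the pairwise mean as denominator. ``pearson_r``
    is None for constant input (undefined) or n < 3.
    """

    n: int
    pearson_r: Optional[float]
    mean_diff: float
    loa_low: float
    loa_high: float
    mean_pct_diff: Optional[float] = None
    pct_loa: Optional[Tuple[float, float]] = None


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks score 1.0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def _boundary_2d(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one background 4-neighbour in-plane."""
    if not mask.any():
        return np.zeros_like(mask)
    eroded = ndimage.binary_erosion(
        mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
        border_value=0)
    return mask & ~eroded


def boundary_f1(a: np.ndarray, b: np.ndarray, tolerance_mm: float,
                spacing: Tuple[float, float] = (1.0, 1.0)) -> float:
    """Boundary F1: harmonic mean of boundary precision and recall.

    Precision is the fraction of A's boundary voxels lying within
    ``tolerance_mm`` of B's boundary (recall symmetric); boundaries and
    distances are in-plane, pooled over all slices containing boundary.
    2D masks are treated as single slices. Both boundaries empty → 1.0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim == 2:
        a, b = a[None], b[None]
    total_a = total_b = hit_a = hit_b = 0
    for z in range(a.shape[0]):
        ba, bb = _boundary_2d(a[z]), _boundary_2d(b[z])
        na, nb = int(ba.sum()), int(bb.sum())
        if na == 0 and nb == 0:
            continue
        total_a += na
        total_b += nb
        if na and nb:
            # Distance (mm) to the other boundary via EDT of its complement.
            dist_to_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
            dist_to_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
            hit_a += int((dist_to_b[ba] <= tolerance_mm).sum())
            hit_b += int((dist_to_a[bb] <= tolerance_mm).sum())
    if total_a == 0 and total_b == 0:
        return 1.0
    if total_a == 0 or total_b == 0:
        return 0.0
    precision = hit_a / total_a
    recall = hit_b / total_b
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def bland_altman(x: Sequence[float], y: Sequence[float],
                 percentage: bool = True) -> AgreementSummary:
    """Bland–Altman agreement of paired measurements x vs y.

    Differences are d = x − y; limits of agreement are mean ± 1.96·SD
    (sample SD, ddof=1). In percentage mode each difference is additionally
    expressed as 100·(x − y)/mean(x, y) per pair. Pearson r of (x, y) is
    included when defined (n ≥ 3, non-constant).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch between paired value arrays")
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("paired values must be finite")
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)
    r: Optional[float] = None
    if x.size >= 3 and x.std() > 0 and y.std() > 0:
        from scipy.stats import pearsonr
        r = float(pearsonr(x, y).statistic)
    mean_pct = pct_loa = None
    if percentage:
        pair_mean = (x + y) / 2.0
        if np.any(pair_mean == 0):
            raise ValueError("pairwise mean of 0 in percentage mode")
        pd = 100.0 * d / pair_mean
        mean_pct = float(pd.mean())
        psd = float(pd.std(ddof=1))
        pct_loa = (mean_pct - 1.96 * psd, mean_pct + 1.96 * psd)
    return AgreementSummary(
        n=int(x.size), pearson_r=r, mean_diff=mean_diff,
        loa_low=float(loa[0]), loa_high=float(loa[1]),
        mean_pct_diff=mean_pct, pct_loa=pct_loa,
    )
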