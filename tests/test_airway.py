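"""Trachea detection, bifurcation tracking and the 0.75 cm carina rule."""

import numpy as np
import pytest
from scipy import ndimage

from ctpa_cade.airway import (detect_airway, extract_candidate_volumes,
                              interior_air_mask, locate_carina,
                              track_to_bifurcation)
from ctpa_cade.config import AirwayConfig
from ctpa_cade.phantom import PhantomSpec, generate
from ctpa_cade.volume_io import CTVolume
from ctpa_cade.evalmetrics import dice


class TestCandidateVolumes:
    def _dummy(self, n):
        return CTVolume(hu=np.full((n, 32, 32), 40.0),
                        spacing_mm=(2.0, 0.7, 0.7))

    def test_default_fractions_on_150_slices(self):
        upper, lower = extract_candidate_volumes(self._dummy(150))
        assert (upper.slice_start, upper.vol.n_slices) == (0, 22)
        assert (lower.slice_start, lower.vol.n_slices) == (22, 30)

    def test_minimum_size_volume(self):
        upper, lower = extract_candidate_volumes(self._dummy(20))
        assert upper.vol.n_slices == 3
        assert lower.vol.n_slices == 4

    def test_no_body_voxels_raises(self):
        vol = CTVolume(hu=np.full((30, 32, 32), -1000.0),
                       spacing_mm=(2.0, 0.7, 0.7))
        with pytest.raises(ValueError, match="empty body bounding box"):
            extract_candidate_volumes(vol)


class TestTracheaSelection:
    def test_clean_phantom_trachea_dice(self, default_bundle, default_result):
        seg = default_result.segmentations["trachea"]
        assert seg.detected
        assert dice(seg.mask, default_bundle.truth_masks["trachea"]) >= 0.95

    def test_narrow_esophageal_air_is_rejected(self):
        bundle = generate(PhantomSpec(esophagus_air_diameter_mm=6.0,
                                      noise_sd_hu=10.0, seed=13))
        res = detect_airway(bundle.volume)
        assert res.detected
        # The selected lumen is the 18 mm trachea, not the 6 mm tube:
        # the esophagus sits 16 mm posterior of the tracheal axis.
        z = 30
        rows, cols = np.nonzero(res.trachea_mask[z])
        truth_rows, _ = np.nonzero(bundle.truth_masks["trachea"][z])
        assert abs(rows.mean() - truth_rows.mean()) < 3

    def test_absent_trachea_is_soft_failure(self):
        bundle = generate(PhantomSpec(trachea=None, noise_sd_hu=10.0, seed=13))
        res = detect_airway(bundle.volume)
        assert not res.detected
        assert res.failure_stage == "trachea"


class TestBifurcationTracking:
    def test_phantom_bifurcation_level(self, default_bundle, default_result):
        truth = default_bundle.truth["bifurcation_slice"]
        assert abs(default_result.landmarks.bifurcation_slice - truth) <= 1

    def test_straight_tube_never_bifurcates(self):
        hu = np.full((30, 64, 64), 40.0, dtype=np.float32)
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        tube = (rr - 32) ** 2 + (cc - 32) ** 2 <= 10 ** 2
        hu[:, tube] = -1000.0
        vol = CTVolume(hu=hu, spacing_mm=(2.0, 0.7, 0.7))
        mask = np.zeros(hu.shape, bool)
        mask[:5] = tube
        bif, _ = track_to_bifurcation(vol, mask)
        assert bif is None

    def test_immediate_y_detects_first_split_slice(self):
        hu = np.full((20, 64, 64), 40.0, dtype=np.float32)
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        tube = (rr - 32) ** 2 + (cc - 32) ** 2 <= 8 ** 2
        left = (rr - 32) ** 2 + (cc - 42) ** 2 <= 5 ** 2
        right = (rr - 32) ** 2 + (cc - 22) ** 2 <= 5 ** 2
        hu[:10, tube] = -1000.0
        hu[10:, left | right] = -1000.0
        vol = CTVolume(hu=hu, spacing_mm=(2.0, 0.7, 0.7))
        mask = np.zeros(hu.shape, bool)
        mask[:10] = tube
        bif, _ = track_to_bifurcation(vol, mask)
        assert bif == 10


class TestCarinaRule:
    SP = (2.0, 0.5, 0.5)

    def _gap_volume(self, gaps_mm):
        """A tube (slices 0..4) splitting into two bars with exact edge gaps.

        At 0.5 mm pixels a gap of g mm is exactly 2g pixel columns."""
        n = 5 + len(gaps_mm)
        hu = np.full((n, 96, 96), 40.0, dtype=np.float32)
        hu[:5, 40:56, 40:56] = -1000.0
        for i, gap in enumerate(gaps_mm):
            half = int(round(gap / 0.5)) // 2
            rem = int(round(gap / 0.5)) - half
            hu[5 + i, 40:56, 48 - half - 10:48 - half] = -1000.0
            hu[5 + i, 40:56, 48 + rem:48 + rem + 10] = -1000.0
        return CTVolume(hu=hu, spacing_mm=self.SP)

    def test_first_slice_with_gap_strictly_above_rule(self):
        vol = self._gap_volume([2, 4, 6, 8, 10])
        carina, left, right = locate_carina(vol, 5)
        assert carina == 5 + 3  # first gap > 7.5 mm is the 8 mm slice
        assert left[1] > right[1]  # patient-left bronchus has larger column

    def test_gap_of_exactly_rule_distance_is_not_carina(self):
        vol = self._gap_volume([7.5, 7.5, 9.0])
        carina, _, _ = locate_carina(vol, 5)
        assert carina == 5 + 2  # strict inequality: 7.5 mm does not qualify

    def test_separation_never_reached_is_soft_failure(self):
        vol = self._gap_volume([2, 3, 4, 5])
        carina, _, _ = locate_carina(vol, 5)
        assert carina is None

    def test_phantom_carina_matches_analytic_truth(self, default_bundle,
                                                   default_result):
        assert default_result.landmarks.carina_slice == \
            default_bundle.truth["carina_slice"]

    def test_rule_is_invariant_to_pixel_spacing(self):
        # The same 8 mm gap expressed on a finer grid: the decision must not
        # change (distances are computed in mm, not pixels).
        for px in (0.5, 0.25):
            n_half = int(round(8.0 / px)) // 2
            hu = np.full((8, int(48 / px), int(48 / px)), 40.0,
                         dtype=np.float32)
            mid = hu.shape[2] // 2
            tube_half = int(round(10.0 / px))  # wide enough to touch both bars
            hu[:2, 10:30, mid - tube_half:mid + tube_half] = -1000.0
            width = int(round(5.0 / px))
            hu[2:, 10:30, mid - n_half - width:mid - n_half] = -1000.0
            hu[2:, 10:30, mid + n_half:mid + n_half + width] = -1000.0
            vol = CTVolume(hu=hu, spacing_mm=(2.0, px, px))
            carina, _, _ = locate_carina(vol, 2)
            assert carina == 2


class TestConnectedComponents:
    def test_labeling_matches_flood_fill_oracle(self):
        """3D 26-connected labeling vs a hand-rolled BFS on random volumes."""
        rng = np.random.default_rng(3)
        structure = np.ones((3, 3, 3), bool)
        for _ in range(5):
            vol = rng.random((12, 12, 12)) > 0.7
            labels, n = ndimage.label(vol, structure=structure)
            # Brute-force flood fill.
            seen = np.zeros_like(vol, dtype=int)
            next_label = 0
            offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
                       for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
            for idx in np.argwhere(vol):
                if seen[tuple(idx)]:
                    continue
                next_label += 1
                stack = [tuple(idx)]
                seen[tuple(idx)] = next_label
                while stack:
                    p = stack.pop()
                    for off in offsets:
                        q = tuple(np.add(p, off))
                        if all(0 <= q[k] < vol.shape[k] for k in range(3)) \
                                and vol[q] and not seen[q]:
                            seen[q] = next_label
                            stack.append(q)
            assert next_label == n
            # Same partition: component of each voxel matches up to relabeling
            for lbl in range(1, n + 1):
                comp = labels == lbl
                oracle_labels = np.unique(seen[comp])
                assert len(oracle_labels) == 1

    def test_interior_air_keeps_open_cranial_lumen(self, default_bundle):
        air = interior_air_mask(default_bundle.volume.hu, -800.0)
        # The tracheal lumen is open at the first slice but must survive
        # exterior-air removal (only in-plane borders seed the flood fill).
        assert air[0][default_bundle.truth_masks["trachea"][0]].mean() > 0.9
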