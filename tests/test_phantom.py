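"""Generator determinism, truth consistency, noise calibration, round trips."""

import numpy as np
import pytest

from ctpa_cade.measure import circular_roi
from ctpa_cade.phantom import (DEFAULT_RANGES, AortaSpec, PhantomSpec, PTSpec,
                               generate, generate_cohort, write_bundle)
from ctpa_cade.volume_io import read_volume


class TestGenerate:
    def test_truth_echoes_spec_inputs(self, default_bundle):
        t = default_bundle.truth
        assert t["aao_diameter_mm"] == 33.0
        assert t["pt_diameter_mm"] == 27.0
        assert t["pt_contrast_hu"] == 385.0
        assert t["noise_sd_hu"] == 20.0
        assert t["carina_slice"] == t["bifurcation_slice"] + 2

    def test_same_seed_is_bit_identical(self):
        from ctpa_cade.phantom import BodySpec, LungSpec

        spec = PhantomSpec(matrix=(30, 128, 128), trachea=None, aorta=None,
                           pt=None, seed=21,
                           body=BodySpec(semi_axes_mm=(30.0, 38.0)),
                           lungs=LungSpec(center_col_mm=20.0,
                                          semi_axes_mm=(12.0, 8.0)))
        a = generate(spec)
        b = generate(spec)
        np.testing.assert_array_equal(a.volume.hu, b.volume.hu)

    def test_noise_free_volume_is_piecewise_constant(self, noisefree_bundle):
        hu = noisefree_bundle.volume.hu
        dao = noisefree_bundle.truth_masks["dao"]
        z = int(np.nonzero(dao.any(axis=(1, 2)))[0][len(dao) // 8])
        from scipy import ndimage
        interior = ndimage.binary_erosion(dao[z], iterations=3)
        assert float(hu[z][interior].std()) == 0.0

    def test_roi_noise_sd_matches_nominal_within_ten_percent(self):
        for sd, seed in ((5.0, 2), (20.0, 3), (35.0, 4)):
            bundle = generate(PhantomSpec(noise_sd_hu=sd, seed=seed))
            dao = bundle.truth_masks["dao"]
            z = int(np.median(np.nonzero(dao.any(axis=(1, 2)))[0]))
            rows, cols = np.nonzero(dao[z])
            roi = circular_roi((rows.mean(), cols.mean()), 1.0, (0.7, 0.7),
                               dao[z].shape)
            measured = float(bundle.volume.hu[z][roi].std())
            assert abs(measured - sd) <= 0.10 * sd

    def test_rendered_mask_diameters_match_request_within_one_voxel(
            self, noisefree_bundle):
        import math
        masks = noisefree_bundle.truth_masks
        t = noisefree_bundle.truth
        z = t["carina_slice"]
        for name, true_d in (("dao", t["dao_diameter_mm"]),
                             ("aao", t["aao_diameter_mm"])):
            area = masks[name][z].sum() * 0.49
            d = 2 * math.sqrt(area / math.pi)
            assert abs(d - true_d) <= 0.7
        # PT is circular below the pulmonary valve.
        area = masks["pt"][t["pv_slice"] + 2].sum() * 0.49
        assert abs(2 * math.sqrt(area / math.pi) - t["pt_diameter_mm"]) <= 0.7

    def test_geometric_premises_of_the_chain(self, default_bundle):
        t = default_bundle.truth
        masks = default_bundle.truth_masks
        z = t["carina_slice"]
        dao_rows, dao_cols = np.nonzero(masks["dao"][z])
        aao_rows, aao_cols = np.nonzero(masks["aao"][z])
        pt_rows, pt_cols = np.nonzero(masks["pt"][z])
        # DAo posterior (larger row) to the airway; PT left (larger col) of AAo
        assert dao_rows.mean() > aao_rows.mean()
        assert pt_cols.mean() > aao_cols.mean()
        assert t["arch_slice"] < t["carina_slice"] < t["pv_slice"]

    def test_colliding_geometry_rejected(self):
        spec = PhantomSpec(aorta=AortaSpec(dao_center_mm=(10.0, -18.0),
                                           dao_diameter_mm=30.0))
        with pytest.raises(ValueError):
            spec.validate()


class TestCohort:
    def test_cohort_manifest_and_distinct_specs(self):
        bundles, manifest = generate_cohort(8, seed=9)
        assert len(bundles) == 8 and len(manifest) == 8
        assert manifest["aao_diameter_mm"].nunique() == 8
        for key, (lo, hi) in DEFAULT_RANGES.items():
            assert manifest[key].between(lo, hi).all()

    def test_degenerate_ranges_give_identical_anatomy(self):
        ranges = {k: (v, v) for k, v in
                  [("aao_diameter_mm", 30.0), ("pt_diameter_mm", 25.0),
                   ("contrast_hu", 400.0), ("noise_sd_hu", 10.0)]}
        bundles, _ = generate_cohort(3, ranges=ranges, seed=2)
        masks = [b.truth_masks["aao"] for b in bundles]
        np.testing.assert_array_equal(masks[0], masks[1])
        # Noise differs (per-phantom seeds) but anatomy is identical.
        assert not np.array_equal(bundles[0].volume.hu, bundles[1].volume.hu)

    def test_cohort_size_validation(self):
        with pytest.raises(ValueError):
            generate_cohort(0)


class TestSerialization:
    def test_nifti_round_trip(self, tmp_path):
        from ctpa_cade.phantom import BodySpec, LungSpec

        spec = PhantomSpec(matrix=(24, 96, 96), trachea=None, aorta=None,
                           pt=None, noise_sd_hu=15.0, seed=31,
                           body=BodySpec(semi_axes_mm=(25.0, 28.0)),
                           lungs=LungSpec(center_col_mm=15.0,
                                          semi_axes_mm=(8.0, 5.0)))
        bundle = generate(spec)
        paths = write_bundle(bundle, tmp_path, "nifti")
        vol = read_volume(paths["volume"])
        np.testing.assert_allclose(vol.hu, bundle.volume.hu, atol=1e-3)
        assert vol.spacing_mm == pytest.approx(bundle.volume.spacing_mm)

    def test_label_mask_round_trip(self, tmp_path, default_bundle):
        paths = write_bundle(default_bundle, tmp_path, "nifti")
        lab = read_volume(paths["labels"])
        for name, value in (("trachea", 1), ("dao", 2), ("aao", 3), ("pt", 4)):
            np.testing.assert_array_equal(
                lab.hu == value, default_bundle.truth_masks[name])

    def test_unwritable_target_raises(self, tmp_path, default_bundle):
        # A regular file in the path makes the output directory uncreatable.
        blocker = tmp_path / "blocker"
        blocker.write_text("")
        with pytest.raises((NotADirectoryError, OSError)):
            write_bundle(default_bundle, blocker / "x", "nifti")

    def test_unknown_format_rejected(self, tmp_path, default_bundle):
        with pytest.raises(ValueError, match="unknown format"):
            write_bundle(default_bundle, tmp_path, "mhd")
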