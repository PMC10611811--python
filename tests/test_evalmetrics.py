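"""Dice, Boundary F1 and Bland–Altman against hand computations and
brute-force oracles."""

import math
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctpa_cade.evalmetrics import AgreementSummary, bland_altman, boundary_f1, dice


def _disc(shape, center, radius):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


class TestDice:
    def test_identical_masks(self):
        a = _disc((32, 32), (16, 16), 8)
        assert dice(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:2], b[8:] = True, True
        assert dice(a, b) == 0.0

    def test_shifted_block_hand_count(self):
        # 2x2 block vs 1-px-shifted 2x2 block: overlap 2 -> 2*2/(4+4) = 0.5
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[2:4, 2:4] = True
        b[3:5, 2:4] = True
        assert dice(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        a = np.zeros((5, 5), bool)
        assert dice(a, a) == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    def test_symmetry_and_brute_force_oracle(self):
        # 1000 random instances against the definition computed longhand.
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a = rng.random((8, 8)) > 0.6
            b = rng.random((8, 8)) > 0.6
            inter = sum(1 for i in range(8) for j in range(8)
                        if a[i, j] and b[i, j])
            na = sum(1 for i in range(8) for j in range(8) if a[i, j])
            nb = sum(1 for i in range(8) for j in range(8) if b[i, j])
            expected = 1.0 if na + nb == 0 else 2 * inter / (na + nb)
            assert abs(dice(a, b) - expected) < 1e-12
            assert dice(a, b) == dice(b, a)


class TestBoundaryF1:
    def test_identical_masks(self):
        a = np.zeros((1, 32, 32), bool)
        a[0] = _disc((32, 32), (16, 16), 9)
        assert boundary_f1(a, a, tolerance_mm=1.0) == 1.0

    def test_one_voxel_dilation_within_tolerance(self):
        from scipy import ndimage

        a = _disc((40, 40), (20, 20), 10)
        b = ndimage.binary_dilation(a)
        assert boundary_f1(a, b, tolerance_mm=1.0) == 1.0

    def test_radius_gap_beyond_tolerance_scores_zero(self):
        a = _disc((64, 64), (32, 32), 8)
        b = _disc((64, 64), (32, 32), 16)
        assert boundary_f1(a, b, tolerance_mm=3.0) == 0.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a = rng.random((2, 20, 20)) > 0.5
        b = rng.random((2, 20, 20)) > 0.5
        assert boundary_f1(a, b, 1.5) == pytest.approx(boundary_f1(b, a, 1.5))

    def test_infinite_tolerance_is_one_for_nonempty(self):
        a = _disc((30, 30), (10, 10), 4)
        b = _disc((30, 30), (22, 22), 5)
        assert boundary_f1(a, b, tolerance_mm=1e9) == 1.0

    def test_both_empty_is_one_single_empty_is_zero(self):
        e = np.zeros((20, 20), bool)
        a = _disc((20, 20), (10, 10), 4)
        assert boundary_f1(e, e, 1.0) == 1.0
        assert boundary_f1(a, e, 1.0) == 0.0

    def test_tolerance_respects_spacing(self):
        # A 2-px offset is 1.4 mm at 0.7 mm pixels: inside 1.5 mm tolerance,
        # outside 1.0 mm tolerance.
        a = np.zeros((30, 30), bool)
        b = np.zeros((30, 30), bool)
        a[10:20, 10:20] = True
        b[10:20, 12:22] = True
        assert boundary_f1(a, b, 1.5, spacing=(0.7, 0.7)) == 1.0
        assert boundary_f1(a, b, 1.0, spacing=(0.7, 0.7)) < 1.0


class TestBlandAltman:
    def test_hand_computed_example(self):
        s = bland_altman([10, 20, 30], [11, 19, 33], percentage=False)
        # d = (-1, 1, -3): mean -1, SD 2 -> LoA (-4.92, 2.92)
        assert s.mean_diff == pytest.approx(-1.0)
        assert s.loa_low == pytest.approx(-4.92, abs=1e-9)
        assert s.loa_high == pytest.approx(2.92, abs=1e-9)
        assert s.n == 3

    def test_identical_pairs(self):
        s = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], percentage=False)
        assert s.mean_diff == 0.0
        assert (s.loa_low, s.loa_high) == (0.0, 0.0)
        assert s.pearson_r == pytest.approx(1.0)

    def test_constant_input_has_undefined_r(self):
        s = bland_altman([5.0, 5.0, 5.0], [4.0, 4.0, 4.0], percentage=False)
        assert s.pearson_r is None

    def test_perfectly_linear_r_is_one(self):
        x = np.arange(1.0, 11.0)
        s = bland_altman(x, 2 * x + 3, percentage=False)
        assert s.pearson_r == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2, 3], [1, 2])

    def test_percentage_mode_uses_pairwise_mean(self):
        s = bland_altman([110.0, 90.0], [90.0, 110.0])
        assert s.mean_pct_diff == pytest.approx(0.0)
        # pct diffs (+20, -20): sample SD = sqrt(800) = 28.28
        assert s.pct_loa[1] == pytest.approx(1.96 * math.sqrt(800.0))

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(
        st.floats(min_value=1.0, max_value=1e3),
        st.floats(min_value=1.0, max_value=1e3)), min_size=2, max_size=40))
    def test_brute_force_oracle(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        s = bland_altman(x, y, percentage=True)
        d = [a - b for a, b in pairs]
        mean = sum(d) / len(d)
        sd = (sum((v - mean) ** 2 for v in d) / max(1, len(d) - 1)) ** 0.5
        assert abs(s.mean_diff - mean) < 1e-9
        assert abs(s.loa_low - (mean - 1.96 * sd)) < 1e-9
        assert abs(s.loa_high - (mean + 1.96 * sd)) < 1e-9
        pd = [100 * (a - b) / ((a + b) / 2) for a, b in pairs]
        pmean = sum(pd) / len(pd)
        assert abs(s.mean_pct_diff - pmean) < 1e-9
        assert s.loa_low <= s.mean_diff <= s.loa_high
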