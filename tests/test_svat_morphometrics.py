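"""SVAT morphometry: areas, the three width measures, capillary statistics,
unit conversion, group comparison."""

import numpy as np
import pytest

from svpath import (
    CalibrationScale,
    SVMetrics,
    average_width,
    capillary_metrics,
    compare_groups,
    compute_sv_metrics,
    midline_width,
    min_feret_diameter,
    sv_area,
    to_micrometers,
)
from conftest import brute_force_min_feret, random_blob_mask


def rect_mask(h, w, pad=5):
    mask = np.zeros((h + 2 * pad, w + 2 * pad), bool)
    mask[pad : pad + h, pad : pad + w] = True
    return mask


class TestSvArea:
    def test_filled_rectangle(self):
        assert sv_area(rect_mask(100, 20)) == 2000

    def test_empty_mask(self):
        assert sv_area(np.zeros((10, 10), bool)) == 0

    def test_planted_band_within_two_percent(self, default_patch):
        _, truth = default_patch
        analytic = truth.analytic["band_area"]
        assert abs(sv_area(truth.sv_mask) - analytic) / analytic <= 0.02


class TestMinFeret:
    def test_axis_aligned_rectangle_exact(self):
        assert min_feret_diameter(rect_mask(100, 20)) == pytest.approx(20.0)

    def test_digital_disk_diameter(self):
        rr, cc = np.mgrid[:80, :80]
        disk = (rr - 40) ** 2 + (cc - 40) ** 2 <= 30**2
        assert min_feret_diameter(disk) == pytest.approx(60.0, abs=1.0)

    def test_rotated_rectangle_matches_projection_oracle(self):
        """A 30-degree rectangle: rotating calipers vs 3600-angle brute force."""
        rr, cc = np.mgrid[:120, :120]
        th = np.deg2rad(30)
        u = (rr - 60) * np.cos(th) + (cc - 60) * np.sin(th)
        v = -(rr - 60) * np.sin(th) + (cc - 60) * np.cos(th)
        mask = (np.abs(u) <= 45) & (np.abs(v) <= 12)
        assert min_feret_diameter(mask) == pytest.approx(brute_force_min_feret(mask), abs=0.5)

    def test_random_masks_match_projection_oracle(self):
        rng = np.random.default_rng(9)
        for i in range(20):
            mask = random_blob_mask(rng, convex=bool(i % 2))
            assert min_feret_diameter(mask) == pytest.approx(
                brute_force_min_feret(mask), abs=0.5
            )

    def test_single_pixel_is_one(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert min_feret_diameter(mask) == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            min_feret_diameter(np.zeros((5, 5), bool))

    def test_never_exceeds_bbox_shorter_side_plus_one(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            mask = random_blob_mask(rng)
            rows, cols = np.nonzero(mask)
            shorter = min(np.ptp(rows) + 1, np.ptp(cols) + 1)
            assert min_feret_diameter(mask) <= shorter + 1


class TestMidlineWidth:
    def test_rectangle_midline_is_shorter_side(self):
        assert midline_width(rect_mask(100, 20)) == 20.0

    def test_c_shape_sums_two_limbs(self):
        """A C whose midline crosses two 5-px limbs: w2 sums the runs (10)."""
        mask = np.zeros((40, 30), bool)
        mask[0:40, 0:5] = True  # spine (long side vertical)
        mask[0:5, 0:25] = True  # top arm
        mask[35:40, 0:25] = True  # bottom arm
        mask[:, 10:15] = False
        mask[0:40, 20:25] = True  # second limb crossing the midline row
        # midline row = 19 or 20: crosses spine (5 px) and second limb (5 px)
        assert midline_width(mask) == 10.0
        assert midline_width(mask, per_run_max=True) == 5.0

    def test_single_pixel(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        assert midline_width(mask) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            midline_width(np.zeros((4, 4), bool))


class TestAverageWidth:
    def test_rectangle_exact(self):
        w3, h = average_width(rect_mask(100, 20))
        assert (w3, h) == (20.0, 100.0)

    def test_half_density_halves_width(self):
        mask = np.zeros((100, 20), bool)
        mask[::2, :] = True  # fill alternate rows: density 0.5, bbox 99 x 20
        mask[99, :] = True  # close the box so h = 100
        w3, h = average_width(mask)
        assert h == 100.0
        assert w3 == pytest.approx(mask.sum() / 100.0)
        assert w3 == pytest.approx(10.2)

    def test_planted_band_within_ten_percent(self, default_patch):
        _, truth = default_patch
        w3, _ = average_width(truth.sv_mask)
        w = truth.analytic["band_width"]
        assert abs(w3 - w) / w <= 0.10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_width(np.zeros((4, 4), bool))


class TestRectangleExactness:
    def test_w1_w2_w3_equal_shorter_side_on_random_rectangles(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            h = int(rng.integers(5, 80))
            w = int(rng.integers(5, 80))
            if h == w:
                w += 1
            mask = rect_mask(h, w)
            shorter, longer = sorted((h, w))
            assert min_feret_diameter(mask) == pytest.approx(float(shorter))
            assert midline_width(mask) == float(shorter)
            w3, hh = average_width(mask)
            assert (w3, hh) == (float(shorter), float(longer))


class TestScalingInvariance:
    def test_integer_upscaling_scales_widths_and_areas(self):
        rng = np.random.default_rng(12)
        mask = random_blob_mask(rng, side=48)
        k = 3
        big = np.kron(mask, np.ones((k, k), dtype=bool))
        assert sv_area(big) == k**2 * sv_area(mask)
        w3s, hs = average_width(mask)
        w3b, hb = average_width(big)
        assert hb == pytest.approx(k * hs, abs=1)
        assert w3b == pytest.approx(k * w3s, rel=0.05)
        assert min_feret_diameter(big) == pytest.approx(k * min_feret_diameter(mask), abs=k)


class TestCapillaryMetrics:
    def test_three_rectangles_counted_exactly(self):
        mask = np.zeros((60, 60), bool)
        mask[2:7, 2:12] = True  # 50 px
        mask[20:26, 20:30] = True  # 60 px
        mask[40:47, 40:50] = True  # 70 px
        count, total, mean = capillary_metrics(mask, min_area=10)
        assert (count, total, mean) == (3, 180.0, 60.0)

    def test_empty_mask(self):
        assert capillary_metrics(np.zeros((5, 5), bool)) == (0, 0.0, 0.0)

    def test_touching_components_merge(self):
        mask = np.zeros((20, 40), bool)
        mask[5:15, 5:15] = True
        mask[5:15, 15:25] = True  # shares an edge: one 8-connected component
        count, total, _ = capillary_metrics(mask, min_area=1)
        assert count == 1 and total == 200.0

    def test_diagonal_touch_is_single_component(self):
        mask = np.zeros((4, 4), bool)
        mask[0:2, 0:2] = True
        mask[2:4, 2:4] = True
        count, _, _ = capillary_metrics(mask, min_area=1)
        assert count == 1

    def test_count_invariant_under_translation(self):
        rng = np.random.default_rng(13)
        mask = np.zeros((50, 50), bool)
        mask[5:10, 5:10] = True
        mask[20:28, 20:26] = True
        shifted = np.roll(mask, (7, 11), axis=(0, 1))
        assert capillary_metrics(mask, 1)[0] == capillary_metrics(shifted, 1)[0]


class TestUnitConversion:
    def test_lengths_and_areas_convert(self):
        m = compute_sv_metrics(rect_mask(100, 20), np.zeros((110, 30), bool))
        um = to_micrometers(m, CalibrationScale(2.0, "test"))
        assert um.w3_average == pytest.approx(10.0)
        assert um.sv_area == pytest.approx(500.0)
        assert um.units == "um"
        assert um.cap_count == m.cap_count

    def test_unit_scale_is_identity_up_to_flag(self):
        m = compute_sv_metrics(rect_mask(10, 4), np.zeros((20, 14), bool))
        um = to_micrometers(m, CalibrationScale(1.0, "test"))
        assert um.sv_area == m.sv_area and um.w1_min_feret == m.w1_min_feret
        assert um.units == "um"

    def test_double_conversion_rejected(self):
        m = compute_sv_metrics(rect_mask(10, 4), np.zeros((20, 14), bool))
        um = to_micrometers(m, CalibrationScale(2.0, "test"))
        with pytest.raises(ValueError, match="already"):
            to_micrometers(um, CalibrationScale(2.0, "test"))

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            CalibrationScale(0.0)


class TestCompareGroups:
    def test_identical_groups(self):
        vals = list(np.arange(10.0))
        stat, _ = compare_groups(vals, vals, method="welch_t")
        assert stat == pytest.approx(0.0)
        _, p = compare_groups(vals, vals, method="mann_whitney")
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, 50)
        b = rng.normal(10, 1, 50)  # shifted by 10 SD
        for method in ("welch_t", "mann_whitney"):
            _, p = compare_groups(list(a), list(b), method=method)
            assert p < 0.001

    def test_welch_rejects_single_observation(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0], method="welch_t")

    def test_metric_extracted_from_records(self):
        def row(area):
            return SVMetrics(area, 1.0, 1.0, area, 1.0, 0, 0.0, 0.0, 0.0)

        a = [row(10.0), row(11.0), row(9.0)]
        b = [row(30.0), row(31.0), row(29.0)]
        _, p = compare_groups(a, b, metric_name="sv_area", method="welch_t")
        assert p < 0.01

    def test_missing_metric_rejected(self):
        m = SVMetrics(1.0, 1.0, 1.0, 1.0, 1.0, 0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="missing"):
            compare_groups([m], [m], metric_name="not_a_metric", method="mann_whitney")


class TestMetricsRecord:
    def test_empty_sv_mask_gives_all_zero_row(self):
        m = compute_sv_metrics(np.zeros((8, 8), bool), np.zeros((8, 8), bool))
        assert m.sv_area == m.w1_min_feret == m.w3_average == 0.0
        assert m.cap_count == 0 and m.nuclei_count == 0.0

    def test_defining_identity_enforced(self):
        with pytest.raises(ValueError, match="sv_area"):
            SVMetrics(100.0, 5.0, 5.0, 5.0, 10.0, 0, 0.0, 0.0, 0.0)
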