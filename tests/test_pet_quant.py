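"""Image quantification operators on constructed arrays and phantoms."""

import numpy as np
import pytest

import hypoxiq as hx
from hypoxiq.data_model import DEFAULT_PIXEL_MM


def image(values, units=hx.Units.KBQ_PER_ML, spacing=(4.25, DEFAULT_PIXEL_MM, DEFAULT_PIXEL_MM)):
    return hx.VoxelImage(np.asarray(values, dtype=float), spacing, units)


def full_mask(shape, label=hx.RoiLabel.TUMOR):
    return hx.RoiMask(np.ones(shape, dtype=bool), label)


class TestComputeSuv:
    def test_zero_activity_gives_zero_suv(self):
        suv = hx.compute_suv(image(np.zeros((2, 4, 4))), hx.SuvParams(370, 74))
        assert suv.units is hx.Units.SUV
        assert np.all(suv.values == 0)

    def test_hand_unit_conversion(self):
        # 5 kBq/ml at 370 MBq / 74 kg: 370000 kBq / 74000 g = 5 kBq/g -> SUV 1
        act = image(np.full((1, 2, 2), 5.0))
        suv = hx.compute_suv(act, hx.SuvParams(370, 74))
        assert suv.values == pytest.approx(1.0)

    def test_dose_weight_scale_invariance(self):
        act = image(np.full((1, 2, 2), 7.3))
        a = hx.compute_suv(act, hx.SuvParams(300, 60))
        b = hx.compute_suv(act, hx.SuvParams(600, 120))
        assert a.values == pytest.approx(b.values)

    def test_units_enforced(self):
        suv_img = image(np.ones((1, 2, 2)), hx.Units.SUV)
        with pytest.raises(hx.UnitsError):
            hx.compute_suv(suv_img, hx.SuvParams(370, 74))


class TestIsocontour:
    def test_all_below_threshold_gives_empty_mask(self):
        roi = hx.isocontour_rois(image(np.full((2, 4, 4), 2.0), hx.Units.SUV))
        assert roi.voxel_count == 0
        assert hx.metabolic_volume(roi, image(np.full((2, 4, 4), 2.0), hx.Units.SUV)) == 0

    def test_cuboid_count_matches_brute_force(self):
        vals = np.ones((4, 10, 10))
        vals[1:3, 2:7, 3:8] = 6.0  # 2*5*5 = 50... use 100-voxel cuboid
        vals = np.ones((4, 10, 10))
        vals[0:4, 0:5, 0:5] = 6.0  # 100 voxels
        suv = image(vals, hx.Units.SUV)
        roi = hx.isocontour_rois(suv, threshold=4.0)
        assert roi.voxel_count == int((vals >= 4.0).sum()) == 100

    def test_threshold_is_inclusive_and_defaults_to_four(self):
        vals = np.ones((1, 3, 3))
        vals[0, 1, 1] = 4.0
        roi = hx.isocontour_rois(image(vals, hx.Units.SUV))
        assert roi.voxel_count == 1

    def test_seed_region_restricts_to_connected_component(self):
        vals = np.ones((1, 5, 9))
        vals[0, 1:4, 0:3] = 6.0   # component A
        vals[0, 1:4, 6:9] = 6.0   # component B, disconnected
        suv = image(vals, hx.Units.SUV)
        seed = np.zeros_like(vals, dtype=bool)
        seed[0, 2, 1] = True
        roi = hx.isocontour_rois(suv, seed=hx.RoiMask(seed, hx.RoiLabel.OTHER))
        assert roi.voxel_count == 9


class TestMetabolicVolume:
    def test_arithmetic_from_spacing(self):
        vals = np.zeros((4, 10, 10))
        vals[1, :5, :5] = 6.0  # not used; mask built directly
        img = image(vals, hx.Units.SUV)
        mask = np.zeros_like(vals, dtype=bool)
        mask.flat[:100] = True
        vol = hx.metabolic_volume(hx.RoiMask(mask, hx.RoiLabel.TUMOR), img)
        assert vol == pytest.approx(100 * 4.25 * DEFAULT_PIXEL_MM**2 / 1000.0)
        assert vol == pytest.approx(2.3404, abs=5e-4)

    def test_additivity_over_plane_subsets(self, clean_phantom):
        _, res = clean_phantom
        whole = hx.metabolic_volume(res.tumor_mask, res.fdg_suv)
        m = res.tumor_mask.mask
        top, bottom = m.copy(), m.copy()
        top[8:] = False
        bottom[:8] = False
        parts = sum(
            hx.metabolic_volume(hx.RoiMask(part, hx.RoiLabel.TUMOR), res.fdg_suv)
            for part in (top, bottom)
        )
        assert parts == pytest.approx(whole)

    def test_misaligned_mask_rejected(self):
        img = image(np.zeros((2, 4, 4)), hx.Units.SUV)
        with pytest.raises(ValueError, match="shape"):
            hx.metabolic_volume(full_mask((2, 4, 5)), img)


class TestMaxSuv3x3:
    def test_uniform_roi_returns_the_constant(self):
        suv = image(np.full((3, 8, 8), 2.7), hx.Units.SUV)
        value, _ = hx.max_suv_3x3(suv, full_mask(suv.shape))
        assert value == pytest.approx(2.7)

    def test_single_hot_voxel_averages_over_nine(self):
        vals = np.zeros((1, 7, 7))
        vals[0, 3, 3] = 9.0
        value, plane = hx.max_suv_3x3(image(vals, hx.Units.SUV), full_mask(vals.shape))
        assert value == pytest.approx(1.0)  # 9/9
        assert plane == 0

    def test_returns_plane_of_global_max(self):
        vals = np.zeros((2, 9, 9))
        vals[0, 4, 4] = 3.0 * 9
        vals[1, 4, 4] = 4.2 * 9
        value, plane = hx.max_suv_3x3(image(vals, hx.Units.SUV), full_mask(vals.shape))
        assert value == pytest.approx(4.2)
        assert plane == 1

    def test_edge_window_clipping_modes(self):
        vals = np.zeros((1, 3, 3))
        vals[0, 0, 0] = 9.0
        suv = image(vals, hx.Units.SUV)
        roi = full_mask(vals.shape)
        padded, _ = hx.max_suv_3x3(suv, roi)          # corner window: 9/9
        clipped, _ = hx.max_suv_3x3(suv, roi, clip_at_edge=True)  # 9/4
        assert padded == pytest.approx(1.0)
        assert clipped == pytest.approx(2.25)

    def test_empty_roi_rejected(self):
        suv = image(np.zeros((1, 4, 4)), hx.Units.SUV)
        with pytest.raises(ValueError, match="empty"):
            hx.max_suv_3x3(suv, hx.RoiMask(np.zeros((1, 4, 4), bool), hx.RoiLabel.TUMOR))


class TestTpRatio:
    def test_tissue_equal_plasma_gives_unity(self):
        tp = hx.tp_ratio_map(image(np.full((2, 3, 3), 4.0)), hx.PlasmaReference(4.0))
        assert tp.units is hx.Units.RATIO
        assert np.all(tp.values == 1.0)

    def test_simple_division(self):
        tp = hx.tp_ratio_map(image(np.full((1, 1, 1), 1.86)), hx.PlasmaReference(1.0))
        assert tp.values == pytest.approx(1.86)

    def test_tumor_max_vs_mean(self):
        vals = np.array([[[0.8, 0.9, 1.4]]])
        tp = image(vals, hx.Units.RATIO)
        roi = full_mask(vals.shape)
        assert hx.tumor_tp_ratio(tp, roi) == pytest.approx(1.4)
        assert hx.tumor_tp_ratio(tp, roi, "mean") == pytest.approx(np.mean([0.8, 0.9, 1.4]))

    def test_adding_subthreshold_voxel_never_decreases_max(self):
        vals = np.array([[[0.8, 0.9, 1.4, 0.1]]])
        tp = image(vals, hx.Units.RATIO)
        small = np.array([[[True, True, True, False]]])
        big = np.array([[[True, True, True, True]]])
        assert hx.tumor_tp_ratio(tp, hx.RoiMask(big, hx.RoiLabel.TUMOR)) >= \
            hx.tumor_tp_ratio(tp, hx.RoiMask(small, hx.RoiLabel.TUMOR))

    def test_empty_tumor_rejected(self):
        tp = image(np.ones((1, 2, 2)), hx.Units.RATIO)
        with pytest.raises(ValueError):
            hx.tumor_tp_ratio(tp, hx.RoiMask(np.zeros((1, 2, 2), bool), hx.RoiLabel.TUMOR))


class TestHypoxiaThreshold:
    def test_constant_pool_gives_the_constant(self):
        t = hx.derive_hypoxia_threshold([0.8, 0.8, 0.8])
        assert t.value == pytest.approx(0.8)
        assert t.pool_sd == pytest.approx(0.0, abs=1e-12)

    def test_two_value_hand_computation(self):
        t = hx.derive_hypoxia_threshold([0.5, 0.7])
        assert t.pool_mean == pytest.approx(0.6)
        assert t.pool_sd == pytest.approx(0.1414213562, abs=1e-9)
        assert t.value == pytest.approx(1.0242640687, abs=1e-9)

    def test_matches_two_pass_oracle_on_large_pool(self, rng):
        pool = rng.normal(0.6, 0.11, size=100_000)
        t = hx.derive_hypoxia_threshold(pool)
        mean = sum(pool) / pool.size
        var = sum((v - mean) ** 2 for v in pool) / (pool.size - 1)
        assert t.value == pytest.approx(mean + 3 * var**0.5, rel=1e-12)
        assert t.n_pixels_pooled == 100_000

    def test_pool_of_one_rejected(self):
        with pytest.raises(ValueError):
            hx.derive_hypoxia_threshold([0.9])


class TestFhv:
    def test_counting_three_of_ten(self):
        vals = np.array([[0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 1.2, 1.2, 1.2]])
        tp = image(vals[None, :, :], hx.Units.RATIO)
        assert hx.fractional_hypoxic_volume(tp, full_mask(tp.shape)) == pytest.approx(30.0)

    def test_bounds(self):
        lo = image(np.full((1, 2, 5), 0.1), hx.Units.RATIO)
        hi = image(np.full((1, 2, 5), 2.0), hx.Units.RATIO)
        assert hx.fractional_hypoxic_volume(lo, full_mask(lo.shape)) == 0.0
        assert hx.fractional_hypoxic_volume(hi, full_mask(hi.shape)) == 100.0

    def test_strictly_above_threshold(self):
        vals = np.full((1, 1, 4), 0.93)
        tp = image(vals, hx.Units.RATIO)
        assert hx.fractional_hypoxic_volume(tp, full_mask(tp.shape), 0.93) == 0.0

    def test_plane_relabeling_invariance(self, clean_phantom):
        _, res = clean_phantom
        fhv = hx.fractional_hypoxic_volume(res.tp_image, res.tumor_mask)
        perm = np.random.default_rng(3).permutation(res.tp_image.n_planes)
        tp2 = hx.VoxelImage(res.tp_image.values[perm], res.tp_image.spacing_mm,
                            hx.Units.RATIO)
        mask2 = hx.RoiMask(res.tumor_mask.mask[perm], hx.RoiLabel.TUMOR)
        assert hx.fractional_hypoxic_volume(tp2, mask2) == pytest.approx(fhv)
        assert hx.tumor_tp_ratio(tp2, mask2) == pytest.approx(
            hx.tumor_tp_ratio(res.tp_image, res.tumor_mask))


class TestAutoradiographicFlow:
    def make_curve(self):
        t = np.linspace(0, 300, 301)
        ca = 40.0 * (t / 30.0) * np.exp(1 - t / 30.0)
        return hx.PlasmaReference(1.0, t, ca)

    def test_zero_integral_gives_zero_flow(self):
        assert hx.autoradiographic_flow(0.0, self.make_curve()) == 0.0

    def test_self_inversion_at_physiological_flow(self):
        curve = self.make_curve()
        params = hx.FlowModelParams()
        for f_true in (15.0, 30.0, 60.0):
            a = hx.kety_forward_integral(f_true, curve, params)
            f_hat = hx.autoradiographic_flow(a, curve, params)
            assert f_hat == pytest.approx(f_true, abs=0.3)

    def test_monotone_in_tissue_integral(self):
        curve = self.make_curve()
        params = hx.FlowModelParams()
        a30 = hx.kety_forward_integral(30.0, curve, params)
        a60 = hx.kety_forward_integral(60.0, curve, params)
        assert a60 > a30
        flows = [hx.autoradiographic_flow(a, curve, params)
                 for a in np.linspace(a30, a60, 7)]
        assert all(f2 >= f1 for f1, f2 in zip(flows, flows[1:]))

    def test_out_of_range_error_names_bracket(self):
        curve = self.make_curve()
        with pytest.raises(ValueError, match="outside lookup range"):
            hx.autoradiographic_flow(1e9, curve)

    def test_curve_must_cover_integration_window(self):
        t = np.linspace(0, 100, 101)
        curve = hx.PlasmaReference(1.0, t, np.ones_like(t))
        with pytest.raises(ValueError, match="cover"):
            hx.kety_forward_integral(30.0, curve, hx.FlowModelParams())


class TestThresholdSweeps:
    def test_fhv_non_increasing_in_threshold(self, clean_phantom):
        _, res = clean_phantom
        sweep = [hx.fractional_hypoxic_volume(res.tp_image, res.tumor_mask, th)
                 for th in np.linspace(0.2, 2.0, 19)]
        assert all(b <= a for a, b in zip(sweep, sweep[1:]))

    def test_metabolic_volume_non_increasing_in_suv_threshold(self, clean_phantom):
        _, res = clean_phantom
        vols = []
        for th in np.linspace(1.0, 14.0, 14):
            roi = hx.isocontour_rois(res.fdg_suv, th)
            vols.append(hx.metabolic_volume(roi, res.fdg_suv))
        assert all(b <= a for a, b in zip(vols, vols[1:]))
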