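"""CT mixture fitting, threshold derivation, voxel classification, quantification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from valvequant import (
    CTVolume,
    IntensityMixture,
    ROIMask,
    TissueLabel,
    TissueThresholds,
    classify_voxels,
    derive_thresholds,
    extract_roi_intensities,
    fit_intensity_mixture,
    quantify_tissue,
)
from valvequant.ct import _weighted_density_crossing


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(intensities=np.asarray(values, dtype=float), voxel_spacing=spacing)


class TestExtractRoiIntensities:
    def test_uniform_volume_preserves_count_and_value(self):
        vol = make_volume(np.full((5, 5, 5), 100.0))
        m = np.zeros((5, 5, 5), bool)
        m.ravel()[:50] = True
        sample = extract_roi_intensities(vol, ROIMask(mask=m))
        assert sample.shape == (50,)
        assert np.all(sample == 100.0)

    def test_empty_mask_is_an_error(self):
        vol = make_volume(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            extract_roi_intensities(vol, ROIMask(mask=np.zeros((3, 3, 3), bool)))

    def test_shape_mismatch_is_an_error(self):
        vol = make_volume(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="shape"):
            extract_roi_intensities(vol, ROIMask(mask=np.ones((3, 3, 4), bool)))

    def test_sample_size_matches_phantom_roi(self, small_phantom):
        _, (vol, mask, truth) = small_phantom
        sample = extract_roi_intensities(vol, mask)
        assert sample.size == mask.n_voxels == (truth.label_mask > 0).sum()


class TestFitIntensityMixture:
    def test_single_component_closed_form(self, rng):
        x = rng.normal(50, 12, 500)
        mix = fit_intensity_mixture(x, K=1)
        assert mix.means[0] == pytest.approx(x.mean(), abs=1e-12)
        assert mix.sds[0] == pytest.approx(x.std(), abs=1e-12)  # population SD
        assert mix.converged and mix.K == 1

    def test_two_component_parameter_recovery(self):
        # 10k draws from 0.5 N(90,35) + 0.5 N(420,45): sampling SE < 1 HU
        r = np.random.default_rng(0)
        x = np.concatenate([r.normal(90, 35, 5000), r.normal(420, 45, 5000)])
        mix = fit_intensity_mixture(x, K=2)
        assert abs(mix.means[0] - 90) < 3
        assert abs(mix.means[1] - 420) < 3
        assert mix.weights == pytest.approx([0.5, 0.5], abs=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_log_likelihood_nondecreasing(self, seed):
        r = np.random.default_rng(seed)
        x = np.concatenate([r.normal(0, 1, 200), r.normal(8, 2, 300), r.normal(30, 4, 100)])
        mix = fit_intensity_mixture(x, K=3)
        assert np.all(np.diff(mix.log_likelihood_path) >= -1e-7 * np.abs(mix.log_likelihood_path[:-1]))
        assert np.all(np.diff(mix.means) >= 0)

    def test_constant_sample_with_k2_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_intensity_mixture(np.full(100, 7.0), K=2)

    def test_sample_too_small_rejected(self):
        with pytest.raises(ValueError, match="sample size"):
            fit_intensity_mixture(np.arange(25), K=3)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(0, 1, 400) + 10 * (rng.random(400) > 0.5)
        m1 = fit_intensity_mixture(x, K=2, seed=3)
        m2 = fit_intensity_mixture(x, K=2, seed=3)
        assert np.array_equal(m1.means, m2.means)
        assert np.array_equal(m1.weights, m2.weights)


def _mixture(weights, means, sds):
    return IntensityMixture(
        weights=np.asarray(weights, float),
        means=np.asarray(means, float),
        sds=np.asarray(sds, float),
        log_likelihood=0.0,
        n_iterations=0,
        converged=True,
    )


def _well_ordered_mixtures(seed, count, hu):
    """Random 3-component mixtures whose posterior argmax is monotone over hu."""
    rng = np.random.default_rng(seed)
    out = []
    attempts = 0
    while len(out) < count and attempts < 50 * count:
        attempts += 1
        sds = np.sort(rng.uniform(20, 80, 3))
        m1 = rng.uniform(0, 150)
        m2 = m1 + 5 * (sds[0] + sds[1]) + rng.uniform(0, 200)
        m3 = m2 + 5 * (sds[1] + sds[2]) + rng.uniform(0, 300)
        w = np.clip(rng.dirichlet([3, 3, 3]), 0.1, None)
        mix = _mixture(w / w.sum(), [m1, m2, m3], sds)
        if np.all(np.diff(mix.posterior_argmax(hu)) >= 0):
            out.append(mix)
    assert len(out) == count
    return out


class TestDeriveThresholds:
    def test_equal_weight_equal_sd_boundary_is_midpoint(self):
        mix = _mixture([1 / 3] * 3, [0.0, 100.0, 300.0], [10.0, 10.0, 10.0])
        th = derive_thresholds(mix)
        assert th.t_low == pytest.approx(50.0, abs=1e-9)
        assert th.t_high == pytest.approx(200.0, abs=1e-9)
        assert not th.fallback_used

    def test_unequal_weights_match_dense_numeric_scan(self):
        # brute-force root of the weighted-density difference at 0.01 HU steps
        w1, m1, s1, w2, m2, s2 = 0.3, 90.0, 35.0, 0.7, 420.0, 45.0
        grid = np.arange(m1, m2, 0.01)
        d1 = w1 / s1 * np.exp(-0.5 * ((grid - m1) / s1) ** 2)
        d2 = w2 / s2 * np.exp(-0.5 * ((grid - m2) / s2) ** 2)
        sign_change = np.flatnonzero(np.diff(np.sign(d1 - d2)) != 0)
        scan_root = grid[sign_change[0]]
        analytic = _weighted_density_crossing(w1, m1, s1, w2, m2, s2)
        assert analytic == pytest.approx(scan_root, abs=0.011)

    def test_threshold_partition_equals_posterior_argmax(self):
        hu = np.arange(-200, 2001, dtype=float)
        for mix in _well_ordered_mixtures(seed=42, count=20, hu=hu):
            th = derive_thresholds(mix, floor=-500.0)
            by_thresh = np.where(hu < th.t_low, 0, np.where(hu < th.t_high, 1, 2))
            assert np.array_equal(mix.posterior_argmax(hu), by_thresh)

    def test_pathological_overlap_falls_back_to_midpoint(self):
        # dominant middle component swallows the first: no density crossing
        mix = _mixture([0.001, 0.998, 0.001], [0.0, 30.0, 800.0], [10.0, 200.0, 10.0])
        th = derive_thresholds(mix, floor=-50.0)
        assert th.fallback_used
        assert th.t_low == pytest.approx(15.0, abs=1e-9)

    def test_requires_three_components(self, rng):
        mix = _mixture([0.5, 0.5], [0.0, 10.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="K=3"):
            derive_thresholds(mix)

    def test_shift_equivariance(self):
        mix = _mixture([0.3, 0.4, 0.3], [90.0, 420.0, 850.0], [35.0, 45.0, 120.0])
        th = derive_thresholds(mix)
        c = 137.0
        shifted = _mixture(mix.weights, mix.means + c, mix.sds)
        th_c = derive_thresholds(shifted, floor=th.floor + c)
        assert th_c.t_low == pytest.approx(th.t_low + c, abs=1e-8)
        assert th_c.t_high == pytest.approx(th.t_high + c, abs=1e-8)


class TestClassifyVoxels:
    thresholds = TissueThresholds(t_low=200.0, t_high=600.0, floor=-30.0)

    def test_half_open_convention_upper_class_wins(self):
        vol = make_volume(np.full((2, 2, 2), 600.0))
        labels = classify_voxels(vol, ROIMask(mask=np.ones((2, 2, 2), bool)), self.thresholds)
        assert np.all(labels == TissueLabel.CALCIFIC)

    def test_below_floor_excluded(self):
        vol = make_volume(np.full((2, 2, 2), -31.0))
        labels = classify_voxels(vol, ROIMask(mask=np.ones((2, 2, 2), bool)), self.thresholds)
        assert np.all(labels == TissueLabel.EXCLUDED)

    def test_non_roi_is_background(self):
        vol = make_volume(np.full((2, 2, 2), 100.0))
        m = np.zeros((2, 2, 2), bool)
        m[0, 0, 0] = True
        labels = classify_voxels(vol, ROIMask(mask=m), self.thresholds)
        assert labels[0, 0, 0] == TissueLabel.FIBROTIC
        assert (labels == TissueLabel.BACKGROUND).sum() == 7

    def test_phantom_label_accuracy_above_99pct(self, small_phantom):
        _, (vol, mask, truth) = small_phantom
        sample = extract_roi_intensities(vol, mask)
        th = derive_thresholds(fit_intensity_mixture(sample, K=3))
        labels = classify_voxels(vol, mask, th)
        acc = np.mean(labels[mask.mask] == truth.label_mask[mask.mask])
        assert acc > 0.99

    def test_shift_leaves_labels_unchanged(self, small_phantom):
        _, (vol, mask, _) = small_phantom
        sample = extract_roi_intensities(vol, mask)
        mix = fit_intensity_mixture(sample, K=3)
        th = derive_thresholds(mix)
        labels = classify_voxels(vol, mask, th)
        c = 250.0
        vol_c = make_volume(vol.intensities + c, vol.voxel_spacing)
        th_c = TissueThresholds(t_low=th.t_low + c, t_high=th.t_high + c, floor=th.floor + c)
        assert np.array_equal(classify_voxels(vol_c, mask, th_c), labels)


class TestQuantifyTissue:
    def test_voxel_count_arithmetic(self):
        labels = np.full((30, 20, 20), TissueLabel.FIBROTIC, dtype=np.uint8)  # 12000 voxels
        q = quantify_tissue(labels, (0.5, 0.5, 0.5))
        assert q.v_fibrotic == pytest.approx(1.5, abs=1e-12)

    def test_composition_and_ratio_formulas(self):
        labels = np.concatenate(
            [
                np.full(3000, TissueLabel.FIBROTIC),
                np.full(1000, TissueLabel.CALCIFIC),
                np.full(500, TissueLabel.BLOOD),
            ]
        ).reshape(50, 30, 3)
        q = quantify_tissue(labels, (1.0, 1.0, 1.0))
        assert q.fibrotic_pct == pytest.approx(75.0, abs=1e-12)
        assert q.calcific_pct == pytest.approx(25.0, abs=1e-12)
        assert q.fibrocalcific_ratio == pytest.approx(3.0, abs=1e-12)
        assert q.v_fibrocalcific == q.v_fibrotic + q.v_calcific

    def test_calcific_pct_is_complement_of_fibrotic(self):
        labels = np.concatenate(
            [np.full(77, TissueLabel.FIBROTIC), np.full(23, TissueLabel.CALCIFIC)]
        ).reshape(10, 10, 1)
        q = quantify_tissue(labels, (1.0, 1.0, 1.0))
        assert q.fibrotic_pct == pytest.approx(77.0)
        assert q.calcific_pct == pytest.approx(100.0 - 77.0, abs=1e-9)

    def test_zero_tissue_flags_undefined(self):
        labels = np.full((4, 4, 4), TissueLabel.BLOOD, dtype=np.uint8)
        q = quantify_tissue(labels, (1.0, 1.0, 1.0))
        assert not q.composition_defined and not q.ratio_defined
        assert math.isnan(q.fibrotic_pct) and math.isnan(q.fibrocalcific_ratio)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_property(self, seed):
        """Every ROI voxel gets exactly one label; volumes over all labels sum to ROI volume."""
        r = np.random.default_rng(seed)
        hu = r.uniform(-200, 1500, size=(8, 8, 8))
        vol = make_volume(hu)
        mask = ROIMask(mask=r.random((8, 8, 8)) > 0.3)
        if mask.n_voxels == 0:
            return
        labels = classify_voxels(vol, mask, self_th := TissueThresholds(200.0, 600.0, -30.0))
        assert np.all((labels[mask.mask] != TissueLabel.BACKGROUND))
        assert np.all(labels[~mask.mask] == TissueLabel.BACKGROUND)
        q = quantify_tissue(labels, (1.0, 1.0, 1.0))
        roi_cm3 = mask.n_voxels / 1000.0
        total = q.v_fibrotic + q.v_calcific + q.v_blood + q.v_excluded
        assert total == pytest.approx(roi_cm3, abs=1e-12)
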