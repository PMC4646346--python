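"""Segmentation, bias correction, VVF normalization and CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventmech.config import ImagingConfig
from ventmech.errors import DegenerateClusteringError, EmptySignalError
from ventmech.imaging import (
    BackgroundEstimate,
    VentilationImage,
    classify_ventilation,
    compute_cv,
    compute_vvf,
    correct_bias,
    denoise,
    estimate_background,
    quantify_image,
    remove_major_airways,
)
from ventmech.phantom import add_rician_noise, make_ventilation_truth, render_image


def img(arr, spacing=(1.0, 1.0, 1.0)):
    return VentilationImage(np.asarray(arr, dtype=float), spacing)


class TestDenoise:
    def test_none_is_identity(self):
        image = img(np.random.default_rng(0).random((6, 6, 3)))
        assert denoise(image, "none") is image

    def test_median_fixes_constant_image(self):
        image = img(np.full((8, 8, 3), 7.0))
        out = denoise(image, "median")
        np.testing.assert_array_equal(out.intensities, image.intensities)

    def test_median_removes_impulse(self):
        # brute-force check on a 5x5x1 grid: interior impulse vanishes
        arr = np.full((5, 5, 1), 10.0)
        arr[2, 2, 0] = 1000.0
        out = denoise(img(arr), "median", radius=1)
        assert np.all(out.intensities == 10.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            denoise(img(np.ones((4, 4, 2))), "wavelet")

    def test_nonnegativity_preserved(self):
        image = img(np.random.default_rng(1).random((8, 8, 4)) * 100)
        for method in ("median", "nonlocal_means"):
            assert np.all(denoise(image, method).intensities >= 0)


class TestClassify:
    def test_two_valued_image_partitions_exactly(self):
        arr = np.zeros((6, 6, 2))
        arr[3:, :, :] = 10.0
        labels = classify_ventilation(img(arr), n_classes=2)
        assert np.all(labels[arr == 0] == 0)
        assert np.all(labels[arr == 10] == 1)

    def test_well_separated_gaussians_grouped(self, rng):
        means = np.array([0.0, 50.0, 100.0])
        comp = rng.integers(0, 3, size=(12, 12, 6))
        arr = np.abs(rng.normal(means[comp], 1.0))
        labels = classify_ventilation(img(arr), n_classes=3, seed=0)
        assert np.mean(labels == comp) >= 0.99

    def test_labels_ordered_by_mean_intensity(self, rng):
        arr = np.abs(rng.normal(rng.integers(0, 4, size=(10, 10, 4)) * 40.0, 1.0))
        image = img(arr)
        labels = classify_ventilation(image, n_classes=4, seed=0)
        class_means = [arr[labels == c].mean() for c in range(4)]
        assert np.all(np.diff(class_means) > 0)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateClusteringError):
            classify_ventilation(img(np.full((6, 6, 2), 3.0)), n_classes=2)


class TestAirwayRemoval:
    def test_phantom_airway_mostly_removed(self, phantom):
        truth = make_ventilation_truth(phantom, 0.4, seed=0)
        image = render_image(phantom, truth, sigma=4.0, seed=1)
        den = denoise(image, "median")
        labels = classify_ventilation(den, 4, seed=0)
        seg = remove_major_airways(labels, den)
        overlap = (seg.airway_mask & phantom.airway_mask).sum()
        assert overlap >= 0.9 * phantom.airway_mask.sum()
        assert not np.any(seg.ventilated_mask & seg.airway_mask)

    def test_no_airway_in_image_leaves_mask_unchanged(self, phantom):
        truth = make_ventilation_truth(phantom, 0.4, seed=0)
        image = add_rician_noise(truth, 4.0, seed=1)  # no bright trachea
        den = denoise(image, "median")
        labels = classify_ventilation(den, 4, seed=0)
        seg = remove_major_airways(labels, den)
        assert not seg.airway_mask.any()
        assert np.array_equal(seg.ventilated_mask, labels > 0)

    def test_all_zero_labels_empty_masks(self, phantom):
        labels = np.zeros(phantom.lung_mask.shape, dtype=np.int32)
        seg = remove_major_airways(labels, img(np.zeros(labels.shape)))
        assert not seg.airway_mask.any()
        assert not seg.ventilated_mask.any()


class TestBackground:
    def test_explicit_region_arithmetic_mean(self):
        arr = np.zeros((6, 6, 2))
        arr[0, 0, 0], arr[0, 1, 0], arr[0, 2, 0] = 1.0, 2.0, 3.0
        region = np.zeros_like(arr, dtype=bool)
        region[0, :3, 0] = True
        bg = estimate_background(img(arr), region)
        assert bg.mean_intensity == 2.0

    def test_rayleigh_corner_background(self):
        sigma = 2.0
        image = add_rician_noise(np.zeros((40, 40, 8)), sigma, seed=3,
                                 spacing=(1, 1, 1))
        bg = estimate_background(image, "corners", corner_size=8)
        assert bg.mean_intensity == pytest.approx(sigma * np.sqrt(np.pi / 2),
                                                  rel=0.03)

    def test_overlap_with_ventilated_mask_rejected(self):
        arr = np.ones((6, 6, 2))
        region = np.zeros_like(arr, dtype=bool)
        region[0, 0, 0] = True
        with pytest.raises(ValueError):
            estimate_background(img(arr), region, ventilated_mask=region)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(img(np.ones((6, 6, 2))),
                                np.zeros((6, 6, 2), dtype=bool))


class TestBiasCorrection:
    def test_zero_background_is_identity(self):
        arr = np.random.default_rng(0).random((5, 5, 2)) * 50
        np.testing.assert_array_equal(correct_bias(img(arr), 0.0), arr)

    def test_direct_arithmetic(self):
        # sqrt(10^2 - (2/pi) 5^2) = 9.16979...
        out = correct_bias(img(np.full((1, 1, 1), 10.0)), 5.0)
        assert out[0, 0, 0] == pytest.approx(9.169760, abs=1e-5)

    def test_negative_radicand_clamped_to_zero(self):
        out = correct_bias(img(np.full((1, 1, 1), 1.0)), 5.0)
        assert out[0, 0, 0] == 0.0

    @given(s=st.floats(0, 1e3), sbg=st.floats(0, 1e3), ds=st.floats(0, 10))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_signal_and_background(self, s, sbg, ds):
        lo = correct_bias(img(np.full((1, 1, 1), s)), sbg)[0, 0, 0]
        hi = correct_bias(img(np.full((1, 1, 1), s + ds)), sbg)[0, 0, 0]
        assert hi >= lo  # nondecreasing in S
        worse = correct_bias(img(np.full((1, 1, 1), s)), sbg + ds)[0, 0, 0]
        assert worse <= lo  # nonincreasing in background


class TestVVF:
    def test_uniform_mask_equal_fractions(self):
        arr = np.full((4, 4, 2), 5.0)
        mask = np.ones_like(arr, dtype=bool)
        vvf = compute_vvf(arr, mask)
        np.testing.assert_allclose(vvf.vvf, 1.0 / arr.size)
        assert compute_cv(vvf) == 0.0

    def test_two_voxel_normalization(self):
        arr = np.array([[[3.0, 1.0]]])
        vvf = compute_vvf(arr, np.ones_like(arr, dtype=bool))
        np.testing.assert_allclose(sorted(vvf.vvf.ravel()), [0.25, 0.75])
        # mu = 0.5, population sigma = 0.25 -> CV = 0.5
        assert vvf.cv == pytest.approx(0.5, abs=1e-12)

    def test_sums_to_one(self, rng):
        arr = rng.random((10, 10, 5)) * 100
        mask = rng.random((10, 10, 5)) > 0.4
        vvf = compute_vvf(arr, mask)
        assert vvf.vvf[mask].sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, rng):
        arr = rng.random((8, 8, 3)) * 50
        mask = np.ones_like(arr, dtype=bool)
        a = compute_vvf(arr, mask)
        b = compute_vvf(arr * 37.5, mask)
        np.testing.assert_allclose(a.vvf, b.vvf, rtol=1e-12)
        assert a.cv == pytest.approx(b.cv, rel=1e-12)

    def test_zero_signal_rejected(self):
        arr = np.zeros((4, 4, 2))
        with pytest.raises(EmptySignalError):
            compute_vvf(arr, np.ones_like(arr, dtype=bool))


class TestQuantifyPipeline:
    def test_noiseless_presegmented_recovers_truth_exactly(self, phantom):
        truth = make_ventilation_truth(phantom, 0.45, seed=2)
        image = add_rician_noise(truth, 0.0, spacing=phantom.spacing)
        cfg = ImagingConfig(denoise_method="none", background_region="none")
        res = quantify_image(image, cfg, ventilated_mask=phantom.lung_mask)
        assert res.cv == pytest.approx(truth.realized_cv, abs=1e-6)

    def test_cv_invariant_under_intensity_rescaling(self, phantom):
        truth = make_ventilation_truth(phantom, 0.45, seed=2)
        image = render_image(phantom, truth, sigma=4.0, seed=3)
        scaled = VentilationImage(image.intensities * 13.0, image.spacing)
        a = quantify_image(image)
        b = quantify_image(scaled)
        # background estimate scales with the image, so Eq 4-6 compose to
        # a scale-free CV
        assert b.cv == pytest.approx(a.cv, rel=1e-6)

    def test_intermediates_are_retrievable(self, phantom):
        truth = make_ventilation_truth(phantom, 0.4, seed=1)
        image = render_image(phantom, truth, sigma=4.0, seed=4)
        res = quantify_image(image)
        assert res.denoised.shape == image.shape
        assert res.segmentation.class_labels.shape == image.shape
        assert res.background is not None and res.background.mean_intensity > 0
        assert res.corrected.shape == image.shape
        assert res.vvf.vvf[res.vvf.mask].sum() == pytest.approx(1.0, abs=1e-9)
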