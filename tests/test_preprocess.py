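"""Background estimation, normalization, FEF filter bank, binarization."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecmkit import (
    BackgroundParams,
    FiberFieldParams,
    Image,
    InvalidInputError,
    InvalidParameterError,
    ThresholdSpec,
    binarize,
    build_filter_bank,
    estimate_background,
    fiber_enhance,
    generate_fiber_image,
    normalize_image,
    preprocess_chain,
)
from ecmkit.preprocess import line_mask
from ecmkit.synthetic import radial_background

from .oracles import brute_correlate_reflect


class TestBackground:
    def test_constant_image_gives_constant_background(self):
        img = Image(np.full((32, 32), 3.7))
        bg = estimate_background(img)
        np.testing.assert_allclose(bg.values, 3.7, atol=1e-12)

    def test_recovers_pure_radial_gaussian_within_1pct(self):
        surface = radial_background(
            (128, 128), BackgroundParams(center_intensity=1.0, falloff_scale_px=80.0)
        )
        est = estimate_background(Image(surface))
        assert np.abs(est.values - surface).max() < 0.01 * surface.max()

    def test_robust_to_sparse_bright_fibers_within_3pct(self):
        surface = radial_background(
            (128, 128), BackgroundParams(center_intensity=1.0, falloff_scale_px=80.0)
        )
        fibers, _ = generate_fiber_image(
            FiberFieldParams(image_size_px=(128, 128), n_fibers=13,
                             mean_length_px=30.0, width_px=2.0, seed=7)
        )
        assert (fibers.values > 0).mean() < 0.05
        est = estimate_background(Image(surface + 0.8 * fibers.values))
        assert np.abs(est.values - surface).max() < 0.03 * surface.max()

    def test_output_depends_on_radius_only(self):
        rng = np.random.default_rng(0)
        est = estimate_background(Image(rng.uniform(size=(65, 65))))
        c = 32
        for dy, dx in [(3, 4), (12, 5)]:
            vals = [est.values[c + dy, c + dx], est.values[c - dy, c - dx],
                    est.values[c - dy, c + dx], est.values[c + dx, c + dy]]
            assert np.ptp(vals) < 1e-9

    def test_tiny_image_rejected(self):
        with pytest.raises(InvalidInputError):
            estimate_background(Image(np.ones((2, 2))))


class TestNormalize:
    def test_uniform_background_is_identity(self, rng):
        raw = Image(rng.uniform(1, 2, size=(32, 32)))
        bg = Image(np.full((32, 32), 5.0), stage="background")
        out = normalize_image(raw, bg)
        np.testing.assert_allclose(out.values, raw.values, atol=1e-12)

    def test_pure_background_normalizes_to_its_mean(self):
        surface = radial_background(
            (64, 64), BackgroundParams(center_intensity=1.0, falloff_scale_px=30.0)
        )
        raw = Image(surface)
        out = normalize_image(raw, Image(surface, stage="background"))
        np.testing.assert_allclose(out.values, surface.mean(), rtol=1e-9)
        assert out.values.mean() == pytest.approx(raw.values.mean())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            normalize_image(Image(np.ones((8, 8))), Image(np.ones((9, 9)), stage="background"))

    def test_flattens_fiber_contrast_across_radii(self):
        # fibers on a strong radial vignette: after normalization the
        # fiber-to-local-background intensity ratio is radius-independent
        fibers, _ = generate_fiber_image(
            FiberFieldParams(image_size_px=(128, 128), n_fibers=15,
                             mean_length_px=30.0, width_px=2.0, seed=7)
        )
        vignette = 0.2 + radial_background(
            (128, 128), BackgroundParams(center_intensity=0.8, falloff_scale_px=60.0)
        )
        raw = Image(vignette * (1.0 + fibers.values))
        norm = normalize_image(raw, estimate_background(raw))
        fib = fibers.values > 0
        yy, xx = np.mgrid[0:128, 0:128]
        r = np.hypot(yy - 63.5, xx - 63.5)
        contrasts = []
        for lo, hi in ((0, 30), (30, 60)):
            ann = (r >= lo) & (r < hi)
            contrasts.append(norm.values[ann & fib].mean() / norm.values[ann & ~fib].mean())
        assert abs(contrasts[0] / contrasts[1] - 1) < 0.05


class TestFilterBank:
    def test_theta_zero_is_middle_row_and_symmetric(self):
        m = line_mask(5, 0.0)
        expected = np.zeros((5, 5))
        expected[2, :] = 1
        np.testing.assert_array_equal(m, expected)
        bank = build_filter_bank(5, 15, 0.7)
        gf0 = bank.gf[0]
        np.testing.assert_allclose(gf0, gf0[::-1, ::-1], atol=1e-12)  # point-symmetric
        np.testing.assert_allclose(gf0[2], gf0[2][::-1], atol=1e-12)

    def test_all_filters_normalized(self):
        bank = build_filter_bank(5, 15, 0.7)
        assert len(bank) == 15
        for gf, af in zip(bank.gf, bank.af):
            assert gf.sum() == pytest.approx(1.0)
            assert af.sum() == pytest.approx(1.0)

    def test_vertical_filters_are_transpose_of_horizontal(self):
        bank = build_filter_bank(5, 2, 0.7)  # orientations 0 and pi/2
        np.testing.assert_allclose(bank.gf[1], bank.gf[0].T, atol=1e-12)
        np.testing.assert_allclose(bank.af[1], bank.af[0].T, atol=1e-12)

    def test_even_mask_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_filter_bank(4, 15, 0.7)


class TestFiberEnhance:
    def test_constant_image_maps_to_zero(self):
        bank = build_filter_bank()
        out = fiber_enhance(Image(np.full((32, 32), 7.0)), bank)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_line_response_exceeds_off_line_response(self):
        img = np.zeros((21, 21))
        img[10, :] = 1.0
        out = fiber_enhance(Image(img), build_filter_bank())
        assert np.all(out.values[10, 5:16] > out.values[13, 5:16])

    def test_matches_direct_convolution_oracle(self, rng):
        img = rng.uniform(size=(16, 16))
        bank = build_filter_bank(5, 4, 0.7)
        expected = np.max(
            [brute_correlate_reflect(img, gf) - brute_correlate_reflect(img, af)
             for gf, af in zip(bank.gf, bank.af)],
            axis=0,
        )
        out = fiber_enhance(Image(img), bank)
        np.testing.assert_allclose(out.values, expected, atol=1e-9)

    @pytest.mark.parametrize("kappa", [0.0, 2.0, 8.0])
    def test_fiber_pixels_respond_more_than_background(self, kappa):
        params = FiberFieldParams(image_size_px=(128, 128), n_fibers=60,
                                  orientation_kappa=kappa, seed=31)
        img, _ = generate_fiber_image(params, BackgroundParams(speckle_sd=0.05, seed=31))
        clean, _ = generate_fiber_image(params)
        gt = clean.values > 0
        out = fiber_enhance(img, build_filter_bank())
        assert out.values[gt].mean() > out.values[~gt].mean()

    def test_rotation_equivariance_when_90deg_in_bank(self, rng):
        bank = build_filter_bank(5, 2, 0.7)  # contains 0 and 90 degrees
        img = rng.uniform(size=(32, 32))
        a = fiber_enhance(Image(np.rot90(img).copy()), bank).values
        b = np.rot90(fiber_enhance(Image(img), bank).values)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_positive_scaling_linearity(self, rng):
        img = rng.uniform(size=(24, 24))
        bank = build_filter_bank()
        base = fiber_enhance(Image(img), bank).values
        scaled = fiber_enhance(Image(3.5 * img), bank).values
        np.testing.assert_allclose(scaled, 3.5 * base, atol=1e-9)

    def test_empty_bank_rejected(self):
        from ecmkit.preprocess import FilterBank

        empty = FilterBank(mask_size=5, orientations_rad=np.array([]), gaussian_sd=0.7)
        with pytest.raises(InvalidParameterError):
            fiber_enhance(Image(np.ones((8, 8))), empty)


class TestBinarize:
    def test_threshold_extremes(self, rng):
        img = Image(rng.uniform(size=(16, 16)), stage="enhanced")
        assert np.all(binarize(img, ThresholdSpec("fixed", 2.0)).values == 0)
        assert np.all(binarize(img, ThresholdSpec("fixed", -1.0)).values == 1)

    def test_idempotent_on_binary_at_half(self):
        mask = (np.arange(64).reshape(8, 8) % 3 == 0).astype(float)
        out = binarize(Image(mask, stage="enhanced"), ThresholdSpec("fixed", 0.5))
        np.testing.assert_array_equal(out.values, mask)

    def test_threshold_recorded_in_metadata(self, rng):
        img = Image(rng.normal(size=(32, 32)), stage="enhanced")
        out = binarize(img, ThresholdSpec("quantile", 0.9))
        assert out.meta["threshold"] == pytest.approx(np.quantile(img.values, 0.9))
        assert out.meta["threshold_method"] == "quantile"

    def test_nonfinite_fixed_threshold_rejected(self):
        with pytest.raises(InvalidParameterError):
            ThresholdSpec("fixed", math.nan)

    def test_otsu_segmentation_quality_on_fixture(self):
        # fixed-seed regression bound: pixelwise F1 vs ground truth
        params = FiberFieldParams(image_size_px=(256, 256), n_fibers=120,
                                  width_px=3.0, orientation_kappa=4.0, seed=42)
        img, _ = generate_fiber_image(
            params, BackgroundParams(center_intensity=0.5, speckle_sd=0.1, seed=42)
        )
        clean, _ = generate_fiber_image(params)
        gt = clean.values > 0
        pred = preprocess_chain(img)["binary"].values > 0
        tp = (pred & gt).sum()
        f1 = 2 * tp / (2 * tp + (pred & ~gt).sum() + (~pred & gt).sum())
        assert f1 >= 0.7

    @given(st.floats(0.1, 10.0))
    def test_pixel_size_preserved_through_chain(self, px):
        rng = np.random.default_rng(5)
        raw = Image(rng.uniform(size=(32, 32)), pixel_size_um=px)
        stages = preprocess_chain(raw)
        assert all(s.pixel_size_um == px for s in stages.values())
        assert set(np.unique(stages["binary"].values)).issubset({0.0, 1.0})
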