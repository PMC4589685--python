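"""Granulometry pore spectrum and FFT alignment index."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecmkit import (
    FiberFieldParams,
    Image,
    InvalidInputError,
    InvalidParameterError,
    MicrostructureConfig,
    PolarPower,
    UndefinedAlignmentError,
    alignment_from_image,
    alignment_index,
    analyze_microstructure,
    angular_power,
    disk_footprint,
    ft_magnitude,
    generate_fiber_image,
    pore_spectrum,
)

from .oracles import brute_open


def binary_image(mask, px=1.0):
    return Image(mask.astype(float), pixel_size_um=px, stage="binary")


class TestPoreSpectrum:
    def test_all_fiber_mask_has_undefined_mean(self):
        mask = binary_image(np.ones((32, 32)))
        with pytest.warns(UserWarning, match="no pore area"):
            spec = pore_spectrum(mask, 5)
        assert spec.empty
        assert math.isnan(spec.mean_radius_px)
        assert np.all(spec.retained_area == 0)

    def test_single_disk_pore_recovers_its_radius(self):
        # a single pore shaped like the radius-10 digital disk, in a
        # fiber-filled field (same disk convention as the openings)
        mask = np.ones((64, 64), dtype=bool)
        mask[32 - 10 : 32 + 11, 32 - 10 : 32 + 11] &= ~disk_footprint(10)
        spec = pore_spectrum(binary_image(mask), 15)
        assert abs(spec.mean_radius_px - 10) <= 1.0
        assert spec.radii_px[np.argmax(spec.freq)] == 10
        assert not spec.truncated

    def test_regular_grid_pore_size_matches_geometry(self):
        # fibers on a square grid, spacing 21 px, width 1 px -> square
        # pores of side 20.  The largest digital disk fitting such a pore
        # has radius 9 (diameter 19), so the modal radius is 9 (within a
        # pixel of the analytic (d-1)/2 = 10); the mean sits below the
        # mode because disk openings clip the square corners at smaller
        # radii.  The brute-force opening oracle defines the expectation.
        mask = np.zeros((85, 85), dtype=bool)
        mask[::21, :] = True
        mask[:, ::21] = True
        spec = pore_spectrum(binary_image(mask), 15)
        assert spec.radii_px[np.argmax(spec.freq)] == 9

        pores = ~mask
        retained = [pores.sum()]
        kept = pores.copy()
        for r in range(1, 17):
            kept &= brute_open(pores, disk_footprint(r))
            retained.append(kept.sum())
        per_radius = -np.diff(retained)
        oracle_mean = np.sum(np.arange(16) * per_radius) / per_radius.sum()
        assert spec.mean_radius_px == pytest.approx(oracle_mean, abs=1e-9)
        assert abs(oracle_mean - 10) < 2  # analytic geometry up to corner clipping

    def test_retained_area_monotone_nonincreasing(self, rng):
        mask = rng.uniform(size=(48, 48)) < 0.4
        spec = pore_spectrum(binary_image(mask), 8)
        assert np.all(np.diff(spec.retained_area) <= 0)
        assert spec.freq.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(spec.freq >= 0)

    def test_matches_bruteforce_opening_oracle(self, rng):
        mask = rng.uniform(size=(64, 64)) < 0.35
        spec = pore_spectrum(binary_image(mask), 6)
        pores = ~mask
        kept = pores.copy()
        for r in range(1, 7):
            kept &= brute_open(pores, disk_footprint(r))
            assert spec.retained_area[r] == kept.sum()

    def test_growing_pores_never_shrinks_mean_size(self, rng):
        fibers = rng.uniform(size=(64, 64)) < 0.45
        fewer = fibers & (rng.uniform(size=(64, 64)) < 0.5)
        s_dense = pore_spectrum(binary_image(fibers), 10)
        s_sparse = pore_spectrum(binary_image(fewer), 10)
        assert s_sparse.mean_radius_px >= s_dense.mean_radius_px

    def test_unit_conversion(self):
        yy, xx = np.mgrid[0:64, 0:64]
        pore = np.hypot(yy - 32, xx - 32) <= 8
        spec = pore_spectrum(binary_image(~pore, px=0.2), 12)
        assert spec.mean_diameter_um == pytest.approx(2 * spec.mean_radius_px * 0.2)

    def test_input_validation(self):
        with pytest.raises(InvalidInputError):
            pore_spectrum(Image(np.full((16, 16), 0.5)), 4)
        with pytest.raises(InvalidParameterError):
            pore_spectrum(binary_image(np.zeros((16, 16))), 9)


class TestFTMagnitude:
    def test_constant_image_with_dc_removal_is_zero(self):
        spec = ft_magnitude(Image(np.full((32, 32), 4.2)), dc_remove=True)
        np.testing.assert_allclose(spec.magnitude, 0.0, atol=1e-9)

    def test_horizontal_sinusoid_concentrates_on_vertical_axis(self):
        yy = np.mgrid[0:64, 0:64][0]
        img = np.sin(2 * math.pi * 8 * yy / 64)
        spec = ft_magnitude(Image(img), dc_remove=True)
        peaks = np.argsort(spec.magnitude.ravel())[-2:]
        rows, cols = np.unravel_index(peaks, spec.magnitude.shape)
        assert set(cols) == {32}           # on the vertical frequency axis
        assert set(rows) == {32 - 8, 32 + 8}

    def test_parseval_identity(self, rng):
        img = rng.uniform(size=(32, 48))
        spec = ft_magnitude(Image(img), dc_remove=False)
        lhs = np.sum(img**2)
        rhs = np.sum(spec.magnitude**2) / (32 * 48)
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_magnitude_consistent_and_point_symmetric(self, rng):
        img = rng.uniform(size=(33, 33))
        spec = ft_magnitude(Image(img), dc_remove=True)
        np.testing.assert_allclose(
            spec.magnitude, np.hypot(spec.real, spec.imag), atol=1e-9
        )
        # real input: |FT(-u,-v)| = |FT(u,v)|; odd size makes the center exact
        np.testing.assert_allclose(
            spec.magnitude, spec.magnitude[::-1, ::-1], atol=1e-6
        )


class TestAngularPower:
    def test_rotationally_symmetric_ring_gives_flat_power(self):
        yy, xx = np.mgrid[0:65, 0:65]
        r = np.hypot(yy - 32, xx - 32)
        from ecmkit.microstructure import SpectrumFT

        ring = np.exp(-((r - 10) ** 2) / 4.0)
        spec = SpectrumFT(real=ring, imag=np.zeros_like(ring), magnitude=ring)
        pp = angular_power(spec, 90)
        assert pp.power.std() / pp.power.mean() < 0.02  # relative spread

    def test_vertical_axis_peaks_maximize_at_pi_over_2(self):
        from ecmkit.microstructure import SpectrumFT

        mag = np.zeros((65, 65))
        mag[32 - 9, 32] = mag[32 + 9, 32] = 1.0
        spec = SpectrumFT(real=mag, imag=np.zeros_like(mag), magnitude=mag)
        pp = angular_power(spec, 180)
        assert pp.thetas_rad[np.argmax(pp.power)] == pytest.approx(math.pi / 2)

    def test_horizontal_fibers_peak_orthogonally(self):
        img = np.zeros((64, 64))
        img[10::16, :] = 1.0  # horizontal lines
        pp = angular_power(ft_magnitude(Image(img)), 180)
        assert pp.thetas_rad[np.argmax(pp.power)] == pytest.approx(math.pi / 2)

    def test_non_centered_spectrum_rejected(self):
        from ecmkit.microstructure import SpectrumFT

        spec = SpectrumFT(real=np.ones((16, 16)), imag=np.zeros((16, 16)),
                          magnitude=np.ones((16, 16)), origin_centered=False)
        with pytest.raises(InvalidInputError):
            angular_power(spec, 90)


class TestAlignmentIndex:
    def test_delta_distribution_is_fully_aligned(self):
        thetas = np.linspace(0, math.pi, 180, endpoint=False)
        power = np.zeros(180)
        power[37] = 3.0
        res = alignment_index(PolarPower(thetas, power))
        assert res.alpha == pytest.approx(1.0, abs=1e-9)
        assert res.lambda2 == pytest.approx(0.0, abs=1e-9 * res.lambda1)
        assert res.principal_orientation_rad == pytest.approx(thetas[37])

    def test_uniform_distribution_is_isotropic(self):
        thetas = np.linspace(0, math.pi, 180, endpoint=False)
        res = alignment_index(PolarPower(thetas, np.ones(180)))
        assert res.alpha == pytest.approx(0.0, abs=1e-9)
        assert res.lambda1 == pytest.approx(res.lambda2, rel=1e-9)

    def test_equal_orthogonal_deltas_are_isotropic(self):
        thetas = np.array([0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4])
        power = np.array([2.0, 0.0, 2.0, 0.0])
        res = alignment_index(PolarPower(thetas, power))
        assert res.alpha == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_power_is_undefined(self):
        thetas = np.linspace(0, math.pi, 16, endpoint=False)
        with pytest.raises(UndefinedAlignmentError):
            alignment_index(PolarPower(thetas, np.zeros(16)))

    @given(
        arrays(float, 45, elements=st.floats(0.0, 100.0)).filter(lambda p: p.max() > 0)
    )
    def test_alpha_always_in_unit_interval(self, power):
        thetas = np.linspace(0, math.pi, 45, endpoint=False)
        res = alignment_index(PolarPower(thetas, power))
        assert 0.0 <= res.alpha <= 1.0
        assert res.lambda1 >= res.lambda2 >= 0


class TestComposedAnalysis:
    def test_alpha_rotation_invariance(self, aligned_field):
        img, _ = aligned_field
        a = alignment_from_image(img).alpha
        b = alignment_from_image(Image(np.rot90(img.values).copy(),
                                       pixel_size_um=img.pixel_size_um)).alpha
        assert abs(a - b) < 0.02

    def test_aligned_field_scores_higher_than_isotropic(self, aligned_field, isotropic_field):
        cfg = MicrostructureConfig(crop_um=None, max_radius_px=20)
        a = analyze_microstructure(aligned_field[0], cfg)
        i = analyze_microstructure(isotropic_field[0], cfg)
        assert a.alignment.alpha > i.alignment.alpha

    def test_recovers_dominant_fiber_orientation(self):
        params = FiberFieldParams(image_size_px=(192, 192), n_fibers=150,
                                  orientation_kappa=50.0,
                                  orientation_center_rad=math.pi / 3, seed=5)
        img, _ = generate_fiber_image(params)
        res = alignment_from_image(img)
        err = abs(res.fiber_orientation_rad - math.pi / 3)
        assert min(err, math.pi - err) < math.radians(6)

    def test_report_is_deterministic(self, aligned_field):
        cfg = MicrostructureConfig(crop_um=None, max_radius_px=15)
        s1 = json.dumps(analyze_microstructure(aligned_field[0], cfg).summary(), sort_keys=True)
        s2 = json.dumps(analyze_microstructure(aligned_field[0], cfg).summary(), sort_keys=True)
        assert s1 == s2

    def test_pore_diameters_scale_with_pixel_size(self, isotropic_field):
        img, _ = isotropic_field
        cfg = MicrostructureConfig(crop_um=None, max_radius_px=20)
        rep = analyze_microstructure(img, cfg)
        assert rep.pore.mean_diameter_um == pytest.approx(
            0.4 * rep.pore.mean_radius_px  # 0.2 um/px fixture
        )
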