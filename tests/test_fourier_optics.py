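"""Image formation: PSF properties against closed-form optics, anamorphic
magnification geometry, convolution identities and interferograms."""

import math

import numpy as np
import pytest

from refractsim.fourier_optics import (
    PSFImage,
    PupilFunction,
    apply_magnification,
    compute_psf,
    render_interferogram,
    render_retinal_image,
    strehl_ratio,
)
from refractsim.grids import GridSpec, WavefrontMap, zero_wavefront
from refractsim.optotypes import make_letter_line
from refractsim.scene import diffraction_limited
from refractsim.zernike import ZernikeCoefficients, evaluate_wavefront

LAMBDA_UM = 0.587


def first_radial_minimum_px(psf: PSFImage) -> int:
    c = psf.center_index
    row = psf.intensity[c, c:]
    i = 1
    while not (row[i] < row[i - 1] and row[i] <= row[i + 1]):
        i += 1
    return i


class TestPSF:
    def test_airy_peak_at_center_pixel(self, grid_2mm):
        psf = diffraction_limited(grid_2mm)
        peak = np.unravel_index(psf.intensity.argmax(), psf.intensity.shape)
        assert peak == (psf.center_index, psf.center_index)

    def test_airy_first_minimum_position(self):
        grid = GridSpec(pupil_radius_mm=2.0, n_pupil=256, pad_factor=4)
        psf = diffraction_limited(grid)
        expected_rad = 1.22 * 587e-9 / 4e-3
        expected_arcmin = math.degrees(expected_rad) * 60.0
        measured = first_radial_minimum_px(psf) * psf.pixel_scale_arcmin
        assert expected_arcmin == pytest.approx(0.6156, abs=1e-3)
        assert abs(measured - expected_arcmin) <= psf.pixel_scale_arcmin

    def test_unit_sum_regardless_of_aberration(self, grid_2mm, rng):
        z = ZernikeCoefficients(
            {j: float(rng.normal(0, 0.2)) for j in range(3, 15)}, 2.0
        )
        psf = compute_psf(PupilFunction(evaluate_wavefront(z, grid_2mm)))
        assert psf.intensity.sum() == pytest.approx(1.0, abs=1e-9)
        assert psf.intensity.min() >= 0.0

    @pytest.mark.parametrize("c4", [0.02, 0.03, 0.0419])
    def test_marechal_strehl_for_small_defocus(self, grid_2mm, c4):
        z = ZernikeCoefficients({4: c4}, 2.0)
        psf = compute_psf(PupilFunction(evaluate_wavefront(z, grid_2mm)))
        s = strehl_ratio(psf, diffraction_limited(grid_2mm))
        marechal = math.exp(-((2 * math.pi * c4 / LAMBDA_UM) ** 2))
        assert s == pytest.approx(marechal, rel=0.02)

    def test_piston_leaves_psf_unchanged(self, grid_2mm):
        base = diffraction_limited(grid_2mm)
        z = ZernikeCoefficients({0: 1.23}, 2.0)
        psf = compute_psf(PupilFunction(evaluate_wavefront(z, grid_2mm)))
        assert np.allclose(psf.intensity, base.intensity, atol=1e-12)

    def test_tilt_translates_without_reshaping(self, grid_2mm):
        base = diffraction_limited(grid_2mm)
        # tilt sized to displace the PSF by exactly 10 PSF pixels:
        # angle = 2 c1 / R (um/mm -> mrad) must equal 10 * dtheta
        k = 10
        c1 = k * grid_2mm.dtheta_rad * grid_2mm.pupil_radius_mm / 2.0 * 1e3
        z = ZernikeCoefficients({2: c1}, 2.0)  # horizontal tilt
        psf = compute_psf(PupilFunction(evaluate_wavefront(z, grid_2mm)))
        shift = np.unravel_index(psf.intensity.argmax(), psf.intensity.shape)
        assert shift[0] == psf.center_index      # moved along x only
        assert abs(shift[1] - psf.center_index) == k
        rolled = np.roll(
            psf.intensity, psf.center_index - shift[1], axis=1
        )
        assert np.allclose(rolled, base.intensity, atol=1e-9)

    def test_nan_phase_rejected(self, grid_2mm):
        w = zero_wavefront(grid_2mm)
        w.values[w.valid_mask.nonzero()[0][0], w.valid_mask.nonzero()[1][0]] = 1.0
        w.values[grid_2mm.n_pupil // 2, grid_2mm.n_pupil // 2] = np.nan
        with pytest.raises(ValueError):
            compute_psf(PupilFunction(w))

    def test_matches_direct_fourier_sum_on_small_pupil(self):
        """Brute-force DFT oracle on a 32-sample pupil with pure defocus."""
        grid = GridSpec(pupil_radius_mm=1.0, n_pupil=32, pad_factor=2)
        z = ZernikeCoefficients({4: 0.3}, 1.0)
        w = evaluate_wavefront(z, grid)
        psf = compute_psf(PupilFunction(w))
        p = PupilFunction(w).complex_values()
        n = grid.n_pupil
        nf = grid.n_fft
        xs = np.arange(n) - n // 2
        us = np.arange(nf) - nf // 2
        phase = np.exp(-2j * np.pi * np.outer(us, xs) / nf)
        amp = phase @ p @ phase.T
        brute = np.abs(amp) ** 2
        brute /= brute.sum()
        assert np.max(np.abs(brute - psf.intensity)) < 1e-10 * brute.max()

    def test_pad_factor_convergence_of_strehl(self):
        vals = []
        for pad in (4, 8):
            grid = GridSpec(pupil_radius_mm=2.0, n_pupil=128, pad_factor=pad)
            z = ZernikeCoefficients({4: 0.1, 5: 0.05}, 2.0)
            psf = compute_psf(PupilFunction(evaluate_wavefront(z, grid)))
            vals.append(strehl_ratio(psf, diffraction_limited(grid)))
        assert vals[1] == pytest.approx(vals[0], rel=0.01)


class TestMagnification:
    def test_unit_magnification_is_identity(self, rng):
        img = rng.random((64, 64))
        out = apply_magnification(img, (1.0, 1.0, 30.0))
        assert np.array_equal(out, img)

    def test_isotropic_doubling_scales_disc_area(self):
        n = 201
        c = np.arange(n) - n // 2
        x, y = np.meshgrid(c, c)
        disc = ((x**2 + y**2) <= 20**2).astype(float)
        out = apply_magnification(disc, (2.0, 2.0, 0.0))
        assert out.sum() / disc.sum() == pytest.approx(4.0, rel=0.02)

    def test_anamorphic_stretch_of_square(self):
        n = 201
        img = np.zeros((n, n))
        img[60:141, 60:141] = 1.0
        out = apply_magnification(img, (1.08, 1.00, 0.0))
        # area grows by the horizontal stretch only (flux-based width
        # measure avoids edge-threshold bias)
        assert out.sum() / img.sum() == pytest.approx(1.08, abs=1.0 / 81)

    def test_meridian_angle_steers_the_stretch(self):
        n = 201
        c = np.arange(n) - n // 2
        x, y = np.meshgrid(c, -c)
        disc = ((x**2 + y**2) <= 30**2).astype(float)
        out = apply_magnification(disc, (1.5, 1.0, 90.0))
        # stretched along the vertical meridian -> taller than wide
        width = (out.sum(axis=0) > 0.5).sum()
        height = (out.sum(axis=1) > 0.5).sum()
        assert height > width


class TestRetinalImage:
    def test_delta_chart_reproduces_psf(self, grid_2mm):
        psf = diffraction_limited(grid_2mm)
        n = 65
        delta = np.zeros((n, n))
        delta[n // 2, n // 2] = 1.0
        img = render_retinal_image(
            delta, psf.pixel_scale_arcmin, psf, mode="same"
        )
        c = psf.center_index
        half = n // 2
        crop = psf.intensity[c - half : c + half + 1, c - half : c + half + 1]
        assert np.allclose(img.intensity, crop, atol=1e-12)

    def test_total_flux_conserved(self, grid_2mm):
        psf = diffraction_limited(grid_2mm)
        chart = make_letter_line(0.3, "OZ", psf.pixel_scale_arcmin)
        img = render_retinal_image(
            chart.image, chart.pixel_scale_arcmin, psf, mode="full"
        )
        assert img.intensity.sum() == pytest.approx(
            chart.image.sum(), rel=1e-6
        )

    def test_large_letters_survive_diffraction_blur(self, grid_2mm):
        psf = diffraction_limited(grid_2mm)
        chart = make_letter_line(1.0, "HNZ", psf.pixel_scale_arcmin)
        img = render_retinal_image(
            chart.image, chart.pixel_scale_arcmin, psf, mode="same"
        )
        a = chart.image - chart.image.mean()
        b = img.intensity - img.intensity.mean()
        corr = (a * b).sum() / math.sqrt((a * a).sum() * (b * b).sum())
        assert corr > 0.99


class TestInterferogram:
    def test_zero_phase_gives_uniform_bright_disc(self, grid_2mm):
        img = render_interferogram(zero_wavefront(grid_2mm))
        mask = grid_2mm.pupil_mask()
        assert np.allclose(img[mask], 1.0)
        assert np.all(img[~mask] == 0.0)

    def test_defocus_ring_count_equals_pv_over_lambda(self, grid_2mm):
        z = ZernikeCoefficients({4: 1.0}, 2.0)
        w = evaluate_wavefront(z, grid_2mm)
        img = render_interferogram(w)
        pv_waves = w.peak_to_valley_um() / LAMBDA_UM
        c = grid_2mm.n_pupil // 2
        profile = img[c, c:]
        inside = grid_2mm.pupil_mask()[c, c:]
        p = profile[inside]
        dark_crossings = int(
            np.sum((p[1:] < 0.5) & (p[:-1] >= 0.5))
        )
        assert abs(dark_crossings - round(pv_waves)) <= 1

    def test_crossed_cylinder_fringes_have_180_symmetry(self, grid_2mm):
        from refractsim.eye_lenses import JCCState, jcc_phase

        w = jcc_phase(JCCState(0.50, 30.0), 0.0, grid_2mm)
        img = render_interferogram(w)
        rotated = np.rot90(img, 2)
        # even-size grid: 180-degree rotation shifts the center by one
        # pixel, so compare on the common interior
        a = img[1:, 1:]
        b = rotated[:-1, :-1]
        assert np.allclose(a, b, atol=1e-9)
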