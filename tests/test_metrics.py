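"""Image-quality metrics: Visual Strehl, dial sharpness, similarity,
defocus curves and the acuity surrogate."""

import math

import numpy as np
import pytest

from refractsim.eye_lenses import PhoropterState, SchematicEye
from refractsim.fixtures import make_eye
from refractsim.fourier_optics import RetinalImage
from refractsim.grids import GridSpec, zero_wavefront
from refractsim.metrics import (
    defocus_curve,
    dial_line_sharpness,
    estimate_va,
    image_pair_similarity,
    neural_csf,
    scene_visual_strehl,
    visual_strehl,
)
from refractsim.optotypes import make_clock_dial, make_letter_line
from refractsim.powers import SpheroCylinder
from refractsim.scene import Scene
from refractsim.zernike import ZernikeCoefficients, evaluate_wavefront

LAMBDA_UM = 0.587


def scene_with(refraction, pupil_radius=3.0, n_pupil=128, **kw) -> Scene:
    eye = SchematicEye(
        make_eye("custom", refraction=refraction, pupil_radius_mm=pupil_radius)
    )
    return Scene(eye, n_pupil=n_pupil, **kw)


class TestVisualStrehl:
    def test_unity_for_zero_aberration(self, grid_3mm):
        assert visual_strehl(zero_wavefront(grid_3mm)) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_strictly_decreasing_with_defocus(self):
        base = scene_with(SpheroCylinder())
        vs = [
            scene_visual_strehl(base.with_extra_sphere(d))
            for d in np.arange(0.0, 1.01, 0.125)
        ]
        assert all(b < a for a, b in zip(vs, vs[1:]))

    @pytest.mark.parametrize("axis", [45.0, 90.0, 135.0])
    def test_invariant_under_cylinder_axis_rotation(self, axis):
        ref = scene_with(SpheroCylinder(0, -1.0, 180.0))
        rot = scene_with(SpheroCylinder(0, -1.0, axis))
        assert scene_visual_strehl(rot) == pytest.approx(
            scene_visual_strehl(ref), rel=0.01
        )

    def test_approaches_marechal_for_vanishing_defocus(self):
        """In the deep-Marechal regime (sigma <= lambda/50) the CSF-weighted
        VS converges onto the Strehl approximation; at larger aberrations
        it sits above it because the neural weight discounts the high
        spatial frequencies that defocus destroys first."""
        grid = GridSpec(pupil_radius_mm=3.0, n_pupil=256)
        for frac in (100.0, 50.0):
            c4 = LAMBDA_UM / frac
            z = ZernikeCoefficients({4: c4}, 3.0)
            vs = visual_strehl(evaluate_wavefront(z, grid))
            marechal = math.exp(-((2 * math.pi * c4 / LAMBDA_UM) ** 2))
            assert vs == pytest.approx(marechal, rel=0.02)
            assert vs >= marechal - 1e-6

    def test_csf_peak_and_cutoff(self):
        f = np.array([0.0, 4.0, 59.0, 61.0])
        w = neural_csf(f)
        assert w[1] == 1.0
        assert w[0] == 0.0 and w[3] == 0.0
        assert 0 < w[2] < 1


class TestDialSharpness:
    def _render_dial(self, scene, bin_factor=2):
        chart = make_clock_dial(
            pixel_scale_arcmin=scene.psf_binned(bin_factor).pixel_scale_arcmin
        )
        return scene.render(chart, bin_factor=bin_factor), chart

    def test_diffraction_limited_scores_equal(self):
        scene = scene_with(SpheroCylinder(), pupil_radius=2.0)
        img, chart = self._render_dial(scene)
        d = dial_line_sharpness(img, chart)
        vals = np.array(list(d.scores.values()))
        assert vals.std() / vals.mean() < 0.03

    def test_vertical_line_sharpest_for_axis_180_astigmatism(self):
        # fogged eye needing minus cylinder at 180: vertical spoke wins
        scene = scene_with(
            SpheroCylinder(0.0, -0.75, 180.0), pupil_radius=2.0,
            phoropter=PhoropterState((SpheroCylinder(1.0),), 0.0),
        )
        img, chart = self._render_dial(scene)
        d = dial_line_sharpness(img, chart)
        assert d.sharpest_orientation == 90.0

    def test_equalizing_cylinder_minimizes_spread(self):
        fogged = PhoropterState((SpheroCylinder(1.0, -0.75, 180.0),), 0.0)
        corrected = scene_with(
            SpheroCylinder(0.0, -0.75, 180.0), pupil_radius=2.0,
            phoropter=fogged,
        )
        img, chart = self._render_dial(corrected)
        d_corr = dial_line_sharpness(img, chart)
        under = scene_with(
            SpheroCylinder(0.0, -0.75, 180.0), pupil_radius=2.0,
            phoropter=PhoropterState((SpheroCylinder(1.0, -0.25, 180.0),), 0.0),
        )
        img2, chart2 = self._render_dial(under)
        d_under = dial_line_sharpness(img2, chart2)
        assert d_corr.relative_spread < d_under.relative_spread

    def test_wrong_chart_kind_rejected(self):
        img = RetinalImage(np.zeros((8, 8)), 1.0)
        chart = make_letter_line(0.0, "N", 1.0)
        with pytest.raises(ValueError):
            dial_line_sharpness(img, chart)


class TestImagePairSimilarity:
    def test_identical_images_score_one(self, rng):
        a = RetinalImage(rng.random((32, 32)), 0.5)
        assert image_pair_similarity(a, a) == pytest.approx(1.0)

    def test_defocused_pair_scores_below_one_and_symmetric(self):
        scene = scene_with(SpheroCylinder(), pupil_radius=2.0)
        blurred = scene.with_extra_sphere(0.25)
        chart = make_letter_line(0.3, "NC", scene.psf.pixel_scale_arcmin)
        a = scene.render(chart)
        b = blurred.render(chart)
        s_ab = image_pair_similarity(a, b)
        assert s_ab < 1.0
        assert s_ab == pytest.approx(image_pair_similarity(b, a), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        a = RetinalImage(np.zeros((8, 8)), 1.0)
        b = RetinalImage(np.zeros((9, 8)), 1.0)
        with pytest.raises(ValueError):
            image_pair_similarity(a, b)


class TestDefocusCurve:
    def test_peaks_at_zero_for_plain_eye(self):
        scene = scene_with(SpheroCylinder())
        grid = np.arange(-1.0, 1.01, 0.25)
        curve = defocus_curve(scene, grid)
        assert curve.defocus_d[np.argmax(curve.vs_ratio)] == pytest.approx(0.0)

    def test_single_point_matches_static_scene(self):
        scene = scene_with(SpheroCylinder())
        curve = defocus_curve(scene, [-0.5])
        static = scene_visual_strehl(scene.with_extra_sphere(-0.5))
        assert curve.vs_ratio[0] == pytest.approx(static, abs=1e-12)

    def test_order_independent(self):
        scene = scene_with(SpheroCylinder())
        grid = [-0.5, 0.0, 0.5]
        fwd = defocus_curve(scene, grid).vs_ratio
        rev = defocus_curve(scene, grid[::-1]).vs_ratio
        assert np.allclose(fwd, rev[::-1])

    def test_non_finite_grid_rejected(self):
        with pytest.raises(ValueError):
            defocus_curve(scene_with(SpheroCylinder()), [0.0, np.nan])


class TestEstimateVa:
    def test_aberration_free_eye_reaches_zero_logmar(self):
        scene = scene_with(SpheroCylinder())
        assert estimate_va(scene) <= 0.0

    def test_two_diopters_uncorrected_worse_than_zero(self):
        scene = scene_with(SpheroCylinder()).with_extra_sphere(2.0)
        assert estimate_va(scene) > 0.0

    def test_non_decreasing_in_defocus(self):
        scene = scene_with(SpheroCylinder(), pupil_radius=2.0)
        vas = [
            estimate_va(scene.with_extra_sphere(d))
            for d in (0.0, 0.5, 1.0, 1.5, 2.0)
        ]
        assert all(b >= a for a, b in zip(vas, vas[1:]))
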