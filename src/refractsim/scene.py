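"""A complete optical scene: eye + phoropter + optional JCC and contact
lens, with cached wavefront/PSF computation and chart rendering."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np

from .eye_lenses import (
    JCCState,
    MultifocalDesign,
    PhoropterState,
    SchematicEye,
    lens_phase,
    total_phase,
)
from .fourier_optics import (
    PSFImage,
    PupilFunction,
    RetinalImage,
    compute_psf,
    render_retinal_image,
)
from .grids import GridSpec, WavefrontMap
from .optotypes import Chart
from .powers import SpheroCylinder


def bin_psf(psf: PSFImage, factor: int) -> PSFImage:
    """Sum-pool a PSF by an integer factor (pixel scale grows, sum kept)."""
    if factor == 1:
        return psf
    n = psf.intensity.shape[0]
    if n % factor:
        raise ValueError("bin factor must divide the PSF size")
    m = n // factor
    binned = psf.intensity.reshape(m, factor, m, factor).sum(axis=(1, 3))
    return PSFImage(binned, psf.pixel_scale_arcmin * factor, psf.grid)


@dataclass(frozen=True)
class Scene:
    """Immutable scene; derived optics are cached on first use."""

    eye: SchematicEye
    phoropter: PhoropterState = field(default_factory=PhoropterState)
    jcc: JCCState | None = None
    contact_lens: MultifocalDesign | None = None
    extra_sphere_d: float = 0.0  # through-focus sphere applied at the pupil
    n_pupil: int = 256
    pad_factor: int = 4
    description: str = ""

    @cached_property
    def grid(self) -> GridSpec:
        return GridSpec(
            pupil_radius_mm=self.eye.pupil_radius_mm,
            wavelength_nm=self.eye.wavelength_nm,
            n_pupil=self.n_pupil,
            pad_factor=self.pad_factor,
        )

    @cached_property
    def wavefront(self) -> WavefrontMap:
        w = total_phase(
            self.eye, self.phoropter, self.jcc, self.contact_lens, self.grid
        )
        if self.extra_sphere_d:
            w = w + lens_phase(
                SpheroCylinder(self.extra_sphere_d), 0.0, self.grid
            )
        return w

    @cached_property
    def psf(self) -> PSFImage:
        return compute_psf(PupilFunction(self.wavefront))

    def psf_binned(self, factor: int) -> PSFImage:
        return bin_psf(self.psf, factor)

    def render(
        self,
        chart: Chart,
        bin_factor: int = 1,
        apply_sm: bool = False,
        mode: str = "same",
    ) -> RetinalImage:
        """Retinal image of a chart through this scene.

        ``apply_sm`` applies the anamorphic spectacle magnification of the
        phoropter stack to the paraxial image before convolution.
        """
        sm = self.phoropter.magnification() if apply_sm else None
        return render_retinal_image(
            chart.image,
            chart.pixel_scale_arcmin,
            self.psf_binned(bin_factor),
            magnification=sm,
            mode=mode,
            provenance=self.description,
        )

    def with_jcc(self, jcc: JCCState | None) -> "Scene":
        return replace(self, jcc=jcc)

    def with_trial(self, trial: SpheroCylinder) -> "Scene":
        return replace(
            self,
            phoropter=PhoropterState(
                (trial,), self.phoropter.vertex_distance_m
            ),
        )

    def with_extra_sphere(self, power_d: float) -> "Scene":
        return replace(self, extra_sphere_d=power_d)

    @property
    def trial(self) -> SpheroCylinder:
        return self.phoropter.combined_power()


def diffraction_limited(scene_or_grid) -> PSFImage:
    """Zero-phase PSF on the same grid (reference for Strehl/VS)."""
    grid = (
        scene_or_grid if isinstance(scene_or_grid, GridSpec)
        else scene_or_grid.grid
    )
    zero = WavefrontMap(
        np.zeros((grid.n_pupil, grid.n_pupil)), grid
    )
    return compute_psf(PupilFunction(zero))
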