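"""Fourier-optics image formation.

The complex pupil function P(x, y) = p(x, y) exp(-i 2 pi W_T(x, y) / lambda)
is zero-padded and Fourier transformed; the PSF is |F(P)|^2, normalized to
unit sum.  The retinal image of a chart is the convolution of its paraxial
image (after anamorphic spectacle magnification) with the PSF.  All imagery
lives in visual-angle coordinates (arcmin); conversion to retinal microns
through the schematic-eye focal length is a reporting utility only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .grids import ARCMIN_PER_RAD, GridSpec, WavefrontMap

__all__ = [
    "PupilFunction",
    "PSFImage",
    "RetinalImage",
    "compute_psf",
    "strehl_ratio",
    "apply_magnification",
    "render_retinal_image",
    "render_interferogram",
    "arcmin_to_retinal_um",
]


@dataclass
class PupilFunction:
    """Circular top-hat amplitude with the total phase W_T (um)."""

    phase: WavefrontMap

    @property
    def grid(self) -> GridSpec:
        return self.phase.grid

    def complex_values(self) -> np.ndarray:
        grid = self.grid
        mask = self.phase.valid_mask
        lam_um = grid.wavelength_nm * 1e-3
        p = np.zeros((grid.n_pupil, grid.n_pupil), dtype=complex)
        w = self.phase.values
        p[mask] = np.exp(-1j * 2.0 * np.pi * w[mask] / lam_um)
        return p


@dataclass
class PSFImage:
    """Point-spread function on the padded grid, unit sum."""

    intensity: np.ndarray
    pixel_scale_arcmin: float
    grid: GridSpec

    @property
    def center_index(self) -> int:
        return self.intensity.shape[0] // 2


@dataclass
class RetinalImage:
    """Rendered retinal intensity with angular sampling metadata."""

    intensity: np.ndarray
    pixel_scale_arcmin: float
    provenance: str = ""


def compute_psf(pf: PupilFunction) -> PSFImage:
    """PSF = |FT(P)|^2, centred on the geometric centre pixel, unit sum.

    Raises on non-finite phase values inside the pupil (NaN guard).
    """
    grid = pf.grid
    if not np.all(np.isfinite(pf.phase.values[pf.phase.valid_mask])):
        raise ValueError("non-finite phase inside the pupil")
    n, nf = grid.n_pupil, grid.n_fft
    field = np.zeros((nf, nf), dtype=complex)
    lo = nf // 2 - n // 2
    field[lo : lo + n, lo : lo + n] = pf.complex_values()
    amp = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field)))
    psf = np.abs(amp) ** 2
    total = psf.sum()
    if total == 0.0:
        raise ValueError("empty pupil")
    return PSFImage(psf / total, grid.dtheta_arcmin, grid)


def strehl_ratio(psf: PSFImage, reference: PSFImage) -> float:
    """Peak intensity relative to a reference (usually diffraction-limited)
    PSF computed on the same grid."""
    return float(psf.intensity.max() / reference.intensity.max())


def apply_magnification(
    image: np.ndarray,
    sm: tuple[float, float, float],
) -> np.ndarray:
    """Anamorphic scaling of a paraxial image about its centre.

    ``sm`` is (SM1 along the meridian, SM2 perpendicular to it, meridian
    angle in degrees, counter-clockwise from horizontal).  Implemented as a
    rotate-scale-rotate affine with bilinear resampling on the same canvas.
    """
    sm1, sm2, meridian = sm
    if sm1 <= 0 or sm2 <= 0:
        raise ValueError("magnification components must be positive")
    if abs(sm1 - 1.0) < 1e-12 and abs(sm2 - 1.0) < 1e-12:
        return np.array(image, dtype=float, copy=True)
    img = np.asarray(image, dtype=float)
    phi = math.radians(meridian)
    c, s = math.cos(phi), math.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    scale = np.diag([1.0 / sm1, 1.0 / sm2])
    # map output (x, y) -> input; y is row-down in array coordinates, so
    # conjugate with the row flip to keep angles counter-clockwise on screen
    mat_xy = rot @ scale @ rot.T
    flip = np.diag([1.0, -1.0])
    mat_xy = flip @ mat_xy @ flip
    mat_rc = mat_xy[::-1, ::-1].T  # (x, y) -> (row, col) ordering
    center = (np.array(img.shape) - 1) / 2.0
    offset = center - mat_rc @ center
    return ndimage.affine_transform(
        img, mat_rc, offset=offset, order=1, mode="constant", cval=0.0
    )


def render_retinal_image(
    chart_image: np.ndarray,
    chart_pixel_scale_arcmin: float,
    psf: PSFImage,
    magnification: tuple[float, float, float] | None = None,
    mode: str = "same",
    provenance: str = "",
) -> RetinalImage:
    """Convolve a paraxial chart image with the PSF.

    The chart (an "emission" raster: ink bright, background zero) is
    resampled to the PSF pixel scale if necessary, optionally distorted by
    the anamorphic spectacle magnification, then convolved in the frequency
    domain.  With a unit-sum PSF the total flux is conserved (``mode="full"``
    keeps the whole support; ``mode="same"`` crops to the chart extent).
    """
    img = np.asarray(chart_image, dtype=float)
    ratio = chart_pixel_scale_arcmin / psf.pixel_scale_arcmin
    if abs(ratio - 1.0) > 1e-9:
        img = ndimage.zoom(img, ratio, order=1, mode="constant", cval=0.0)
    if magnification is not None:
        img = apply_magnification(img, magnification)
    if mode not in ("same", "full"):
        raise ValueError("mode must be 'same' or 'full'")
    out = signal.fftconvolve(img, psf.intensity, mode="full")
    if mode == "same":
        # crop about the PSF centre pixel so that a delta chart reproduces
        # the PSF exactly (scipy's own "same" is half a sample off for the
        # even-sized kernel)
        c = psf.center_index
        out = out[c : c + img.shape[0], c : c + img.shape[1]]
    np.clip(out, 0.0, None, out=out)
    return RetinalImage(out, psf.pixel_scale_arcmin, provenance)


def render_interferogram(w: WavefrontMap) -> np.ndarray:
    """Two-beam interferogram of a wavefront: 1/2 [1 + cos(2 pi W / lambda)]
    inside the pupil, zero outside."""
    lam_um = w.grid.wavelength_nm * 1e-3
    img = np.zeros_like(w.values)
    m = w.valid_mask
    img[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * w.values[m] / lam_um))
    return img


def arcmin_to_retinal_um(
    arcmin: float, focal_length_mm: float = 22.4
) -> float:
    """Visual angle (arcmin) to distance on the retina (um) through the
    schematic-eye focal length."""
    return arcmin / ARCMIN_PER_RAD * focal_length_mm * 1e3
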