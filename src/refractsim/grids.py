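"""Sampling grids and wavefront maps.

All pupil-plane quantities live on a square Cartesian grid of ``n_pupil``
samples across the pupil *diameter*.  For image formation the pupil patch is
zero-padded to ``n_fft = n_pupil * pad_factor`` samples, which fixes the
angular sampling of the point-spread function:

    dtheta = lambda / (n_fft * dx)   [rad/pixel],  dx = 2 R / n_pupil.

The grid uses the "center at index n//2" convention: sample i sits at
x_i = (i - n//2) * dx, so an even-sized grid has one sample exactly at the
origin and FFT centering is done with fftshift/ifftshift pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARCMIN_PER_RAD = 180.0 * 60.0 / np.pi


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the pupil sampling grid.

    Parameters
    ----------
    pupil_radius_mm : float
        Radius of the (entrance) pupil, mm.
    wavelength_nm : float
        Design wavelength, nm (monochromatic; 587 nm by default).
    n_pupil : int
        Samples across the pupil diameter.
    pad_factor : int
        Zero-padding factor for the FFT (>= 2).
    """

    pupil_radius_mm: float
    wavelength_nm: float = 587.0
    n_pupil: int = 256
    pad_factor: int = 4

    def __post_init__(self) -> None:
        if self.pupil_radius_mm <= 0:
            raise ValueError("pupil_radius_mm must be positive")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")
        if self.n_pupil < 8:
            raise ValueError("n_pupil too small")
        if self.pad_factor < 2:
            raise ValueError("pad_factor must be >= 2")

    @property
    def dx_mm(self) -> float:
        """Pupil-plane sample spacing, mm."""
        return 2.0 * self.pupil_radius_mm / self.n_pupil

    @property
    def n_fft(self) -> int:
        return self.n_pupil * self.pad_factor

    @property
    def dtheta_rad(self) -> float:
        """PSF angular sampling, rad/pixel."""
        lam_mm = self.wavelength_nm * 1e-6
        return lam_mm / (self.n_fft * self.dx_mm)

    @property
    def dtheta_arcmin(self) -> float:
        """PSF angular sampling, arcmin/pixel."""
        return self.dtheta_rad * ARCMIN_PER_RAD

    def pupil_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate grids over the pupil patch, mm.

        y increases upward (row index decreasing), x increases with column.
        """
        n = self.n_pupil
        c = (np.arange(n) - n // 2) * self.dx_mm
        x = c[np.newaxis, :]
        y = -c[:, np.newaxis]
        return np.broadcast_arrays(x, y)

    def pupil_mask(self) -> np.ndarray:
        x, y = self.pupil_coords_mm()
        return x * x + y * y <= self.pupil_radius_mm**2


@dataclass
class WavefrontMap:
    """Optical path difference over the pupil, in micrometres.

    ``values`` is defined on the pupil patch of ``grid`` (n_pupil x n_pupil);
    entries outside ``valid_mask`` are zero.
    """

    values: np.ndarray
    grid: GridSpec
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = self.grid.pupil_mask()
        if self.values.shape != (self.grid.n_pupil, self.grid.n_pupil):
            raise ValueError("wavefront shape does not match grid")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite wavefront values inside the pupil")

    def __add__(self, other: "WavefrontMap") -> "WavefrontMap":
        if other.grid != self.grid:
            raise ValueError("cannot add wavefronts on different grids")
        return WavefrontMap(
            self.values + other.values, self.grid,
            self.valid_mask & other.valid_mask,
        )

    def peak_to_valley_um(self) -> float:
        v = self.values[self.valid_mask]
        return float(v.max() - v.min())

    def rms_um(self) -> float:
        v = self.values[self.valid_mask]
        return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def zero_wavefront(grid: GridSpec) -> WavefrontMap:
    return WavefrontMap(np.zeros((grid.n_pupil, grid.n_pupil)), grid)
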