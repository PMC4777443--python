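"""The optical scene: reduced schematic eye, virtual phoropter with vertex
transposition, Jackson Cross Cylinder states and concentric-ring multifocal
contact lenses, combined into the total pupil-plane phase

    W_T(x, y) = W_eye + sum(W_lens) + S * W_JCC  [+ W_CL]

with S the activation step of the cross cylinder.

Sign convention: a physical thin lens of power vector (M, J0, J45) placed at
the pupil contributes

    W(x, y) = +1/2 [ M (x^2 + y^2) + J0 (x^2 - y^2) + 2 J45 x y ]   (um)

with x, y in mm and powers in D, so a lens equal to the eye's manifest
refraction nulls the second-order wavefront.  Phoropter lenses are first
vertex-transposed to the pupil plane, meridian by meridian; a contact lens
sits in the pupil plane and needs no transposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import GridSpec, WavefrontMap, zero_wavefront
from .powers import (
    SpheroCylinder,
    spectacle_magnification_sc,
    transpose_to_pupil,
)
from .zernike import (
    ZernikeCoefficients,
    evaluate_wavefront,
    rescale_coefficients,
)

# Reduced schematic eye of the simulator: a single refracting surface with
# these constants; aberrometry is layered on top of it.
DEFAULT_FOCAL_LENGTH_MM = 22.4
DEFAULT_REFRACTIVE_INDEX = 1.33
DEFAULT_WAVELENGTH_NM = 587.0
DEFAULT_VERTEX_DISTANCE_M = 0.015  # 12 mm spectacle vertex + 3 mm to pupil


@dataclass(frozen=True)
class SchematicEye:
    """Reduced schematic eye carrying a subject's aberrometry."""

    aberrometry: ZernikeCoefficients
    pupil_radius_mm: float | None = None
    focal_length_mm: float = DEFAULT_FOCAL_LENGTH_MM
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM

    def __post_init__(self) -> None:
        if self.focal_length_mm <= 0 or self.wavelength_nm <= 0:
            raise ValueError("focal length and wavelength must be positive")
        r = self.pupil_radius_mm
        if r is None:
            object.__setattr__(
                self, "pupil_radius_mm", self.aberrometry.pupil_radius_mm
            )
        elif r <= 0 or r > self.aberrometry.pupil_radius_mm * (1 + 1e-12):
            raise ValueError(
                "entrance pupil radius must lie in (0, aberrometry radius]"
            )

    def rescaled_aberrometry(self) -> ZernikeCoefficients:
        return rescale_coefficients(self.aberrometry, self.pupil_radius_mm)

    def wavefront(self, grid: GridSpec) -> WavefrontMap:
        z = self.rescaled_aberrometry().drop_piston_tilt()
        return evaluate_wavefront(z, grid)


@dataclass(frozen=True)
class PhoropterState:
    """Stack of trial lenses at a common vertex distance from the pupil."""

    lenses: tuple[SpheroCylinder, ...] = ()
    vertex_distance_m: float = DEFAULT_VERTEX_DISTANCE_M

    def __post_init__(self) -> None:
        if self.vertex_distance_m < 0:
            raise ValueError("vertex distance must be >= 0")
        object.__setattr__(self, "lenses", tuple(self.lenses))

    def combined_power(self) -> SpheroCylinder:
        """Power-vector sum of the stack at the phoropter plane."""
        total = SpheroCylinder()
        for lens in self.lenses:
            total = total + lens
        return total

    def magnification(self) -> tuple[float, float, float]:
        """(SM1, SM2, meridian) of the combined stack at its vertex."""
        return spectacle_magnification_sc(
            self.combined_power(), self.vertex_distance_m
        )


@dataclass(frozen=True)
class JCCState:
    """Jackson Cross Cylinder: equal plus and minus cylinders crossed at 90.

    ``axis`` is the axis of the *minus* cylinder; flipping swaps the plus
    and minus cylinders, i.e. rotates the minus axis by 90 degrees.  The
    equivalent sphero-cylinder is S = +P, C = -2P at the current minus axis,
    whose spherical equivalent is exactly zero.
    """

    power: float = 0.50
    axis: float = 0.0
    flipped: bool = False
    active: bool = True
    mode: str = "axis-search"

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("JCC power must be positive")
        if self.mode not in ("axis-search", "power-search"):
            raise ValueError(f"unknown JCC mode {self.mode!r}")

    @property
    def minus_axis(self) -> float:
        return (self.axis + (90.0 if self.flipped else 0.0)) % 180.0

    def equivalent_sphero_cylinder(self) -> SpheroCylinder:
        return SpheroCylinder(self.power, -2.0 * self.power, self.minus_axis)

    def flip(self) -> "JCCState":
        return replace(self, flipped=not self.flipped)


@dataclass(frozen=True)
class MultifocalDesign:
    """Concentric-ring multifocal contact lens.

    ``zones`` lists (outer_radius_mm, add_power_D) from the centre outward;
    the lens is assumed to cover the whole pupil.
    """

    zones: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        zones = tuple((float(r), float(a)) for r, a in self.zones)
        if not zones:
            raise ValueError("a multifocal design needs at least one zone")
        radii = [r for r, _ in zones]
        if any(r <= 0 for r in radii) or any(
            r2 <= r1 for r1, r2 in zip(radii, radii[1:])
        ):
            raise ValueError("zone outer radii must be positive, increasing")
        object.__setattr__(self, "zones", zones)

    @property
    def outer_radius_mm(self) -> float:
        return self.zones[-1][0]


def centre_near_trifocal(
    add_power: float = 2.00, intermediate_add: float = 1.00
) -> MultifocalDesign:
    """CL1-style design: centre-near, intermediate transition ring, outer
    distance zone (adds +2.00, +1.00, 0.00 D from centre outward)."""
    return MultifocalDesign(
        zones=((1.5, add_power), (2.25, intermediate_add), (3.0, 0.0)),
        label="CL1 centre-near with intermediate ring",
    )


def centre_near_alternating(add_power: float = 2.00) -> MultifocalDesign:
    """CL2-style design: centre-near with alternating near/distance rings
    and no intermediate zone (adds +2.00, 0.00, +2.00 D)."""
    return MultifocalDesign(
        zones=((1.5, add_power), (2.25, 0.0), (3.0, add_power)),
        label="CL2 centre-near alternating, no intermediate zone",
    )


def lens_phase(
    sc: SpheroCylinder,
    vertex_distance_m: float,
    grid: GridSpec,
) -> WavefrontMap:
    """Pupil-plane phase of a thin phoropter lens (um).

    The power is first vertex-transposed to the pupil plane per principal
    meridian, then expanded as the quadratic power-vector phase.
    """
    eff = transpose_to_pupil(sc, vertex_distance_m)
    m, j0, j45 = eff.power_vector()
    x, y = grid.pupil_coords_mm()
    mask = grid.pupil_mask()
    w = 0.5 * (m * (x * x + y * y) + j0 * (x * x - y * y) + 2.0 * j45 * x * y)
    w[~mask] = 0.0
    return WavefrontMap(w, grid, mask)


def jcc_phase(
    jcc: JCCState, vertex_distance_m: float, grid: GridSpec
) -> WavefrontMap:
    """Phase of the cross cylinder in its current flip state; the inactive
    state contributes a zero map (Heaviside gate of the total phase)."""
    if not jcc.active:
        return zero_wavefront(grid)
    return lens_phase(jcc.equivalent_sphero_cylinder(), vertex_distance_m, grid)


def multifocal_phase(design: MultifocalDesign, grid: GridSpec) -> WavefrontMap:
    """Piecewise-quadratic phase of a concentric-ring contact lens.

    Each annulus contributes the defocus phase of its add power; the lens
    sits in the pupil plane, so no vertex transposition or magnification
    applies.  Discontinuities at ring boundaries are permitted.
    """
    if design.outer_radius_mm < grid.pupil_radius_mm * (1 - 1e-12):
        raise ValueError("contact lens zones do not cover the pupil")
    x, y = grid.pupil_coords_mm()
    r2 = x * x + y * y
    mask = grid.pupil_mask()
    w = np.zeros_like(r2)
    inner = 0.0
    for outer, add in design.zones:
        ring = (r2 >= inner**2) & (r2 < outer**2)
        w[ring] = 0.5 * add * r2[ring]
        inner = outer
    w[r2 >= inner**2] = 0.0
    w[~mask] = 0.0
    return WavefrontMap(w, grid, mask)


def total_phase(
    eye: SchematicEye,
    phoropter: PhoropterState | None = None,
    jcc: JCCState | None = None,
    contact_lens: MultifocalDesign | None = None,
    grid: GridSpec | None = None,
) -> WavefrontMap:
    """Total pupil-plane phase W_T of the scene (um)."""
    if grid is None:
        grid = GridSpec(
            pupil_radius_mm=eye.pupil_radius_mm,
            wavelength_nm=eye.wavelength_nm,
        )
    if abs(grid.pupil_radius_mm - eye.pupil_radius_mm) > 1e-12:
        raise ValueError("grid pupil radius must match the eye pupil radius")
    w = eye.wavefront(grid)
    if phoropter is not None:
        for lens in phoropter.lenses:
            w = w + lens_phase(lens, phoropter.vertex_distance_m, grid)
    if jcc is not None and jcc.active:
        d_v = phoropter.vertex_distance_m if phoropter is not None else 0.0
        w = w + jcc_phase(jcc, d_v, grid)
    if contact_lens is not None:
        w = w + multifocal_phase(contact_lens, grid)
    return w
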