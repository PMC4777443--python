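"""Sphero-cylindrical powers, power vectors, vertex transposition and
spectacle magnification.

A prescription is written (S, C x alpha) with the cylinder in minus form and
the axis in TABO notation: degrees counter-clockwise from the horizontal as
seen by the observer, in [0, 180).  The equivalent power vector is

    M   = S + C/2
    J0  = -(C/2) cos 2a
    J45 = -(C/2) sin 2a

which is additive under thin-lens stacking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class SpheroCylinder:
    """Thin sphero-cylindrical lens power (dioptres), minus-cylinder form."""

    sphere: float = 0.0
    cylinder: float = 0.0
    axis: float = 0.0

    def canonical(self) -> "SpheroCylinder":
        """Minus-cylinder form with axis in [0, 180); axis 0 when C == 0."""
        s, c, a = self.sphere, self.cylinder, self.axis
        if c > 0:  # transpose plus-cyl to minus-cyl
            s, c, a = s + c, -c, a + 90.0
        if c == 0:
            return SpheroCylinder(s, 0.0, 0.0)
        a = a % 180.0
        if a == 0.0:  # clinical notation writes the horizontal axis as 180
            a = 180.0
        return SpheroCylinder(s, c, a)

    @property
    def spherical_equivalent(self) -> float:
        return self.sphere + self.cylinder / 2.0

    def power_vector(self) -> tuple[float, float, float]:
        """(M, J0, J45) in dioptres."""
        sc = self.canonical()
        two_a = 2.0 * math.radians(sc.axis)
        half_c = sc.cylinder / 2.0
        return (
            sc.sphere + half_c,
            -half_c * math.cos(two_a),
            -half_c * math.sin(two_a),
        )

    @staticmethod
    def from_power_vector(m: float, j0: float, j45: float) -> "SpheroCylinder":
        """Inverse map; returns minus-cylinder form, axis in [0, 180)."""
        cyl_mag = math.hypot(j0, j45)
        if cyl_mag == 0.0:
            return SpheroCylinder(m, 0.0, 0.0)
        c = -2.0 * cyl_mag
        a = math.degrees(math.atan2(j45, j0)) / 2.0 % 180.0
        s = m - c / 2.0
        return SpheroCylinder(s, c, a).canonical()

    def principal_powers(self) -> tuple[float, float, float]:
        """(power along axis meridian, power along cross meridian, axis)."""
        sc = self.canonical()
        return sc.sphere, sc.sphere + sc.cylinder, sc.axis

    def __add__(self, other: "SpheroCylinder") -> "SpheroCylinder":
        m1, j01, j451 = self.power_vector()
        m2, j02, j452 = other.power_vector()
        return SpheroCylinder.from_power_vector(m1 + m2, j01 + j02, j451 + j452)

    def __neg__(self) -> "SpheroCylinder":
        m, j0, j45 = self.power_vector()
        return SpheroCylinder.from_power_vector(-m, -j0, -j45)

    def is_plano(self, tol: float = 1e-12) -> bool:
        m, j0, j45 = self.power_vector()
        return abs(m) < tol and abs(j0) < tol and abs(j45) < tol

    def __str__(self) -> str:
        sc = self.canonical()
        if sc.cylinder == 0:
            return f"{sc.sphere:+.2f} DS"
        return f"{sc.sphere:+.2f} {sc.cylinder:+.2f} x {sc.axis:.0f}"


PLANO = SpheroCylinder(0.0, 0.0, 0.0)


def effective_power_at_pupil(power_d: float, vertex_distance_m: float) -> float:
    """Transpose a thin-lens power (D) from the phoropter plane to the
    entrance-pupil plane a distance ``vertex_distance_m`` behind it:

        F' = F / (1 - d_v F).
    """
    denom = 1.0 - vertex_distance_m * power_d
    if denom == 0.0:
        raise ValueError("lens focal point coincides with the pupil plane")
    return power_d / denom


def transpose_to_pupil(sc: SpheroCylinder, vertex_distance_m: float) -> SpheroCylinder:
    """Vertex-transpose a sphero-cylinder, meridian by meridian."""
    f1, f2, axis = sc.principal_powers()
    f1p = effective_power_at_pupil(f1, vertex_distance_m)
    f2p = effective_power_at_pupil(f2, vertex_distance_m)
    return SpheroCylinder(f1p, f2p - f1p, axis).canonical()


def spectacle_magnification(power_d: float, vertex_distance_m: float) -> float:
    """SM = 1 / (1 - d_v F) for a single thin-lens power."""
    denom = 1.0 - vertex_distance_m * power_d
    if denom == 0.0:
        raise ValueError("lens focal point coincides with the pupil plane")
    return 1.0 / denom


def spectacle_magnification_sc(
    sc: SpheroCylinder, vertex_distance_m: float
) -> tuple[float, float, float]:
    """Anamorphic magnification of a sphero-cylinder.

    Returns (SM along the axis meridian, SM along the cross meridian,
    axis meridian angle in degrees).  A power acting in meridian phi
    magnifies along that meridian, so the axis meridian (power S) scales
    by SM(S) and the perpendicular meridian by SM(S + C).
    """
    f1, f2, axis = sc.principal_powers()
    return (
        spectacle_magnification(f1, vertex_distance_m),
        spectacle_magnification(f2, vertex_distance_m),
        axis,
    )


def axis_difference_deg(a: float, b: float) -> float:
    """Smallest angular separation of two cylinder axes (mod 180)."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)
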