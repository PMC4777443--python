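"""Zernike polynomial algebra over a circular pupil.

Coefficients follow the OSA/ANSI single-index ordering with *orthonormal*
normalization, so the total wavefront RMS is the Euclidean norm of the
coefficient vector.  The single index j maps to radial order n and azimuthal
frequency m through j = (n(n+2) + m) / 2.

Units: coefficients and wavefronts in micrometres (um), pupil radii in mm,
powers in dioptres (D).

Convention linking second-order coefficients to the manifest refraction
(power vector M, J0, J45 of the *correcting* prescription):

    c(2,0)  = -M   R^2 / (4 sqrt(3))
    c(2,2)  = -J0  R^2 / (2 sqrt(6))
    c(2,-2) = -J45 R^2 / (2 sqrt(6))

with R the pupil radius in mm.  A myopic eye therefore carries a positive
defocus coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .grids import GridSpec, WavefrontMap
from .powers import SpheroCylinder

SQRT3 = math.sqrt(3.0)
SQRT6 = math.sqrt(6.0)

# OSA single indices of the second-order terms
J_ASTIG_OBLIQUE = 3   # (n, m) = (2, -2)
J_DEFOCUS = 4         # (2, 0)
J_ASTIG_WTR = 5       # (2, +2)


def osa_to_nm(j: int) -> tuple[int, int]:
    """OSA single index -> (radial order n, azimuthal frequency m)."""
    if j < 0 or int(j) != j:
        raise ValueError(f"invalid OSA index {j!r}")
    n = int(math.ceil((-3.0 + math.sqrt(9.0 + 8.0 * j)) / 2.0))
    m = 2 * j - n * (n + 2)
    return n, m


def nm_to_osa(n: int, m: int) -> int:
    if n < 0 or abs(m) > n or (n - m) % 2:
        raise ValueError(f"invalid (n, m) = ({n}, {m})")
    return (n * (n + 2) + m) // 2


def radial_poly_coeffs(n: int, m: int) -> np.ndarray:
    """Monomial coefficients of the radial polynomial R_n^|m|.

    Returns array ``a`` with R(rho) = sum_p a[p] rho^p (length n+1).
    """
    m = abs(m)
    a = np.zeros(n + 1)
    for k in range((n - m) // 2 + 1):
        a[n - 2 * k] = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)
            )
        )
    return a


def norm_factor(n: int, m: int) -> float:
    """Orthonormal normalization N_n^m = sqrt(2(n+1)/(1+delta_m0))."""
    return math.sqrt(2.0 * (n + 1) / (1.0 + (1 if m == 0 else 0)))


def zernike_values(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Sample the orthonormal Zernike polynomial Z_j on (rho, theta)."""
    n, m = osa_to_nm(j)
    a = radial_poly_coeffs(n, m)
    radial = np.polynomial.polynomial.polyval(rho, a)
    nf = norm_factor(n, m)
    if m > 0:
        return nf * radial * np.cos(m * theta)
    if m < 0:
        return nf * radial * np.sin(-m * theta)
    return nf * radial


@dataclass(frozen=True)
class ZernikeCoefficients:
    """OSA-indexed wavefront coefficients (um) bound to a pupil radius (mm)."""

    coeffs: dict[int, float] = field(default_factory=dict)
    pupil_radius_mm: float = 3.0
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.pupil_radius_mm <= 0:
            raise ValueError("pupil_radius_mm must be positive")
        clean = {}
        for j, c in self.coeffs.items():
            osa_to_nm(int(j))  # validates
            if c != 0.0:
                clean[int(j)] = float(c)
        object.__setattr__(self, "coeffs", clean)

    def __getitem__(self, j: int) -> float:
        return self.coeffs.get(j, 0.0)

    @property
    def max_order(self) -> int:
        if not self.coeffs:
            return 0
        return max(osa_to_nm(j)[0] for j in self.coeffs)

    def rms_total_um(self) -> float:
        return math.sqrt(sum(c * c for c in self.coeffs.values()))

    def with_coeff(self, j: int, value: float) -> "ZernikeCoefficients":
        d = dict(self.coeffs)
        d[j] = value
        return replace(self, coeffs=d)

    def drop_piston_tilt(self) -> "ZernikeCoefficients":
        d = {j: c for j, c in self.coeffs.items() if j > 2}
        return replace(self, coeffs=d)


def evaluate_wavefront(z: ZernikeCoefficients, grid: GridSpec) -> WavefrontMap:
    """Synthesize the wavefront W(x, y) = sum_j c_j Z_j(rho, theta) (um).

    The grid's physical half-width must reach the coefficient pupil radius;
    the map is zero outside the unit pupil.
    """
    if grid.pupil_radius_mm > z.pupil_radius_mm * (1 + 1e-12):
        raise ValueError(
            "grid pupil radius exceeds the aberrometry pupil radius; "
            "rescale the coefficients first"
        )
    x, y = grid.pupil_coords_mm()
    rho = np.hypot(x, y) / z.pupil_radius_mm
    theta = np.arctan2(y, x)
    mask = grid.pupil_mask()
    w = np.zeros_like(rho)
    for j, c in z.coeffs.items():
        w += c * zernike_values(j, rho, theta)
    w[~mask] = 0.0
    return WavefrontMap(w, grid, mask)


def _rescale_matrix_for_m(orders: list[int], m: int, eps: float) -> np.ndarray:
    """Transform matrix T with c'_n = sum_{n'} T[n, n'] c_{n'} for one |m|
    group when the pupil shrinks by factor eps = R_new / R_old.

    Derivation: restricting W to rho_old = eps * rho_new re-expands each
    radial polynomial as R_{n'}(eps rho) = sum_n b_{n n'} R_n(rho) with

        b_{n n'} = 2 (n+1) \\int_0^1 R_{n'}(eps rho) R_n(rho) rho d rho,

    evaluated exactly through the monomial coefficients; the orthonormal
    normalization contributes a factor sqrt((n'+1)/(n+1)).
    """
    size = len(orders)
    t = np.zeros((size, size))
    polys = {n: radial_poly_coeffs(n, abs(m)) for n in orders}
    for i, n in enumerate(orders):
        a_n = polys[n]
        for k, np_ in enumerate(orders):
            if np_ < n:
                continue
            a_src = polys[np_]
            # integral of R_{n'}(eps rho) R_n(rho) rho d rho, term by term
            integ = 0.0
            for q, aq in enumerate(a_src):
                if aq == 0.0:
                    continue
                eq = aq * eps**q
                for p, ap in enumerate(a_n):
                    if ap == 0.0:
                        continue
                    integ += eq * ap / (p + q + 2)
            t[i, k] = 2.0 * (n + 1) * integ * math.sqrt((np_ + 1) / (n + 1))
    return t


def rescale_coefficients(
    z: ZernikeCoefficients, new_radius_mm: float
) -> ZernikeCoefficients:
    """Re-express the wavefront over a smaller concentric pupil.

    The returned coefficients reproduce the original wavefront exactly on
    the sub-pupil (analytic triangular transform within each azimuthal
    group).  Up-scaling is rejected: it would extrapolate the measurement.
    """
    if new_radius_mm <= 0:
        raise ValueError("new_radius_mm must be positive")
    if new_radius_mm > z.pupil_radius_mm * (1 + 1e-12):
        raise ValueError("cannot rescale to a larger pupil (extrapolation)")
    if abs(new_radius_mm - z.pupil_radius_mm) < 1e-15:
        return z
    eps = new_radius_mm / z.pupil_radius_mm
    n_max = z.max_order
    new_coeffs: dict[int, float] = {}
    for m in range(-n_max, n_max + 1):
        orders = [n for n in range(abs(m), n_max + 1, 2)]
        c_vec = np.array([z[nm_to_osa(n, m)] for n in orders])
        if not np.any(c_vec):
            continue
        t = _rescale_matrix_for_m(orders, m, eps)
        c_new = t @ c_vec
        for n, c in zip(orders, c_new):
            new_coeffs[nm_to_osa(n, m)] = float(c)
    return ZernikeCoefficients(
        new_coeffs, new_radius_mm, source_label=z.source_label
    )


def rms(z: ZernikeCoefficients, min_radial_order: int = 0) -> float:
    """RMS wavefront error (um) over terms with radial order >= the given
    minimum; ``min_radial_order=3`` gives the higher-order RMS (RMS_HOA)."""
    if min_radial_order < 0:
        raise ValueError("min_radial_order must be >= 0")
    s = 0.0
    for j, c in z.coeffs.items():
        n, _ = osa_to_nm(j)
        if n >= min_radial_order:
            s += c * c
    return math.sqrt(s)


def sphero_cylinder_to_zernike(
    sc: SpheroCylinder, pupil_radius_mm: float
) -> ZernikeCoefficients:
    """Second-order Zernike representation of a manifest refraction.

    The argument is read as a *prescription* (the correcting lens powers);
    the returned coefficients are the wavefront of an eye whose subjective
    refraction equals that prescription, following the standard
    M = -4*sqrt(3)*c(2,0)/R^2 relation.
    """
    if pupil_radius_mm <= 0:
        raise ValueError("pupil_radius_mm must be positive")
    m, j0, j45 = sc.power_vector()
    r2 = pupil_radius_mm**2
    coeffs = {
        J_DEFOCUS: -m * r2 / (4.0 * SQRT3),
        J_ASTIG_WTR: -j0 * r2 / (2.0 * SQRT6),
        J_ASTIG_OBLIQUE: -j45 * r2 / (2.0 * SQRT6),
    }
    return ZernikeCoefficients(coeffs, pupil_radius_mm)


def zernike_to_sphero_cylinder(z: ZernikeCoefficients) -> SpheroCylinder:
    """Manifest refraction implied by the second-order coefficients
    (minus-cylinder form; exact inverse of sphero_cylinder_to_zernike)."""
    r2 = z.pupil_radius_mm**2
    m = -4.0 * SQRT3 * z[J_DEFOCUS] / r2
    j0 = -2.0 * SQRT6 * z[J_ASTIG_WTR] / r2
    j45 = -2.0 * SQRT6 * z[J_ASTIG_OBLIQUE] / r2
    return SpheroCylinder.from_power_vector(m, j0, j45)
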