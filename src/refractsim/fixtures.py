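"""Deterministic example eyes.

The two subjects discussed throughout the documentation are emulated, not
reproduced: only their published summary properties are honoured.

* ``P1_like`` — a low-order-aberration-only eye whose manifest refraction
  is plano sphere with -0.75 D of cylinder at 180 degrees.
* ``P2_like`` — an eye with irregular astigmatism: seeded random
  higher-order coefficients (radial orders 3-6) rescaled so that
  RMS_HOA is exactly 1.44 um, plus a second-order irregular-astigmatism
  component.  The individual coefficients are synthetic; any analysis that
  needs the real subject must load the measured table instead
  (:func:`load_s1_table`).
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np

from .powers import SpheroCylinder
from .zernike import (
    ZernikeCoefficients,
    nm_to_osa,
    rms,
    sphero_cylinder_to_zernike,
)

P1_REFRACTION = SpheroCylinder(0.0, -0.75, 180.0)
P2_RMS_HOA_UM = 1.44
DEFAULT_PUPIL_RADIUS_MM = 3.0


def make_eye(
    kind: str,
    seed: int = 0,
    pupil_radius_mm: float = DEFAULT_PUPIL_RADIUS_MM,
    refraction: SpheroCylinder | None = None,
) -> ZernikeCoefficients:
    """Build a reproducible example eye.

    kind:
      - "emmetrope": all-zero coefficients.
      - "P1_like": second-order terms only, manifest refraction
        plano -0.75 x 180 (override with ``refraction``).
      - "P2_like": irregular astigmat, RMS over radial orders >= 3 pinned
        to 1.44 um; ``seed`` selects the higher-order pattern.
      - "custom": second-order eye from the given ``refraction``.
    """
    if kind == "emmetrope":
        return ZernikeCoefficients({}, pupil_radius_mm, "emmetrope fixture")
    if kind == "P1_like":
        rx = refraction if refraction is not None else P1_REFRACTION
        z = sphero_cylinder_to_zernike(rx, pupil_radius_mm)
        return ZernikeCoefficients(
            z.coeffs, pupil_radius_mm, "P1-like fixture (LOA only, synthetic)"
        )
    if kind == "custom":
        if refraction is None:
            raise ValueError("custom eyes need an explicit refraction")
        z = sphero_cylinder_to_zernike(refraction, pupil_radius_mm)
        return ZernikeCoefficients(z.coeffs, pupil_radius_mm, "custom LOA eye")
    if kind == "P2_like":
        rng = np.random.default_rng(seed)
        coeffs: dict[int, float] = {}
        for n in range(3, 7):
            for m in range(-n, n + 1, 2):
                coeffs[nm_to_osa(n, m)] = rng.normal(0.0, 1.0 / n)
        hoa = math.sqrt(sum(c * c for c in coeffs.values()))
        for j in coeffs:
            coeffs[j] *= P2_RMS_HOA_UM / hoa
        # irregular second-order component: mixed with- and against-the-rule
        low = sphero_cylinder_to_zernike(
            SpheroCylinder(-0.50, -1.00, 45.0), pupil_radius_mm
        )
        coeffs.update(low.coeffs)
        return ZernikeCoefficients(
            coeffs, pupil_radius_mm,
            f"P2-like fixture (synthetic irregular astigmat, seed={seed})",
        )
    raise ValueError(f"unknown eye kind {kind!r}")


def load_s1_table(path) -> tuple[ZernikeCoefficients, ZernikeCoefficients]:
    """Load the two-subject aberrometry table (user-supplied XLSX/CSV).

    Expected layout: columns ``osa_index``, ``P1``, ``P2`` (coefficients in
    um) and a ``pupil_radius_mm`` value either as a column or stated in a
    leading comment line; CSV or XLSX.  Validates that subject P2's
    higher-order RMS is close to 1.44 um and warns otherwise.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(
            f"{p}: supplementary aberrometry table not available; "
            "use fixtures.make_eye('P1_like'/'P2_like') instead"
        )
    import pandas as pd

    if p.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(p)
    else:
        df = pd.read_csv(p, comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    for need in ("osa_index", "p1", "p2"):
        if need not in cols:
            raise ValueError(f"table is missing a {need!r} column")
    radius = DEFAULT_PUPIL_RADIUS_MM
    if "pupil_radius_mm" in cols:
        radius = float(df[cols["pupil_radius_mm"]].iloc[0])
    idx = df[cols["osa_index"]].astype(int)
    p1 = ZernikeCoefficients(
        dict(zip(idx, df[cols["p1"]].astype(float))), radius, "subject P1"
    )
    p2 = ZernikeCoefficients(
        dict(zip(idx, df[cols["p2"]].astype(float))), radius, "subject P2"
    )
    hoa = rms(p2, 3)
    if abs(hoa - P2_RMS_HOA_UM) > 0.05:
        warnings.warn(
            f"subject P2 RMS_HOA = {hoa:.3f} um differs from the expected "
            f"{P2_RMS_HOA_UM} um; check the table",
            stacklevel=2,
        )
    return p1, p2
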