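"""Readers and writers: aberrometry files, scene configuration, PNG export.

Aberrometry formats
-------------------
CSV: a ``# pupil_radius_mm = <r>`` comment line followed by a header
``osa_index,coefficient_um`` and one row per nonzero coefficient (missing
indices read as zero).  JSON: one object with keys ``pupil_radius_mm``,
``coefficients`` (OSA index -> um) and optional ``source_label``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .eye_lenses import (
    DEFAULT_VERTEX_DISTANCE_M,
    JCCState,
    MultifocalDesign,
    PhoropterState,
    SchematicEye,
)
from .powers import SpheroCylinder
from .scene import Scene
from .zernike import ZernikeCoefficients


def write_aberrometry(z: ZernikeCoefficients, path) -> None:
    p = Path(path)
    if p.suffix.lower() == ".json":
        p.write_text(
            json.dumps(
                {
                    "pupil_radius_mm": z.pupil_radius_mm,
                    "source_label": z.source_label,
                    "coefficients": {str(j): c for j, c in sorted(z.coeffs.items())},
                },
                indent=2,
            )
        )
        return
    lines = [f"# pupil_radius_mm = {z.pupil_radius_mm!r}"]
    if z.source_label:
        lines.append(f"# source = {z.source_label}")
    lines.append("osa_index,coefficient_um")
    for j in sorted(z.coeffs):
        lines.append(f"{j},{z.coeffs[j]!r}")
    p.write_text("\n".join(lines) + "\n")


def read_aberrometry(path) -> ZernikeCoefficients:
    p = Path(path)
    if p.suffix.lower() == ".json":
        data = json.loads(p.read_text())
        return ZernikeCoefficients(
            {int(j): float(c) for j, c in data["coefficients"].items()},
            float(data["pupil_radius_mm"]),
            data.get("source_label", str(p)),
        )
    radius = None
    label = str(p)
    coeffs: dict[int, float] = {}
    for line in p.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.search(r"pupil_radius_mm\s*=\s*([0-9.eE+-]+)", line)
            if m:
                radius = float(m.group(1))
            continue
        if line.lower().startswith("osa_index"):
            continue
        j_str, c_str = line.split(",")[:2]
        coeffs[int(j_str)] = float(c_str)
    if radius is None:
        raise ValueError(f"{p}: no '# pupil_radius_mm = ...' metadata line")
    return ZernikeCoefficients(coeffs, radius, label)


def _sc_from_config(obj) -> SpheroCylinder:
    if isinstance(obj, (list, tuple)):
        s, c, a = (list(obj) + [0.0, 0.0])[:3]
        return SpheroCylinder(float(s), float(c), float(a)).canonical()
    return SpheroCylinder(
        float(obj.get("sphere", 0.0)),
        float(obj.get("cylinder", 0.0)),
        float(obj.get("axis", 0.0)),
    ).canonical()


def scene_from_config(config: dict, base_dir: Path | None = None) -> Scene:
    """Build a Scene from a configuration mapping (parsed YAML/JSON).

    Keys: ``eye`` (aberrometry file path), ``pupil_radius_mm``,
    ``vertex_distance_mm``, ``lenses`` (list of [S, C, axis] or mappings),
    ``jcc`` ({power, axis, flipped, active, mode}), ``contact_lens``
    ({zones: [[outer_radius_mm, add_D], ...], label}), ``n_pupil``,
    ``pad_factor``.
    """
    base = base_dir or Path.cwd()
    if "eye" in config:
        eye_path = Path(config["eye"])
        if not eye_path.is_absolute():
            eye_path = base / eye_path
        aber = read_aberrometry(eye_path)
    else:
        aber = ZernikeCoefficients(
            {}, float(config.get("pupil_radius_mm", 3.0)), "emmetrope"
        )
    eye = SchematicEye(
        aberrometry=aber,
        pupil_radius_mm=config.get("pupil_radius_mm"),
    )
    lenses = tuple(_sc_from_config(o) for o in config.get("lenses", []))
    phoropter = PhoropterState(
        lenses,
        float(config.get("vertex_distance_mm", DEFAULT_VERTEX_DISTANCE_M * 1e3))
        / 1e3,
    )
    jcc = None
    if "jcc" in config and config["jcc"]:
        j = config["jcc"]
        jcc = JCCState(
            power=float(j.get("power", 0.50)),
            axis=float(j.get("axis", 0.0)),
            flipped=bool(j.get("flipped", False)),
            active=bool(j.get("active", True)),
            mode=j.get("mode", "axis-search"),
        )
    cl = None
    if "contact_lens" in config and config["contact_lens"]:
        c = config["contact_lens"]
        cl = MultifocalDesign(
            zones=tuple((float(r), float(a)) for r, a in c["zones"]),
            label=c.get("label", ""),
        )
    return Scene(
        eye=eye,
        phoropter=phoropter,
        jcc=jcc,
        contact_lens=cl,
        n_pupil=int(config.get("n_pupil", 256)),
        pad_factor=int(config.get("pad_factor", 4)),
        description=config.get("description", ""),
    )


def load_scene(path) -> Scene:
    """Load a scene from a YAML or JSON configuration file."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() in (".yaml", ".yml"):
        import yaml

        config = yaml.safe_load(text)
    else:
        config = json.loads(text)
    return scene_from_config(config, p.parent)


def save_png(image: np.ndarray, path, invert: bool = False) -> None:
    """Save a float image as 8-bit grayscale PNG (max-normalized)."""
    from PIL import Image

    arr = np.asarray(image, dtype=float)
    arr = arr / max(arr.max(), 1e-300)
    if invert:
        arr = 1.0 - arr
    Image.fromarray(
        np.round(arr * 255).astype(np.uint8), mode="L"
    ).save(path)
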