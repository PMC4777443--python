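"""Programmatic optotype charts with exact angular geometry.

Charts are "emission" rasters: ink is bright (1.0) on a dark (0.0)
background, ready for convolution with the PSF; invert for display as a
printed chart.  Letter geometry follows the logMAR convention: a letter at
acuity level L subtends 5 * 10**L arcmin in height with a stroke width of
one fifth of the height (1 arcmin at 0 logMAR).

Glyphs come from a built-in 5x5 Sloan-style bitmap font so that rendering
is bit-reproducible and needs no system fonts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

# 5x5 stroke bitmaps of the Sloan letter set (plus E for the tumbling chart)
_FONT: dict[str, tuple[str, ...]] = {
    "C": ("11111", "10000", "10000", "10000", "11111"),
    "D": ("11110", "10001", "10001", "10001", "11110"),
    "E": ("11111", "10000", "11111", "10000", "11111"),
    "H": ("10001", "10001", "11111", "10001", "10001"),
    "K": ("10001", "10010", "11100", "10010", "10001"),
    "N": ("10001", "11001", "10101", "10011", "10001"),
    "O": ("11111", "10001", "10001", "10001", "11111"),
    "R": ("11110", "10001", "11110", "10010", "10001"),
    "S": ("11111", "10000", "11111", "00001", "11111"),
    "V": ("10001", "10001", "10001", "01010", "00100"),
    "Z": ("11111", "00010", "00100", "01000", "11111"),
}


@dataclass
class Chart:
    """A paraxial optotype O(x, y) with angular metadata."""

    image: np.ndarray
    pixel_scale_arcmin: float
    kind: str
    angular_size_arcmin: float
    logmar: float | None = None

    def display_image(self) -> np.ndarray:
        """Black-on-white version for printing/saving."""
        return 1.0 - self.image


def letter_height_arcmin(logmar: float) -> float:
    return 5.0 * 10.0**logmar


def _glyph_raster(letter: str, height_px: int) -> np.ndarray:
    try:
        rows = _FONT[letter.upper()]
    except KeyError:
        raise ValueError(f"no glyph for letter {letter!r}") from None
    bitmap = np.array([[int(ch) for ch in row] for row in rows], dtype=float)
    idx = np.minimum((np.arange(height_px) * 5) // height_px, 4)
    return bitmap[np.ix_(idx, idx)]


def make_letter_line(
    logmar: float,
    letters: str = "NCKZO",
    pixel_scale_arcmin: float = 0.125,
    margin_fraction: float = 0.5,
) -> Chart:
    """A line of letters at one acuity level.

    Each letter is square (width = height = 5 * 10**logmar arcmin) and
    letters are separated by one letter width.
    """
    if not letters:
        raise ValueError("letter line must contain at least one letter")
    h_arc = letter_height_arcmin(logmar)
    h_px = max(2, round(h_arc / pixel_scale_arcmin))
    margin = round(margin_fraction * h_px)
    n = len(letters)
    width = n * h_px + (n - 1) * h_px + 2 * margin
    img = np.zeros((h_px + 2 * margin, width))
    for i, letter in enumerate(letters):
        c0 = margin + i * 2 * h_px
        img[margin : margin + h_px, c0 : c0 + h_px] = _glyph_raster(letter, h_px)
    return Chart(img, pixel_scale_arcmin, "letter_line", h_arc, logmar)


def make_single_letter(
    logmar: float,
    letter: str = "E",
    pixel_scale_arcmin: float = 0.125,
    margin_fraction: float = 0.5,
) -> Chart:
    return make_letter_line(
        logmar, letter, pixel_scale_arcmin, margin_fraction
    )


def make_snellen_e(
    logmar: float,
    orientation: int = 0,
    pixel_scale_arcmin: float = 0.125,
    margin_fraction: float = 0.5,
) -> Chart:
    """Tumbling Snellen E.  ``orientation`` in {0, 90, 180, 270} degrees,
    counter-clockwise; 0 is the standard E (limbs pointing right... i.e.
    the printed orientation of the glyph)."""
    if orientation not in (0, 90, 180, 270):
        raise ValueError("orientation must be one of 0, 90, 180, 270")
    h_arc = letter_height_arcmin(logmar)
    h_px = max(2, round(h_arc / pixel_scale_arcmin))
    glyph = _glyph_raster("E", h_px)
    glyph = np.rot90(glyph, k=orientation // 90)
    margin = round(margin_fraction * h_px)
    img = np.zeros((h_px + 2 * margin, h_px + 2 * margin))
    img[margin : margin + h_px, margin : margin + h_px] = glyph
    chart = Chart(img, pixel_scale_arcmin, "snellen_e", h_arc, logmar)
    return chart


def make_clock_dial(
    pixel_scale_arcmin: float = 0.25,
    diameter_arcmin: float = 250.0,
    line_width_arcmin: float = 5.0,
    n_spokes: int = 12,
    inner_fraction: float = 0.25,
    margin_fraction: float = 0.1,
) -> Chart:
    """Astigmatic clock dial: radii at even angular intervals (30 degrees
    for the default 12 spokes) inside a disc of the given angular size."""
    r_out = diameter_arcmin / 2.0
    r_in = inner_fraction * r_out
    half_w = line_width_arcmin / 2.0
    margin = margin_fraction * r_out
    half_px = math.ceil((r_out + margin) / pixel_scale_arcmin)
    size = 2 * half_px + 1
    c = (np.arange(size) - half_px) * pixel_scale_arcmin
    x = c[np.newaxis, :]
    y = -c[:, np.newaxis]  # y up
    img = np.zeros((size, size))
    for k in range(n_spokes):
        phi = math.radians(k * 360.0 / n_spokes)
        ux, uy = math.cos(phi), math.sin(phi)
        along = x * ux + y * uy
        across = -x * uy + y * ux
        stroke = (
            (np.abs(across) <= half_w)
            & (along >= r_in)
            & (along <= r_out)
        )
        img[stroke] = 1.0
    return Chart(img, pixel_scale_arcmin, "clock_dial", diameter_arcmin)


def make_dot_pattern(
    pixel_scale_arcmin: float = 0.125,
    extent_arcmin: float = 50.0,
    n_dots: int = 5,
    dot_diameter_arcmin: float = 2.0,
    margin_fraction: float = 0.25,
) -> Chart:
    """Square grid of circular dots with a given overall angular extent."""
    half = extent_arcmin / 2.0
    margin = margin_fraction * half
    half_px = math.ceil((half + margin) / pixel_scale_arcmin)
    size = 2 * half_px + 1
    c = (np.arange(size) - half_px) * pixel_scale_arcmin
    x = c[np.newaxis, :]
    y = -c[:, np.newaxis]
    img = np.zeros((size, size))
    r_dot = dot_diameter_arcmin / 2.0
    centers = np.linspace(-(half - r_dot), half - r_dot, n_dots)
    for cy in centers:
        for cx in centers:
            img[(x - cx) ** 2 + (y - cy) ** 2 <= r_dot**2] = 1.0
    return Chart(img, pixel_scale_arcmin, "dot_pattern", extent_arcmin)


def custom_chart(
    image: np.ndarray, pixel_scale_arcmin: float, invert: bool = True
) -> Chart:
    """Wrap a user raster as a chart.  ``invert=True`` treats the input as
    black-ink-on-white and converts it to the internal emission form."""
    img = np.asarray(image, dtype=float)
    img = (img - img.min()) / max(img.max() - img.min(), 1e-12)
    if invert:
        img = 1.0 - img
    h, w = img.shape
    return Chart(
        img, pixel_scale_arcmin, "custom", max(h, w) * pixel_scale_arcmin
    )
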