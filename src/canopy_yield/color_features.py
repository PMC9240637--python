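"""Per-plot colour statistics and visible-band vegetation indices.

Each plot ROI is summarised by the arithmetic mean digital number (DN) of the
red, green and blue channels; indices are then computed on that mean colour
(not per-pixel), which is the convention for plot-mean canopy analysis. A
per-pixel mode is available for sensitivity studies.

The 13 vegetation indices are the classic visible-band set (NGRDI, MGRVI,
RGBVI, NDI, VARI, WI, CIVE, GLA, ExG, ExR, ExGR, GLI, NGBDI). All ratio
indices are computed on chromatic coordinates r, g, b = R/(R+G+B), ...; GLA is
computed on raw channel means, which is algebraically identical to GLI on
normalised ones. A denominator of exactly zero (|d| < 1e-12) yields NaN.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from skimage import color as skcolor

from .io_core import ROI, COLOR_COLUMNS, VI_COLUMNS

_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class ColorSummary:
    """Mean colour of an ROI in several colour spaces."""

    R: float
    G: float
    B: float
    r: float
    g: float
    b: float
    Y: float
    Cb: float
    Cr: float
    U: float
    hsv: tuple[float, float, float]
    lab: tuple[float, float, float]
    yiq: tuple[float, float, float]

    def as_row(self) -> dict[str, float]:
        h, s, v = self.hsv
        L, a_star, b_star = self.lab
        yq, i, q = self.yiq
        return dict(zip(COLOR_COLUMNS,
                        (self.R, self.G, self.B, self.r, self.g, self.b,
                         self.Y, self.Cb, self.Cr, self.U,
                         h, s, v, L, a_star, b_star, yq, i, q)))


@dataclasses.dataclass(frozen=True)
class VIVector:
    """The 13 visible-band vegetation indices (NaN where undefined)."""

    NGRDI: float
    MGRVI: float
    RGBVI: float
    NDI: float
    VARI: float
    WI: float
    CIVE: float
    GLA: float
    ExG: float
    ExR: float
    ExGR: float
    GLI: float
    NGBDI: float

    def as_row(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in VI_COLUMNS}


def mean_dn(image: np.ndarray, roi: ROI) -> tuple[float, float, float]:
    """Unweighted mean DN of each channel over the ROI pixels.

    Parameters
    ----------
    image
        ``(H, W, 3)`` uint8 array.
    roi
        Pixel-space ROI; must cover at least one pixel after rasterisation.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    mask = roi.mask(image.shape[:2])
    if not mask.any():
        raise ValueError("ROI rasterises to zero pixels")
    px = image[mask].astype(np.float64)
    m = px.mean(axis=0)
    return float(m[0]), float(m[1]), float(m[2])


def normalize_rgb(R: float, G: float, B: float) -> tuple[float, float, float]:
    """Chromatic coordinates r, g, b; NaN triple when R+G+B == 0."""
    s = R + G + B
    if s <= _EPS:
        return (math.nan, math.nan, math.nan)
    return (R / s, G / s, B / s)


def ycbcr_channels(R: float, G: float, B: float) -> tuple[float, float, float, float]:
    """Y, Cb, Cr and YUV-U of a mean colour, unclipped.

    Y = 0.299R + 0.587G + 0.114B; Cb = 0.568(B−Y) + 128;
    Cr = 0.713(R−Y) + 128; U = 0.493(B−Y).
    """
    Y = 0.299 * R + 0.587 * G + 0.114 * B
    Cb = 0.568 * (B - Y) + 128.0
    Cr = 0.713 * (R - Y) + 128.0
    U = 0.493 * (B - Y)
    return Y, Cb, Cr, U


def convert_color_spaces(R: float, G: float, B: float):
    """Standard sRGB→HSV, sRGB→CIE L*a*b* (D65, 2°) and RGB→YIQ conversions.

    Input is the mean DN triple in [0, 255]; conversions operate on the unit
    scale. HSV hue is returned in [0, 1) as scikit-image produces it.
    """
    rgb = np.asarray([[[R, G, B]]], dtype=np.float64) / 255.0
    hsv = skcolor.rgb2hsv(rgb)[0, 0]
    lab = skcolor.rgb2lab(rgb)[0, 0]
    yiq = skcolor.rgb2yiq(rgb)[0, 0]
    return tuple(map(float, hsv)), tuple(map(float, lab)), tuple(map(float, yiq))


def _ratio(num: float, den: float) -> float:
    if not np.isfinite(num) or not np.isfinite(den) or abs(den) < _EPS:
        return math.nan
    return num / den


def vegetation_indices(r: float, g: float, b: float,
                       R: float, G: float, B: float) -> VIVector:
    """The 13 visible-band indices from normalised (r,g,b) and raw (R,G,B) means."""
    return VIVector(
        NGRDI=_ratio(g - r, g + r),
        MGRVI=_ratio(g**2 - r**2, g**2 + r**2),
        RGBVI=_ratio(g**2 - b * r, g**2 + b * r),
        NDI=_ratio(r - g, r + g + 0.01),
        VARI=_ratio(g - r, g + r - b),
        WI=_ratio(g - b, r - g),
        CIVE=0.441 * r - 0.881 * g + 0.385 * b + 18.78745
        if np.isfinite(r) else math.nan,
        GLA=_ratio(2 * G - B - R, 2 * G + B + R),
        ExG=2 * g - b - r,
        ExR=1.4 * r - g,
        ExGR=3 * g - 2.4 * r - b,
        GLI=_ratio(2 * g - b - r, 2 * g + b + r),
        NGBDI=_ratio(g - b, g + b),
    )


def summarize_color(image: np.ndarray, roi: ROI,
                    per_pixel: bool = False) -> tuple[ColorSummary, VIVector]:
    """Full colour summary + VI vector for one plot ROI.

    With ``per_pixel=True`` the indices are computed per pixel and then
    averaged instead of being evaluated at the ROI-mean colour.
    """
    R, G, B = mean_dn(image, roi)
    r, g, b = normalize_rgb(R, G, B)
    Y, Cb, Cr, U = ycbcr_channels(R, G, B)
    hsv, lab, yiq = convert_color_spaces(R, G, B)
    summary = ColorSummary(R, G, B, r, g, b, Y, Cb, Cr, U, hsv, lab, yiq)
    if not per_pixel:
        return summary, vegetation_indices(r, g, b, R, G, B)
    mask = roi.mask(image.shape[:2])
    px = image[mask].astype(np.float64)
    rows = []
    for Rp, Gp, Bp in px:
        rp, gp, bp = normalize_rgb(Rp, Gp, Bp)
        rows.append(vegetation_indices(rp, gp, bp, Rp, Gp, Bp).as_row())
    import pandas as pd

    mean_vi = pd.DataFrame(rows).mean()  # NaN-skipping per-pixel average
    return summary, VIVector(**{k: float(mean_vi[k]) for k in VI_COLUMNS})
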