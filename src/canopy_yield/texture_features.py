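"""Gray-level co-occurrence matrix (GLCM) texture statistics.

Texture is summarised per plot by four Haralick-style statistics — angular
second moment (ASM), entropy (ENT), contrast (CON) and correlation (COR) —
computed from GLCMs at the four standard offsets (0°, 45°, 90° and 135°),
then aggregated across angles by the directional mean and population standard
deviation. The SD across angles (e.g. CON_SD) measures texture anisotropy.

Definitions (P the normalised co-occurrence matrix over L gray levels):

    ASM = ΣΣ P(i,j)²                    ENT = −ΣΣ P(i,j) log₂ P(i,j)
    CON = ΣΣ (i−j)² P(i,j)              COR = [ΣΣ i·j·P(i,j) − μxμy] / (σxσy)

with μ, σ the marginal means/SDs. COR is NaN when a marginal is degenerate.

Pixels are quantised into ``levels`` equal-width bins over the 8-bit range.
Offsets use (row, col) displacement: 0°→(0,+d), 45°→(−d,+d), 90°→(−d,0),
135°→(−d,−d). Only pairs with both pixels inside the ROI are counted;
out-of-ROI neighbours are skipped, not padded.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_core import ROI, TEXTURE_ANGLES, TEXTURE_STATS

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclasses.dataclass(frozen=True)
class GLCMatrix:
    """Normalised co-occurrence matrix with its construction parameters."""

    P: np.ndarray
    levels: int
    distance: int
    angle: int
    symmetric: bool

    def __post_init__(self) -> None:
        P = self.P
        if P.shape != (self.levels, self.levels):
            raise ValueError("P must be levels x levels")
        if (P < 0).any() or abs(P.sum() - 1.0) > 1e-12:
            raise ValueError("P must be a normalised frequency matrix")


def to_gray(image: np.ndarray, mode: str = "luminance") -> np.ndarray:
    """RGB tile → gray tile(s).

    ``mode="luminance"`` returns round(0.299R + 0.587G + 0.114B) as uint8;
    ``mode="per_band"`` returns the three channels stacked on axis 0.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if mode == "per_band":
        return np.moveaxis(image, 2, 0).copy()
    if mode != "luminance":
        raise ValueError(f"unknown gray mode {mode!r}")
    f = image.astype(np.float64)
    y = 0.299 * f[..., 0] + 0.587 * f[..., 1] + 0.114 * f[..., 2]
    return np.rint(y).clip(0, 255).astype(np.uint8)


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width binning of 8-bit DN into ``levels`` bins."""
    return (gray.astype(np.int64) * levels // 256).astype(np.int64)


def glcm(gray: np.ndarray, roi: ROI | None, levels: int = 32,
         distance: int = 1, angle: int = 0, symmetric: bool = True) -> GLCMatrix:
    """Co-occurrence matrix of quantised gray levels at one angle.

    Raises if the ROI admits no valid pixel pair for the offset.
    """
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_OFFSETS)}")
    dr, dc = (d * distance for d in _OFFSETS[angle])
    q = quantize(gray, levels)
    h, w = q.shape
    mask = roi.mask((h, w)) if roi is not None else np.ones((h, w), bool)

    # valid source positions: both endpoints inside the image and the ROI
    r0 = max(0, -dr); r1 = min(h, h - dr)
    c0 = max(0, -dc); c1 = min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"no valid pixel pairs at angle {angle} in ROI")
    src = q[r0:r1, c0:c1]
    dst = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    ok = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    if not ok.any():
        raise ValueError(f"no valid pixel pairs at angle {angle} in ROI")
    counts = np.bincount((src[ok] * levels + dst[ok]).ravel(),
                         minlength=levels * levels).reshape(levels, levels)
    counts = counts.astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    return GLCMatrix(counts / counts.sum(), levels, distance, angle, symmetric)


def texture_stats(P: GLCMatrix | np.ndarray) -> tuple[float, float, float, float]:
    """(ASM, ENT, CON, COR) of a normalised co-occurrence matrix."""
    M = P.P if isinstance(P, GLCMatrix) else np.asarray(P, dtype=np.float64)
    if abs(M.sum() - 1.0) > 1e-9 or (M < 0).any():
        raise ValueError("co-occurrence matrix is not normalised")
    L = M.shape[0]
    i = np.arange(L, dtype=np.float64)
    asm = float((M**2).sum())
    nz = M[M > 0]
    ent = float(-(nz * np.log2(nz)).sum())
    ii, jj = np.meshgrid(i, i, indexing="ij")
    con = float((((ii - jj) ** 2) * M).sum())
    px, py = M.sum(axis=1), M.sum(axis=0)
    mx, my = float(px @ i), float(py @ i)
    sx = float(np.sqrt(px @ (i - mx) ** 2))
    sy = float(np.sqrt(py @ (i - my) ** 2))
    if sx * sy < 1e-15:
        cor = float("nan")
    else:
        cor = float(((ii * jj * M).sum() - mx * my) / (sx * sy))
    return asm, ent, con, cor


def directional_aggregate(per_angle: dict[int, tuple[float, float, float, float]]
                          ) -> dict[str, float]:
    """Directional mean and population SD of each statistic over the 4 angles.

    NaN in any angle propagates to that statistic's mean and SD.
    """
    if sorted(per_angle) != sorted(TEXTURE_ANGLES):
        raise ValueError(f"need statistics at angles {TEXTURE_ANGLES}")
    out: dict[str, float] = {}
    for k, stat in enumerate(TEXTURE_STATS):
        vals = np.array([per_angle[a][k] for a in TEXTURE_ANGLES], dtype=np.float64)
        for a, v in zip(TEXTURE_ANGLES, vals):
            out[f"{stat}_{a}"] = float(v)
        out[f"{stat}_MEAN"] = float(vals.mean())
        out[f"{stat}_SD"] = float(vals.std())  # population SD
    return out


def texture_vector(image: np.ndarray, roi: ROI | None = None, *,
                   levels: int = 32, distance: int = 1,
                   symmetric: bool = True, mode: str = "luminance"
                   ) -> dict[str, float]:
    """Full texture feature row for one plot: 4 stats x (4 angles + mean + SD).

    In ``per_band`` mode the three channel-wise values of each statistic are
    averaged before aggregation across angles.
    """
    gray = to_gray(image, mode=mode)
    bands = gray if mode == "per_band" else gray[None]
    per_angle: dict[int, tuple[float, float, float, float]] = {}
    for a in TEXTURE_ANGLES:
        vals = np.array([
            texture_stats(glcm(b, roi, levels=levels, distance=distance,
                               angle=a, symmetric=symmetric))
            for b in bands
        ])
        per_angle[a] = tuple(vals.mean(axis=0))
    return directional_aggregate(per_angle)
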