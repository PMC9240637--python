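"""Synthetic cotton-canopy scenes and feature tables.

Two generator tiers let every downstream stage be tested without field data:

* **Image tier** — :func:`simulate_plot_image` composites a plot tile the way
  a pre-harvest cotton field looks from a low-altitude RGB survey: gray-white
  plastic mulch-film strips over brown soil, green canopy ellipses whose area
  shrinks with defoliation, and white open-boll blobs whose count carries the
  yield signal (1 t·ha⁻¹ = 100 g·m⁻²; count = yield ÷ single-boll weight ×
  tile ground area).
* **Table tier** — :func:`simulate_feature_table` skips rendering and draws a
  feature table directly with the statistical structure the analysis assumes:
  vegetation-index features saturate in yield (Michaelis–Menten response
  a·y/(y+k), so the response flattens at high yield), texture features are
  near-linear in yield, and each family shares a latent noise component that
  reproduces the strong within-family collinearity seen in real plot data.

Yields are drawn from a truncated normal on [0, 11.58] t·ha⁻¹ whose
*truncated* mean is calibrated to 3.0 t·ha⁻¹ with the largest spread the
family admits (CV ≈ 85%), emulating a highly variable multi-treatment trial.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import optimize, stats
from PIL import Image

from .io_core import (
    ROI, FeatureTable, PlotSample, TARGET_COLUMN, TEXTURE_COLUMNS,
    VI_COLUMNS, write_plot_table,
)

# scene palette (mean DN); values loosely matched to field RGB orthomosaics
_SOIL = np.array([118.0, 86.0, 60.0])
_FILM = np.array([205.0, 203.0, 198.0])
_CANOPY = np.array([52.0, 110.0, 48.0])
_BOLL = np.array([242.0, 240.0, 236.0])

# mask classes of the rendered tile
SOIL, FILM, CANOPY, BOLL = 0, 1, 2, 3


@dataclasses.dataclass(frozen=True)
class SceneParams:
    """Parameters of the simulated trial and of each rendered tile."""

    n_plots: int = 48
    tile_size: int = 256
    pixel_size_m: float = 0.003          # 0.3 cm ground resolution
    yield_mean: float = 3.0              # t·ha⁻¹, truncated-distribution target
    yield_sd: float = 2.91
    yield_min: float = 0.0
    yield_max: float = 11.58
    boll_weight_g: float = 5.0
    film_fraction: float = 0.35
    canopy_cover: float = 0.55           # green fraction before defoliation
    noise_sd: float = 3.0                # additive DN noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.film_fraction <= 1.0:
            raise ValueError("film_fraction must lie in [0, 1]")
        if self.yield_min < 0 or self.yield_max <= self.yield_min:
            raise ValueError("need 0 <= yield_min < yield_max")
        if self.boll_weight_g <= 0:
            raise ValueError("boll_weight_g must be positive")

    @property
    def tile_area_m2(self) -> float:
        return (self.tile_size * self.pixel_size_m) ** 2


@lru_cache(maxsize=32)
def _fit_truncnorm(mean: float, sd: float, lo: float, hi: float
                   ) -> tuple[float, float]:
    """Underlying (mu, sigma) whose truncation to [lo, hi] best matches the
    target truncated mean and SD (mean weighted heavier; the family cannot
    exceed CV ≈ 87% at mean 3 on [0, 11.58], so large target SDs are met as
    closely as possible)."""
    span = hi - lo

    def loss(p):
        mu, s = p
        if not (lo - 3 * span < mu < hi and 0.05 < s < 5 * span):
            return 1e6
        a, b = (lo - mu) / s, (hi - mu) / s
        d = stats.truncnorm(a, b, loc=mu, scale=s)
        return 10 * ((d.mean() - mean) / max(mean, 1e-9)) ** 2 \
            + ((d.std() - sd) / max(sd, 1e-9)) ** 2

    best = None
    for x0 in [(mean, sd), (mean - span, 2 * sd), (lo - 1.5 * span, span)]:
        r = optimize.minimize(loss, x0, method="Nelder-Mead",
                              options=dict(xatol=1e-7, fatol=1e-12, maxiter=2000))
        if best is None or r.fun < best.fun:
            best = r
    return float(best.x[0]), float(best.x[1])


def yield_distribution(params: SceneParams) -> stats.rv_continuous:
    """Frozen truncated-normal yield distribution calibrated to the params."""
    mu, s = _fit_truncnorm(params.yield_mean, params.yield_sd,
                           params.yield_min, params.yield_max)
    a, b = (params.yield_min - mu) / s, (params.yield_max - mu) / s
    return stats.truncnorm(a, b, loc=mu, scale=s)


def draw_yields(params: SceneParams, n: int, rng: np.random.Generator
                ) -> np.ndarray:
    return yield_distribution(params).rvs(size=n, random_state=rng)


def boll_count(yield_t_ha: float, boll_weight_g: float, tile_area_m2: float) -> int:
    """Open bolls per tile: 1 t·ha⁻¹ = 100 g·m⁻², divided by single-boll weight."""
    return int(round(yield_t_ha * 100.0 / boll_weight_g * tile_area_m2))


def simulate_plot_image(params: SceneParams, yield_t_ha: float,
                        rng: np.random.Generator, *,
                        defoliation_level: float = 0.5
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Render one plot tile; returns (uint8 RGB tile, per-class mask).

    The mask uses classes SOIL=0, FILM=1, CANOPY=2, BOLL=3. Deterministic
    given the same Generator state.
    """
    if not params.yield_min <= yield_t_ha <= params.yield_max:
        raise ValueError(f"yield {yield_t_ha} outside distribution bounds")
    if not 0.0 <= defoliation_level <= 1.0:
        raise ValueError("defoliation_level must lie in [0, 1]")
    n = params.tile_size
    mask = np.full((n, n), SOIL, dtype=np.uint8)

    # mulch-film strips: vertical bands covering film_fraction of the width
    n_strips = 3
    strip_w = int(round(params.film_fraction * n / n_strips))
    if strip_w > 0:
        for s in range(n_strips):
            x0 = int((s + 0.5) * n / n_strips - strip_w / 2)
            mask[:, max(x0, 0):min(x0 + strip_w, n)] = FILM

    yy, xx = np.mgrid[0:n, 0:n]

    # canopy ellipses along plant rows; area shrinks with defoliation
    target_cover = params.canopy_cover * (1.0 - defoliation_level)
    if target_cover > 0:
        canopy = np.zeros((n, n), bool)
        attempts = 0
        while canopy.mean() < target_cover and attempts < 4000:
            cx, cy = rng.uniform(0, n, size=2)
            ax = rng.uniform(0.04, 0.10) * n
            ay = ax * rng.uniform(0.6, 1.4)
            canopy |= ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
            attempts += 1
        mask[canopy] = CANOPY

    # open-boll blobs: count fixed by yield, boll weight and ground area
    n_bolls = boll_count(yield_t_ha, params.boll_weight_g, params.tile_area_m2)
    boll_r = max(0.035 / params.pixel_size_m / 2, 1.5)  # ~3.5 cm open bolls
    if n_bolls * np.pi * boll_r**2 > 0.8 * n * n:
        raise ValueError(
            f"{n_bolls} bolls exceed tile capacity; use a larger tile_size")
    if n_bolls > 0:
        centers = rng.uniform(0, n, size=(n_bolls, 2))
        bolls = np.zeros((n, n), bool)
        for cx, cy in centers:
            r = boll_r * rng.uniform(0.8, 1.2)
            bolls |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        mask[bolls] = BOLL

    palette = np.stack([_SOIL, _FILM, _CANOPY, _BOLL])
    tile = palette[mask]
    if params.noise_sd > 0:
        tile = tile + rng.normal(0.0, params.noise_sd, size=tile.shape)
    return np.clip(np.rint(tile), 0, 255).astype(np.uint8), mask


def simulate_image_dataset(out_dir: str | Path, params: SceneParams,
                           n_dates: int = 5, seed: int | None = None
                           ) -> list[PlotSample]:
    """Render a full trial: ``n_plots`` plots x ``n_dates`` observation dates.

    Each plot keeps one true (harvest) yield across dates; defoliation
    advances with the date offset (3, 6, 9, ... days after spraying), so the
    green fraction declines over the campaign while boll cover stays tied to
    yield. Writes PNG tiles and a ``plots.csv`` plot table; returns the
    samples.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    yields = draw_yields(params, params.n_plots, rng)
    concs = [f"C{1 + i % 4}" for i in range(params.n_plots)]
    times = [f"T{1 + (i // 4) % 6}" for i in range(params.n_plots)]
    samples = []
    for d in range(n_dates):
        offset = 3 * (d + 1)
        for p in range(params.n_plots):
            defol = float(np.clip(0.10 + 0.16 * d + rng.normal(0, 0.04), 0, 0.95))
            tile, _ = simulate_plot_image(params, yields[p], rng,
                                          defoliation_level=defol)
            name = f"plot{p + 1:02d}_d{offset:02d}.png"
            Image.fromarray(tile).save(out / name)
            samples.append(PlotSample(
                plot_id=f"P{p + 1:02d}",
                roi=ROI(box=(0, 0, params.tile_size, params.tile_size)),
                variety=f"V{1 + p % 2}",
                defoliant_conc=concs[p],
                spray_time=times[p],
                date_offset=offset,
                yield_t_ha=float(yields[p]),
                image_path=out / name,
            ))
    write_plot_table(samples, out / "plots.csv")
    return samples


# ---------------------------------------------------------------------------
# table tier

# response signs: greenness indices fall with yield (defoliated, boll-covered
# high-yield plots are less green); redness-type indices rise. Texture: plots
# get more uniform with yield, so ASM/COR rise while ENT/CON fall.
_VI_SIGNS = {"NDI": 1.0, "ExR": 1.0, "CIVE": 1.0}
_TEX_SIGNS = {"ASM": 1.0, "COR": 1.0, "ENT": -1.0, "CON": -1.0}

#: per-column independent noise SDs (sd_vi on the saturating-response scale,
#: sd_tex on the yield scale); shared latents below scale with these
DEFAULT_NOISE = (0.14, 0.8)
#: family-level latent noise for VIs, as a multiple of sd_vi — models the
#: strong collinearity between visible-band indices (all functions of the
#: same mean colour)
_SHARED_FRAC_VI = 0.19 / 0.14
#: statistic-level latent noise for texture, as a multiple of sd_tex — the
#: six variants (4 angles + mean + SD) of one GLCM statistic are nearly
#: collinear, while different statistics carry partly independent noise
_SHARED_FRAC_TEX = 3.1 / 0.8


def simulate_feature_table(n: int, saturation_k: float = 3.0,
                           noise: tuple[float, float] = DEFAULT_NOISE,
                           seed: int = 0,
                           params: SceneParams | None = None) -> FeatureTable:
    """Feature table with saturating VI and near-linear texture responses.

    Each VI column i is ``sign_i (a_i · y/(y+k) + η_vi + ε_i)`` with one
    family-wide latent η_vi; each texture column is
    ``sign (b_j · y + η_stat + ε_j)`` with one latent per GLCM statistic, so
    variants of a statistic are nearly collinear while the four statistics
    form partly independent measurement channels. ``noise = (sd_vi, sd_tex)``
    are the per-column independent SDs; the latent SDs scale with them, so
    ``(0, 0)`` gives noise-free monotone responses.
    """
    if n < 10:
        raise ValueError("need n >= 10 samples")
    if saturation_k <= 0:
        raise ValueError("saturation_k must be positive")
    sd_vi, sd_tex = noise
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    y = draw_yields(params, n, rng)
    sat = y / (y + saturation_k)

    import pandas as pd

    data = {}
    eta_vi = rng.normal(0.0, 1.0, size=n) * _SHARED_FRAC_VI * sd_vi
    for i, name in enumerate(VI_COLUMNS):
        a = 0.8 + 0.4 * i / max(len(VI_COLUMNS) - 1, 1)
        sign = _VI_SIGNS.get(name, -1.0)
        data[name] = sign * (a * sat + eta_vi + rng.normal(0, sd_vi, size=n))
    eta_stat = {s: rng.normal(0.0, 1.0, size=n) * _SHARED_FRAC_TEX * sd_tex
                for s in _TEX_SIGNS}
    for j, name in enumerate(TEXTURE_COLUMNS):
        b = 0.8 + 0.4 * j / max(len(TEXTURE_COLUMNS) - 1, 1)
        stat = name.split("_")[0]
        sign = _TEX_SIGNS[stat]
        data[name] = sign * (b * y + eta_stat[stat] + rng.normal(0, sd_tex, size=n))
    data[TARGET_COLUMN] = y
    df = pd.DataFrame(data, index=[f"S{i + 1:03d}" for i in range(n)])
    return FeatureTable(df)
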