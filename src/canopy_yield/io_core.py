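"""Plot tables, feature tables and on-disk interchange formats.

The pipeline moves data between stages as two objects: a list of
:class:`PlotSample` (one row per plot x observation date, pointing at an RGB
tile and a pixel-space ROI) and a :class:`FeatureTable` (samples x named
feature columns plus the measured yield). Both round-trip through plain CSV.

Conventions
-----------
* Pixel coordinates are 0-based; box ROIs are half-open ``(x0, y0, x1, y1)``.
* Polygon ROIs are WKT strings, rasterised with the pixel-centre-inside rule.
* Yields are stored in t·ha⁻¹ throughout.
* Features that are undefined for a plot (e.g. a vegetation index with a zero
  denominator) propagate as NaN and serialise as empty CSV fields.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.wkt
import yaml
from PIL import Image

logger = logging.getLogger("canopy_yield")

PLOT_TABLE_COLUMNS = [
    "plot_id", "roi", "variety", "conc", "time",
    "date_offset", "yield_t_ha", "image_path",
]

#: column family tags used by the screening and modelling stages
FAMILIES = ("color", "vi", "texture")

VI_COLUMNS = [
    "NGRDI", "MGRVI", "RGBVI", "NDI", "VARI", "WI", "CIVE",
    "GLA", "ExG", "ExR", "ExGR", "GLI", "NGBDI",
]
COLOR_COLUMNS = [
    "R", "G", "B", "r", "g", "b", "Y", "Cb", "Cr", "U",
    "H", "S", "V", "L", "a_star", "b_star", "Yiq", "I", "Q",
]
TEXTURE_STATS = ("ASM", "ENT", "CON", "COR")
TEXTURE_ANGLES = (0, 45, 90, 135)
TEXTURE_COLUMNS = [
    f"{s}_{suffix}"
    for s in TEXTURE_STATS
    for suffix in [str(a) for a in TEXTURE_ANGLES] + ["MEAN", "SD"]
]

TARGET_COLUMN = "yield_t_ha"


class SchemaError(ValueError):
    """A table is missing required columns or has malformed fields."""


class ValidationError(ValueError):
    """A row violates a domain invariant (e.g. ROI outside the image)."""


@dataclasses.dataclass(frozen=True)
class ROI:
    """A pixel-space region of interest: a half-open box or a polygon."""

    box: tuple[int, int, int, int] | None = None
    polygon: shapely.Polygon | None = None

    def __post_init__(self) -> None:
        if (self.box is None) == (self.polygon is None):
            raise ValueError("ROI needs exactly one of box or polygon")
        if self.box is not None:
            x0, y0, x1, y1 = self.box
            if x1 <= x0 or y1 <= y0:
                raise ValidationError(f"inverted or empty box ROI {self.box}")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        if self.box is not None:
            return tuple(map(float, self.box))  # type: ignore[return-value]
        return self.polygon.bounds  # type: ignore[union-attr]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of shape (rows, cols); centre-inside rule for polygons."""
        h, w = shape
        m = np.zeros((h, w), dtype=bool)
        if self.box is not None:
            x0, y0, x1, y1 = self.box
            m[max(y0, 0):min(y1, h), max(x0, 0):min(x1, w)] = True
            return m
        minx, miny, maxx, maxy = self.polygon.bounds
        x0, x1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)) + 1, w)
        y0, y1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)) + 1, h)
        if x1 <= x0 or y1 <= y0:
            return m
        xs, ys = np.meshgrid(np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5)
        inside = shapely.contains_xy(self.polygon, xs.ravel(), ys.ravel())
        m[y0:y1, x0:x1] = inside.reshape(ys.shape)
        return m

    @classmethod
    def parse(cls, text: str) -> "ROI":
        """Parse ``"x0,y0,x1,y1"`` or a WKT POLYGON string."""
        text = text.strip()
        if text.upper().startswith("POLYGON"):
            return cls(polygon=shapely.wkt.loads(text))
        parts = text.split(",")
        if len(parts) != 4:
            raise SchemaError(f"cannot parse ROI {text!r}")
        return cls(box=tuple(int(round(float(p))) for p in parts))  # type: ignore[arg-type]

    def to_string(self) -> str:
        if self.box is not None:
            return ",".join(str(v) for v in self.box)
        return self.polygon.wkt


@dataclasses.dataclass
class PlotSample:
    """One plot x date observation with its measured yield and image."""

    plot_id: str
    roi: ROI
    variety: str
    defoliant_conc: str
    spray_time: str
    date_offset: int
    yield_t_ha: float
    image_path: Path

    def __post_init__(self) -> None:
        self.image_path = Path(self.image_path)
        if self.yield_t_ha < 0:
            raise ValidationError(
                f"plot {self.plot_id}: negative yield {self.yield_t_ha}"
            )


class FeatureTable:
    """Samples x named features with the yield target and family tags.

    Parameters
    ----------
    data
        DataFrame with one row per sample; must contain ``yield_t_ha``.
    families
        Mapping feature column -> family in {"color", "vi", "texture"}.
        Columns not listed are inferred from the registries above; unknown
        columns raise.
    """

    def __init__(self, data: pd.DataFrame, families: Mapping[str, str] | None = None):
        if TARGET_COLUMN not in data.columns:
            raise SchemaError(f"feature table lacks target column {TARGET_COLUMN!r}")
        if data.columns.duplicated().any():
            dupes = data.columns[data.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate feature columns {dupes}")
        self.data = data.copy()
        feats = [c for c in data.columns if c != TARGET_COLUMN]
        fam = dict(families or {})
        for c in feats:
            if c not in fam:
                fam[c] = infer_family(c)
            if fam[c] not in FAMILIES:
                raise SchemaError(f"column {c!r} has unknown family {fam[c]!r}")
        self.families = {c: fam[c] for c in feats}

    # -- accessors ---------------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return list(self.families)

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def y(self) -> pd.Series:
        return self.data[TARGET_COLUMN]

    def __len__(self) -> int:
        return len(self.data)

    def family_columns(self, family: str) -> list[str]:
        return [c for c, f in self.families.items() if f == family]

    def subset(self, columns: Sequence[str]) -> "FeatureTable":
        """Restrict to the given feature columns (target kept)."""
        cols = list(columns)
        missing = set(cols) - set(self.feature_names)
        if missing:
            raise SchemaError(f"unknown feature columns {sorted(missing)}")
        return FeatureTable(
            self.data[cols + [TARGET_COLUMN]],
            {c: self.families[c] for c in cols},
        )

    def select_rows(self, index) -> "FeatureTable":
        return FeatureTable(self.data.loc[index], self.families)

    def drop_nan_columns(self) -> "FeatureTable":
        """Drop feature columns containing any NaN (the default model policy)."""
        keep = [c for c in self.feature_names if not self.data[c].isna().any()]
        dropped = sorted(set(self.feature_names) - set(keep))
        if dropped:
            logger.info("dropping %d all/partial-NaN feature columns: %s",
                        len(dropped), dropped)
        return self.subset(keep)

    def drop_nan_rows(self) -> "FeatureTable":
        return FeatureTable(self.data.dropna(axis=0), self.families)


_KNOWN_FAMILIES: dict[str, str] = {}
_KNOWN_FAMILIES.update({c: "color" for c in COLOR_COLUMNS})
_KNOWN_FAMILIES.update({c: "vi" for c in VI_COLUMNS})
_KNOWN_FAMILIES.update({c: "texture" for c in TEXTURE_COLUMNS})


def infer_family(column: str) -> str:
    """Family tag for one of the pipeline's standard feature columns."""
    try:
        return _KNOWN_FAMILIES[column]
    except KeyError:
        raise SchemaError(
            f"cannot infer family for column {column!r}; pass families= explicitly"
        ) from None


# ---------------------------------------------------------------------------
# plot tables


def read_plot_table(path: str | Path, *, check_bounds: bool = True) -> list[PlotSample]:
    """Read a plot CSV into validated :class:`PlotSample` records.

    The CSV must have header columns ``plot_id, roi, variety, conc, time,
    date_offset, yield_t_ha, image_path``. ROIs are ``"x0,y0,x1,y1"`` boxes
    (quoted) or WKT polygons. When *check_bounds* is true and the referenced
    image file exists, the ROI is checked to lie inside the image.
    """
    df = pd.read_csv(path, dtype={"plot_id": str})
    missing = [c for c in PLOT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plot table {path} missing columns {missing}")
    base = Path(path).parent
    samples = []
    sizes: dict[Path, tuple[int, int]] = {}
    for _, row in df.iterrows():
        roi = ROI.parse(str(row["roi"]))
        img = Path(str(row["image_path"]))
        if not img.is_absolute():
            img = base / img
        s = PlotSample(
            plot_id=str(row["plot_id"]),
            roi=roi,
            variety=str(row["variety"]),
            defoliant_conc=str(row["conc"]),
            spray_time=str(row["time"]),
            date_offset=int(row["date_offset"]),
            yield_t_ha=float(row["yield_t_ha"]),
            image_path=img,
        )
        if check_bounds and img.exists():
            if img not in sizes:
                with Image.open(img) as im:
                    sizes[img] = im.size  # (width, height)
            w, h = sizes[img]
            minx, miny, maxx, maxy = roi.bounds
            if minx < 0 or miny < 0 or maxx > w or maxy > h:
                raise ValidationError(
                    f"plot {s.plot_id}: ROI {roi.to_string()} outside "
                    f"{w}x{h} image {img.name}"
                )
        samples.append(s)
    return samples


def write_plot_table(samples: Iterable[PlotSample], path: str | Path) -> None:
    rows = [
        {
            "plot_id": s.plot_id,
            "roi": s.roi.to_string(),
            "variety": s.variety,
            "conc": s.defoliant_conc,
            "time": s.spray_time,
            "date_offset": s.date_offset,
            "yield_t_ha": s.yield_t_ha,
            "image_path": str(s.image_path),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=PLOT_TABLE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature tables

_FAMILY_ORDER = {"color": 0, "vi": 1, "texture": 2}


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV, columns ordered color→vi→texture→yield.

    Floats are written with 12 significant digits; NaN serialises as an empty
    field. An optional ``sample_id`` index is written as the first column.
    """
    order = sorted(
        table.feature_names,
        key=lambda c: (_FAMILY_ORDER[table.families[c]], table.feature_names.index(c)),
    )
    df = table.data[order + [TARGET_COLUMN]]
    df = df.copy()
    df.insert(0, "sample_id", table.data.index.astype(str))
    df.to_csv(path, index=False, float_format="%.12g", na_rep="")


def read_feature_table(path: str | Path,
                       families: Mapping[str, str] | None = None) -> FeatureTable:
    df = pd.read_csv(path)
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
        df.index = df.index.astype(str)
    return FeatureTable(df, families)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "plot_area_m2": 25.0,       # each plot is 2.5 m x 10 m
    "simulate": {
        "n_plots": 48,
        "n_dates": 5,
        "tile_size": 256,
        "pixel_size_m": 0.003,  # 0.3 cm ground resolution
        "yield_mean": 3.0,
        "yield_sd": 2.91,
        "yield_min": 0.0,
        "yield_max": 11.58,
        "boll_weight_g": 5.0,
        "film_fraction": 0.35,
        "noise_sd": 3.0,
    },
    "glcm": {"levels": 32, "distance": 1, "symmetric": True, "mode": "luminance"},
    "select": {"k": 6, "fusion_k": 3, "mic_alpha": 0.6, "mic_c": 15,
               "rf_trees": 500},
    "train": {"ratio": 199 / 315, "cv_folds": 5},
    "map": {"bin_edges": [3.62, 8.33]},
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config, deep-merged over :data:`DEFAULT_CONFIG`."""
    cfg = _deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _merge(cfg, user)
    return cfg


def _deepcopy(d: dict) -> dict:
    return {k: _deepcopy(v) if isinstance(v, dict) else v for k, v in d.items()}


def _merge(dst: dict, src: dict) -> None:
    for k, v in src.items():
        if isinstance(v, dict) and isinstance(dst.get(k), dict):
            _merge(dst[k], v)
        else:
            dst[k] = v
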