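"""Accuracy metrics, yield arithmetic and the per-plot inversion table.

Metrics follow the squared-correlation convention:

    R²    = [Σ(xᵢ−x̄)(yᵢ−ȳ)]² / [Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²]   (squared Pearson r)
    RMSE  = sqrt(mean (yᵢ−xᵢ)²)                       (t·ha⁻¹)
    rRMSE = 100 · RMSE / x̄                            (%)

with x the measured and y the predicted yields. Note R² as a squared
correlation is insensitive to additive bias — a pure offset keeps R² = 1
while RMSE grows; this is a property of the convention, not a bug.

Ground truth comes from boll counts: single-boll weight is the 10-plant
yield divided by the 10-plant boll count, and theoretical yield is
single-boll weight × boll density (g·m⁻² → t·ha⁻¹ is a ×0.01 conversion).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import PlotSample


@dataclasses.dataclass(frozen=True)
class EvalMetrics:
    """R², RMSE and rRMSE of one prediction set."""

    n: int
    r2: float
    rmse: float
    rrmse: float
    mean_measured: float
    mean_predicted: float


@dataclasses.dataclass(frozen=True)
class YieldRecord:
    """Ten-plant yield survey for one plot."""

    ten_plant_yield_g: float
    ten_plant_boll_count: int
    boll_density_per_m2: float

    def __post_init__(self) -> None:
        if self.ten_plant_boll_count <= 0:
            raise ValueError("boll count must be positive")
        if self.ten_plant_yield_g < 0 or self.boll_density_per_m2 < 0:
            raise ValueError("yield and boll density must be non-negative")

    @property
    def single_boll_weight_g(self) -> float:
        return self.ten_plant_yield_g / self.ten_plant_boll_count


def yield_from_bolls(record: YieldRecord, plot_area_m2: float = 25.0) -> float:
    """Theoretical yield in t·ha⁻¹ from the boll survey.

    yield = single-boll weight (g) × boll density (m⁻²) gives g·m⁻²;
    1 g·m⁻² = 0.01 t·ha⁻¹. The plot area is accepted for callers that carry
    densities as per-plot counts.
    """
    g_per_m2 = record.single_boll_weight_g * record.boll_density_per_m2
    return g_per_m2 * 0.01


def compute_metrics(measured, predicted) -> EvalMetrics:
    """R² (squared Pearson r), RMSE and rRMSE of predictions vs measurements."""
    x = np.asarray(measured, dtype=np.float64)
    y = np.asarray(predicted, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("measured and predicted must be equal-length vectors")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    syy = ((y - ym) ** 2).sum()
    if sxx == 0:
        raise ValueError("measured vector is constant; R² undefined")
    if syy == 0:
        r2 = 0.0  # constant predictions carry no correlation information
    else:
        r2 = float(((x - xm) @ (y - ym)) ** 2 / (sxx * syy))
    rmse = float(np.sqrt(((y - x) ** 2).mean()))
    rrmse = float(100.0 * rmse / xm) if xm > 0 else float("nan")
    return EvalMetrics(n=n, r2=r2, rmse=rmse, rrmse=rrmse,
                       mean_measured=float(xm), mean_predicted=float(ym))


# ---------------------------------------------------------------------------
# model-comparison tables

_METRIC_COLS = ("R2", "RMSE", "rRMSE")


def comparison_table(reports) -> pd.DataFrame:
    """Selector-by-model table of Cal/Val metrics, best model flagged per row.

    Rows are selectors; columns a MultiIndex (model, split, metric). The
    extra column ("best", "", "") names the model with the highest
    validation R² in each row.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to tabulate")
    rows: dict[str, dict] = {}
    for rep in reports:
        row = rows.setdefault(rep.selector, {})
        for split, m in (("Cal", rep.train_metrics), ("Val", rep.val_metrics)):
            if m is None:
                continue
            row[(rep.model, split, "R2")] = m.r2
            row[(rep.model, split, "RMSE")] = m.rmse
            row[(rep.model, split, "rRMSE")] = m.rrmse
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    df = df.sort_index(axis=1)
    best = []
    for sel in df.index:
        val_r2 = {m: df.loc[sel].get((m, "Val", "R2"), np.nan)
                  for m in df.columns.levels[0]}
        best.append(max(val_r2, key=lambda m: (np.nan_to_num(val_r2[m], nan=-1))))
    df[("best", "", "")] = best
    return df


def format_comparison(df: pd.DataFrame) -> str:
    """Plain-text rendering of a comparison table."""
    return df.to_string(float_format=lambda v: f"{v:.4f}")


# ---------------------------------------------------------------------------
# inversion map

DEFAULT_BIN_EDGES = (3.62, 8.33)  # t·ha⁻¹ low/high yield class boundaries


def inversion_map(samples: list[PlotSample], predictions,
                  bin_edges=DEFAULT_BIN_EDGES) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plot inversion table and bin-wise bias diagnostics.

    Returns ``(table, diagnostics)``: the table has one row per plot with
    measured and predicted yield, its yield bin and signed error
    (predicted − measured); diagnostics report per-bin sample count, mean
    signed error and RMSE, quantifying low-yield overestimation and
    high-yield underestimation.
    """
    preds = np.asarray(predictions, dtype=np.float64)
    if len(preds) != len(samples):
        raise ValueError("need exactly one prediction per plot sample")
    edges = [-np.inf, *sorted(bin_edges), np.inf]
    labels = [f"<{edges[1]:g}"] + [
        f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(1, len(edges) - 2)
    ] + [f">{edges[-2]:g}"]
    rows = []
    for s, p in zip(samples, preds):
        b = int(np.searchsorted(edges[1:-1], s.yield_t_ha, side="right"))
        rows.append({
            "plot_id": s.plot_id, "date_offset": s.date_offset,
            "measured_t_ha": s.yield_t_ha, "predicted_t_ha": float(p),
            "bin": labels[b], "error_t_ha": float(p) - s.yield_t_ha,
        })
    table = pd.DataFrame(rows)
    diag = (table.groupby("bin", sort=False)
            .agg(n=("error_t_ha", "size"),
                 mean_signed_error=("error_t_ha", "mean"),
                 rmse=("error_t_ha", lambda e: float(np.sqrt((e**2).mean()))))
            .reindex(labels).dropna(how="all"))
    return table, diag


def export_geojson(samples: list[PlotSample], table: pd.DataFrame,
                   path: str | Path) -> None:
    """Write the inversion table as a GeoJSON choropleth (pixel-space rings)."""
    feats = []
    by_id = {(s.plot_id, s.date_offset): s for s in samples}
    for _, row in table.iterrows():
        s = by_id.get((row["plot_id"], row["date_offset"]))
        geom = None
        if s is not None:
            if s.roi.box is not None:
                x0, y0, x1, y1 = s.roi.box
                ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
            else:
                ring = [list(c) for c in s.roi.polygon.exterior.coords]
            geom = {"type": "Polygon", "coordinates": [ring]}
        feats.append({
            "type": "Feature", "geometry": geom,
            "properties": {k: row[k] for k in
                           ("plot_id", "measured_t_ha", "predicted_t_ha",
                            "bin", "error_t_ha")},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
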