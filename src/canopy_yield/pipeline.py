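"""End-to-end orchestration: simulate → extract → select → train → evaluate → map.

Each stage is a plain function over the interchange objects (plot sample
lists and feature tables), so the CLI, the examples and the test suite all
drive the same code path. Feature selection and model tuning see training
data only; validation rows never influence scaling, screening or grids.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import feature_selection as fs
from . import models as mdl
from .color_features import summarize_color
from .evaluation import compute_metrics, inversion_map
from .io_core import FeatureTable, PlotSample, TARGET_COLUMN
from .synthetic import SceneParams, simulate_image_dataset
from .texture_features import texture_vector

logger = logging.getLogger("canopy_yield")


def extract_features(samples: list[PlotSample], *, levels: int = 32,
                     distance: int = 1, symmetric: bool = True,
                     gray_mode: str = "luminance") -> FeatureTable:
    """Colour + VI + texture feature row per plot sample."""
    rows, index = [], []
    cache: dict[Path, np.ndarray] = {}
    for s in samples:
        if s.image_path not in cache:
            cache[s.image_path] = np.asarray(Image.open(s.image_path).convert("RGB"))
        img = cache[s.image_path]
        summary, vis = summarize_color(img, s.roi)
        row = summary.as_row() | vis.as_row()
        row |= texture_vector(img, s.roi, levels=levels, distance=distance,
                              symmetric=symmetric, mode=gray_mode)
        row[TARGET_COLUMN] = s.yield_t_ha
        rows.append(row)
        index.append(f"{s.plot_id}_d{s.date_offset:02d}")
    return FeatureTable(pd.DataFrame(rows, index=index))


def family_table(table: FeatureTable, family: str) -> FeatureTable:
    """Restrict a table to one feature family ('vi', 'texture' or 'fused')."""
    if family == "fused":
        cols = table.family_columns("vi") + table.family_columns("texture")
    else:
        cols = table.family_columns(family)
    if not cols:
        raise ValueError(f"table has no {family!r} features")
    return table.subset(cols)


def select_and_fit(table: FeatureTable, *, selector: str = "RFE",
                   model: str = "ELM", family: str = "fused",
                   k: int = 6, fusion_k: int = 3,
                   ratio: float = mdl.DEFAULT_SPLIT_RATIO,
                   cv_folds: int = 5, seed: int = 42) -> mdl.FitReport:
    """Split, screen features on the training split only, tune and fit."""
    sub = family_table(table, family).drop_nan_columns()
    train, val = mdl.split_train_validation(sub, ratio=ratio, seed=seed)
    fusion = family == "fused"
    sel = fs.run_selector(selector, train, k=fusion_k if fusion else k,
                          fusion=fusion, seed=seed)
    logger.info("selector %s picked %s", selector, sel.selected)
    report = mdl.fit_model(
        mdl.ModelSpec(model, cv_folds=cv_folds, seed=seed),
        train.subset(sel.selected), val.subset(sel.selected),
        selector=selector,
    )
    return report


def run_image_pipeline(work_dir: str | Path, params: SceneParams | None = None,
                       *, n_dates: int = 5, seed: int = 42,
                       selector: str = "RFE", model: str = "ELM",
                       family: str = "fused",
                       bin_edges=(3.62, 8.33)) -> dict:
    """Full image-tier run; returns reports, tables and diagnostics."""
    params = params or SceneParams(seed=seed)
    samples = simulate_image_dataset(Path(work_dir) / "tiles", params,
                                     n_dates=n_dates, seed=seed)
    table = extract_features(samples)
    report = select_and_fit(table, selector=selector, model=model,
                            family=family, seed=seed)
    preds = mdl.predict(report, family_table(table, family)
                        .drop_nan_columns().subset(report.feature_names))
    map_table, diag = inversion_map(samples, preds, bin_edges=bin_edges)
    return {
        "samples": samples, "features": table, "report": report,
        "all_metrics": compute_metrics([s.yield_t_ha for s in samples], preds),
        "map": map_table, "diagnostics": diag,
    }
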