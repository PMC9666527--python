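"""Canopy-area to dry-biomass regression at the individual-plant level.

Detected bounding-box and segmented canopy-mask areas are regressed
(ordinary least squares with intercept, species fitted separately)
against oven-dried above-ground biomass in grams. Pixel areas convert to
physical areas through the ground sample distance (GSD, mm per pixel):
``cm^2 = px * (gsd_mm / 10)^2``. The coefficient of determination R^2
summarizes predictability; mask area typically beats box area because
boxes over-cover sprawling canopies non-systematically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AreaMeasurement",
    "RegressionFit",
    "measure_areas",
    "merge_seasons",
    "fit_area_biomass",
]


@dataclass
class AreaMeasurement:
    """Per-plant areas: bbox (px^2), mask (px^2), physical (cm^2)."""

    plant_id: str
    bbox_area: float
    mask_area: float | None = None
    physical_area: float | None = None


@dataclass
class RegressionFit:
    """OLS fit of biomass on area: slope, intercept, R^2, sample size."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    predictor: str = "mask_area"


def measure_areas(record: dict, gsd_mm: float | None = None, plant_id: str = "") -> AreaMeasurement:
    """Areas of one annotation or detection record.

    ``bbox_area`` is w * h of the [x, y, w, h] box; ``mask_area`` is the
    visible-mask pixel count (absent when the record carries no mask);
    ``physical_area`` converts mask pixels to cm^2 via the GSD.
    """
    x, y, w, h = record["bbox"]
    bbox_area = float(w) * float(h)
    mask_area: float | None = None
    if record.get("area") is not None and record.get("segmentation") is not None:
        mask_area = float(record["area"])
    elif isinstance(record.get("mask"), np.ndarray):
        mask_area = float(np.count_nonzero(record["mask"]))
    physical = None
    if mask_area is not None and gsd_mm is not None:
        physical = mask_area * (gsd_mm / 10.0) ** 2
    return AreaMeasurement(
        plant_id=plant_id or str(record.get("id", "")),
        bbox_area=bbox_area,
        mask_area=mask_area,
        physical_area=physical,
    )


def merge_seasons(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-season biomass tables; plant ids must stay unique.

    Expected columns: ``plant_id``, ``species``, ``dry_biomass_g`` (a
    ``year`` column, when present, is carried through). Per-species counts
    are strictly additive.
    """
    merged = pd.concat(tables, ignore_index=True)
    dup = merged["plant_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate plant_id across seasons: {sorted(merged.loc[dup, 'plant_id'].unique())}"
        )
    if (merged["dry_biomass_g"] < 0).any():
        raise ValueError("dry biomass must be >= 0")
    return merged


def fit_area_biomass(
    areas, biomass, predictor: str = "mask_area"
) -> RegressionFit:
    """Ordinary least squares of biomass (g) on canopy area, with intercept.

    Raises on length mismatch, n < 3, or a constant predictor. R^2 is
    1 - SS_res / SS_tot and is invariant to affine rescaling of the
    predictor (e.g. px^2 -> cm^2).
    """
    x = np.asarray(areas, dtype=np.float64)
    y = np.asarray(biomass, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("areas and biomass must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a regression fit")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance: fit is degenerate")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=int(x.size),
        predictor=predictor,
    )
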