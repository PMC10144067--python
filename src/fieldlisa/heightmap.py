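"""Canopy height model and per-plant height extraction.

The height map is the cell-wise difference DSM − DTM (crop surface minus
bare ground).  Per-plant heights are the maximum height-map value inside
a circular buffer around each sowing point (default 0.40 m diameter),
then standardized over the whole field and filtered with a lower z-score
cutoff (default −1.646, the lowest ~5% of the cumulative distribution).
A plot-level regression of actual on estimated maxima validates the
extraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    InvalidInputError,
    InvalidParameterError,
)
from .raster import Raster

logger = logging.getLogger(__name__)

DEFAULT_BUFFER_DIAMETER = 0.40
DEFAULT_OUTLIER_CUTOFF = -1.646

__all__ = [
    "ValidationReport",
    "compute_height_map",
    "extract_buffer_max",
    "normalize_heights",
    "filter_outliers",
    "validate_heights",
    "DEFAULT_BUFFER_DIAMETER",
    "DEFAULT_OUTLIER_CUTOFF",
]


@dataclass
class ValidationReport:
    """OLS fit of actual on estimated plot-maximum heights."""

    slope: float  # regression coefficient (RC)
    intercept: float  # meters
    r_squared: float
    n: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"actual = {self.slope:.3f} x estimated + {self.intercept:.3f} "
            f"(R^2 = {self.r_squared:.3f}, n = {self.n})"
        )


def compute_height_map(dsm: Raster, dtm: Raster, clamp_negative: bool = False) -> Raster:
    """Cell-wise canopy height: DSM − DTM.

    Cells where either input is nodata propagate nodata.  With
    ``clamp_negative`` any negative difference (surface reconstruction
    artifacts) is set to zero.
    """
    dsm.require_alignment(dtm, "DSM and DTM")
    valid = dsm.mask() & dtm.mask()
    height = dsm.values - dtm.values
    if clamp_negative:
        height = np.maximum(height, 0.0)
    height = np.where(valid, height, dsm.nodata)
    return dsm.copy_with(height)


def extract_buffer_max(
    height_map: Raster,
    plants: pd.DataFrame,
    buffer_diameter: float = DEFAULT_BUFFER_DIAMETER,
) -> pd.DataFrame:
    """Fill ``height_est`` with the buffer-maximum height per plant.

    A cell belongs to a plant's buffer iff its center lies within
    ``buffer_diameter / 2`` of the sowing point.  Plants whose buffer
    holds only nodata are dropped with a logged warning.
    """
    if buffer_diameter <= 0:
        raise InvalidParameterError(f"buffer_diameter must be > 0, got {buffer_diameter}")
    if buffer_diameter < height_map.cell_size:
        raise InvalidParameterError(
            f"buffer_diameter {buffer_diameter} m is smaller than one raster cell "
            f"({height_map.cell_size} m)"
        )

    radius = buffer_diameter / 2.0
    cs = height_map.cell_size
    nrows, ncols = height_map.shape
    x0, y0 = height_map.origin
    halo = int(math.ceil(radius / cs)) + 1

    out = plants.copy()
    est = np.full(len(out), np.nan)
    for k, (x, y) in enumerate(out[["x", "y"]].to_numpy()):
        prow, pcol = height_map.world_to_index(x, y)
        r0, r1 = max(0, prow - halo), min(nrows, prow + halo + 1)
        c0, c1 = max(0, pcol - halo), min(ncols, pcol + halo + 1)
        cx = x0 + (np.arange(c0, c1) + 0.5) * cs
        cy = y0 - (np.arange(r0, r1) + 0.5) * cs
        dx, dy = np.meshgrid(cx - x, cy - y)
        window = height_map.values[r0:r1, c0:c1]
        in_buffer = (np.hypot(dx, dy) <= radius) & (window != height_map.nodata)
        if in_buffer.any():
            est[k] = window[in_buffer].max()
    out["height_est"] = est

    dropped = out["height_est"].isna()
    if dropped.any():
        logger.warning(
            "dropping %d plant(s) whose buffer contains only nodata: %s",
            dropped.sum(),
            out.loc[dropped, "plant_id"].tolist(),
        )
        out = out[~dropped].reset_index(drop=True)
    return out


def normalize_heights(plants: pd.DataFrame, height_col: str = "height_est") -> pd.DataFrame:
    """Standardize heights over all plants jointly: z = (h − mean) / sd.

    Uses the population (divide-by-N) standard deviation, matching the
    local Moran normalization m = ΣZ²/N, so that m = 1 exactly on the
    standardized values.
    """
    if len(plants) < 2:
        raise InvalidInputError("need at least 2 plants to standardize heights")
    h = plants[height_col].to_numpy(dtype=float)
    sd = h.std(ddof=0)
    if sd == 0:
        raise DegenerateVarianceError("all heights identical; z-scores are undefined")
    out = plants.copy()
    out["z"] = (h - h.mean()) / sd
    return out


def filter_outliers(plants: pd.DataFrame, cutoff: float = DEFAULT_OUTLIER_CUTOFF) -> pd.DataFrame:
    """Flag low-tail outliers: ``outlier`` ⇔ z < cutoff.

    The default cutoff −1.646 removes roughly the lowest 5% under a
    standard-normal distribution (non-germinated or failed extractions).
    Flagged rows stay in the table; downstream spatial stages use
    :func:`non_outliers`.  z-scores are not recomputed after flagging.
    """
    if "z" not in plants.columns:
        raise InvalidInputError("plants table has no z column; run normalize_heights first")
    out = plants.copy()
    out["outlier"] = out["z"] < cutoff
    return out


def non_outliers(plants: pd.DataFrame) -> pd.DataFrame:
    """Rows that survived the outlier filter."""
    if "outlier" not in plants.columns:
        return plants
    return plants[~plants["outlier"]].reset_index(drop=True)


def validate_heights(estimated_plot_max, actual_plot_max) -> ValidationReport:
    """OLS of actual plot-maximum height on the estimated one.

    The slope is the regression coefficient (RC); R² measures how much of
    the actual-height variance the map-derived estimate explains.
    """
    est = np.asarray(estimated_plot_max, dtype=float)
    act = np.asarray(actual_plot_max, dtype=float)
    if est.shape != act.shape:
        raise InvalidInputError(f"length mismatch: {est.shape} estimated vs {act.shape} actual")
    if est.size < 3:
        raise InvalidInputError(f"need at least 3 plots to validate, got {est.size}")
    fit = stats.linregress(est, act)
    return ValidationReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=int(est.size),
    )
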