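"""Cluster-region delineation and management-zone blocking.

Per-plant LISA classes are aggregated to plot level: a plot whose
non-outlier plants are dominated by L-L (low value among low neighbors)
joins the low-growth region, H-H plots the high-growth region.  The two
regions plus the remainder give the A/B/C management zones used to block
future trials against field heterogeneity: A = low growing conditions,
B = high, C = neutral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union

from .errors import ConsistencyError, InvalidInputError, InvalidParameterError
from .synthetic import FieldLayout

logger = logging.getLogger(__name__)

DEFAULT_MIN_FRACTION = 0.5

__all__ = ["ClusterRegion", "delineate_regions", "compare_dates", "assign_zones"]


@dataclass
class ClusterRegion:
    """A set of plots dominated by one LISA cluster class."""

    kind: str  # "low_growth" | "high_growth"
    plot_ids: frozenset
    polygon: object  # shapely geometry, union of member plot rectangles
    fraction_per_plot: dict

    def __len__(self) -> int:
        return len(self.plot_ids)


def _region(kind: str, plot_ids: set, fractions: dict, layout: FieldLayout) -> ClusterRegion:
    rects = [box(*layout.plot_rectangle(pid)) for pid in sorted(plot_ids)]
    poly = unary_union(rects) if rects else box(0, 0, 0, 0).buffer(0)
    return ClusterRegion(
        kind=kind,
        plot_ids=frozenset(plot_ids),
        polygon=poly,
        fraction_per_plot={pid: fractions[pid] for pid in sorted(plot_ids)},
    )


def delineate_regions(
    lisa_table: pd.DataFrame,
    layout: FieldLayout,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> tuple[ClusterRegion, ClusterRegion]:
    """Plot-level low/high growth regions from per-plant cluster labels.

    A plot joins the low-growth region when at least ``min_fraction`` of
    its non-outlier plants are class L-L, and the high-growth region
    analogously for H-H.  At ``min_fraction`` <= 0.5 a plot could qualify
    for both; the larger fraction wins, and an exact tie raises
    :class:`ConsistencyError`.  Returns ``(low, high)``.
    """
    if not 0 < min_fraction <= 1:
        raise InvalidParameterError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if len(lisa_table) == 0:
        raise InvalidInputError("empty LISA table")
    if "class" not in lisa_table.columns or "plot_id" not in lisa_table.columns:
        raise InvalidInputError("LISA table needs plot_id and class columns")

    plants = lisa_table
    if "outlier" in plants.columns:
        plants = plants[~plants["outlier"]]

    frac_ll: dict = {}
    frac_hh: dict = {}
    for pid, grp in plants.groupby("plot_id"):
        n = len(grp)
        frac_ll[pid] = (grp["class"] == "LL").sum() / n
        frac_hh[pid] = (grp["class"] == "HH").sum() / n

    low_ids, high_ids = set(), set()
    for pid in frac_ll:
        lo, hi = frac_ll[pid] >= min_fraction, frac_hh[pid] >= min_fraction
        if lo and hi:
            if frac_ll[pid] == frac_hh[pid]:
                raise ConsistencyError(
                    f"plot {pid} qualifies equally for both regions "
                    f"(fraction {frac_ll[pid]:.2f} at min_fraction {min_fraction})"
                )
            (low_ids if frac_ll[pid] > frac_hh[pid] else high_ids).add(pid)
        elif lo:
            low_ids.add(pid)
        elif hi:
            high_ids.add(pid)

    return _region("low_growth", low_ids, frac_ll, layout), _region("high_growth", high_ids, frac_hh, layout)


def compare_dates(region_t1: ClusterRegion, region_t2: ClusterRegion) -> float | None:
    """Jaccard index of the two regions' plot-id sets.

    1.0 for identical sets, 0.0 for disjoint non-empty sets; ``None``
    (with a warning) when both sets are empty, where similarity is
    undefined.
    """
    a, b = set(region_t1.plot_ids), set(region_t2.plot_ids)
    union = a | b
    if not union:
        logger.warning("both cluster regions are empty; Jaccard similarity undefined")
        return None
    return len(a & b) / len(union)


def assign_zones(
    low: ClusterRegion,
    high: ClusterRegion,
    layout: FieldLayout,
) -> dict:
    """Total A/B/C partition of the plots.

    A = low-growth plots, B = high-growth plots, C = everything else
    (including bare plots).  Overlapping regions raise
    :class:`ConsistencyError`.
    """
    overlap = set(low.plot_ids) & set(high.plot_ids)
    if overlap:
        raise ConsistencyError(f"plots {sorted(overlap)} belong to both regions")
    zones = {}
    for pid in layout.plots["plot_id"]:
        if pid in low.plot_ids:
            zones[pid] = "A"
        elif pid in high.plot_ids:
            zones[pid] = "B"
        else:
            zones[pid] = "C"
    return zones
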