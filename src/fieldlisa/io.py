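"""CSV and GeoJSON serialization of layouts, plant tables and regions.

All geometry is in a local planar CRS in meters; GeoJSON files carry the
coordinates as-is (no geographic reprojection is meaningful for a
synthetic field).
"""

from __future__ import annotations

import json

import pandas as pd
from shapely.geometry import box, mapping

from .errors import InvalidInputError
from .lisa import CLASS_COLORS
from .synthetic import FieldLayout

__all__ = [
    "write_layout_csv",
    "read_layout_csv",
    "write_layout_geojson",
    "write_lisa_geojson",
    "write_regions_geojson",
]


def write_layout_csv(layout: FieldLayout, plots_path, plants_path) -> None:
    layout.plots.to_csv(plots_path, index=False)
    layout.plants.to_csv(plants_path, index=False)


def read_layout_csv(plots_path, plants_path) -> FieldLayout:
    plots = pd.read_csv(plots_path)
    plants = pd.read_csv(plants_path)
    needed = {"plot_id", "germplasm", "replicate", "x_min", "y_min", "x_max", "y_max"}
    if not needed <= set(plots.columns):
        raise InvalidInputError(f"plots CSV needs columns {sorted(needed)}")
    extent = (
        float(plots["x_min"].min()),
        float(plots["y_min"].min()),
        float(plots["x_max"].max()),
        float(plots["y_max"].max()),
    )
    return FieldLayout(plots=plots, plants=plants, extent=extent)


def _feature_collection(features) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_layout_geojson(layout: FieldLayout, path, zones: dict | None = None) -> None:
    """Plot rectangles as polygon features, optionally tagged with A/B/C zones."""
    features = []
    for row in layout.plots.itertuples(index=False):
        props = {
            "plot_id": int(row.plot_id),
            "germplasm": row.germplasm,
            "replicate": int(row.replicate),
        }
        if zones is not None:
            props["zone"] = zones.get(row.plot_id, "C")
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(box(row.x_min, row.y_min, row.x_max, row.y_max)),
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump(_feature_collection(features), fh, indent=1)


def write_lisa_geojson(lisa_table: pd.DataFrame, path) -> None:
    """Plant points with LISA class labels and the conventional palette."""
    features = []
    for row in lisa_table.to_dict("records"):
        cls = row["class"]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row["x"]), float(row["y"])]},
                "properties": {
                    "plant_id": int(row["plant_id"]),
                    "z": float(row["z"]),
                    "I": float(row["I"]),
                    "pseudo_p": None if pd.isna(row["pseudo_p"]) else float(row["pseudo_p"]),
                    "class": cls,
                    "color": CLASS_COLORS.get(cls, CLASS_COLORS["NS"]),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump(_feature_collection(features), fh, indent=1)


def write_regions_geojson(low, high, path) -> None:
    """Low/high growth cluster regions as (multi)polygon features."""
    features = []
    for region in (low, high):
        if len(region) == 0:
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(region.polygon),
                "properties": {
                    "kind": region.kind,
                    "plot_ids": sorted(int(p) for p in region.plot_ids),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump(_feature_collection(features), fh, indent=1)
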