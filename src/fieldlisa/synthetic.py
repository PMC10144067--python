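"""Synthetic breeding-field generator.

Emulates a randomized single-factor field trial: ``n_germplasms``
accessions replicated ``n_reps`` times on a rectangular plot grid, each
plot direct-sown as a single ridge row of equally spaced plants.  On top
of the layout the module generates a bare-ground terrain (DTM) with a
directional slope, germplasm-specific true plant heights modulated by an
elevation-linked growth suppression (standing in for poor drainage at
low altitude), and a rendered crop surface (DSM) from which the
downstream canopy-height pipeline can be exercised end to end.

Every generator is a pure function of its parameters and an explicit
integer seed; no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidParameterError, OutOfExtentError
from .raster import Raster

__all__ = [
    "FieldLayout",
    "GrowthModel",
    "generate_layout",
    "generate_terrain",
    "generate_true_heights",
    "render_dsm",
    "logistic_env_effect",
    "default_germplasm_means",
    "simulate_field",
]


@dataclass
class FieldLayout:
    """Plots (germplasm, replicate, rectangle) and plant sowing points.

    ``plots`` columns: plot_id, germplasm, replicate, x_min, y_min, x_max, y_max.
    ``plants`` columns: plant_id, plot_id, germplasm, replicate, x, y.
    ``extent``: (x_min, y_min, x_max, y_max) of the whole field in meters.
    """

    plots: pd.DataFrame
    plants: pd.DataFrame
    extent: tuple[float, float, float, float]

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    def plot_rectangle(self, plot_id: int) -> tuple[float, float, float, float]:
        row = self.plots.set_index("plot_id").loc[plot_id]
        return (row.x_min, row.y_min, row.x_max, row.y_max)


@dataclass
class GrowthModel:
    """True-height model: germplasm mean x environmental multiplier + noise.

    ``env_effect`` maps terrain elevation (m) to a multiplier in (0, 1],
    monotone non-decreasing (lower ground grows worse).  ``None`` means no
    environmental effect (multiplier 1 everywhere), the spatially
    exchangeable null configuration.  ``bare_germplasms`` lists accessions
    that failed to germinate; their plots stay bare ground.
    """

    germplasm_means: Mapping[str, float]
    env_effect: Callable[[np.ndarray], np.ndarray] | None = None
    noise_sd: float = 0.05
    bare_germplasms: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.germplasm_means.values()):
            raise InvalidParameterError("germplasm mean heights must be strictly positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        self.bare_germplasms = frozenset(self.bare_germplasms)


def generate_layout(
    n_germplasms: int = 24,
    n_reps: int = 3,
    plants_per_plot: int = 15,
    plant_spacing: float = 0.25,
    plot_spacing: float = 0.50,
    grid_cols: int = 8,
    seed: int = 0,
    *,
    margin: float = 0.25,
    border: float = 1.0,
    germplasm_names: Iterable[str] | None = None,
) -> FieldLayout:
    """Randomized layout of ``n_germplasms`` x ``n_reps`` plots on a grid.

    Plots are rectangles on a ``grid_cols``-wide grid separated by
    ``plot_spacing``; each holds one ridge row of ``plants_per_plot``
    points ``plant_spacing`` apart.  The plot rectangle is the planted row
    plus a ``margin`` on every side (the trial records spacings only, so
    plot dimensions are derived).  Germplasm-to-plot assignment is a
    uniform random permutation under ``seed``.
    """
    for name, v in [
        ("n_germplasms", n_germplasms),
        ("n_reps", n_reps),
        ("plants_per_plot", plants_per_plot),
        ("plant_spacing", plant_spacing),
        ("plot_spacing", plot_spacing),
        ("grid_cols", grid_cols),
    ]:
        if v <= 0:
            raise InvalidParameterError(f"{name} must be positive, got {v}")

    rng = np.random.default_rng(seed)
    if germplasm_names is None:
        germplasm_names = [f"G{i + 1:02d}" for i in range(n_germplasms)]
    else:
        germplasm_names = list(germplasm_names)
        if len(germplasm_names) != n_germplasms:
            raise InvalidParameterError(
                f"got {len(germplasm_names)} germplasm names for n_germplasms={n_germplasms}"
            )

    n_plots = n_germplasms * n_reps
    assignment = np.repeat(np.arange(n_germplasms), n_reps)
    assignment = rng.permutation(assignment)

    plot_w = (plants_per_plot - 1) * plant_spacing + 2 * margin
    plot_h = 2 * margin
    n_rows = math.ceil(n_plots / grid_cols)
    field_w = grid_cols * plot_w + (grid_cols - 1) * plot_spacing
    field_h = n_rows * plot_h + (n_rows - 1) * plot_spacing

    plot_rows, plant_rows = [], []
    rep_seen = {g: 0 for g in germplasm_names}
    plant_id = 0
    for k in range(n_plots):
        gcol, grow = k % grid_cols, k // grid_cols
        x_min = border + gcol * (plot_w + plot_spacing)
        # grid row 0 is the northernmost strip
        y_max = border + field_h - grow * (plot_h + plot_spacing)
        y_min = y_max - plot_h
        g = germplasm_names[assignment[k]]
        rep_seen[g] += 1
        plot_rows.append((k + 1, g, rep_seen[g], x_min, y_min, x_min + plot_w, y_max))
        y_mid = 0.5 * (y_min + y_max)
        for j in range(plants_per_plot):
            plant_id += 1
            plant_rows.append((plant_id, k + 1, g, rep_seen[g], x_min + margin + j * plant_spacing, y_mid))

    plots = pd.DataFrame(
        plot_rows, columns=["plot_id", "germplasm", "replicate", "x_min", "y_min", "x_max", "y_max"]
    )
    plants = pd.DataFrame(plant_rows, columns=["plant_id", "plot_id", "germplasm", "replicate", "x", "y"])
    extent = (0.0, 0.0, field_w + 2 * border, field_h + 2 * border)
    return FieldLayout(plots=plots, plants=plants, extent=extent)


def generate_terrain(
    extent: tuple[float, float, float, float],
    slope_azimuth: float = 315.0,
    slope_drop: float = 2.0,
    roughness_sd: float = 0.03,
    cell_size: float = 0.05,
    seed: int = 0,
    *,
    base_elevation: float = 100.0,
    smoothing_length: float = 2.0,
) -> Raster:
    """Bare-ground DTM: a plane descending toward ``slope_azimuth`` plus smoothed noise.

    ``slope_azimuth`` is a compass bearing in degrees (0 = north, 90 =
    east; the default 315 drops toward the northwest, so the southeast
    corner is the highest ground).  The planar component spans exactly
    ``slope_drop`` meters between the extreme cells along the azimuth.
    ``roughness_sd`` meters of Gaussian micro-relief, smoothed over
    ``smoothing_length`` meters, is superimposed; zero gives an exact plane.
    """
    if cell_size <= 0:
        raise InvalidParameterError(f"cell_size must be > 0, got {cell_size}")
    if slope_drop < 0 or roughness_sd < 0:
        raise InvalidParameterError("slope_drop and roughness_sd must be >= 0")

    x_min, y_min, x_max, y_max = extent
    ncols = max(1, int(math.ceil((x_max - x_min) / cell_size)))
    nrows = max(1, int(math.ceil((y_max - y_min) / cell_size)))
    origin = (x_min, y_min + nrows * cell_size)

    xs = x_min + (np.arange(ncols) + 0.5) * cell_size
    ys = origin[1] - (np.arange(nrows) + 0.5) * cell_size
    xx, yy = np.meshgrid(xs, ys)

    az = math.radians(slope_azimuth)
    # projection onto the downhill direction; larger t = farther downhill
    t = xx * math.sin(az) + yy * math.cos(az)
    span = t.max() - t.min()
    if span > 0 and slope_drop > 0:
        values = base_elevation + slope_drop * (1.0 - (t - t.min()) / span)
    else:
        values = np.full_like(t, base_elevation + slope_drop)

    if roughness_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((nrows, ncols))
        noise = ndimage.gaussian_filter(noise, sigma=smoothing_length / cell_size, mode="reflect")
        sd = noise.std()
        if sd > 0:
            values = values + noise * (roughness_sd / sd)

    return Raster(values, cell_size, origin)


def logistic_env_effect(
    dtm: Raster,
    low_percentile: float = 10.0,
    high_percentile: float = 40.0,
    floor: float = 0.6,
) -> Callable[[np.ndarray], np.ndarray]:
    """Elevation-linked growth suppression for the low-lying part of a field.

    Returns a monotone non-decreasing logistic ramp of elevation: the
    multiplier approaches ``floor`` at the bottom of the field (waterlogged
    ground) and 1.0 on the high ground, with the transition centered
    between the ``low_percentile``-th and ``high_percentile``-th elevation
    percentiles of the DTM.
    """
    if not 0 < floor <= 1:
        raise InvalidParameterError(f"floor must be in (0, 1], got {floor}")
    valid = dtm.values[dtm.mask()]
    e_lo, e_hi = np.percentile(valid, [low_percentile, high_percentile])
    mid = 0.5 * (e_lo + e_hi)
    scale = max((e_hi - e_lo) / 8.0, 1e-9)

    def env_effect(elevation: np.ndarray) -> np.ndarray:
        elevation = np.asarray(elevation, dtype=float)
        return floor + (1.0 - floor) / (1.0 + np.exp(-(elevation - mid) / scale))

    return env_effect


def default_germplasm_means(
    germplasm_names: Iterable[str],
    low: float = 1.5,
    high: float = 3.0,
    seed: int = 0,
) -> dict[str, float]:
    """Germplasm mean heights drawn uniformly on [low, high] meters."""
    rng = np.random.default_rng(seed)
    names = list(germplasm_names)
    return dict(zip(names, rng.uniform(low, high, size=len(names))))


def generate_true_heights(
    layout: FieldLayout,
    dtm: Raster,
    model: GrowthModel,
    seed: int = 0,
) -> pd.Series:
    """True plant heights: germplasm mean x env multiplier + Gaussian noise.

    Heights are truncated below at zero.  Plants of bare (non-germinated)
    germplasms are omitted from the result.  Raises
    :class:`OutOfExtentError` naming the first plant outside the DTM.
    """
    plants = layout.plants
    keep = ~plants["germplasm"].isin(model.bare_germplasms)
    plants = plants[keep]

    for pid, x, y in plants[["plant_id", "x", "y"]].itertuples(index=False):
        if not dtm.contains(x, y):
            raise OutOfExtentError(f"plant {pid} at ({x:.3f}, {y:.3f}) lies outside the DTM extent")

    elev = np.array([dtm.sample(x, y) for x, y in plants[["x", "y"]].to_numpy()])
    mult = np.ones(len(plants)) if model.env_effect is None else np.asarray(model.env_effect(elev), dtype=float)
    means = plants["germplasm"].map(model.germplasm_means).to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, model.noise_sd, size=len(plants)) if model.noise_sd > 0 else 0.0
    heights = np.maximum(means * mult + noise, 0.0)
    return pd.Series(heights, index=pd.Index(plants["plant_id"], name="plant_id"), name="true_height")


def render_dsm(
    layout: FieldLayout,
    true_heights: pd.Series,
    dtm: Raster,
    canopy_radius: float = 0.10,
    render_noise_sd: float = 0.02,
    seed: int = 0,
) -> Raster:
    """Crop-surface raster: DTM plus a cosine-tapered crown per plant.

    Each plant raises the surface within ``canopy_radius`` of its sowing
    point by ``height * cos(pi*r / (2*radius))``; the apex cell (the cell
    containing the point) carries the full height exactly, so the
    noise-free pipeline recovers true heights bit-exactly.  Overlapping
    crowns combine by maximum.  Seeded Gaussian render noise is added to
    the whole surface afterward.
    """
    if canopy_radius < dtm.cell_size / 2:
        raise InvalidParameterError(
            f"canopy_radius {canopy_radius} must be >= half the cell size {dtm.cell_size / 2}"
        )
    if render_noise_sd < 0:
        raise InvalidParameterError("render_noise_sd must be >= 0")

    canopy = np.zeros(dtm.shape)
    plants = layout.plants.set_index("plant_id")
    nrows, ncols = dtm.shape
    x0, y0 = dtm.origin
    cs = dtm.cell_size
    halo = int(math.ceil(canopy_radius / cs)) + 1

    for pid, h in true_heights.items():
        if h <= 0:
            continue
        x, y = plants.at[pid, "x"], plants.at[pid, "y"]
        arow, acol = dtm.world_to_index(x, y)
        r0, r1 = max(0, arow - halo), min(nrows, arow + halo + 1)
        c0, c1 = max(0, acol - halo), min(ncols, acol + halo + 1)
        cx = x0 + (np.arange(c0, c1) + 0.5) * cs
        cy = y0 - (np.arange(r0, r1) + 0.5) * cs
        dx, dy = np.meshgrid(cx - x, cy - y)
        r = np.hypot(dx, dy)
        crown = np.where(r < canopy_radius, h * np.cos(np.pi * r / (2 * canopy_radius)), 0.0)
        crown[arow - r0, acol - c0] = h  # apex carries the full height exactly
        np.maximum(canopy[r0:r1, c0:c1], crown, out=canopy[r0:r1, c0:c1])

    values = dtm.values + canopy
    if render_noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, render_noise_sd, size=dtm.shape)
    values = np.where(dtm.mask(), values, dtm.nodata)
    return dtm.copy_with(values)


def simulate_field(
    seed: int = 0,
    *,
    layout_kwargs: dict | None = None,
    terrain_kwargs: dict | None = None,
    growth_kwargs: dict | None = None,
    render_kwargs: dict | None = None,
    env_suppression: bool = True,
) -> tuple[FieldLayout, Raster, Raster, pd.Series]:
    """One-call convenience: layout, DTM, DSM and true heights under defaults.

    Sub-seeds for layout, terrain, heights and rendering are derived from
    ``seed`` so the whole field is reproducible from a single integer.
    Returns ``(layout, dtm, dsm, true_heights)``.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    layout = generate_layout(seed=sub[0], **(layout_kwargs or {}))
    dtm = generate_terrain(layout.extent, seed=sub[1], **(terrain_kwargs or {}))

    gk = dict(growth_kwargs or {})
    names = list(layout.plots["germplasm"].unique())
    means = gk.pop("germplasm_means", None) or default_germplasm_means(names, seed=sub[0])
    env = gk.pop("env_effect", logistic_env_effect(dtm) if env_suppression else None)
    model = GrowthModel(germplasm_means=means, env_effect=env, **gk)

    heights = generate_true_heights(layout, dtm, model, seed=sub[2])
    dsm = render_dsm(layout, heights, dtm, seed=sub[3], **(render_kwargs or {}))
    return layout, dtm, dsm, heights
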