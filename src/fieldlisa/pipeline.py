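"""End-to-end orchestration: simulate → extract → LISA → regions → tests.

A :class:`PipelineConfig` carries every stage parameter with defaults
equal to the study's printed protocol values (0.40 m buffer, −1.646
cutoff, 1.75 m distance band, 999 permutations, alpha 0.01).  Two
acquisition dates share the same layout, terrain and germplasm means but
differ in a growth scale and in the noise realizations, mimicking
repeated UAV campaigns over a growing crop; the report includes the
cross-date Jaccard similarity of the delineated cluster regions.
Identical config and seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import heightmap, io, lisa, regions, stats, synthetic
from .errors import FieldLisaError

logger = logging.getLogger(__name__)

__all__ = ["DateConfig", "SyntheticConfig", "PipelineConfig", "run_pipeline"]


@dataclass
class DateConfig:
    """One acquisition date: a name and a growth scale on germplasm means."""

    name: str = "99DAS"
    growth_scale: float = 1.0


@dataclass
class SyntheticConfig:
    n_germplasms: int = 24
    n_reps: int = 3
    plants_per_plot: int = 15
    plant_spacing: float = 0.25
    plot_spacing: float = 0.50
    grid_cols: int = 8
    seed: int = 1
    slope_azimuth: float = 315.0
    slope_drop: float = 2.0
    roughness_sd: float = 0.03
    cell_size: float = 0.05
    noise_sd: float = 0.05
    render_noise_sd: float = 0.02
    canopy_radius: float = 0.10
    env_suppression: bool = True
    bare_germplasms: list = field(default_factory=list)
    dates: list = field(default_factory=lambda: [DateConfig("50DAS", 0.45), DateConfig("99DAS", 1.0)])


@dataclass
class ExtractionConfig:
    buffer_diameter: float = heightmap.DEFAULT_BUFFER_DIAMETER
    cutoff: float = heightmap.DEFAULT_OUTLIER_CUTOFF


@dataclass
class LisaStageConfig:
    threshold: float = lisa.DEFAULT_THRESHOLD
    style: str = "binary"
    n_permutations: int = lisa.DEFAULT_PERMUTATIONS
    alpha: float = lisa.DEFAULT_ALPHA
    seed: int = 7


@dataclass
class RegionsConfig:
    min_fraction: float = regions.DEFAULT_MIN_FRACTION


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    lisa: LisaStageConfig = field(default_factory=LisaStageConfig)
    regions: RegionsConfig = field(default_factory=RegionsConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        syn = dict(d.get("synthetic", {}))
        dates = [DateConfig(**dd) for dd in syn.pop("dates", [])] or None
        syn_cfg = SyntheticConfig(**syn)
        if dates:
            syn_cfg.dates = dates
        return cls(
            synthetic=syn_cfg,
            extraction=ExtractionConfig(**d.get("extraction", {})),
            lisa=LisaStageConfig(**d.get("lisa", {})),
            regions=RegionsConfig(**d.get("regions", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""

    class _ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, FieldLisaError):
                raise FieldLisaError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _ctx()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage on the synthetic field and write all artifacts.

    Returns the run report (also written as ``report.json``): a file
    manifest with checksums and per-date summary statistics (plant and
    outlier counts, cluster-class counts, zone sizes, plot-max validation
    fit, replicate-test summary) plus the cross-date Jaccard indices.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = config.synthetic

    with _stage("simulate"):
        layout = synthetic.generate_layout(
            syn.n_germplasms,
            syn.n_reps,
            syn.plants_per_plot,
            syn.plant_spacing,
            syn.plot_spacing,
            syn.grid_cols,
            seed=syn.seed,
        )
        dtm = synthetic.generate_terrain(
            layout.extent,
            slope_azimuth=syn.slope_azimuth,
            slope_drop=syn.slope_drop,
            roughness_sd=syn.roughness_sd,
            cell_size=syn.cell_size,
            seed=syn.seed + 1,
        )
        names = list(layout.plots["germplasm"].unique())
        means = synthetic.default_germplasm_means(names, seed=syn.seed)
        env = synthetic.logistic_env_effect(dtm) if syn.env_suppression else None
        dtm.write_ascii(out / "dtm.asc")
        io.write_layout_csv(layout, out / "plots.csv", out / "plants.csv")
        io.write_layout_geojson(layout, out / "layout.geojson")

    report: dict = {
        "n_plots": layout.n_plots,
        "n_plants_sown": layout.n_plants,
        "dates": {},
        "config": config.to_dict(),
    }
    date_regions = []

    for di, date in enumerate(syn.dates):
        tag = date.name
        model = synthetic.GrowthModel(
            germplasm_means={g: m * date.growth_scale for g, m in means.items()},
            env_effect=env,
            noise_sd=syn.noise_sd,
            bare_germplasms=frozenset(syn.bare_germplasms),
        )
        with _stage(f"render[{tag}]"):
            heights = synthetic.generate_true_heights(layout, dtm, model, seed=syn.seed + 100 + di)
            dsm = synthetic.render_dsm(
                layout,
                heights,
                dtm,
                canopy_radius=syn.canopy_radius,
                render_noise_sd=syn.render_noise_sd,
                seed=syn.seed + 200 + di,
            )
            dsm.write_ascii(out / f"dsm_{tag}.asc")

        with _stage(f"extract[{tag}]"):
            chm = heightmap.compute_height_map(dsm, dtm, clamp_negative=True)
            plants = layout.plants[~layout.plants["germplasm"].isin(model.bare_germplasms)]
            table = heightmap.extract_buffer_max(chm, plants, config.extraction.buffer_diameter)
            table = heightmap.normalize_heights(table)
            table = heightmap.filter_outliers(table, config.extraction.cutoff)
            table["true_height"] = table["plant_id"].map(heights)
            table.to_csv(out / f"plants_{tag}.csv", index=False)
            plot_true = table.groupby("plot_id")["true_height"].max()
            plot_est = table.groupby("plot_id")["height_est"].max()
            validation = heightmap.validate_heights(plot_est.to_numpy(), plot_true.to_numpy())

        with _stage(f"lisa[{tag}]"):
            clean = heightmap.non_outliers(table)
            lisa_table = lisa.run_lisa(
                clean,
                threshold=config.lisa.threshold,
                style=config.lisa.style,
                n_permutations=config.lisa.n_permutations,
                alpha=config.lisa.alpha,
                seed=config.lisa.seed + di,
            )
            lisa_table.to_csv(out / f"lisa_{tag}.csv", index=False)
            io.write_lisa_geojson(lisa_table, out / f"lisa_{tag}.geojson")

        with _stage(f"regions[{tag}]"):
            low, high = regions.delineate_regions(lisa_table, layout, config.regions.min_fraction)
            zones = regions.assign_zones(low, high, layout)
            io.write_regions_geojson(low, high, out / f"regions_{tag}.geojson")
            io.write_layout_geojson(layout, out / f"zones_{tag}.geojson", zones=zones)
            date_regions.append((low, high))

        with _stage(f"tests[{tag}]"):
            results = stats.germplasm_similarity(lisa_table)
            rows = [
                {"germplasm": r.germplasm, "H": r.H, "df": r.df, "p_value": r.p_value, "stars": r.stars}
                for r in results
            ]
            pd.DataFrame(rows).to_csv(out / f"tests_{tag}.csv", index=False)

        counts = lisa_table["class"].value_counts().to_dict()
        zone_sizes = {z: sum(1 for v in zones.values() if v == z) for z in ("A", "B", "C")}
        report["dates"][tag] = {
            "n_plants_extracted": int(len(table)),
            "n_outliers": int(table["outlier"].sum()),
            "class_counts": {k: int(v) for k, v in counts.items()},
            "zone_sizes": zone_sizes,
            "validation": asdict(validation),
            "n_germplasms_tested": len(results),
            "n_replicate_differences": sum(1 for r in results if r.stars),
        }

    if len(date_regions) >= 2:
        jac = {}
        for (l1, h1), (l2, h2), d1, d2 in zip(date_regions, date_regions[1:], syn.dates, syn.dates[1:]):
            key = f"{d1.name}_vs_{d2.name}"
            jac[key] = {
                "low_growth": regions.compare_dates(l1, l2),
                "high_growth": regions.compare_dates(h1, h2),
            }
        report["jaccard"] = jac

    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "report.json"}
    report["manifest"] = manifest
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
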