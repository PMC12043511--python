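"""Configuration, orchestration, and standard-format I/O for full runs.

A single YAML config drives the whole pipeline: simulate -> cwm ->
covariates -> train -> predict -> diversity -> compare -> sampling-needs.
Stages can be toggled; a toggled-on stage whose inputs are neither in memory
nor on disk fails with a :class:`DependencyError` naming the missing
artefact. Every run writes a manifest with the config hash, per-file SHA-256
digests and wall-clock times, so reruns with identical config and seeds can
be verified byte-for-byte on the deterministic stages.

Formats: tables are CSV, stem maps are GeoJSON (point features plus plot
rectangles), rasters are ESRI ASCII grids (text; origin and cell size in the
header).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import cwm_scaling as cwm_mod
from . import priority_comparison as prio
from . import trait_models as tm
from . import trait_space as ts
from .grids import PixelGrid, read_ascii_grid, write_ascii_grid
from .synthetic_landscape import (
    REGION_NAMES,
    TRAITS,
    PlotInventory,
    SimulationConfig,
    TreeRecord,
    generate_landscape,
)

STAGES = ("simulate", "cwm", "covariates", "train", "predict",
          "diversity", "compare", "sampling_needs")


class DependencyError(RuntimeError):
    """A stage's upstream artefact is missing."""


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "canopyscale_run"
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    simulation: dict = field(default_factory=dict)       # SimulationConfig overrides
    cwm_threshold: float = 0.70
    coverage_basis: str = "canopy-area"
    traits: list[str] = field(default_factory=lambda: list(TRAITS))
    texture_window: int = 9
    texture_levels: int = 32
    mcwd_multi_year: str = "mean"
    climate_resampling: str = "nearest"
    tree_grid: list[int] = field(default_factory=lambda: [500, 1000, 1500])
    mtry_grid: list[int] = field(default_factory=lambda: list(range(1, 11)))
    max_pixels_per_plot: int | None = 20
    tuning_max_rows: int | None = 800
    rmse_rel_tol: float = 0.005
    forest_cover_threshold: float = 25.0
    tpd_grid_size: int = 150
    tpd_trim_level: float = 0.99
    tpd_max_points: int | None = 20000
    compare_fractions: list[float] = field(default_factory=lambda: [1.0, 0.1, 0.01])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        unknown_stages = set(cfg.stages) - set(STAGES)
        if unknown_stages:
            raise ConfigError(f"unknown stages: {sorted(unknown_stages)}")
        stages = {s: True for s in STAGES}
        stages.update(cfg.stages)
        cfg.stages = stages
        sim_known = set(SimulationConfig.__dataclass_fields__)
        sim_unknown = set(cfg.simulation) - sim_known
        if sim_unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(sim_unknown)}")
        return cfg

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.simulation)
        params.setdefault("seed", self.seed)
        return SimulationConfig(**params)

    def canonical(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(self.__dict__, sort_keys=True, default=default)


# ---------------------------------------------------------------------------
# file I/O


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"species", "genus"} - set(table.columns)
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {sorted(missing)}")
    return table


def write_inventories_geojson(inventories: list[PlotInventory], path: str | Path) -> None:
    """Stem points (landscape coordinates) plus plot-rectangle features."""
    features = []
    for inv in inventories:
        x0, y0, s = inv.origin_x, inv.origin_y, inv.side
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[x0, y0], [x0 + s, y0], [x0 + s, y0 + s], [x0, y0 + s], [x0, y0]]],
                },
                "properties": {"kind": "plot", "plot_id": inv.plot_id, "side": s},
            }
        )
        for t in inv.trees:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [x0 + t.x, y0 + t.y]},
                    "properties": {
                        "kind": "stem", "plot_id": t.plot_id, "dbh": t.dbh,
                        "species": t.species, "genus": t.genus,
                    },
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_inventories_geojson(path: str | Path) -> list[PlotInventory]:
    with open(path) as fh:
        try:
            collection = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: malformed GeoJSON ({exc})") from exc
    plots: dict[str, PlotInventory] = {}
    stems: list[dict] = []
    for i, feat in enumerate(collection.get("features", [])):
        props = feat.get("properties", {})
        kind = props.get("kind")
        if kind == "plot":
            ring = feat["geometry"]["coordinates"][0]
            xs = [p[0] for p in ring]
            ys = [p[1] for p in ring]
            plots[props["plot_id"]] = PlotInventory(
                plot_id=props["plot_id"], origin_x=min(xs), origin_y=min(ys),
                side=props["side"], trees=[],
            )
        elif kind == "stem":
            stems.append(feat)
        else:
            raise ConfigError(f"{path}: feature {i} has unknown kind {kind!r}")
    for feat in stems:
        props = feat["properties"]
        pid = props["plot_id"]
        if pid not in plots:
            raise ConfigError(f"{path}: stem references unknown plot {pid!r}")
        inv = plots[pid]
        x, y = feat["geometry"]["coordinates"]
        inv.trees.append(
            TreeRecord(
                plot_id=pid, x=x - inv.origin_x, y=y - inv.origin_y,
                dbh=props["dbh"], species=props["species"], genus=props["genus"],
            )
        )
    return list(plots.values())


def write_inventories_csv(inventories: list[PlotInventory], path: str | Path) -> None:
    frames = [inv.to_frame().assign(origin_x=inv.origin_x, origin_y=inv.origin_y,
                                    side=inv.side) for inv in inventories]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict[str, dict]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the toggled-on stages in dependency order; write the manifest."""
    from . import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    manifest_stages: dict[str, dict] = {}

    def record(stage: str, files: list[Path], t0: float, params: dict | None = None) -> None:
        manifest_stages[stage] = {
            "outputs": {str(f.relative_to(out)): sha256_file(f) for f in files},
            "wall_seconds": round(time.time() - t0, 3),
            **({"parameters": params} if params else {}),
        }

    if config.stages["simulate"]:
        t0 = time.time()
        land = generate_landscape(config.simulation_config())
        state["land"] = land
        files = []
        f = out / "trait_table.csv"
        write_trait_table(land.field_table, f)
        files.append(f)
        f = out / "trait_table_truth.csv"
        write_trait_table(land.pool, f)
        files.append(f)
        f = out / "inventories.geojson"
        write_inventories_geojson(land.inventories, f)
        files.append(f)
        f = out / "inventories.csv"
        write_inventories_csv(land.inventories, f)
        files.append(f)
        for trait in config.traits:
            f = out / f"truth_cwm_{trait}.asc"
            write_ascii_grid(f, land.truth.cwm_surface(trait), land.grid)
            files.append(f)
        record("simulate", files, t0, {"seed": config.seed})

    def need_land():
        if "land" not in state:
            raise DependencyError("stage requires the 'simulate' stage output (landscape)")
        return state["land"]

    if config.stages["cwm"]:
        t0 = time.time()
        land = need_land()
        rasters, report, plot_layer = cwm_mod.rasterize_landscape(
            land.inventories, land.field_table, land.grid, config.traits,
            crown_a=land.config.crown_a, crown_b=land.config.crown_b,
            threshold=config.cwm_threshold, coverage_basis=config.coverage_basis,
        )
        state["cwm"] = rasters
        state["plot_layer"] = plot_layer
        files = []
        for trait, r in rasters.items():
            f = out / f"cwm_{trait}.asc"
            write_ascii_grid(f, np.where(r.retained, r.values, np.nan), land.grid)
            files.append(f)
            f = out / f"coverage_{trait}.asc"
            write_ascii_grid(f, r.coverage, land.grid)
            files.append(f)
        f = out / "retained_pixels.csv"
        report.to_csv(f, index=False)
        files.append(f)
        record("cwm", files, t0, {
            "threshold": config.cwm_threshold, "coverage_basis": config.coverage_basis,
        })

    if config.stages["covariates"]:
        t0 = time.time()
        land = need_land()
        stack = cov.build_stack(
            land.reflectance, land.grid, climate=land.climate,
            environment=land.environment,
            texture_window=config.texture_window, texture_levels=config.texture_levels,
            climate_resampling=config.climate_resampling,
            mcwd_multi_year=config.mcwd_multi_year,
        )
        state["stack"] = stack
        files = []
        for name in stack.names():
            f = out / f"covariate_{name}.asc"
            write_ascii_grid(f, stack[name], land.grid)
            files.append(f)
        record("covariates", files, t0, {
            "texture_window": config.texture_window,
            "mcwd_multi_year": config.mcwd_multi_year,
        })

    def need_table():
        if "table" in state:
            return state["table"]
        if "cwm" not in state or "stack" not in state:
            raise DependencyError("training needs 'cwm' and 'covariates' stage outputs")
        state["table"] = tm.build_training_table(
            state["cwm"], state["stack"], state["plot_layer"],
            max_pixels_per_plot=config.max_pixels_per_plot, seed=config.seed,
        )
        return state["table"]

    if config.stages["train"]:
        t0 = time.time()
        table = need_table()
        specs, metrics = {}, []
        for trait in config.traits:
            spec = tm.tune_rf(
                table, f"cwm_{trait}", tuple(config.tree_grid), tuple(config.mtry_grid),
                seed=config.seed, rmse_rel_tol=config.rmse_rel_tol,
                max_rows=config.tuning_max_rows,
            )
            cvres = tm.evaluate_cv(table, f"cwm_{trait}", spec)
            specs[trait] = spec
            metrics.append({
                "trait": trait, "n_trees": spec.n_trees, "mtry": spec.mtry,
                "r2": cvres.r2, "rmse": cvres.rmse, "n_pixels": len(cvres.predictions),
            })
        state["specs"] = specs
        f = out / "cv_metrics.csv"
        pd.DataFrame(metrics).to_csv(f, index=False)
        record("train", [f], t0, {"tree_grid": config.tree_grid, "mtry_grid": config.mtry_grid})

    if config.stages["predict"]:
        t0 = time.time()
        table = need_table()
        land = need_land()
        if "specs" not in state:
            raise DependencyError("'predict' needs the 'train' stage output (tuned specs)")
        maps, importances = {}, []
        for trait in config.traits:
            trait_map, imp = tm.fit_predict_uncertainty(
                table, f"cwm_{trait}", state["specs"][trait], state["stack"]
            )
            maps[trait] = trait_map
            imp.insert(0, "trait", trait)
            importances.append(imp)
        maps = tm.apply_forest_mask(
            maps, land.environment["forest_cover"], config.forest_cover_threshold
        )
        state["maps"] = maps
        files = []
        for trait, m in maps.items():
            f = out / f"predicted_{trait}.asc"
            write_ascii_grid(f, m.prediction, land.grid)
            files.append(f)
            f = out / f"se_{trait}.asc"
            write_ascii_grid(f, m.se, land.grid)
            files.append(f)
        f = out / "importance.csv"
        pd.concat(importances, ignore_index=True).to_csv(f, index=False)
        files.append(f)
        record("predict", files, t0, {
            "se_estimator": "infinitesimal-jackknife",
            "forest_cover_threshold": config.forest_cover_threshold,
        })

    def need_maps():
        if "maps" in state:
            return state["maps"], need_land().grid, need_land().regions
        # fall back to prediction rasters on disk
        maps = {}
        grid = None
        for trait in config.traits:
            fp = out / f"predicted_{trait}.asc"
            fs = out / f"se_{trait}.asc"
            if not fp.exists() or not fs.exists():
                raise DependencyError(
                    f"'{fp.name}' not found: run the 'predict' stage first"
                )
            pred, grid = read_ascii_grid(fp)
            se, _ = read_ascii_grid(fs)
            maps[trait] = tm.TraitMap(prediction=pred, se=se, forest_mask_applied=True)
        from .synthetic_landscape import region_labels

        return maps, grid, region_labels(grid)

    if config.stages["diversity"]:
        t0 = time.time()
        maps, grid, regions = need_maps()
        X = np.stack([maps[t].prediction.ravel() for t in config.traits], axis=1)
        pca = ts.fit_pca(X, trait_names=config.traits)
        ok = np.isfinite(X).all(axis=1)
        tpd = ts.estimate_tpd(
            pca.scores[:, :2], grid_size=config.tpd_grid_size,
            trim_level=config.tpd_trim_level, max_points=config.tpd_max_points,
            seed=config.seed,
        )
        region_flat = regions.ravel()[ok]
        scores_by_region = {
            REGION_NAMES[k]: pca.scores[region_flat == k, :2] for k in range(3)
        }
        regional = ts.regional_tpd(scores_by_region, tpd)
        metrics = [ts.DiversityMetrics("global", ts.frich(tpd), ts.fdiv(tpd))]
        metrics += ts.diversity_metrics(regional)
        state["pca"], state["tpd"], state["diversity"] = pca, tpd, metrics
        files = []
        f = out / "pca_loadings.csv"
        pd.DataFrame(
            pca.loadings, columns=pca.trait_names,
            index=[f"PC{i+1}" for i in range(len(pca.loadings))],
        ).to_csv(f)
        files.append(f)
        f = out / "pca_variance.csv"
        pd.DataFrame({
            "component": [f"PC{i+1}" for i in range(len(pca.explained_variance_ratio))],
            "variance_fraction": pca.explained_variance_ratio,
        }).to_csv(f, index=False)
        files.append(f)
        f = out / "diversity_metrics.csv"
        pd.DataFrame([m.__dict__ for m in metrics]).to_csv(f, index=False)
        files.append(f)
        record("diversity", files, t0, {
            "tpd_grid_size": config.tpd_grid_size, "trim_level": config.tpd_trim_level,
            "bandwidth": list(tpd.bandwidth),
        })

    if config.stages["compare"]:
        t0 = time.time()
        maps, grid, regions = need_maps()
        masks = {REGION_NAMES[k]: regions == k for k in range(3)}
        results = prio.region_compare(
            {t: maps[t].prediction for t in config.traits}, masks,
            fractions=tuple(config.compare_fractions), seed=config.seed,
        )
        f = out / "region_comparisons.csv"
        prio.comparisons_frame(results).to_csv(f, index=False)
        record("compare", [f], t0, {"fractions": config.compare_fractions})

    if config.stages["sampling_needs"]:
        t0 = time.time()
        maps, grid, _ = need_maps()
        needs = prio.sampling_needs({t: maps[t].se for t in config.traits})
        files = []
        f = out / "sampling_needs_mean_se.asc"
        write_ascii_grid(f, needs.mean_standardized_se, grid)
        files.append(f)
        f = out / "sampling_needs_class.asc"
        write_ascii_grid(f, np.where(needs.classes >= 0, needs.classes.astype(float), np.nan), grid)
        files.append(f)
        f = out / "sampling_needs_classes.csv"
        pd.DataFrame({
            "class": prio.CLASS_NAMES,
            "pixels": [int((needs.classes == k).sum()) for k in range(3)],
            "cutpoint_low": [np.nan, needs.cutpoints[0], needs.cutpoints[1]],
        }).to_csv(f, index=False)
        files.append(f)
        record("sampling_needs", files, t0, {"cutpoints": list(needs.cutpoints)})

    manifest = RunManifest(
        config_hash=hashlib.sha256(config.canonical().encode()).hexdigest(),
        version=__version__,
        stages=manifest_stages,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
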