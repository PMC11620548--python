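"""End-to-end orchestration: scenes -> indices -> composites -> classes
-> anomaly -> change -> vectors -> accuracy, driven by one config.

Every inter-stage product is written to the output directory in the
declared file formats (float32 TIFF composites, uint8 class and change
maps, GeoJSON polygons, CSV tables) and the run ends with a JSON
manifest recording the seed, the config hash, per-stage product paths
and the summary numbers.  Identical config + seed gives identical
products.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from . import __version__
from .grids import ClassRaster, GridGeoref, write_raster
from .indices import compute_cmri, NDWI_VARIANTS
from .compositing import (annual_max, bimonthly_max, filter_scenes,
                          PERIODS_PER_YEAR)
from .classification import (DEFAULT_MANGROVE_THRESHOLD, DEFAULT_N_TREES,
                             classify, extract_mangrove_mask,
                             train_species_classifier)
from .change import (DEFAULT_PERSISTENCE, accumulate_anomaly, call_change,
                     change_area_summary, LOSS, GAIN)
from .vectorize import (DEFAULT_MIN_MAPPABLE_HA, filter_min_area,
                        raster_to_polygons, zonal_area_table)
from .accuracy import accuracy_metrics, build_confusion, kappa, report_text
from . import synthetic

__all__ = ["RunConfig", "run_pipeline", "generate_fixture"]

log = logging.getLogger(__name__)

_PAPER_DEFAULTS = {"cloud_threshold": 0.10, "n_trees": DEFAULT_N_TREES,
                   "min_mappable_ha": DEFAULT_MIN_MAPPABLE_HA,
                   "ndwi_variant": "swir"}


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its published default.

    ``scene_dir`` may be None, in which case the synthetic block is used
    to generate the input archive.
    """

    baseline_year: int = 2019
    final_year: int = 2020
    cloud_threshold: float = 0.10        # scene-level filter, strict <
    ndwi_variant: str = "swir"
    mangrove_threshold: float = DEFAULT_MANGROVE_THRESHOLD
    extraction_method: str = "fixed"     # or "otsu"
    n_trees: int = DEFAULT_N_TREES
    persistence_threshold: int = DEFAULT_PERSISTENCE
    min_mappable_ha: float = DEFAULT_MIN_MAPPABLE_HA
    seed: int = 0
    out_dir: str = "cmri_run"
    scene_dir: str = None
    zones_file: str = None
    validation_file: str = None
    train_file: str = None
    # synthetic block
    shape: tuple = (256, 256)
    scenes_per_period: int = 5
    cloud_fraction_range: tuple = (0.0, 0.12)
    mangrove_sd: float = 0.05
    landscape_seed: int = None           # defaults to seed
    n_loss_patches: int = 2
    n_gain_patches: int = 1
    change_area_px: int = 60
    n_train_per_class: int = 500
    n_validation_per_class: int = 240

    def __post_init__(self):
        if self.baseline_year >= self.final_year:
            raise ValueError("baseline year must precede the final year")
        if not 0 < self.cloud_threshold <= 1:
            raise ValueError("cloud threshold must be in (0, 1]")
        if self.ndwi_variant not in NDWI_VARIANTS:
            raise ValueError(f"ndwi_variant must be one of {NDWI_VARIANTS}")
        if not -2 <= self.mangrove_threshold <= 2:
            raise ValueError("mangrove threshold outside [-2, 2]")
        if self.persistence_threshold < 1:
            raise ValueError("persistence threshold must be >= 1")
        if self.min_mappable_ha < 0:
            raise ValueError("minimum mappable area must be >= 0")
        self.shape = tuple(self.shape)
        self.cloud_fraction_range = tuple(self.cloud_fraction_range)
        for key, default in _PAPER_DEFAULTS.items():
            if getattr(self, key) != default:
                log.warning("config overrides the published default "
                            "%s=%s with %s", key, default, getattr(self, key))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh,
                           default_flow_style=None, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def generate_fixture(config: RunConfig):
    """Build the synthetic study area: truth, scenes, zones, validation.

    Returns (truth, scenes, zones, validation_set).  The landscape and
    its change events are controlled by ``landscape_seed`` so clouds can
    vary (via ``seed``) over a fixed class geography.
    """
    lseed = config.seed if config.landscape_seed is None \
        else config.landscape_seed
    truth = synthetic.build_landscape(seed=lseed, shape=config.shape)
    truth = synthetic.inject_change(
        truth, n_loss=config.n_loss_patches, n_gain=config.n_gain_patches,
        area_px=config.change_area_px, event_year=config.final_year,
        seed=lseed + 1)
    profiles = synthetic.default_profiles(mangrove_sd=config.mangrove_sd)
    years = list(range(config.baseline_year, config.final_year + 1))
    scenes = synthetic.render_scenes(
        truth, profiles, years=years,
        scenes_per_period=config.scenes_per_period,
        cloud_fraction_range=config.cloud_fraction_range, seed=config.seed)
    # two equal west/east zones for the area accounting
    h, w = config.shape
    px = truth.pixel_size
    g = truth.georef
    x0, x1 = g.x0, g.x0 + w * px
    xm = g.x0 + (w // 2) * px
    y0, y1 = g.y0 - h * px, g.y0
    zones = [("west", shapely.box(x0, y0, xm, y1)),
             ("east", shapely.box(xm, y0, x1, y1))]
    validation = synthetic.sample_validation_points(
        truth, date=_dt.date(config.final_year, 12, 31),
        n_per_class=config.n_validation_per_class, seed=config.seed + 2)
    return truth, scenes, zones, validation


def _truth_training_samples(truth, series, year, n_per_class, seed):
    """Truth-derived bimonthly-CMRI training vectors for the species RF."""
    rng = np.random.default_rng(seed)
    labels = truth.labels_at(_dt.date(year, 12, 31))
    cube = np.stack([r.values for r in series.year_composites(year)],
                    axis=-1)
    valid = np.stack([r.valid for r in series.year_composites(year)],
                     axis=-1).all(axis=-1)
    X, y = [], []
    for lab in synthetic.MANGROVE_LABELS:
        rows, cols = np.nonzero((labels == lab) & valid)
        if rows.size == 0:
            raise ValueError(f"no valid training pixels for class {lab}")
        k = min(n_per_class, rows.size)
        pick = rng.choice(rows.size, size=k, replace=False)
        X.append(cube[rows[pick], cols[pick]])
        y.append(np.full(k, synthetic._SCHEME[lab]))
    return np.concatenate(X), np.concatenate(y)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config.digest(), "products": {},
                "summary": {}}
    config.to_yaml(out / "config.yaml")

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                from exc

    # ---- input archive -------------------------------------------------
    if config.scene_dir is None:
        truth, scenes, zones, validation = _stage(
            "generate_fixture", generate_fixture, config)
        manifest["summary"]["truth"] = {
            "mangrove_area_ha_baseline": truth.mangrove_area_ha(
                _dt.date(config.baseline_year, 12, 31)),
            "mangrove_area_ha_final": truth.mangrove_area_ha(
                _dt.date(config.final_year, 12, 31)),
            "injected_loss_px": sum(ev.area_px for ev in truth.change_events
                                    if ev.kind == "loss"),
            "injected_gain_px": sum(ev.area_px for ev in truth.change_events
                                    if ev.kind == "gain"),
        }
        write_raster(out / "truth_labels.tif",
                     truth.label_grid.astype(np.uint8), truth.georef,
                     kind="truth")
        truth.events_to_geojson(out / "change_events_truth.geojson")
    else:
        from .grids import SceneStack
        scene_paths = sorted(Path(config.scene_dir).glob("*.tif"))
        scenes = [SceneStack.from_file(p) for p in scene_paths]
        truth = None
        zones = _load_zones(config.zones_file) if config.zones_file else []
        validation = None
        if config.validation_file:
            from .accuracy import ValidationSet
            validation = ValidationSet.from_csv(config.validation_file)

    # ---- filter, index, composite --------------------------------------
    kept = _stage("filter_scenes", filter_scenes, scenes,
                  config.cloud_threshold)
    log.info("scene filter: %d of %d scenes below the %.0f%% cloud cover",
             len(kept), len(scenes), 100 * config.cloud_threshold)
    dated = [(s.date, _stage("compute_cmri", compute_cmri, s,
                             config.ndwi_variant)) for s in kept]
    years = list(range(config.baseline_year, config.final_year + 1))
    series = _stage("bimonthly_max", bimonthly_max, dated, years)
    for raster, (yr, p), cov in zip(series.composites, series.period_labels,
                                    series.coverage):
        write_raster(out / f"cmri_{yr}_p{p}.tif",
                     raster.values.astype(np.float32), series.georef,
                     kind="composite", nodata="nan")
        write_raster(out / f"cmri_{yr}_p{p}_n.tif", cov.astype(np.int32),
                     series.georef, kind="coverage")

    # ---- extraction and classification ---------------------------------
    masks, annual_maps, period_maps = {}, {}, []
    amax = {y: _stage("annual_max", annual_max, series, y) for y in years}
    for y in years:
        masks[y] = _stage("extract_mangrove_mask", extract_mangrove_mask,
                          amax[y], config.mangrove_threshold,
                          config.extraction_method)
    if truth is not None:
        X, ylab = _truth_training_samples(truth, series,
                                          config.baseline_year,
                                          config.n_train_per_class,
                                          config.seed + 3)
    else:
        X, ylab = _load_training(config.train_file, series,
                                 config.baseline_year)
    model = _stage("train_species_classifier", train_species_classifier,
                   X, ylab, config.n_trees, config.seed)
    for y in years:
        periods, annual = _stage("classify", classify, model, series,
                                 masks[y], y, config.mangrove_threshold)
        annual_maps[y] = annual
        period_maps.extend(periods)
        write_raster(out / f"classes_{y}_annual.tif", annual.labels,
                     series.georef, kind="classes", nodata=255)

    # ---- change detection ----------------------------------------------
    anomaly = _stage("accumulate_anomaly", accumulate_anomaly, period_maps,
                     config.baseline_year)
    change = _stage("call_change", call_change, anomaly,
                    config.persistence_threshold)
    write_raster(out / "anomaly.tif", anomaly.accumulated.astype(np.float32),
                 series.georef, kind="anomaly")
    write_raster(out / "change.tif", change.labels, series.georef,
                 kind="change")
    loss_px = int(((change.labels == LOSS) & change.valid).sum())
    gain_px = int(((change.labels == GAIN) & change.valid).sum())
    ha = series.georef.pixel_size ** 2 / 10000.0
    manifest["summary"]["change"] = {"loss_ha": loss_px * ha,
                                     "gain_ha": gain_px * ha}

    # ---- vectorization and area accounting ------------------------------
    final_map = annual_maps[config.final_year]
    polys = _stage("raster_to_polygons", raster_to_polygons, final_map)
    polys = _stage("filter_min_area", filter_min_area, polys,
                   config.min_mappable_ha)
    polys.to_geojson(out / f"mangrove_{config.final_year}.geojson")
    if zones:
        area_table = _stage("zonal_area_table", zonal_area_table, polys,
                            zones)
        area_table.to_csv(out / "area_by_zone.csv", index=False)
        change_table = _stage("change_area_summary", change_area_summary,
                              change, zones)
        change_table.to_csv(out / "change_by_zone.csv", index=False)
        manifest["summary"]["area_by_zone"] = area_table.to_dict("records")
        manifest["summary"]["change_by_zone"] = \
            change_table.to_dict("records")
    manifest["summary"]["mapped"] = {
        str(y): {"mangrove_ha": float(masks[y].sum()) * ha} for y in years}
    manifest["summary"]["mapped_post_mmu_ha"] = \
        float(polys.table["area_ha"].sum())

    # ---- accuracy assessment --------------------------------------------
    if validation is not None:
        cm = _stage("build_confusion", build_confusion, final_map,
                    validation)
        metrics = accuracy_metrics(cm)
        metrics.to_csv(out / "accuracy_metrics.csv", index=False)
        (out / "error_matrix.txt").write_text(report_text(cm))
        validation.to_csv(out / "validation_points.csv")
        oa = float(metrics.loc[metrics.metric == "overall_accuracy",
                               "pct"].iloc[0])
        manifest["summary"]["accuracy"] = {
            "overall_accuracy_pct": oa,
            "kappa": round(float(kappa(cm)), 4),
            "n": cm.n, "excluded": cm.excluded,
            "counts": cm.counts.tolist()}

    manifest["products"] = sorted({p.name for p in out.iterdir()} |
                                  {"manifest.json"})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _load_zones(path):
    with open(path) as fh:
        gj = json.load(fh)
    zones = []
    for feat in gj["features"]:
        zid = feat.get("properties", {}).get("zone",
                                             str(len(zones)))
        zones.append((zid, shapely.geometry.shape(feat["geometry"])))
    return zones


def _load_training(path, series, year):
    """Rasterize labelled training points (CSV x,y,label) to feature rows."""
    if path is None:
        raise ValueError("no training samples: supply train_file or use "
                         "the synthetic fixture")
    pts = pd.read_csv(path)
    rasters = series.year_composites(year)
    cube = np.stack([r.values for r in rasters], axis=-1)
    valid = np.stack([r.valid for r in rasters], axis=-1).all(axis=-1)
    rows, cols = series.georef.world_to_pixel(pts["x"].to_numpy(),
                                              pts["y"].to_numpy())
    h, w = valid.shape
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    ok[ok] &= valid[rows[ok], cols[ok]]
    if not ok.any():
        raise ValueError("no training point falls on valid composites")
    return cube[rows[ok], cols[ok]], pts["label"].to_numpy()[ok]
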