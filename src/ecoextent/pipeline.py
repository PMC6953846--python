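"""End-to-end pipeline: composite -> indices -> sequential classification
-> flood merge -> accuracy report.

Two entry points: :func:`run_on_landscape` drives the whole chain
in-memory from a synthetic landscape (the test and benchmark path), and
:func:`run_from_files` does the same from rasters/vectors on disk as
written by the ``simulate`` CLI subcommand.  Every stage failure aborts
with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import accuracy as acc
from .classify import LandCoverMap, SequentialLandCoverClassifier
from .compositing import Composite, SceneStack, mask_clouds, median_composite, select_window
from .config import PipelineConfig
from .geo import RasterGrid, read_geojson, read_raster, write_raster
from .indices import IndexStack, compute_stack
from .sar import FloodDetectionConfig, FloodMap, map_flooded_forests
from .synthetic import (Landscape, SARSpec, SceneCollectionSpec, SpectralLibrary,
                        default_library, generate_sar_pair, generate_scenes,
                        generate_truth_map, sample_training)

log = logging.getLogger("ecoextent")


@dataclass
class PipelineResult:
    lc_map: LandCoverMap
    composite: Composite
    index_stack: IndexStack
    flood_map: FloodMap | None
    samples: pd.DataFrame
    error_matrix: acc.ErrorMatrix
    stats: dict
    areas: acc.AreaSummary
    overall_vs_truth: float | None = None


class StageError(RuntimeError):
    pass


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_on_landscape(config: PipelineConfig, landscape: Landscape,
                     library: SpectralLibrary | None = None,
                     scene_spec: SceneCollectionSpec | None = None,
                     sar_spec: SARSpec | None = None,
                     flood_config: FloodDetectionConfig | None = None,
                     n_training_per_class: int = 600) -> PipelineResult:
    """Full run against a synthetic landscape, validated against its own
    truth raster."""
    library = library or default_library()
    scene_spec = scene_spec or SceneCollectionSpec(seed=config.seed)
    scenes = _stage("simulate", generate_scenes, landscape, library, scene_spec)
    flood_map = None
    if any(s.sar_derived for s in config.ordered_specs()):
        sar_spec = sar_spec or SARSpec(seed=config.seed)
        hh_dry, hh_rainy, dem = _stage("sar-simulate", generate_sar_pair,
                                       landscape, sar_spec)
        flood_map = _stage("flood", map_flooded_forests, hh_dry, hh_rainy,
                           dem, flood_config)
    training = sample_training(landscape, n_training_per_class, seed=config.seed)
    return run_core(config, scenes, training, landscape.ancillary,
                    landscape.dem, flood_map=flood_map,
                    truth=landscape.truth.values)


def run_core(config: PipelineConfig, scenes, training: pd.DataFrame,
             ancillary, dem: RasterGrid, flood_map: FloodMap | None = None,
             truth: np.ndarray | None = None) -> PipelineResult:
    """The shared pipeline body once scenes and training data exist."""
    masked = [_stage("cloud-mask", mask_clouds, s, config.qa) for s in scenes]
    window = _stage("window", select_window, masked, config.window)
    composite = _stage("composite", median_composite, window)
    stack = _stage("indices", compute_stack, composite.bands,
                   eps=config.index_eps)
    clf = SequentialLandCoverClassifier(
        legend=config.legend, class_specs=config.class_specs,
        classifier_config=config.classifier)
    _stage("classify", clf.fit, composite, stack, training,
           ancillary=ancillary, dem=dem, flood_map=flood_map)
    lc_map = clf.map_

    samples = _stage("validate", acc.stratified_sample, lc_map,
                     config.n_validation_per_class, seed=config.seed)
    overall_vs_truth = None
    if truth is not None:
        samples = acc.label_from_reference(samples, truth)
        overall_vs_truth = acc.overall_map_accuracy(lc_map, truth)
    else:
        samples = samples.assign(ref_label=samples["map_label"])
    labels = sorted(set(samples.ref_label) | set(samples.map_label))
    matrix = _stage("error-matrix", acc.build_error_matrix, samples, labels)
    stats = _stage("accuracy", acc.accuracy_stats, matrix)
    areas = _stage("areas", acc.class_areas, lc_map)
    return PipelineResult(lc_map, composite, stack, flood_map, samples,
                          matrix, stats, areas, overall_vs_truth)


# ---------------------------------------------------------------------------
# File-based entry (CLI)
# ---------------------------------------------------------------------------

def simulate_to_dir(outdir, config: PipelineConfig,
                    scene_spec: SceneCollectionSpec | None = None) -> Path:
    """Write a synthetic landscape, scene collection (+ SAR for profiles
    with flood classes), ancillary layers, training data and manifest."""
    from .geo import write_geojson
    from .synthetic import training_polygons

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene_spec = scene_spec or SceneCollectionSpec(seed=config.seed)
    landscape = generate_truth_map(scene_spec, config.profile)
    library = default_library()
    scenes = generate_scenes(landscape, library, scene_spec)

    write_raster(landscape.truth, outdir / "truth.tif",
                 colormap=config.legend.colormap())
    write_raster(landscape.dem, outdir / "dem.tif")
    rows = []
    for i, s in enumerate(scenes):
        bp, qp = outdir / f"scene_{i:02d}.tif", outdir / f"scene_{i:02d}_qa.tif"
        write_raster(s.bands, bp)
        write_raster(s.qa, qp)
        rows.append({"bands": bp.name, "qa": qp.name, "date": s.date,
                     "season": s.season})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    for name, layer in landscape.ancillary.items():
        write_geojson(layer, outdir / f"{name}.geojson")
    training = sample_training(landscape, seed=config.seed)
    training.to_csv(outdir / "training.csv", index=False)
    from .geo import write_geojson as _wg
    _wg(training_polygons(landscape, training.groupby("class_name").head(50)),
        outdir / "training_polygons.geojson")
    if any(s.sar_derived for s in config.ordered_specs()):
        hh_dry, hh_rainy, _ = generate_sar_pair(landscape, SARSpec(seed=config.seed))
        write_raster(hh_dry, outdir / "hh_dry.tif")
        write_raster(hh_rainy, outdir / "hh_rainy.tif")
    return outdir


def run_from_files(workdir, config: PipelineConfig,
                   keep_intermediates: bool = False) -> PipelineResult:
    """Run the pipeline from a simulated (or equivalently laid out)
    working directory and write the map, report and matrices back."""
    workdir = Path(workdir)
    manifest = pd.read_csv(workdir / "manifest.csv")
    scenes = [SceneStack(read_raster(workdir / r.bands),
                         read_raster(workdir / r.qa), r.date, r.season)
              for r in manifest.itertuples()]
    ancillary = {}
    for p in workdir.glob("*.geojson"):
        if p.stem != "training_polygons":
            ancillary[p.stem] = read_geojson(p)
    dem = read_raster(workdir / "dem.tif")
    training = pd.read_csv(workdir / "training.csv")
    flood_map = None
    if (workdir / "hh_dry.tif").exists():
        flood_map = map_flooded_forests(read_raster(workdir / "hh_dry.tif"),
                                        read_raster(workdir / "hh_rainy.tif"),
                                        dem)
    truth = None
    if (workdir / "truth.tif").exists():
        truth = read_raster(workdir / "truth.tif").values
    result = run_core(config, scenes, training, ancillary, dem,
                      flood_map=flood_map, truth=truth)

    write_raster(result.lc_map.grid, workdir / "landcover.tif",
                 colormap=config.legend.colormap())
    result.error_matrix.table.to_csv(workdir / "error_matrix.csv")
    result.areas.table.to_csv(workdir / "areas.csv")
    report = {
        "profile": config.profile, "seed": config.seed,
        "overall_accuracy": result.stats["overall"],
        "overall_vs_truth": result.overall_vs_truth,
        "n_validation": result.stats["n"],
        "gap_pixels": int(result.composite.gap_mask.sum()),
    }
    (workdir / "report.json").write_text(json.dumps(report, indent=2))
    if keep_intermediates:
        write_raster(result.composite.bands, workdir / "composite.tif")
        count = result.composite.bands.with_values(
            result.composite.valid_count.astype(np.int16))
        write_raster(count, workdir / "valid_count.tif")
        for name, layer in result.index_stack.layers.items():
            write_raster(layer, workdir / f"index_{name}.tif")
    return result
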