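"""Flooded-forest mapping from dual-season L-band HH amplitude pairs.

Water standing beneath forest canopy raises HH backscatter through the
double-bounce mechanism, so flooded forest appears as anomalously high HH
amplitude.  Because flooded forests occur in low, flood-prone areas along
rivers, detection is constrained by a DEM (elevation cap, optionally a
river-corridor buffer): a pixel is flooded when its amplitude exceeds the
season's threshold *and* the DEM constraint holds.  The threshold is
either fixed in config or derived per scene by Otsu's bimodal histogram
split inside the DEM-constrained region.

Season combination: flooded in both seasons = permanently flooded; flooded
only in the rainy scene = seasonally flooded.  A dry-only detection has no
defined category; it is treated as not flooded (the conservative choice)
and counted as an anomaly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .geo import RasterGrid, VectorLayer, ensure_same_grid, rasterize_mask

log = logging.getLogger("ecoextent")

NOT_FLOODED, SEASONAL, PERMANENT = 0, 1, 2

#: legend names consumed by the sequential classifier
FLOOD_CLASS_NAMES = {SEASONAL: "flooded_forest_seasonal",
                     PERMANENT: "flooded_forest_permanent"}


@dataclass
class FloodDetectionConfig:
    """Detection settings.  ``amplitude_threshold=None`` derives the
    threshold by Otsu inside the DEM-constrained region; amplitudes are
    used on whatever scale the input provides (linear or dB), so fixed
    thresholds are scale-dependent."""

    amplitude_threshold: float | None = None
    dem_cap_m: float = 20.0
    river_lines: VectorLayer | None = None
    corridor_distance_m: float = 2000.0


@dataclass
class FloodMap:
    """Category raster {not flooded, seasonal, permanent} with pixel
    counts, areas and the dry-only anomaly count."""

    grid: RasterGrid
    counts: dict[int, int]
    dry_only_anomalies: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def class_mask(self, legend_name: str) -> np.ndarray:
        for code, name in FLOOD_CLASS_NAMES.items():
            if name == legend_name:
                return self.values == code
        raise KeyError(f"{legend_name!r} is not a flood class")

    def area_km2(self, category: int) -> float:
        return self.counts.get(category, 0) * self.grid.pixel_area_km2

    @property
    def total_flooded_km2(self) -> float:
        return self.area_km2(SEASONAL) + self.area_km2(PERMANENT)


def _dem_constraint(dem: RasterGrid, config: FloodDetectionConfig) -> np.ndarray:
    low = np.asarray(dem.values, float) < config.dem_cap_m
    if config.river_lines is not None:
        low &= rasterize_mask(config.river_lines.geometries, dem,
                              buffer=config.corridor_distance_m)
    return low


def detect_flooded(hh: RasterGrid, dem: RasterGrid,
                   config: FloodDetectionConfig = None) -> np.ndarray:
    """Boolean flood raster for one season's HH amplitude scene."""
    config = config or FloodDetectionConfig()
    ensure_same_grid(hh, dem, names=["HH", "DEM"])
    lowland = _dem_constraint(dem, config)
    amp = np.asarray(hh.values, float)
    if config.amplitude_threshold is not None:
        thr = float(config.amplitude_threshold)
    else:
        region = amp[lowland & np.isfinite(amp)]
        if region.size == 0 or np.ptp(region) < 1e-9:
            raise ValueError(
                "amplitude histogram in the DEM-constrained region is "
                "degenerate; supply a fixed amplitude_threshold")
        thr = float(threshold_otsu(region))
    flooded = (amp > thr) & lowland
    log.info("flood detection: threshold %.4f, %d pixels flooded "
             "(%d lowland candidates)", thr, int(flooded.sum()),
             int(lowland.sum()))
    return flooded


def combine_seasons(flood_dry: np.ndarray, flood_rainy: np.ndarray,
                    ref: RasterGrid) -> FloodMap:
    """Apply the permanent/seasonal season-combination rule.

    permanent = dry AND rainy; seasonal = rainy AND NOT dry; a dry-only
    detection maps to not-flooded and increments the anomaly counter.
    """
    if flood_dry.shape != flood_rainy.shape:
        raise ValueError("season rasters must share a grid")
    cat = np.full(flood_dry.shape, NOT_FLOODED, dtype=np.uint8)
    cat[flood_rainy & ~flood_dry] = SEASONAL
    cat[flood_rainy & flood_dry] = PERMANENT
    anomalies = int((flood_dry & ~flood_rainy).sum())
    if anomalies:
        log.info("season combination: %d dry-only detections treated as "
                 "not flooded", anomalies)
    counts = {int(c): int((cat == c).sum())
              for c in (NOT_FLOODED, SEASONAL, PERMANENT)}
    grid = RasterGrid(cat, ref.transform, ref.crs)
    return FloodMap(grid, counts, dry_only_anomalies=anomalies)


def map_flooded_forests(hh_dry: RasterGrid, hh_rainy: RasterGrid,
                        dem: RasterGrid,
                        config: FloodDetectionConfig = None) -> FloodMap:
    """Detect both seasons and combine them into a flood map."""
    config = config or FloodDetectionConfig()
    dry = detect_flooded(hh_dry, dem, config)
    rainy = detect_flooded(hh_rainy, dem, config)
    return combine_seasons(dry, rainy, hh_dry)


def flood_to_class_mask(flood_map: FloodMap, legend,
                        available: np.ndarray) -> tuple[dict, np.ndarray, int]:
    """Per-class boolean rasters for the flood legend entries and the
    shrunken available pool; pixels already claimed by an earlier class
    stay with that class (conflicts are counted)."""
    masks = {}
    conflicts = 0
    out_avail = available.copy()
    for code, name in FLOOD_CLASS_NAMES.items():
        if name not in legend.names:
            continue
        want = flood_map.values == code
        conflicts += int((want & ~out_avail).sum())
        take = want & out_avail
        masks[name] = take
        out_avail &= ~take
    return masks, out_avail, conflicts
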