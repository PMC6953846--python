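"""Synthetic Landsat-like landscapes for exercising every pipeline stage.

The generator emulates the statistical structure the classification
assumes: per-class multispectral signatures (bands B2-B7 plus a thermal
proxy B10) with within-class Gaussian noise, seasonal reflectance offsets,
cloud/shadow contamination flagged in QA bits, a low-relief DEM with a
coastal gradient and a low-lying river corridor, ancillary geometry
(shoreline, settlement points, concession and forest-extent polygons), and
dry/rainy L-band HH amplitude pairs in which water under forest canopy
raises backscatter (double-bounce).

The default spectral library is constructed so that every default masking
rule is *true* for its target class's mean signature and *false* for at
least one other class; class-pair mean separations are at least five
default noise standard deviations in some band wherever two classes must
be told apart by the random forest.  Geometry follows class semantics:
water, mangroves and flooded forests sit at low elevations, the
sand/intertidal strip hugs the shoreline, artificial surfaces center on
settlement points, and woody-crop patches lie inside concession polygons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union

from .compositing import SceneStack
from .config import ClassLegend, QADialect, default_legend
from .geo import Affine, RasterGrid, VectorLayer
from .indices import BAND_NAMES

# ---------------------------------------------------------------------------
# Spectral library
# ---------------------------------------------------------------------------

#: classes whose canopy reflectance rises in the rainy season (B5 greens up)
_VEGETATED = {"mangroves_wetlands", "woody_crops", "tree_covered_dense",
              "tree_covered_open", "mixed_vegetation", "grasslands",
              "flooded_forest_permanent", "flooded_forest_seasonal"}

DEFAULT_NOISE_SD = 0.01
DEFAULT_RAINY_B5_OFFSET = 0.02

#                B2    B3    B4    B5    B6    B7    B10
_MEANS = {
    "water_bodies":             (0.08, 0.09, 0.06, 0.04, 0.02, 0.01, 0.30),
    "mangroves_wetlands":       (0.06, 0.08, 0.05, 0.35, 0.08, 0.03, 0.40),
    "artificial_surfaces":      (0.14, 0.15, 0.18, 0.22, 0.30, 0.28, 0.65),
    "barren_land":              (0.17, 0.18, 0.22, 0.27, 0.35, 0.31, 0.70),
    "ecosystem_complex":        (0.21, 0.22, 0.24, 0.26, 0.28, 0.25, 0.60),
    "woody_crops":              (0.04, 0.05, 0.06, 0.33, 0.25, 0.10, 0.45),
    "tree_covered_dense":       (0.03, 0.04, 0.04, 0.30, 0.18, 0.07, 0.40),
    "tree_covered_open":        (0.04, 0.05, 0.06, 0.35, 0.20, 0.09, 0.42),
    "mixed_vegetation":         (0.08, 0.09, 0.10, 0.32, 0.24, 0.14, 0.55),
    "grasslands":               (0.10, 0.12, 0.13, 0.24, 0.24, 0.18, 0.60),
    "flooded_forest_permanent": (0.03, 0.05, 0.04, 0.29, 0.17, 0.06, 0.41),
    "flooded_forest_seasonal":  (0.03, 0.05, 0.04, 0.29, 0.17, 0.06, 0.41),
}


@dataclass
class ClassSignature:
    means: dict[str, float]
    sds: dict[str, float]
    rainy_offsets: dict[str, float]

    def mean_vector(self, season: str = "dry") -> np.ndarray:
        off = self.rainy_offsets if season == "rainy" else {}
        return np.array([self.means[b] + off.get(b, 0.0) for b in BAND_NAMES])


@dataclass
class SpectralLibrary:
    """Per-class band means, within-class SDs and dry/rainy offsets."""

    signatures: dict[str, ClassSignature]

    def __contains__(self, name: str) -> bool:
        return name in self.signatures

    def __getitem__(self, name: str) -> ClassSignature:
        return self.signatures[name]


def default_library(noise_sd: float = DEFAULT_NOISE_SD,
                    rainy_b5_offset: float = DEFAULT_RAINY_B5_OFFSET) -> SpectralLibrary:
    sigs = {}
    for name, means in _MEANS.items():
        offsets = {"B5": rainy_b5_offset} if name in _VEGETATED else {}
        sigs[name] = ClassSignature(
            means=dict(zip(BAND_NAMES, means)),
            sds={b: noise_sd for b in BAND_NAMES},
            rainy_offsets=offsets,
        )
    return SpectralLibrary(sigs)


# ---------------------------------------------------------------------------
# Landscape (truth map + DEM + ancillary geometry)
# ---------------------------------------------------------------------------

@dataclass
class SceneCollectionSpec:
    """Grid size, acquisition calendar, contamination and noise settings."""

    shape: tuple[int, int] = (200, 200)
    pixel_size: float = 30.0
    crs: str = "EPSG:32629"
    dates: list[tuple[str, str]] = field(default_factory=lambda: [
        ("2015-01-15", "dry"), ("2015-12-15", "dry"), ("2016-02-15", "dry"),
        ("2016-12-15", "dry"), ("2017-03-10", "dry"),
        ("2015-07-20", "rainy"), ("2016-08-15", "rainy"),
    ])
    cloud_fraction: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    min_class_pixels: int = 30
    qa: QADialect = field(default_factory=QADialect)

    def __post_init__(self) -> None:
        if not 0.0 <= self.cloud_fraction <= 1.0:
            raise ValueError("cloud_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Landscape:
    """Ground truth and ancillary layers for one synthetic country."""

    truth: RasterGrid  # uint8 legend codes
    dem: RasterGrid
    legend: ClassLegend
    ancillary: dict[str, VectorLayer]
    flood_permanent: np.ndarray  # boolean, empty outside gabon profiles
    flood_seasonal: np.ndarray
    profile: str

    def class_mask(self, name: str) -> np.ndarray:
        return self.truth.values == self.legend.code_of(name)


def _grid_transform(spec: SceneCollectionSpec) -> Affine:
    h, _ = spec.shape
    return Affine.from_origin(0.0, h * spec.pixel_size, spec.pixel_size)


def generate_truth_map(spec: SceneCollectionSpec, profile: str = "liberia") -> Landscape:
    """Paint a class-code raster plus consistent DEM and ancillary layers.

    The layout is expressed in grid fractions so it scales with
    ``spec.shape``: a shoreline along the western edge, an intertidal
    strip inside the 1,000-m shore buffer, mangroves and a lagoon at low
    elevation, a north-south river inside a low-lying corridor (with
    flooded-forest belts for the Gabon profile), settlement-centered
    artificial patches, woody-crop patches inside concession polygons, and
    grass/barren/open/mixed patches on a dense-forest background.
    """
    h, w = spec.shape
    ps = spec.pixel_size
    legend = default_legend(profile)
    transform = _grid_transform(spec)
    names = set(legend.names)

    truth = np.full((h, w), 0, dtype=np.uint8)

    def paint(name: str, r0, r1, c0, c1):
        """Paint a fractional box; returns its shapely footprint."""
        rr0, rr1 = int(round(r0 * h)), int(round(r1 * h))
        cc0, cc1 = int(round(c0 * w)), int(round(c1 * w))
        if name in names:
            truth[rr0:rr1, cc0:cc1] = legend.code_of(name)
        return box(cc0 * ps, (h - rr1) * ps, cc1 * ps, (h - rr0) * ps)

    # background: dense forest
    truth[:, :] = legend.code_of("tree_covered_dense")

    open_boxes = [paint("tree_covered_open", 0.15, 0.30, 0.80, 1.00),
                  paint("tree_covered_open", 0.50, 0.60, 0.20, 0.28)]
    mixed_boxes = [paint("mixed_vegetation", 0.55, 0.65, 0.30, 0.45)]
    grass_boxes = [paint("grasslands", 0.00, 0.08, 0.60, 0.80),
                   paint("grasslands", 0.90, 1.00, 0.55, 0.70)]
    barren_boxes = [paint("barren_land", 0.20, 0.28, 0.50, 0.58),
                    paint("barren_land", 0.70, 0.78, 0.70, 0.78)]

    concession_boxes = [paint("__concession__", 0.30, 0.46, 0.75, 0.95),
                        paint("__concession__", 0.85, 0.98, 0.20, 0.40)]
    paint("woody_crops", 0.32, 0.44, 0.77, 0.93)
    paint("woody_crops", 0.87, 0.96, 0.22, 0.38)

    art_boxes, settlements = [], []
    for rc, cc in [(0.13, 0.33), (0.48, 0.63), (0.80, 0.48)]:
        half = 0.03
        b = paint("artificial_surfaces", rc - half, rc + half, cc - half, cc + half)
        art_boxes.append(b)
        settlements.append(Point(b.centroid))

    # low-lying wet classes near the coast and along the river corridor
    flood_perm = np.zeros((h, w), dtype=bool)
    flood_seas = np.zeros((h, w), dtype=bool)
    if "flooded_forest_permanent" in names:
        paint("flooded_forest_permanent", 0.00, 0.45, 0.155, 0.175)
        paint("flooded_forest_seasonal", 0.55, 1.00, 0.155, 0.175)
        flood_perm = truth == legend.code_of("flooded_forest_permanent")
        flood_seas = truth == legend.code_of("flooded_forest_seasonal")
    lagoon_box = paint("water_bodies", 0.30, 0.70, 0.07, 0.10)
    paint("water_bodies", 0.00, 1.00, 0.125, 0.15)  # river
    paint("mangroves_wetlands", 0.15, 0.85, 0.02, 0.065)
    ec_cols = max(2, int(round(0.015 * w)))
    paint("ecosystem_complex", 0.0, 1.0, 0.0, ec_cols / w)

    # DEM: gentle eastward rise from the shore, dipping inside the river
    # corridor; slopes stay well below the 10-degree verification cap.
    cols = np.arange(w, dtype=float)
    base = 2.0 + 0.02 * (cols + 0.5) * ps  # ~0.6 m per 30-m pixel
    dem = np.tile(base, (h, 1))
    corridor = slice(int(0.11 * w), int(0.18 * w) + 1)
    dem[:, corridor] = np.minimum(dem[:, corridor], 12.0)
    dem_grid = RasterGrid(dem, transform, spec.crs, nodata=None)

    # class-count floor
    counts = {name: int((truth == legend.code_of(name)).sum()) for name in legend.names}
    short = {n: c for n, c in counts.items() if c < spec.min_class_pixels}
    if short:
        raise ValueError(f"grid {spec.shape} too small to place all classes "
                         f"(short: {short})")

    shoreline = LineString([(0.0, 0.0), (0.0, h * ps)])
    ancillary = {
        "shoreline": VectorLayer([shoreline], "shoreline", crs=spec.crs),
        "settlements": VectorLayer(settlements, "settlements", crs=spec.crs),
        "concessions": VectorLayer(concession_boxes, "concessions", crs=spec.crs),
    }
    if profile == "gabon":
        # forest-extent polygon: everything except the clearly non-forest
        # patches; used by the dense tree-cover ancillary mask rule
        whole = box(0, 0, w * ps, h * ps)
        holes = unary_union(grass_boxes + barren_boxes + art_boxes + [lagoon_box])
        ancillary["forest_extent"] = VectorLayer(
            [whole.difference(holes)], "forest_extent", crs=spec.crs)

    truth_grid = RasterGrid(truth, transform, spec.crs, nodata=None)
    return Landscape(truth_grid, dem_grid, legend, ancillary,
                     flood_perm, flood_seas, profile)


# ---------------------------------------------------------------------------
# Scene synthesis
# ---------------------------------------------------------------------------

def generate_scenes(landscape: Landscape, library: SpectralLibrary,
                    spec: SceneCollectionSpec) -> list[SceneStack]:
    """Reflectance = class mean (+ rainy offset) + Gaussian noise truncated
    to [0, 1]; clouds are bright random disks with the QA cloud bit set and
    a paired dark shadow disk with the shadow bit set."""
    missing = [n for n in landscape.legend.names if n not in library]
    if missing:
        raise ValueError(f"spectral library misses classes: {missing}")
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    truth = landscape.truth.values
    scenes = []
    for date, season in spec.dates:
        arr = np.zeros((len(BAND_NAMES), h, w), dtype=float)
        for name in landscape.legend.names:
            m = truth == landscape.legend.code_of(name)
            if not m.any():
                continue
            arr[:, m] = library[name].mean_vector(season)[:, None]
        if spec.noise_sd > 0:
            arr += rng.normal(0.0, spec.noise_sd, size=arr.shape)
        np.clip(arr, 0.0, 1.0, out=arr)
        qa = np.zeros((h, w), dtype=np.uint16)
        if spec.cloud_fraction >= 1.0:
            qa |= np.uint16(1 << spec.qa.cloud_bit)
            arr[:] = 0.55
        elif spec.cloud_fraction > 0:
            _paint_clouds(arr, qa, spec, rng)
        bands = RasterGrid(arr, landscape.truth.transform, spec.crs,
                           nodata=None, band_names=list(BAND_NAMES))
        qa_grid = RasterGrid(qa, landscape.truth.transform, spec.crs)
        scenes.append(SceneStack(bands, qa_grid, date, season))
    return scenes


def _paint_clouds(arr, qa, spec: SceneCollectionSpec, rng) -> None:
    h, w = qa.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cloud = np.zeros((h, w), dtype=bool)
    target = spec.cloud_fraction * h * w
    guard = 0
    while cloud.sum() < target and guard < 500:
        guard += 1
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        r = rng.integers(max(3, h // 40), max(4, h // 8))
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        cloud |= disk
        # cloud shadow cast a few pixels to the south-west
        sy, sx = cy + r, cx - r
        shadow = (yy - sy) ** 2 + (xx - sx) ** 2 <= (r // 2) ** 2
        shadow &= ~cloud
        qa[shadow] |= np.uint16(1 << spec.qa.shadow_bit)
        arr[:, shadow] *= 0.3
    qa[cloud] |= np.uint16(1 << spec.qa.cloud_bit)
    arr[:, cloud] = 0.55 + rng.normal(0, 0.02, size=(arr.shape[0], int(cloud.sum())))


# ---------------------------------------------------------------------------
# SAR pair synthesis
# ---------------------------------------------------------------------------

@dataclass
class SARSpec:
    """Linear HH amplitude model: non-flooded forest background vs the
    elevated double-bounce response of water beneath canopy."""

    background_amplitude: float = 0.30
    flooded_amplitude: float = 0.70
    noise_sd: float = 0.04
    upland_anomaly_fraction: float = 0.002  # bright pixels outside the lowlands
    seed: int = 0


def generate_sar_pair(landscape: Landscape, sar: SARSpec = None
                      ) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Dry and rainy HH amplitude rasters plus the DEM.

    Permanent-flood pixels are elevated in both seasons, seasonal-flood
    pixels only in the rainy scene; a small fraction of upland pixels get
    anomalously high amplitude in both seasons so the DEM constraint has
    something to reject.
    """
    sar = sar or SARSpec()
    rng = np.random.default_rng(sar.seed)
    shape = landscape.truth.shape
    if not landscape.flood_permanent.any() and not landscape.flood_seasonal.any():
        raise ValueError("landscape designates no flooded-forest pixels")

    def scene(flooded: np.ndarray) -> np.ndarray:
        amp = np.full(shape, sar.background_amplitude)
        amp[flooded] = sar.flooded_amplitude
        amp += rng.normal(0, sar.noise_sd, size=shape)
        return np.clip(amp, 0.0, None)

    hh_dry = scene(landscape.flood_permanent)
    hh_rainy = scene(landscape.flood_permanent | landscape.flood_seasonal)
    if sar.upland_anomaly_fraction > 0:
        upland = landscape.dem.values >= 40.0
        idx = np.flatnonzero(upland.ravel())
        n = int(sar.upland_anomaly_fraction * upland.size)
        pick = rng.choice(idx, size=min(n, idx.size), replace=False)
        for hh in (hh_dry, hh_rainy):
            hh.ravel()[pick] = sar.flooded_amplitude
    t, crs = landscape.truth.transform, landscape.truth.crs
    return (RasterGrid(hh_dry, t, crs), RasterGrid(hh_rainy, t, crs),
            landscape.dem)


# ---------------------------------------------------------------------------
# Training data
# ---------------------------------------------------------------------------

def sample_training(landscape: Landscape, n_per_class: int = 600,
                    seed: int = 0) -> pd.DataFrame:
    """Random training pixels per class from the truth raster (capped by
    availability), as a (row, col, class_name, code) table."""
    rng = np.random.default_rng(seed)
    rows = []
    truth = landscape.truth.values
    for name in landscape.legend.names:
        code = landscape.legend.code_of(name)
        rr, cc = np.nonzero(truth == code)
        if rr.size == 0:
            continue
        take = min(n_per_class, rr.size)
        pick = rng.choice(rr.size, size=take, replace=False)
        for i in pick:
            rows.append((int(rr[i]), int(cc[i]), name, code))
    return pd.DataFrame(rows, columns=["row", "col", "class_name", "code"])


def training_polygons(landscape: Landscape, training: pd.DataFrame) -> VectorLayer:
    """Training pixels as one-pixel square polygons (the GeoJSON exchange
    form of the training set)."""
    ps = landscape.truth.pixel_size
    h = landscape.truth.shape[0]
    geoms, attrs = [], []
    for _, rec in training.iterrows():
        x0, y1 = rec.col * ps, (h - rec.row) * ps
        geoms.append(box(x0, y1 - ps, x0 + ps, y1))
        attrs.append({"class": rec.class_name, "code": int(rec.code)})
    return VectorLayer(geoms, "training_polygons", attrs, landscape.truth.crs)
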