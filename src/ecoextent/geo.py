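"""Raster and vector data model shared by every pipeline stage.

Rasters are plain numpy arrays with an affine georeference, carried by
:class:`RasterGrid` and persisted as TIFF files whose georeferencing
metadata (transform, CRS, nodata, band names, legend) travels in the TIFF
image-description tag as JSON.  Vector layers are shapely geometries read
and written as GeoJSON.  A single projected CRS per run is assumed: inputs
must be co-registered, and no on-the-fly reprojection is performed.

Coordinate convention: 0-based ``(row, col)`` indices; the affine transform
maps pixel *edges*, and pixel-center coordinates are obtained at
``(col + 0.5, row + 0.5)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.ops import unary_union


class GridMismatchError(ValueError):
    """Raised when rasters or vectors that must share a grid/CRS do not."""


class Affine(NamedTuple):
    """Row-major affine georeference: ``x = a*col + b*row + c``,
    ``y = d*col + e*row + f`` (same layout as the GDAL/rasterio convention)."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, pixel_size: float) -> "Affine":
        return cls(pixel_size, 0.0, west, 0.0, -pixel_size, north)

    def xy(self, row, col, center: bool = True):
        """Map coordinates of a pixel; center of the cell by default."""
        off = 0.5 if center else 0.0
        colf = np.asarray(col, dtype=float) + off
        rowf = np.asarray(row, dtype=float) + off
        return (self.a * colf + self.b * rowf + self.c,
                self.d * colf + self.e * rowf + self.f)

    @property
    def pixel_size(self) -> float:
        return float(abs(self.a))


@dataclass
class RasterGrid:
    """A 2-D single-band or 3-D band-stacked raster on an affine grid.

    ``values`` holds reflectance (unitless, nominally [0, 1]), SAR amplitude,
    elevation in metres, or integer category codes; ``nodata`` is the
    sentinel for missing observations.  3-D stacks are band-first
    ``(band, row, col)``.
    """

    values: np.ndarray
    transform: Affine
    crs: str = "EPSG:32629"
    nodata: float | int | None = None
    band_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"raster must be 2-D or 3-D, got {self.values.ndim}-D")
        if not isinstance(self.transform, Affine):
            self.transform = Affine(*self.transform)
        if self.transform.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.band_names is not None and len(self.band_names) != self.n_bands:
            raise ValueError("band_names length does not match band count")

    # -- shape helpers -------------------------------------------------
    @property
    def n_bands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[-2:]

    @property
    def pixel_size(self) -> float:
        return self.transform.pixel_size

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size ** 2) / 1e6

    def band(self, name: str) -> np.ndarray:
        if self.band_names is None:
            raise KeyError("raster carries no band names")
        try:
            i = self.band_names.index(name)
        except ValueError:
            raise KeyError(f"unknown band {name!r}; have {self.band_names}") from None
        return self.values if self.values.ndim == 2 else self.values[i]

    def valid_mask(self) -> np.ndarray:
        """True where every band is a real observation (not nodata/NaN)."""
        v = self.values if self.values.ndim == 3 else self.values[None]
        ok = ~np.isnan(v.astype(float))
        if self.nodata is not None and not np.isnan(float(self.nodata)):
            ok &= v != self.nodata
        return ok.all(axis=0)

    def with_values(self, values: np.ndarray, band_names=None) -> "RasterGrid":
        """New grid sharing this raster's georeference."""
        return RasterGrid(values, self.transform, self.crs, self.nodata,
                          band_names if band_names is not None else
                          (self.band_names if np.ndim(values) == np.ndim(self.values) else None))

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.mgrid[0:self.shape[0], 0:self.shape[1]]
        return self.transform.xy(rows, cols)


def ensure_same_grid(*grids: RasterGrid, names: Sequence[str] | None = None) -> None:
    """Raise :class:`GridMismatchError` naming the offending layer if any
    raster disagrees in shape, transform or CRS with the first."""
    ref = grids[0]
    labels = names or [f"raster[{i}]" for i in range(len(grids))]
    for g, label in zip(grids[1:], labels[1:]):
        if g.shape != ref.shape:
            raise GridMismatchError(f"{label}: shape {g.shape} != {ref.shape}")
        if not np.allclose(g.transform, ref.transform):
            raise GridMismatchError(f"{label}: transform differs from {labels[0]}")
        if g.crs != ref.crs:
            raise GridMismatchError(f"{label}: CRS {g.crs} != {ref.crs}")


# ---------------------------------------------------------------------------
# Raster IO (TIFF + JSON metadata tag)
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path, colormap: dict[int, tuple] | None = None):
    """Write a raster as TIFF; georeference metadata goes into the image
    description tag.  When ``colormap`` maps category codes to RGB tuples
    (0-255) and the raster is uint8, an embedded palette is written too."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "transform": list(grid.transform),
        "crs": grid.crs,
        "nodata": None if grid.nodata is None else float(grid.nodata),
        "band_names": grid.band_names,
        "colormap": {str(k): list(v) for k, v in colormap.items()} if colormap else None,
    }
    kwargs = {}
    if colormap and grid.values.dtype == np.uint8 and grid.values.ndim == 2:
        palette = np.zeros((3, 256), dtype=np.uint16)
        for code, rgb in colormap.items():
            palette[:, int(code)] = [int(c) * 257 for c in rgb[:3]]
        kwargs["colormap"] = palette
    tifffile.imwrite(path, grid.values, description=json.dumps(meta), **kwargs)
    return path


def read_raster(path) -> RasterGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    transform = Affine(*meta.get("transform", Affine.from_origin(0, 0, 30.0)))
    nodata = meta.get("nodata")
    if nodata is not None and values.dtype.kind in "iu":
        nodata = int(nodata)
    return RasterGrid(values, transform, meta.get("crs", "EPSG:32629"),
                      nodata, meta.get("band_names"))


def read_colormap(path) -> dict[int, tuple] | None:
    """Color table embedded in a written category raster, if any."""
    with tifffile.TiffFile(path) as tif:
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    cm = meta.get("colormap")
    return {int(k): tuple(v) for k, v in cm.items()} if cm else None


# ---------------------------------------------------------------------------
# Vector layers (shapely + GeoJSON)
# ---------------------------------------------------------------------------

VECTOR_KINDS = ("settlements", "concessions", "shoreline", "protected_areas",
                "training_polygons", "forest_extent")


@dataclass
class VectorLayer:
    """Point/line/polygon features with per-feature attributes, in the
    working raster's CRS."""

    geometries: list
    kind: str
    attributes: list[dict] = field(default_factory=list)
    crs: str = "EPSG:32629"

    def __post_init__(self) -> None:
        if not self.attributes:
            self.attributes = [{} for _ in self.geometries]
        if len(self.attributes) != len(self.geometries):
            raise ValueError("one attribute record per geometry required")
        for i, g in enumerate(self.geometries):
            if g.is_empty:
                continue
            if not g.is_valid:
                raise ValueError(f"{self.kind} feature {i} has invalid geometry")

    def __len__(self) -> int:
        return len(self.geometries)


def write_geojson(layer: VectorLayer, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": attrs}
        for g, attrs in zip(layer.geometries, layer.attributes)
    ]
    doc = {"type": "FeatureCollection", "features": features,
           "ecoextent": {"kind": layer.kind, "crs": layer.crs}}
    path.write_text(json.dumps(doc))
    return path


def read_geojson(path, kind: str | None = None) -> VectorLayer:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vector layer not found: {path}")
    doc = json.loads(path.read_text())
    extra = doc.get("ecoextent", {})
    geoms, attrs = [], []
    for feat in doc.get("features", []):
        geoms.append(shape(feat["geometry"]))
        attrs.append(feat.get("properties") or {})
    return VectorLayer(geoms, kind or extra.get("kind", "training_polygons"),
                       attrs, extra.get("crs", "EPSG:32629"))


# ---------------------------------------------------------------------------
# Vector-on-grid operations
# ---------------------------------------------------------------------------

def rasterize_mask(geometries: Iterable, grid: RasterGrid,
                   buffer: float = 0.0) -> np.ndarray:
    """Boolean mask of pixels whose *center* lies inside the (optionally
    buffered) union of ``geometries``."""
    geoms = [g for g in geometries if not g.is_empty]
    if not geoms:
        return np.zeros(grid.shape, dtype=bool)
    union = unary_union(geoms)
    if buffer > 0:
        union = union.buffer(buffer)
    x, y = grid.pixel_centers()
    inside = shapely.contains_xy(union, x.ravel(), y.ravel())
    return inside.reshape(grid.shape)


def horn_slope(dem: RasterGrid) -> RasterGrid:
    """Slope in degrees from a DEM by Horn's 3x3 weighted-difference method
    (the standard GIS slope operator); edges use replicated borders."""
    z = np.pad(np.asarray(dem.values, dtype=float), 1, mode="edge")
    cell = dem.pixel_size
    # Neighbours: z1..z9 left-to-right, top-to-bottom around the center z5.
    z1, z2, z3 = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    z4, z6 = z[1:-1, :-2], z[1:-1, 2:]
    z7, z8, z9 = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((z3 + 2 * z6 + z9) - (z1 + 2 * z4 + z7)) / (8 * cell)
    dzdy = ((z7 + 2 * z8 + z9) - (z1 + 2 * z2 + z3)) / (8 * cell)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.with_values(slope)
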