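"""Reflectance-based spectral indices used as masking and classification
predictors.

Thirteen indices are supported, grouped by the surface property they
enhance: water/mangrove (NDMI, MNDWI), built-up/bare (NDBI, NDII, NDBaI,
BI, UI), green vegetation (NDVI, GCVI, SR) and plain band ratios (R75,
R65, R34).  Formulas are evaluated exactly as configured on Landsat-8-style
band names B2-B7 plus a thermal layer B10; NDII and NDBaI mix reflectance
with the thermal layer, so their thresholds are scaling-dependent (the
index is computed on whatever B10 values the composite provides).

Pixels where any required band is nodata, or where the denominator falls
below a small epsilon, are returned as nodata rather than +/-inf, keeping
threshold comparisons well-defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geo import RasterGrid

#: category -> index names, mirroring the predictor grouping used when a
#: class's random forest is assembled.
INDEX_CATEGORIES = {
    "water_wetland": ["NDMI", "MNDWI"],
    "barren_builtup": ["NDBI", "NDII", "NDBaI", "BI", "UI"],
    "green_vegetation": ["NDVI", "GCVI", "SR"],
    "band_ratios": ["R75", "R65", "R34"],
}

# (kind, numerator band(s)): "nd" = normalized difference (x - y)/(x + y),
# "ratio" = x / y, "ratio_m1" = x / y - 1.
_FORMULAS = {
    "NDMI": ("nd", "B7", "B3"),
    "MNDWI": ("nd", "B3", "B6"),
    "NDBI": ("nd", "B6", "B5"),
    "NDII": ("nd", "B3", "B10"),
    "NDBaI": ("nd", "B6", "B10"),
    "BI": ("nd", "B6", "B7"),
    "UI": ("nd", "B7", "B5"),
    "NDVI": ("nd", "B5", "B4"),
    "GCVI": ("ratio_m1", "B5", "B3"),
    "SR": ("ratio", "B5", "B4"),
    "R75": ("ratio", "B7", "B5"),
    "R65": ("ratio", "B6", "B5"),
    "R34": ("ratio", "B3", "B4"),
}

INDEX_NAMES = list(_FORMULAS)

BAND_NAMES = ["B2", "B3", "B4", "B5", "B6", "B7", "B10"]


def compute_index(composite_bands: RasterGrid, name: str,
                  eps: float = 1e-10) -> RasterGrid:
    """Evaluate one spectral index over a band-stacked composite.

    Parameters
    ----------
    composite_bands : band-stacked RasterGrid with named bands.
    name : index name (one of :data:`INDEX_NAMES`).
    eps : denominators with absolute value below this become nodata.
    """
    if name not in _FORMULAS:
        raise KeyError(f"unknown spectral index {name!r}; "
                       f"known: {', '.join(INDEX_NAMES)}")
    kind, xa, xb = _FORMULAS[name]
    valid = composite_bands.valid_mask() if composite_bands.nodata is not None \
        else np.ones(composite_bands.shape, bool)
    a = np.asarray(composite_bands.band(xa), dtype=float)
    b = np.asarray(composite_bands.band(xb), dtype=float)
    if composite_bands.nodata is not None:
        nd = float(composite_bands.nodata)
        valid = valid & (a != nd) & (b != nd)
    denom = a + b if kind == "nd" else b
    ok = valid & (np.abs(denom) >= eps) & np.isfinite(a) & np.isfinite(b)
    out = np.full(composite_bands.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "nd":
            out[ok] = (a[ok] - b[ok]) / denom[ok]
        elif kind == "ratio":
            out[ok] = a[ok] / denom[ok]
        else:  # ratio_m1
            out[ok] = a[ok] / denom[ok] - 1.0
    return RasterGrid(out, composite_bands.transform, composite_bands.crs,
                      nodata=np.nan, band_names=None)


@dataclass
class IndexStack:
    """Named index layers sharing the source composite's grid."""

    layers: dict[str, RasterGrid]
    source: str = ""

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)


def compute_stack(composite_bands: RasterGrid, names=None,
                  eps: float = 1e-10, source: str = "") -> IndexStack:
    """Batch :func:`compute_index`; duplicate names collapse to a single
    layer with a warning."""
    names = list(names) if names is not None else list(INDEX_NAMES)
    seen, unique = set(), []
    for n in names:
        if n in seen:
            warnings.warn(f"duplicate index name {n!r} ignored", stacklevel=2)
            continue
        seen.add(n)
        unique.append(n)
    return IndexStack({n: compute_index(composite_bands, n, eps) for n in unique},
                      source=source)
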