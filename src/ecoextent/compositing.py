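"""QA-based cloud screening and per-band, per-pixel median compositing.

Cloud-prone study areas need multi-date composites: each scene is cloud
screened with its per-pixel QA bit flags, a window of scenes is selected
(one season across the central year +/- one season-year, or all scenes of
the central year +/- one year), and the stack is reduced to the per-band,
per-pixel median of the valid observations.  Pixels with zero valid
observations anywhere in the window form the composite's gap mask and stay
nodata through the rest of the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .config import CompositeWindow, QADialect
from .geo import RasterGrid, GridMismatchError, ensure_same_grid

log = logging.getLogger("ecoextent")


@dataclass
class SceneStack:
    """One acquisition: band-stacked reflectance plus its QA bit raster."""

    bands: RasterGrid
    qa: RasterGrid
    date: str  # ISO "YYYY-MM-DD"
    season: str  # "dry" | "rainy"

    def __post_init__(self) -> None:
        if self.qa.shape != self.bands.shape:
            raise GridMismatchError(
                f"QA raster shape {self.qa.shape} != bands {self.bands.shape}")

    @property
    def year(self) -> int:
        return int(self.date[:4])

    @property
    def month(self) -> int:
        return int(self.date[5:7])


@dataclass
class Composite:
    """Gap-flagged median image: per-pixel valid-observation counts and a
    mask of pixels no scene observed."""

    bands: RasterGrid
    valid_count: np.ndarray
    gap_mask: np.ndarray


def mask_clouds(scene: SceneStack, qa: QADialect = QADialect()) -> SceneStack:
    """Set cloud-, shadow- or fill-flagged pixels to nodata in every band."""
    flagged = (scene.qa.values.astype(np.int64) & qa.flag_mask) != 0
    values = np.array(scene.bands.values, dtype=float)
    nodata = scene.bands.nodata
    nodata = np.nan if nodata is None else float(nodata)
    if values.ndim == 3:
        values[:, flagged] = nodata
    else:
        values[flagged] = nodata
    log.info("cloud screening %s: removed %d of %d pixels",
             scene.date, int(flagged.sum()), flagged.size)
    masked = RasterGrid(values, scene.bands.transform, scene.bands.crs,
                        nodata=nodata, band_names=scene.bands.band_names)
    return replace(scene, bands=masked)


def select_window(collection, window: CompositeWindow):
    """Scenes whose date/season fall inside the compositing window.

    ``seasonal`` mode keeps scenes of the configured season whose
    season-year lies in the central year +/- 1 (a December scene belongs to
    the season of the year it starts, so Dec 2015-Mar 2016 is season-year
    2015); ``annual`` mode keeps every scene dated in the central year
    +/- 1.
    """
    collection = list(collection)
    selected = []
    for scene in collection:
        if window.mode == "annual":
            keep = scene.year in window.years
        elif window.mode == "seasonal":
            season_year = scene.year - 1 if scene.month <= 6 else scene.year
            keep = scene.season == window.season and season_year in window.years
        else:
            raise ValueError(f"unknown window mode {window.mode!r}")
        if keep:
            selected.append(scene)
    log.info("window %s selected %d of %d scenes: %s", window,
             len(selected), len(collection), [s.date for s in selected])
    if not selected:
        raise ValueError(f"no scenes fall inside compositing window {window}")
    return selected


def median_composite(scenes) -> Composite:
    """Per-band, per-pixel median of the valid observations.

    An even observation count takes the mean of the two middle values;
    zero observations set the gap mask and nodata (NaN) in every band.
    """
    scenes = list(scenes)
    if not scenes:
        raise ValueError("median composite needs at least one scene")
    ensure_same_grid(*[s.bands for s in scenes],
                     names=[f"scene {s.date}" for s in scenes])
    ref = scenes[0].bands
    stack = np.stack([np.asarray(s.bands.values, dtype=float)[None]
                      if s.bands.values.ndim == 2
                      else np.asarray(s.bands.values, dtype=float)
                      for s in scenes])  # (scene, band, row, col)
    for s, sub in zip(scenes, stack):
        nd = s.bands.nodata
        if nd is not None and not np.isnan(float(nd)):
            sub[sub == float(nd)] = np.nan
    valid = ~np.isnan(stack)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels -> gap
        med = np.nanmedian(stack, axis=0)
    count = valid.all(axis=1).sum(axis=0)  # a pixel counts when all bands are valid
    gap = count == 0
    med[:, gap] = np.nan
    bands = RasterGrid(med if ref.values.ndim == 3 else med[0],
                       ref.transform, ref.crs, nodata=np.nan,
                       band_names=ref.band_names)
    log.info("median composite of %d scenes: %d gap pixels of %d",
             len(scenes), int(gap.sum()), gap.size)
    return Composite(bands=bands, valid_count=count, gap_mask=gap)
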