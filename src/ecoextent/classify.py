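"""Sequential binary random-forest classification.

The mapping strategy classifies one class at a time: mask candidate
pixels (Phases I and II), train a binary random forest (the target class
against all other classes collapsed to "Other"), predict over the
candidates only, verify the result against knowledge-based rules (e.g.
water and mangroves occur on low slopes), store the class, and remove its
pixels from the pool before the next class.  Classes already mapped are
never touched again, so a later class can be revisited without disturbing
earlier ones; the final map composites all classes into one coded raster.

SAR-derived flood classes are slotted into the same iteration order: their
pixels come from the flooded-forest map instead of a random forest, and
they are removed from the pool before the tree-covered classes run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

from .config import (NODATA_CODE, UNCLASSIFIED, ClassLegend, ClassSpec,
                     ClassifierConfig, ConfigError)
from .geo import RasterGrid, horn_slope
from .indices import IndexStack
from .masking import CandidateMask, apply_phase1, apply_phase2, resolve_layer

log = logging.getLogger("ecoextent")


@dataclass
class LandCoverMap:
    """Integer-coded land-cover raster with its legend and per-class
    provenance (iteration index, training size, candidate count)."""

    grid: RasterGrid
    legend: ClassLegend
    provenance: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def class_mask(self, name: str) -> np.ndarray:
        return self.values == self.legend.code_of(name)


# ---------------------------------------------------------------------------
# Binary RF building blocks
# ---------------------------------------------------------------------------

def train_binary_rf(features: pd.DataFrame, predictors,
                    config: ClassifierConfig) -> RandomForestClassifier:
    """Fit a majority-vote forest on a binary training table.

    ``features`` carries one row per training pixel with the predictor
    columns and a 0/1 ``label`` column.  Out-of-bag accuracy is logged when
    the sample permits it.
    """
    labels = features["label"].to_numpy()
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError("binary training set contains a single label")
    counts = {int(v): int((labels == v).sum()) for v in present}
    floor = config.min_training_pixels
    if min(counts.values()) < floor:
        raise ValueError(f"need >= {floor} training pixels per label, got {counts}")
    use_oob = min(counts.values()) >= 15
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        oob_score=use_oob,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(features[list(predictors)].to_numpy(), labels)
    if use_oob:
        log.info("binary RF (%d trees, n=%d): OOB accuracy %.3f",
                 config.n_trees, len(features), model.oob_score_)
    return model


def pixel_features(pixels: np.ndarray, composite_bands: RasterGrid,
                   index_stack: IndexStack | None, predictors) -> np.ndarray:
    """Predictor matrix for flat pixel indices into the working grid."""
    cols = []
    for name in predictors:
        cols.append(resolve_layer(name, composite_bands, index_stack).ravel()[pixels])
    return np.column_stack(cols)


def _assemble_training(spec: ClassSpec, training: pd.DataFrame,
                       candidate: np.ndarray, shape,
                       floor: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat pixel indices and 0/1 labels for one class's binary problem.

    "Other" pixels are the non-target training pixels restricted to the
    current candidate mask; if fewer than the floor remain there, fall
    back to the unrestricted non-target training set so the binary problem
    stays well-posed."""
    flat = training["row"].to_numpy() * shape[1] + training["col"].to_numpy()
    is_target = (training["class_name"] == spec.name).to_numpy()
    target_px = flat[is_target]
    other_px = flat[~is_target]
    in_candidate = candidate.ravel()[other_px]
    if in_candidate.sum() >= floor:
        other_px = other_px[in_candidate]
    pixels = np.concatenate([target_px, other_px])
    labels = np.concatenate([np.ones(target_px.size, dtype=int),
                             np.zeros(other_px.size, dtype=int)])
    return pixels, labels


def classify_class(composite_bands: RasterGrid, index_stack: IndexStack,
                   spec: ClassSpec, candidate: CandidateMask,
                   training: pd.DataFrame, config: ClassifierConfig
                   ) -> tuple[np.ndarray, dict]:
    """Binary Class/Other prediction restricted to the candidate pixels.

    Returns the boolean class raster (never touching non-candidates;
    "Other" pixels stay in the pool) and a provenance record.
    """
    shape = composite_bands.shape
    if not candidate.mask.any():
        log.warning("class %s: empty candidate mask, skipped", spec.name)
        return np.zeros(shape, bool), {"skipped": "empty candidates"}
    pixels, labels = _assemble_training(spec, training, candidate.mask, shape,
                                        config.min_training_pixels)
    X = pixel_features(pixels, composite_bands, index_stack, spec.predictors)
    ok = np.isfinite(X).all(axis=1)
    feats = pd.DataFrame(X[ok], columns=spec.predictors)
    feats["label"] = labels[ok]
    model = train_binary_rf(feats, spec.predictors, config)

    cand_px = np.flatnonzero(candidate.mask.ravel())
    Xc = pixel_features(cand_px, composite_bands, index_stack, spec.predictors)
    finite = np.isfinite(Xc).all(axis=1)
    pred = np.zeros(cand_px.size, dtype=bool)
    pred[finite] = model.predict(Xc[finite]) == 1
    out = np.zeros(shape, dtype=bool)
    out.ravel()[cand_px[pred]] = True
    prov = {"training_size": int(ok.sum()), "candidates": candidate.retained,
            "assigned": int(out.sum()), "rules": candidate.rules}
    log.info("class %s: %d of %d candidates assigned", spec.name,
             prov["assigned"], prov["candidates"])
    return out, prov


def verify_class(class_mask: np.ndarray, slope_cap_deg: float | None,
                 dem: RasterGrid | None) -> tuple[np.ndarray, int]:
    """Knowledge-based verification: revert pixels on slopes above the cap
    back to "other".  Identity when no rule or no DEM is configured."""
    if slope_cap_deg is None or dem is None:
        return class_mask, 0
    slope = horn_slope(dem).values
    bad = class_mask & (slope > slope_cap_deg)
    if bad.any():
        log.info("verification reverted %d pixels (slope > %.1f deg)",
                 int(bad.sum()), slope_cap_deg)
    return class_mask & ~bad, int(bad.sum())


def propagate_mask(available: np.ndarray, assigned_so_far: np.ndarray,
                   new_class: np.ndarray) -> np.ndarray:
    """Remove a newly mapped class from the pool; assigning a pixel twice
    is an invariant breach and a hard error."""
    overlap = new_class & assigned_so_far
    if overlap.any():
        raise ValueError(f"{int(overlap.sum())} pixels already carry a class")
    if (new_class & ~available).any():
        raise ValueError("new class contains pixels outside the available pool")
    return available & ~new_class


def composite_map(class_masks: dict[str, np.ndarray], legend: ClassLegend,
                  ref: RasterGrid, gap_mask: np.ndarray | None = None,
                  provenance: dict | None = None) -> LandCoverMap:
    """Combine disjoint per-class boolean rasters into one coded map;
    never-assigned pixels become unclassified, gap pixels nodata."""
    code = np.full(ref.shape, UNCLASSIFIED, dtype=np.uint8)
    taken = np.zeros(ref.shape, dtype=bool)
    for name, mask in class_masks.items():
        if (mask & taken).any():
            raise ValueError(f"class rasters overlap at {name!r}")
        code[mask] = legend.code_of(name)
        taken |= mask
    if gap_mask is not None:
        code[gap_mask] = NODATA_CODE
    grid = RasterGrid(code, ref.transform, ref.crs, nodata=NODATA_CODE)
    return LandCoverMap(grid, legend, provenance or {})


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class SequentialLandCoverClassifier(BaseEstimator):
    """Sequential one-class-at-a-time land-cover mapper.

    Parameters
    ----------
    legend : ClassLegend
        Class order; earlier classes claim pixels first.
    class_specs : dict[str, ClassSpec]
        Masking rules, predictors and verification per class.
    classifier_config : ClassifierConfig
        Forest size (default 100 trees), per-split feature subset
        (sqrt of the predictor count) and seed.

    After :meth:`fit`, ``map_`` holds the composite :class:`LandCoverMap`,
    ``models_`` the per-class forests and ``provenance_`` the per-class
    masking/training records.
    """

    def __init__(self, legend: ClassLegend = None,
                 class_specs: dict[str, ClassSpec] = None,
                 classifier_config: ClassifierConfig = None):
        self.legend = legend
        self.class_specs = class_specs
        self.classifier_config = classifier_config

    def fit(self, composite, index_stack: IndexStack,
            training: pd.DataFrame, ancillary=None, dem: RasterGrid = None,
            flood_map=None):
        """Run the full sequential classification over one composite.

        ``composite`` is a :class:`~ecoextent.compositing.Composite`;
        ``flood_map`` (optional) is a :class:`~ecoextent.sar.FloodMap`
        whose classes are consumed by SAR-derived legend entries.
        """
        if self.legend is None or self.class_specs is None:
            raise ConfigError("legend and class_specs are required")
        cfg = self.classifier_config or ClassifierConfig()
        bands = composite.bands
        gap = composite.gap_mask
        available = ~gap
        assigned = np.zeros(bands.shape, dtype=bool)
        class_masks: dict[str, np.ndarray] = {}
        prov: dict[str, dict] = {}
        mapped: set[str] = set()

        for iteration, name in enumerate(self.legend.names):
            spec = self.class_specs[name]
            if spec.sar_derived:
                mask, record = self._take_flood(name, flood_map, available)
            else:
                candidate = apply_phase1(bands, index_stack, spec.phase1, available)
                if spec.phase2:
                    candidate = apply_phase2(candidate, spec.phase2, ancillary,
                                             dem, mapped, grid=bands)
                step_cfg = ClassifierConfig(
                    n_trees=cfg.n_trees, max_features=cfg.max_features,
                    min_training_pixels=cfg.min_training_pixels,
                    seed=cfg.seed + iteration)
                mask, record = classify_class(bands, index_stack, spec,
                                              candidate, training, step_cfg)
                mask, reverted = verify_class(mask, spec.slope_cap_deg, dem)
                record["verification_reverted"] = reverted
            record["iteration"] = iteration
            available = propagate_mask(available, assigned, mask)
            assigned |= mask
            class_masks[name] = mask
            prov[name] = record
            mapped.add(name)

        self.models_ = None  # per-class forests are transient; records stay
        self.map_ = composite_map(class_masks, self.legend, bands,
                                  gap_mask=gap, provenance=prov)
        self.class_masks_ = class_masks
        self.provenance_ = prov
        return self

    @staticmethod
    def _take_flood(name: str, flood_map, available: np.ndarray):
        if flood_map is None:
            log.warning("class %s is SAR-derived but no flood map was "
                        "supplied; skipped", name)
            return np.zeros(available.shape, bool), {"skipped": "no flood map"}
        want = flood_map.class_mask(name)
        conflict = want & ~available
        mask = want & available
        if conflict.any():
            log.info("flood class %s: %d pixels already claimed by earlier "
                     "classes (earlier class wins)", name, int(conflict.sum()))
        return mask, {"assigned": int(mask.sum()),
                      "conflicts": int(conflict.sum()), "source": "sar"}

    def predict(self) -> LandCoverMap:
        """The fitted land-cover map (the estimator maps the scene it was
        fitted on; there is no separate inference input)."""
        if not hasattr(self, "map_"):
            raise ValueError("classifier is not fitted")
        return self.map_
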