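"""Pre-classification filtering (Masking Phases I and II).

Phase I intersects strict spectral-threshold rules (band or index
comparisons) with the pool of still-unassigned pixels; Phase II intersects
the result with ancillary spatial constraints: buffers around points or
lines, containment in polygons, elevation caps, and ordering dependencies
on previously mapped classes.  Rules within a class combine by logical
AND, so masking is monotone (adding a rule never grows the candidate set)
and Phase-I output is independent of rule order.

Thresholds can also be *derived*: per-class layer signatures (mean/SD) are
computed from sample pixels, and :func:`suggest_threshold` returns the
loosest strict threshold that retains every target-class sample on a
layer, erring on the side of commission rather than omission.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, MaskRule
from .geo import RasterGrid, VectorLayer, rasterize_mask
from .indices import BAND_NAMES, IndexStack

log = logging.getLogger("ecoextent")


@dataclass
class CandidateMask:
    """Boolean candidate raster plus the provenance of how it was cut."""

    mask: np.ndarray
    rules: list[str] = field(default_factory=list)
    retained: int = 0
    removed: int = 0

    def __post_init__(self) -> None:
        self.retained = int(self.mask.sum())


def resolve_layer(name: str, composite_bands: RasterGrid,
                  index_stack: IndexStack | None) -> np.ndarray:
    """Band from the composite or layer from the index stack, as floats."""
    if name in BAND_NAMES:
        return np.asarray(composite_bands.band(name), dtype=float)
    if index_stack is not None and name in index_stack:
        return np.asarray(index_stack[name].values, dtype=float)
    raise ConfigError(f"rule references layer {name!r} which is neither a "
                      f"band nor a computed index")


# ---------------------------------------------------------------------------
# Signature analysis and threshold suggestion
# ---------------------------------------------------------------------------

def extract_layer_values(samples: pd.DataFrame, composite_bands: RasterGrid,
                         index_stack: IndexStack | None,
                         layers) -> pd.DataFrame:
    """Per-sample-pixel layer values: ``samples`` carries (row, col,
    class_name); the result adds one column per requested layer."""
    out = samples[["row", "col", "class_name"]].copy()
    rr = samples["row"].to_numpy()
    cc = samples["col"].to_numpy()
    for layer in layers:
        out[layer] = resolve_layer(layer, composite_bands, index_stack)[rr, cc]
    return out


def derive_signatures(samples: pd.DataFrame, composite_bands: RasterGrid,
                      index_stack: IndexStack | None = None,
                      layers=None) -> pd.DataFrame:
    """Mean and SD per class per layer from sample pixels.

    Returns a frame indexed by class with MultiIndex columns
    ``(layer, 'mean'|'sd')``; single-pixel classes get SD 0.
    """
    if layers is None:
        layers = list(BAND_NAMES) + (index_stack.names if index_stack else [])
    counts = samples.groupby("class_name").size()
    empty = [c for c in counts.index if counts[c] == 0]
    if samples.empty or empty:
        raise ValueError(f"classes without sample pixels: {empty or 'all'}")
    values = extract_layer_values(samples, composite_bands, index_stack, layers)
    grouped = values.groupby("class_name")[list(layers)]
    sig = pd.concat({"mean": grouped.mean(), "sd": grouped.std(ddof=0)}, axis=1)
    return sig.swaplevel(axis=1).sort_index(axis=1)


def suggest_threshold(sample_values: pd.DataFrame, target_class: str,
                      layer: str, margin: float = 1e-6) -> MaskRule:
    """Loosest strict threshold on ``layer`` retaining 100% of the target
    class's sample pixels.

    The comparator points toward the target's side of the layer
    distribution (``>`` when the target mean exceeds the pooled mean of the
    other classes).  If the layer shows no separation the rule is returned
    flagged non-discriminative with a warning.
    """
    if target_class not in set(sample_values["class_name"]):
        raise ValueError(f"target class {target_class!r} absent from samples")
    vals = sample_values[[layer, "class_name"]].dropna()
    target = vals.loc[vals.class_name == target_class, layer].to_numpy()
    others = vals.loc[vals.class_name != target_class, layer].to_numpy()
    note = ""
    if others.size == 0 or np.ptp(vals[layer].to_numpy()) < 1e-12 or \
            abs(target.mean() - others.mean()) < 1e-12:
        warnings.warn(f"layer {layer!r} does not discriminate "
                      f"{target_class!r} from the other classes", stacklevel=2)
        note = "non-discriminative"
    if others.size and target.mean() < others.mean():
        op, threshold = "<", float(target.max()) + margin
    else:
        op, threshold = ">", float(target.min()) - margin
    return MaskRule("spectral", layer=layer, op=op, threshold=threshold, note=note)


# ---------------------------------------------------------------------------
# Phase I / II application
# ---------------------------------------------------------------------------

def apply_phase1(composite_bands: RasterGrid, index_stack: IndexStack | None,
                 rules, available: np.ndarray) -> CandidateMask:
    """AND of all spectral rules over the currently available pixels."""
    mask = np.asarray(available, bool).copy()
    before = int(mask.sum())
    applied = []
    for rule in rules:
        if rule.kind != "spectral":
            raise ConfigError(f"phase I accepts spectral rules only, got "
                              f"{rule.describe()}")
        layer = resolve_layer(rule.layer, composite_bands, index_stack)
        with np.errstate(invalid="ignore"):
            ok = layer > rule.threshold if rule.op == ">" else layer < rule.threshold
        ok &= ~np.isnan(layer)
        mask &= ok
        applied.append(rule.describe())
    out = CandidateMask(mask, rules=applied, removed=before - int(mask.sum()))
    log.info("phase I (%s): retained %d / removed %d",
             "; ".join(applied) or "no rules", out.retained, out.removed)
    return out


def apply_phase2(candidate: CandidateMask, rules,
                 ancillary: dict[str, VectorLayer] | None = None,
                 dem: RasterGrid | None = None,
                 mapped_classes=(), grid: RasterGrid | None = None) -> CandidateMask:
    """Intersect Phase-I candidates with ancillary spatial constraints.

    Buffers and polygon containment use the pixel-center test on the
    working ``grid``; ``after_class_removed`` is an ordering check only —
    the named class must already be mapped (its pixels are then guaranteed
    to be out of the pool)."""
    ancillary = ancillary or {}
    mask = candidate.mask.copy()
    before = int(mask.sum())
    applied = list(candidate.rules)
    for rule in rules:
        if rule.kind != "spatial":
            raise ConfigError(f"phase II accepts spatial rules only, got "
                              f"{rule.describe()}")
        if rule.constraint == "after_class_removed":
            if rule.layer not in mapped_classes:
                raise ConfigError(
                    f"rule '{rule.describe()}' requires class {rule.layer!r} "
                    f"to be mapped first (mapped: {sorted(mapped_classes)})")
        elif rule.constraint == "elevation_below":
            if dem is None:
                raise ConfigError(f"rule '{rule.describe()}' needs a DEM")
            mask &= np.asarray(dem.values, float) < rule.cap_m
        else:  # within_buffer / within_polygons
            layer = ancillary.get(rule.layer)
            if layer is None:
                raise ConfigError(f"rule '{rule.describe()}' needs missing "
                                  f"ancillary layer {rule.layer!r}")
            if grid is None:
                grid = dem
            if grid is None:
                raise ConfigError("phase II needs a reference grid")
            radius = rule.radius_m if rule.constraint == "within_buffer" else 0.0
            mask &= rasterize_mask(layer.geometries, grid, buffer=radius)
        applied.append(rule.describe())
    out = CandidateMask(mask, rules=applied, removed=before - int(mask.sum()))
    log.info("phase II: retained %d / removed %d", out.retained, out.removed)
    return out
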