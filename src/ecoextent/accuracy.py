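"""Stratified validation sampling, error matrices and map accuracy
statistics.

Accuracy assessment follows the equal-weight stratified design: the same
number of random pixels per mapped class (50 by default, 500 for a
10-class map), each with a single-pixel 30 m x 30 m footprint, compared
against reference labels in an error matrix.  From the matrix come overall
accuracy (trace/n), per-class user's accuracy (1 - commission), producer's
accuracy (1 - omission) and Portmanteau accuracy — the overall accuracy of
the matrix collapsed to class-versus-rest — plus 95% confidence intervals
(Wilson score by default, Wald available).

Area summaries convert class pixel counts to km^2 (a 30-m pixel is
0.0009 km^2) and support per-class comparisons between maps or against
published extents.  An area-weighted variant of the accuracy estimators
(good practice for unequal strata) is available but off by default, since
the equal-weight design is what the assessment reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .config import NODATA_CODE, UNCLASSIFIED
from .classify import LandCoverMap

log = logging.getLogger("ecoextent")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def stratified_sample(lc_map: LandCoverMap, n_per_class: int = 50,
                      seed: int = 0) -> pd.DataFrame:
    """Equal-weight stratified random pixel sample of the mapped classes.

    Uniform without replacement within each stratum; classes with fewer
    pixels than ``n_per_class`` contribute all of them (logged as a
    shortfall).  Returns (row, col, x, y, map_label) — one 30 m x 30 m
    footprint per sample.
    """
    values = lc_map.values
    present = [c for c in lc_map.legend.codes if (values == c).any()]
    if not present:
        raise ValueError("map contains no mapped class pixels")
    rng = np.random.default_rng(seed)
    records = []
    for code in present:
        rr, cc = np.nonzero(values == code)
        take = min(n_per_class, rr.size)
        if take < n_per_class:
            log.warning("stratum %d has only %d pixels (wanted %d)",
                        code, rr.size, n_per_class)
        pick = rng.choice(rr.size, size=take, replace=False)
        x, y = lc_map.grid.transform.xy(rr[pick], cc[pick])
        for r, c, xi, yi in zip(rr[pick], cc[pick], x, y):
            records.append((int(r), int(c), float(xi), float(yi), int(code)))
    df = pd.DataFrame(records, columns=["row", "col", "x", "y", "map_label"])
    return df.sort_values(["map_label", "row", "col"]).reset_index(drop=True)


def label_from_reference(samples: pd.DataFrame,
                         reference: LandCoverMap | np.ndarray) -> pd.DataFrame:
    """Attach reference labels from a truth raster (the test-time stand-in
    for visual interpretation; externally interpreted labels arrive as a
    CSV with the same columns)."""
    values = reference.values if hasattr(reference, "values") else np.asarray(reference)
    out = samples.copy()
    out["ref_label"] = values[out["row"].to_numpy(), out["col"].to_numpy()].astype(int)
    return out


# ---------------------------------------------------------------------------
# Error matrix
# ---------------------------------------------------------------------------

@dataclass
class ErrorMatrix:
    """Square count matrix, reference classes on rows, map classes on
    columns."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise ValueError("error matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.table.to_numpy().sum())

    @property
    def labels(self) -> list:
        return list(self.table.index)

    def count(self, ref, mapped) -> int:
        return int(self.table.loc[ref, mapped])


def build_error_matrix(samples: pd.DataFrame, labels=None) -> ErrorMatrix:
    """Cross-tabulate reference against map labels.

    ``labels`` fixes the class set (and order); samples carrying a label
    outside it are an error.
    """
    if "ref_label" not in samples or "map_label" not in samples:
        raise ValueError("samples need both ref_label and map_label")
    ref = samples["ref_label"]
    mapped = samples["map_label"]
    if labels is None:
        labels = sorted(set(ref) | set(mapped))
    labels = list(labels)
    stray = (set(ref) | set(mapped)) - set(labels)
    if stray:
        raise ValueError(f"labels outside the legend: {sorted(stray)}")
    table = pd.crosstab(ref, mapped).reindex(index=labels, columns=labels,
                                             fill_value=0)
    table.index.name, table.columns.name = "reference", "map"
    return ErrorMatrix(table)


# ---------------------------------------------------------------------------
# Accuracy statistics
# ---------------------------------------------------------------------------

def _ci(k: int, n: int, level: float, method: str) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(k, n, alpha=1 - level,
                                method="wilson" if method == "wilson" else "normal")
    return float(lo), float(hi)


def portmanteau_accuracy(matrix: ErrorMatrix, label) -> float:
    """Overall accuracy of the matrix collapsed to ``label`` vs all other
    classes combined: (TP + TN) / n."""
    m = matrix.table.to_numpy(dtype=float)
    i = matrix.labels.index(label)
    tp = m[i, i]
    tn = m.sum() - m[i, :].sum() - m[:, i].sum() + m[i, i]
    return (tp + tn) / m.sum()


def accuracy_stats(matrix: ErrorMatrix, ci_level: float = 0.95,
                   ci_method: str = "wilson") -> dict:
    """Overall, per-class user's/producer's and Portmanteau accuracies
    with confidence intervals.

    Statistics are stored as proportions at full precision (rounding to
    the displayed percent is left to the caller); a zero marginal makes
    the corresponding statistic NaN (undefined), never 0.
    """
    m = matrix.table.to_numpy(dtype=float)
    n = m.sum()
    if n <= 0:
        raise ValueError("empty error matrix")
    diag = np.diag(m)
    row_tot = m.sum(axis=1)  # reference totals
    col_tot = m.sum(axis=0)  # map totals
    overall = diag.sum() / n
    per_class = {}
    for i, label in enumerate(matrix.labels):
        users = diag[i] / col_tot[i] if col_tot[i] > 0 else float("nan")
        producers = diag[i] / row_tot[i] if row_tot[i] > 0 else float("nan")
        per_class[label] = {
            "users": users,
            "producers": producers,
            "portmanteau": portmanteau_accuracy(matrix, label),
            "users_ci": _ci(int(diag[i]), int(col_tot[i]), ci_level, ci_method)
            if col_tot[i] > 0 else (float("nan"),) * 2,
            "producers_ci": _ci(int(diag[i]), int(row_tot[i]), ci_level, ci_method)
            if row_tot[i] > 0 else (float("nan"),) * 2,
        }
    return {
        "overall": overall,
        "overall_ci": _ci(int(diag.sum()), int(n), ci_level, ci_method),
        "n": int(n),
        "per_class": per_class,
    }


def overall_map_accuracy(lc_map: LandCoverMap,
                         truth: np.ndarray | LandCoverMap,
                         ignore_gaps: bool = False) -> float:
    """Wall-to-wall fraction of pixels whose map code equals the truth
    code; unclassified and gap pixels count as wrong unless
    ``ignore_gaps``."""
    truth_values = truth.values if hasattr(truth, "values") else np.asarray(truth)
    mapv = lc_map.values
    keep = np.ones(mapv.shape, bool)
    if ignore_gaps:
        keep = mapv != NODATA_CODE
    return float((mapv[keep] == truth_values[keep]).mean())


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

@dataclass
class AreaSummary:
    """Per-class pixel counts and areas; km^2 = count x pixel area
    exactly (0.0009 km^2 for 30-m pixels)."""

    table: pd.DataFrame  # index: class name; columns: pixels, km2
    pixel_size: float = 30.0

    def km2(self, name: str) -> float:
        return float(self.table.loc[name, "km2"])

    @classmethod
    def from_km2(cls, areas: dict[str, float], pixel_size: float = 30.0) -> "AreaSummary":
        """Summary built directly from published per-class areas."""
        px_area = (pixel_size ** 2) / 1e6
        table = pd.DataFrame({
            "pixels": {k: v / px_area for k, v in areas.items()},
            "km2": dict(areas),
        })
        return cls(table, pixel_size)

    @property
    def total_km2(self) -> float:
        return float(self.table["km2"].sum())


def class_areas(lc_map: LandCoverMap) -> AreaSummary:
    ps = lc_map.grid.pixel_size
    px_area = lc_map.grid.pixel_area_km2
    rows = {}
    for name in lc_map.legend.names:
        count = int(lc_map.class_mask(name).sum())
        rows[name] = {"pixels": count, "km2": count * px_area}
    rows["unclassified"] = {
        "pixels": int((lc_map.values == UNCLASSIFIED).sum()),
        "km2": int((lc_map.values == UNCLASSIFIED).sum()) * px_area}
    return AreaSummary(pd.DataFrame(rows).T, ps)


def compare_areas(a: AreaSummary, b: AreaSummary, name: str) -> float:
    """Per-class extent difference a - b in km^2 (positive: a larger)."""
    if a.pixel_size != b.pixel_size:
        raise ValueError("area comparison requires matching pixel sizes")
    return a.km2(name) - b.km2(name)
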