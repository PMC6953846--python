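"""Class legends, masking rules and pipeline configuration.

Two built-in country profiles (``liberia`` and ``gabon``) encode the
default 10-class legends, the published spectral/spatial masking
thresholds, the per-class predictor categories and the classifier settings
(100 trees, 50 validation samples per class).  A YAML file can override
any of it; unspecified fields fall back to the profile defaults and the
fully resolved configuration is echoed to the log.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import yaml

from .indices import BAND_NAMES, INDEX_CATEGORIES, INDEX_NAMES

log = logging.getLogger("ecoextent")


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


# ---------------------------------------------------------------------------
# Legend
# ---------------------------------------------------------------------------

UNCLASSIFIED = 0  #: code for pixels never assigned by any class iteration
NODATA_CODE = 255  #: sentinel for gap pixels in written category rasters


@dataclass(frozen=True)
class LegendEntry:
    code: int
    name: str
    color: tuple[int, int, int]
    countries: tuple[str, ...] = ("liberia", "gabon")


@dataclass
class ClassLegend:
    """Ordered class list; the order *is* the sequential-classification
    order, so earlier classes claim pixels first."""

    entries: list[LegendEntry]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ConfigError("legend codes must be unique")
        if any(c < 1 for c in codes):
            raise ConfigError("legend codes must be >= 1 (0 is unclassified)")

    @property
    def codes(self) -> list[int]:
        return [e.code for e in self.entries]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def code_of(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.code
        raise ConfigError(f"unknown class name {name!r}")

    def name_of(self, code: int) -> str:
        for e in self.entries:
            if e.code == code:
                return e.name
        raise ConfigError(f"unknown class code {code}")

    def colormap(self) -> dict[int, tuple[int, int, int]]:
        cm = {UNCLASSIFIED: (220, 220, 220)}
        cm.update({e.code: e.color for e in self.entries})
        return cm


_COLORS = {
    "water_bodies": (31, 119, 255),
    "mangroves_wetlands": (128, 0, 160),
    "artificial_surfaces": (220, 40, 40),
    "barren_land": (180, 150, 110),
    "ecosystem_complex": (255, 230, 130),
    "woody_crops": (200, 160, 40),
    "tree_covered_dense": (0, 90, 0),
    "tree_covered_open": (60, 160, 60),
    "mixed_vegetation": (140, 200, 80),
    "grasslands": (230, 220, 60),
    "flooded_forest_permanent": (0, 160, 180),
    "flooded_forest_seasonal": (120, 210, 220),
}

LIBERIA_CLASS_ORDER = [
    "water_bodies", "mangroves_wetlands", "artificial_surfaces", "barren_land",
    "ecosystem_complex", "woody_crops", "tree_covered_dense",
    "tree_covered_open", "mixed_vegetation", "grasslands",
]

GABON_CLASS_ORDER = [
    "water_bodies", "mangroves_wetlands", "artificial_surfaces", "barren_land",
    "woody_crops", "flooded_forest_permanent", "flooded_forest_seasonal",
    "tree_covered_dense", "tree_covered_open", "grasslands",
]


def default_legend(profile: str) -> ClassLegend:
    order = {"liberia": LIBERIA_CLASS_ORDER, "gabon": GABON_CLASS_ORDER}.get(profile)
    if order is None:
        raise ConfigError(f"unknown country profile {profile!r}")
    return ClassLegend([
        LegendEntry(i + 1, name, _COLORS[name], (profile,))
        for i, name in enumerate(order)
    ])


# ---------------------------------------------------------------------------
# Masking rules
# ---------------------------------------------------------------------------

SPATIAL_CONSTRAINTS = ("within_buffer", "within_polygons", "elevation_below",
                       "after_class_removed")


@dataclass(frozen=True)
class MaskRule:
    """One pre-classification filter.

    Spectral rules compare a band or index layer against a threshold with a
    strict inequality (``>`` or ``<``, exactly as published).  Spatial rules
    constrain candidates with ancillary geometry or the DEM:

    - ``within_buffer``: pixel center within ``radius_m`` of the named
      point/line layer;
    - ``within_polygons``: pixel center inside the named polygon layer;
    - ``elevation_below``: DEM below ``cap_m`` metres;
    - ``after_class_removed``: ordering dependency — the named class must
      already have been mapped and removed from the pool.
    """

    kind: str  # "spectral" | "spatial"
    layer: str = ""
    op: str = ">"
    threshold: float = 0.0
    constraint: str = ""
    radius_m: float = 0.0
    cap_m: float = 0.0
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind == "spectral":
            if self.layer not in BAND_NAMES and self.layer not in INDEX_NAMES:
                raise ConfigError(f"spectral rule references undefined layer "
                                  f"{self.layer!r}")
            if self.op not in (">", "<"):
                raise ConfigError(f"comparator must be '>' or '<', got {self.op!r}")
        elif self.kind == "spatial":
            if self.constraint not in SPATIAL_CONSTRAINTS:
                raise ConfigError(f"unknown spatial constraint {self.constraint!r}")
            if self.constraint == "within_buffer" and self.radius_m <= 0:
                raise ConfigError("within_buffer requires a positive radius")
        else:
            raise ConfigError(f"rule kind must be spectral or spatial, got {self.kind!r}")

    def describe(self) -> str:
        if self.kind == "spectral":
            return f"{self.layer} {self.op} {self.threshold:g}"
        parts = [self.constraint, self.layer]
        if self.constraint == "within_buffer":
            parts.append(f"{self.radius_m:g} m")
        if self.constraint == "elevation_below":
            parts.append(f"{self.cap_m:g} m")
        return " ".join(p for p in parts if p)


def spectral(layer: str, op: str, threshold: float) -> MaskRule:
    return MaskRule("spectral", layer=layer, op=op, threshold=threshold)


def within_buffer(layer: str, radius_m: float) -> MaskRule:
    return MaskRule("spatial", layer=layer, constraint="within_buffer",
                    radius_m=radius_m)


def within_polygons(layer: str) -> MaskRule:
    return MaskRule("spatial", layer=layer, constraint="within_polygons")


def elevation_below(cap_m: float) -> MaskRule:
    return MaskRule("spatial", layer="dem", constraint="elevation_below",
                    cap_m=cap_m)


def after_class_removed(class_name: str) -> MaskRule:
    return MaskRule("spatial", layer=class_name, constraint="after_class_removed")


@dataclass
class ClassSpec:
    """Everything the sequential classifier needs for one class: masking
    rules (Phase I spectral, Phase II spatial), the predictor layers its
    random forest sees, and post-classification verification rules."""

    name: str
    phase1: list[MaskRule] = field(default_factory=list)
    phase2: list[MaskRule] = field(default_factory=list)
    predictor_categories: list[str] = field(default_factory=list)
    slope_cap_deg: float | None = None  # knowledge-based verification
    sar_derived: bool = False  # mapped from the SAR flood mask, not by RF

    @property
    def predictors(self) -> list[str]:
        names = list(BAND_NAMES)
        for cat in self.predictor_categories:
            try:
                names.extend(INDEX_CATEGORIES[cat])
            except KeyError:
                raise ConfigError(f"unknown predictor category {cat!r}") from None
        return names


# Settlement buffer radius: no published value exists; 2,000 m is the
# package default and a prominent calibration knob (see docs/methods.md).
DEFAULT_SETTLEMENT_BUFFER_M = 2000.0
DEFAULT_SHORE_BUFFER_M = 1000.0
DEFAULT_SLOPE_CAP_DEG = 10.0

def _liberia_specs() -> dict[str, ClassSpec]:
    return {s.name: s for s in [
        ClassSpec("water_bodies",
                  phase1=[spectral("MNDWI", ">", -0.2)],
                  predictor_categories=["water_wetland"],
                  slope_cap_deg=DEFAULT_SLOPE_CAP_DEG),
        ClassSpec("mangroves_wetlands",
                  phase1=[spectral("MNDWI", ">", -0.35), spectral("NDVI", ">", 0.3)],
                  predictor_categories=["water_wetland", "green_vegetation"],
                  slope_cap_deg=DEFAULT_SLOPE_CAP_DEG),
        ClassSpec("artificial_surfaces",
                  phase1=[spectral("B6", ">", 0.25), spectral("NDVI", "<", 0.45)],
                  phase2=[within_buffer("settlements", DEFAULT_SETTLEMENT_BUFFER_M)],
                  predictor_categories=["barren_builtup"]),
        ClassSpec("barren_land",
                  phase1=[spectral("B6", ">", 0.25), spectral("NDVI", "<", 0.45)],
                  predictor_categories=["barren_builtup"]),
        ClassSpec("ecosystem_complex",
                  phase1=[spectral("R65", ">", 0.8)],
                  phase2=[within_buffer("shoreline", DEFAULT_SHORE_BUFFER_M)],
                  predictor_categories=["band_ratios"]),
        ClassSpec("woody_crops",
                  phase1=[spectral("R65", ">", 0.6)],
                  phase2=[within_polygons("concessions")],
                  predictor_categories=["green_vegetation", "band_ratios"]),
        ClassSpec("tree_covered_dense",
                  phase1=[spectral("B6", ">", 0.14)],
                  predictor_categories=["green_vegetation", "band_ratios"]),
        ClassSpec("tree_covered_open",
                  phase1=[spectral("B5", ">", 0.28)],
                  predictor_categories=["green_vegetation", "band_ratios"]),
        ClassSpec("mixed_vegetation",
                  predictor_categories=["green_vegetation", "band_ratios"]),
        ClassSpec("grasslands",
                  phase1=[spectral("R65", ">", 0.8), spectral("NDVI", "<", 0.4)],
                  predictor_categories=["green_vegetation", "band_ratios"]),
    ]}


def _gabon_specs() -> dict[str, ClassSpec]:
    return {s.name: s for s in [
        ClassSpec("water_bodies",
                  phase1=[spectral("MNDWI", ">", -0.23)],
                  predictor_categories=["water_wetland"],
                  slope_cap_deg=DEFAULT_SLOPE_CAP_DEG),
        ClassSpec("mangroves_wetlands",
                  phase1=[spectral("MNDWI", ">", -0.3), spectral("NDVI", ">", 0.35)],
                  phase2=[elevation_below(95.0)],
                  predictor_categories=["water_wetland", "green_vegetation"],
                  slope_cap_deg=DEFAULT_SLOPE_CAP_DEG),
        ClassSpec("artificial_surfaces",
                  phase1=[spectral("UI", ">", -0.568)],
                  phase2=[within_buffer("settlements", DEFAULT_SETTLEMENT_BUFFER_M)],
                  predictor_categories=["barren_builtup"]),
        ClassSpec("barren_land",
                  phase1=[spectral("UI", ">", -0.568)],
                  phase2=[after_class_removed("artificial_surfaces")],
                  predictor_categories=["barren_builtup"]),
        ClassSpec("woody_crops",
                  phase1=[spectral("R65", ">", 0.6)],
                  phase2=[within_polygons("concessions")],
                  predictor_categories=["green_vegetation", "band_ratios"]),
        ClassSpec("flooded_forest_permanent", sar_derived=True),
        ClassSpec("flooded_forest_seasonal", sar_derived=True),
        ClassSpec("tree_covered_dense",
                  phase2=[within_polygons("forest_extent")],
                  predictor_categories=["green_vegetation", "band_ratios"]),
        ClassSpec("tree_covered_open",
                  predictor_categories=["green_vegetation", "band_ratios"]),
        ClassSpec("grasslands",
                  phase1=[spectral("R65", ">", 0.59), spectral("NDVI", "<", 0.45)],
                  predictor_categories=["green_vegetation", "band_ratios"]),
    ]}


# ---------------------------------------------------------------------------
# QA dialect, classifier settings, top-level config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QADialect:
    """Bit positions of the flags removed by cloud screening.  The default
    is the synthetic dialect (bit0 cloud, bit1 shadow, bit2 fill); a Landsat
    Collection-style mapping can be supplied in config."""

    cloud_bit: int = 0
    shadow_bit: int = 1
    fill_bit: int = 2

    @property
    def flag_mask(self) -> int:
        return (1 << self.cloud_bit) | (1 << self.shadow_bit) | (1 << self.fill_bit)


@dataclass
class ClassifierConfig:
    """Random-forest settings: 100 majority-vote trees; each split draws a
    random predictor subset of size sqrt(n_predictors)."""

    n_trees: int = 100
    max_features: str | float = "sqrt"
    min_training_pixels: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")


@dataclass
class CompositeWindow:
    """Scene-selection window: ``seasonal`` keeps one season across the
    central year +/- one season-year (Liberia-style); ``annual`` keeps all
    scenes of the central year +/- one year (Gabon-style)."""

    mode: str = "seasonal"  # "seasonal" | "annual"
    central_year: int = 2015
    season: str = "dry"

    @property
    def years(self) -> tuple[int, int, int]:
        return (self.central_year - 1, self.central_year, self.central_year + 1)


@dataclass
class PipelineConfig:
    profile: str = "liberia"
    legend: ClassLegend = None
    class_specs: dict[str, ClassSpec] = None
    window: CompositeWindow = None
    classifier: ClassifierConfig = None
    qa: QADialect = field(default_factory=QADialect)
    n_validation_per_class: int = 50
    seed: int = 0
    index_eps: float = 1e-10

    def __post_init__(self) -> None:
        if self.legend is None:
            self.legend = default_legend(self.profile)
        if self.class_specs is None:
            self.class_specs = {"liberia": _liberia_specs,
                                "gabon": _gabon_specs}[self.profile]()
        if self.window is None:
            self.window = CompositeWindow(
                mode="seasonal" if self.profile == "liberia" else "annual")
        if self.classifier is None:
            self.classifier = ClassifierConfig(seed=self.seed)
        for name in self.legend.names:
            if name not in self.class_specs:
                raise ConfigError(f"legend class {name!r} has no ClassSpec")

    def ordered_specs(self) -> list[ClassSpec]:
        return [self.class_specs[name] for name in self.legend.names]


def load_config(path_or_mapping) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file or mapping.

    The mapping selects a country profile and may override seeds, window,
    classifier settings and per-class rules, e.g.::

        profile: liberia
        seed: 7
        classes:
          water_bodies:
            phase1: [{layer: MNDWI, op: ">", threshold: -0.25}]
    """
    if isinstance(path_or_mapping, dict):
        raw = copy.deepcopy(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")

    profile = raw.get("profile", "liberia")
    cfg = PipelineConfig(
        profile=profile,
        seed=int(raw.get("seed", 0)),
        n_validation_per_class=int(raw.get("n_validation_per_class", 50)),
    )
    if "window" in raw:
        cfg.window = CompositeWindow(**raw["window"])
    if "classifier" in raw:
        cc = dict(raw["classifier"])
        cc.setdefault("seed", cfg.seed)
        cfg.classifier = ClassifierConfig(**cc)
    if "qa" in raw:
        cfg.qa = QADialect(**raw["qa"])
    for name, over in (raw.get("classes") or {}).items():
        if name not in cfg.class_specs:
            raise ConfigError(f"unknown class name {name!r} in config")
        spec = cfg.class_specs[name]
        if "phase1" in over:
            spec.phase1 = [MaskRule("spectral", **r) for r in over["phase1"]]
        if "phase2" in over:
            spec.phase2 = [MaskRule("spatial", **r) for r in over["phase2"]]
        if "predictor_categories" in over:
            spec.predictor_categories = list(over["predictor_categories"])
            spec.predictors  # validate categories eagerly
        if "slope_cap_deg" in over:
            spec.slope_cap_deg = over["slope_cap_deg"]
    _echo(cfg)
    return cfg


def _echo(cfg: PipelineConfig) -> None:
    log.info("resolved config: profile=%s seed=%d window=%s trees=%d",
             cfg.profile, cfg.seed, cfg.window, cfg.classifier.n_trees)
    for spec in cfg.ordered_specs():
        rules = "; ".join(r.describe() for r in spec.phase1 + spec.phase2) or "none"
        log.info("  class %-26s rules: %s", spec.name, rules)
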