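import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ecoextent as ee

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec_small():
    return ee.SceneCollectionSpec(shape=(100, 100), seed=7)


@pytest.fixture(scope="session")
def library():
    return ee.default_library()


@pytest.fixture(scope="session")
def landscape(spec_small):
    return ee.generate_truth_map(spec_small, "liberia")


@pytest.fixture(scope="session")
def gabon_landscape(spec_small):
    return ee.generate_truth_map(spec_small, "gabon")


@pytest.fixture(scope="session")
def scenes(landscape, library, spec_small):
    return ee.generate_scenes(landscape, library, spec_small)


@pytest.fixture(scope="session")
def composite(scenes):
    cfg = ee.PipelineConfig(profile="liberia", seed=7)
    masked = [ee.mask_clouds(s, cfg.qa) for s in scenes]
    return ee.median_composite(ee.select_window(masked, cfg.window))


@pytest.fixture(scope="session")
def index_stack(composite):
    return ee.compute_stack(composite.bands)


@pytest.fixture(scope="session")
def zero_noise(spec_small, library):
    """Single cloud-free dry scene with no noise: reflectance is exactly
    the library mean per class."""
    spec = ee.SceneCollectionSpec(shape=(100, 100), seed=7, noise_sd=0.0,
                                  dates=[("2015-12-15", "dry")])
    land = ee.generate_truth_map(spec, "liberia")
    scene = ee.generate_scenes(land, library, spec)[0]
    comp = ee.median_composite([scene])
    stack = ee.compute_stack(comp.bands)
    return land, comp, stack


@pytest.fixture(scope="session")
def zero_noise_gabon(spec_small, library):
    spec = ee.SceneCollectionSpec(shape=(100, 100), seed=7, noise_sd=0.0,
                                  dates=[("2015-12-15", "dry")])
    land = ee.generate_truth_map(spec, "gabon")
    scene = ee.generate_scenes(land, library, spec)[0]
    comp = ee.median_composite([scene])
    stack = ee.compute_stack(comp.bands)
    return land, comp, stack
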