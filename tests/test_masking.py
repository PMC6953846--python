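import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point

import ecoextent as ee
from ecoextent.config import (ConfigError, after_class_removed, elevation_below,
                              spectral, within_buffer)
from ecoextent.indices import BAND_NAMES
from ecoextent.masking import apply_phase1, apply_phase2, extract_layer_values


class TestSignatures:
    def test_zero_noise_signatures_equal_library_means(self, zero_noise, library):
        land, comp, stack = zero_noise
        samples = ee.sample_training(land, n_per_class=40, seed=1)
        sig = ee.derive_signatures(samples, comp.bands, stack, layers=BAND_NAMES)
        for name in land.legend.names:
            for b in BAND_NAMES:
                assert sig.loc[name, (b, "mean")] == pytest.approx(
                    library[name].means[b], abs=1e-12)
                assert sig.loc[name, (b, "sd")] == pytest.approx(0.0, abs=1e-12)

    def test_single_pixel_class_gets_zero_sd(self, zero_noise):
        _, comp, stack = zero_noise
        samples = pd.DataFrame({"row": [3], "col": [3], "class_name": ["only"]})
        sig = ee.derive_signatures(samples, comp.bands, stack, layers=["B5"])
        assert sig.loc["only", ("B5", "sd")] == 0.0

    def test_noisy_signature_mean_within_standard_error(self, composite, index_stack,
                                                        landscape, library):
        n = 500
        samples = ee.sample_training(landscape, n_per_class=n, seed=9)
        dense = samples[samples.class_name == "tree_covered_dense"]
        sig = ee.derive_signatures(dense, composite.bands, index_stack,
                                   layers=["B6"])
        sd = 0.01  # generator noise SD; composite of 5 scenes shrinks it
        assert sig.loc["tree_covered_dense", ("B6", "mean")] == pytest.approx(
            library["tree_covered_dense"].means["B6"], abs=3 * sd / np.sqrt(n))


class TestSuggestThreshold:
    def _values(self, target, others):
        rows = [{"row": 0, "col": 0, "class_name": "t", "L": v} for v in target]
        rows += [{"row": 0, "col": 0, "class_name": "o", "L": v} for v in others]
        df = pd.DataFrame(rows)
        df["MNDWI"] = df["L"]
        return df

    def test_retains_all_target_samples_on_high_side(self):
        df = self._values([0.1, 0.3, 0.5], [-0.5, -0.2])
        rule = ee.suggest_threshold(df, "t", "MNDWI")
        assert rule.op == ">"
        assert rule.threshold <= 0.1
        assert all(v > rule.threshold for v in [0.1, 0.3, 0.5])

    def test_low_side_direction(self):
        df = self._values([0.1, 0.2], [0.8, 0.9])
        rule = ee.suggest_threshold(df, "t", "MNDWI")
        assert rule.op == "<" and rule.threshold >= 0.2

    def test_fully_separated_classes_are_excluded(self):
        rng = np.random.default_rng(0)
        df = self._values(rng.normal(0.5, 0.01, 200), rng.normal(-0.5, 0.01, 200))
        rule = ee.suggest_threshold(df, "t", "MNDWI")
        held_out = rng.normal(-0.5, 0.01, 500)
        assert not (held_out > rule.threshold).any()

    def test_identical_distributions_flagged(self):
        df = self._values([0.2, 0.2], [0.2, 0.2])
        with pytest.warns(UserWarning, match="discriminate"):
            rule = ee.suggest_threshold(df, "t", "MNDWI")
        assert rule.note == "non-discriminative"

    def test_missing_target_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            ee.suggest_threshold(self._values([0.1], [0.2]), "nope", "MNDWI")


class TestPhase1:
    def _tiny(self, mndwi_values):
        b3 = np.full((1, len(mndwi_values)), 0.1)
        b6 = b3 * (1 - np.asarray(mndwi_values)) / (1 + np.asarray(mndwi_values))
        arr = np.stack([np.full_like(b3, 0.2)] * 7)
        arr[BAND_NAMES.index("B3")] = b3
        arr[BAND_NAMES.index("B6")] = b6
        comp = ee.RasterGrid(arr, ee.Affine.from_origin(0, 30, 30),
                             band_names=list(BAND_NAMES))
        return comp, ee.compute_stack(comp)

    def test_water_rule_thresholds_exactly_as_printed(self):
        comp, stack = self._tiny([0.0, -0.3])
        cand = apply_phase1(comp, stack, [spectral("MNDWI", ">", -0.2)],
                            np.ones((1, 2), bool))
        assert cand.mask[0, 0] and not cand.mask[0, 1]

    def test_rules_combine_by_and(self, zero_noise):
        land, comp, stack = zero_noise
        rules = [spectral("MNDWI", ">", -0.35), spectral("NDVI", ">", 0.3)]
        cand = apply_phase1(comp.bands, stack, rules, np.ones(comp.bands.shape, bool))
        mang = land.class_mask("mangroves_wetlands")
        assert cand.mask[mang].all()
        water = land.class_mask("water_bodies")
        assert not cand.mask[water].any()  # NDVI rule cuts water

    def test_no_survivors_yields_empty_mask(self):
        comp, stack = self._tiny([-0.9, -0.8])
        cand = apply_phase1(comp, stack, [spectral("MNDWI", ">", 0.5)],
                            np.ones((1, 2), bool))
        assert cand.retained == 0 and not cand.mask.any()

    def test_monotone_and_order_invariant(self, zero_noise):
        _, comp, stack = zero_noise
        available = np.ones(comp.bands.shape, bool)
        r1, r2 = spectral("NDVI", ">", 0.3), spectral("B6", "<", 0.15)
        one = apply_phase1(comp.bands, stack, [r1], available)
        both = apply_phase1(comp.bands, stack, [r1, r2], available)
        swapped = apply_phase1(comp.bands, stack, [r2, r1], available)
        assert both.retained <= one.retained
        np.testing.assert_array_equal(both.mask, swapped.mask)

    def test_zero_omission_of_every_default_rule(self, zero_noise, zero_noise_gabon):
        """On a noise-free scene the published Phase-I rules retain 100%
        of each target class's pixels."""
        for (land, comp, stack), profile in [(zero_noise, "liberia"),
                                             (zero_noise_gabon, "gabon")]:
            cfg = ee.PipelineConfig(profile=profile)
            for spec in cfg.ordered_specs():
                if spec.sar_derived or not spec.phase1:
                    continue
                cand = apply_phase1(comp.bands, stack, spec.phase1,
                                    np.ones(comp.bands.shape, bool))
                target = land.class_mask(spec.name)
                assert cand.mask[target].all(), f"{profile}/{spec.name}"


class TestPhase2:
    def _grid(self):
        return ee.RasterGrid(np.zeros((10, 10)), ee.Affine.from_origin(0, 300, 30))

    def test_settlement_buffer_removes_distant_pixels(self):
        grid = self._grid()
        cand = ee.CandidateMask(np.ones((10, 10), bool))
        settlements = ee.VectorLayer([Point(15, 285)], "settlements")
        out = apply_phase2(cand, [within_buffer("settlements", 70.0)],
                           {"settlements": settlements}, grid=grid)
        assert out.mask[0, 0]
        assert not out.mask[9, 9]  # far corner, ~340 m away

    def test_shoreline_buffer_removes_inland_pixels(self):
        grid = self._grid()
        shoreline = ee.VectorLayer([LineString([(0, 0), (0, 300)])], "shoreline")
        cand = ee.CandidateMask(np.ones((10, 10), bool))
        out = apply_phase2(cand, [within_buffer("shoreline", 100.0)],
                           {"shoreline": shoreline}, grid=grid)
        # pixel centers at 15, 45, 75 m are inside; 105 m and beyond are not
        assert out.mask[:, :3].all() and not out.mask[:, 3:].any()

    def test_elevation_cap(self):
        dem = ee.RasterGrid(np.array([[50.0, 120.0]]), ee.Affine.from_origin(0, 30, 30))
        cand = ee.CandidateMask(np.ones((1, 2), bool))
        out = apply_phase2(cand, [elevation_below(95.0)], dem=dem)
        assert out.mask[0, 0] and not out.mask[0, 1]

    def test_after_class_removed_is_ordering_check(self):
        cand = ee.CandidateMask(np.ones((2, 2), bool))
        rule = after_class_removed("artificial_surfaces")
        out = apply_phase2(cand, [rule], mapped_classes={"artificial_surfaces"},
                           grid=self._grid())
        np.testing.assert_array_equal(out.mask, cand.mask)
        with pytest.raises(ConfigError, match="mapped first"):
            apply_phase2(cand, [rule], mapped_classes=set(), grid=self._grid())

    def test_missing_ancillary_layer_is_error(self):
        cand = ee.CandidateMask(np.ones((2, 2), bool))
        with pytest.raises(ConfigError, match="concessions"):
            apply_phase2(cand, [within_buffer("concessions", 10.0)], {},
                         grid=self._grid())
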