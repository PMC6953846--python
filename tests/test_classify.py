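import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import train_test_split

import ecoextent as ee
from ecoextent.classify import pixel_features
from ecoextent.config import ClassifierConfig
from ecoextent.masking import CandidateMask, apply_phase1


def _cloud(n=1000, sep=5.0, sd=1.0, seed=0, shuffle_labels=False):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack([rng.normal(0.0, sd, (half, 3)),
                   rng.normal(sep * sd, sd, (n - half, 3))])
    y = np.repeat([0, 1], [half, n - half])
    if shuffle_labels:
        y = rng.permutation(y)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["label"] = y
    return df


class TestBinaryRF:
    def test_separable_cloud_reaches_high_heldout_accuracy(self):
        df = _cloud(1000, sep=5.0)
        train, test = train_test_split(df, test_size=0.3, random_state=0,
                                       stratify=df.label)
        model = ee.train_binary_rf(train, ["a", "b", "c"], ClassifierConfig(seed=0))
        acc = (model.predict(test[["a", "b", "c"]].to_numpy())
               == test.label.to_numpy()).mean()
        assert acc >= 0.99

    def test_shuffled_labels_hit_chance_level(self):
        df = _cloud(2000, sep=5.0, shuffle_labels=True)
        train, test = train_test_split(df, test_size=0.3, random_state=1,
                                       stratify=df.label)
        model = ee.train_binary_rf(train, ["a", "b", "c"], ClassifierConfig(seed=1))
        acc = (model.predict(test[["a", "b", "c"]].to_numpy())
               == test.label.to_numpy()).mean()
        assert acc == pytest.approx(0.5, abs=0.05)

    def test_duplicate_rows_train_fine(self):
        df = pd.concat([_cloud(100)] * 3, ignore_index=True)
        ee.train_binary_rf(df, ["a", "b", "c"], ClassifierConfig(seed=0))

    def test_single_label_rejected(self):
        df = _cloud(100)
        df["label"] = 1
        with pytest.raises(ValueError, match="single label"):
            ee.train_binary_rf(df, ["a", "b", "c"], ClassifierConfig())

    def test_uses_100_trees_by_default(self):
        model = ee.train_binary_rf(_cloud(200), ["a", "b", "c"], ClassifierConfig())
        assert len(model.estimators_) == 100


class TestClassifyClass:
    def test_zero_noise_scene_recovers_water_exactly(self, zero_noise):
        land, comp, stack = zero_noise
        cfg = ee.PipelineConfig(profile="liberia")
        spec = cfg.class_specs["water_bodies"]
        training = ee.sample_training(land, 200, seed=3)
        available = ~comp.gap_mask
        cand = apply_phase1(comp.bands, stack, spec.phase1, available)
        mask, prov = ee.classify_class(comp.bands, stack, spec, cand, training,
                                       ClassifierConfig(seed=3))
        np.testing.assert_array_equal(mask, land.class_mask("water_bodies"))

    def test_empty_candidates_assign_nothing(self, zero_noise):
        land, comp, stack = zero_noise
        cfg = ee.PipelineConfig(profile="liberia")
        spec = cfg.class_specs["water_bodies"]
        training = ee.sample_training(land, 50, seed=3)
        cand = CandidateMask(np.zeros(comp.bands.shape, bool))
        mask, prov = ee.classify_class(comp.bands, stack, spec, cand, training,
                                       ClassifierConfig(seed=3))
        assert not mask.any() and "skipped" in prov

    def test_noncandidates_never_assigned(self, zero_noise):
        land, comp, stack = zero_noise
        cfg = ee.PipelineConfig(profile="liberia")
        spec = cfg.class_specs["water_bodies"]
        training = ee.sample_training(land, 200, seed=3)
        half = np.zeros(comp.bands.shape, bool)
        half[:, : comp.bands.shape[1] // 2] = True
        cand = apply_phase1(comp.bands, stack, spec.phase1, half)
        mask, _ = ee.classify_class(comp.bands, stack, spec, cand, training,
                                    ClassifierConfig(seed=3))
        assert not mask[~half].any()


class TestVerification:
    def test_steep_water_pixels_reverted(self):
        dem = ee.RasterGrid(np.outer(np.ones(10), np.arange(10) * 20.0),
                            ee.Affine.from_origin(0, 300, 30))
        mask = np.ones((10, 10), bool)
        out, reverted = ee.verify_class(mask, 10.0, dem)
        assert reverted > 0 and not out[:, 4:6].any()

    def test_no_rules_is_identity(self):
        mask = np.random.default_rng(0).random((5, 5)) > 0.5
        out, reverted = ee.verify_class(mask, None, None)
        np.testing.assert_array_equal(out, mask)
        assert reverted == 0

    def test_flat_scene_zero_reversions(self):
        dem = ee.RasterGrid(np.full((5, 5), 3.0), ee.Affine.from_origin(0, 150, 30))
        mask = np.ones((5, 5), bool)
        out, reverted = ee.verify_class(mask, 10.0, dem)
        assert reverted == 0 and out.all()


class TestMaskPropagation:
    def test_pool_drops_by_exactly_assigned_count(self):
        available = np.ones((6, 6), bool)
        assigned = np.zeros((6, 6), bool)
        new = np.zeros((6, 6), bool)
        new[:2, :3] = True
        out = ee.propagate_mask(available, assigned, new)
        assert out.sum() == 36 - 6
        empty = ee.propagate_mask(out, new, np.zeros((6, 6), bool))
        np.testing.assert_array_equal(empty, out)

    def test_double_assignment_is_hard_error(self):
        available = np.ones((3, 3), bool)
        taken = np.zeros((3, 3), bool)
        taken[0, 0] = True
        clash = np.zeros((3, 3), bool)
        clash[0, 0] = True
        with pytest.raises(ValueError, match="already"):
            ee.propagate_mask(available, taken, clash)

    def test_assignment_outside_pool_is_error(self):
        available = np.zeros((2, 2), bool)
        new = np.ones((2, 2), bool)
        with pytest.raises(ValueError, match="outside"):
            ee.propagate_mask(available, np.zeros((2, 2), bool), new)


class TestCompositeMap:
    def test_disjoint_classes_compose_with_unclassified_rest(self):
        legend = ee.default_legend("liberia")
        ref = ee.RasterGrid(np.zeros((10, 10)), ee.Affine.from_origin(0, 300, 30))
        masks = {}
        for i, name in enumerate(legend.names):
            m = np.zeros((10, 10), bool)
            m[i, :5] = True
            masks[name] = m
        lc = ee.composite_map(masks, legend, ref)
        assert set(np.unique(lc.values)) == set(legend.codes) | {0}
        assert (lc.values == 0).sum() == 50

    def test_overlapping_rasters_rejected(self):
        legend = ee.default_legend("liberia")
        ref = ee.RasterGrid(np.zeros((4, 4)), ee.Affine.from_origin(0, 120, 30))
        m = np.ones((4, 4), bool)
        with pytest.raises(ValueError, match="overlap"):
            ee.composite_map({"water_bodies": m, "grasslands": m}, legend, ref)


class TestSequentialClassifier:
    def test_revisiting_a_late_class_leaves_earlier_pixels_untouched(self, zero_noise):
        """Loosening the last class's rules must not change any earlier
        class's pixels (classes are independent once mapped)."""
        land, comp, stack = zero_noise
        training = ee.sample_training(land, 150, seed=5)
        base = ee.PipelineConfig(profile="liberia", seed=5)
        clf1 = ee.SequentialLandCoverClassifier(
            base.legend, base.class_specs, base.classifier).fit(
            comp, stack, training, ancillary=land.ancillary, dem=land.dem)
        alt = ee.PipelineConfig(profile="liberia", seed=5)
        alt.class_specs["grasslands"].phase1 = [
            ee.MaskRule("spectral", layer="R65", op=">", threshold=0.7)]
        clf2 = ee.SequentialLandCoverClassifier(
            alt.legend, alt.class_specs, alt.classifier).fit(
            comp, stack, training, ancillary=land.ancillary, dem=land.dem)
        for name in base.legend.names[:-1]:
            np.testing.assert_array_equal(clf1.class_masks_[name],
                                          clf2.class_masks_[name])

    def test_sklearn_param_interface(self):
        clf = ee.SequentialLandCoverClassifier()
        params = clf.get_params()
        assert set(params) == {"legend", "class_specs", "classifier_config"}
        clf.set_params(legend=ee.default_legend("gabon"))
        assert clf.legend.names[0] == "water_bodies"
        with pytest.raises(ValueError, match="not fitted"):
            clf.predict()
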