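import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ecoextent as ee
from ecoextent.accuracy import AreaSummary, label_from_reference


def _map_from(values, profile="liberia"):
    grid = ee.RasterGrid(np.asarray(values, dtype=np.uint8),
                         ee.Affine.from_origin(0, np.shape(values)[0] * 30, 30))
    return ee.LandCoverMap(grid, ee.default_legend(profile))


@pytest.fixture
def ten_class_map():
    rng = np.random.default_rng(0)
    return _map_from(rng.integers(1, 11, size=(100, 100)))


class TestStratifiedSampling:
    def test_ten_classes_times_fifty_gives_five_hundred(self, ten_class_map):
        samples = ee.stratified_sample(ten_class_map, 50, seed=1)
        assert len(samples) == 500
        assert (samples.groupby("map_label").size() == 50).all()

    def test_small_stratum_capped_by_availability(self):
        values = np.ones((10, 10), np.uint8)
        values[:3, :10] = 2  # only 30 pixels of class 2
        samples = ee.stratified_sample(_map_from(values), 50, seed=1)
        by = samples.groupby("map_label").size()
        assert by[2] == 30 and by[1] == 50

    def test_same_seed_reproduces_sample_set(self, ten_class_map):
        a = ee.stratified_sample(ten_class_map, 20, seed=9)
        b = ee.stratified_sample(ten_class_map, 20, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="no mapped class"):
            ee.stratified_sample(_map_from(np.zeros((5, 5))), 10)

    def test_samples_within_stratum_are_unique_pixels(self, ten_class_map):
        samples = ee.stratified_sample(ten_class_map, 50, seed=3)
        assert not samples.duplicated(["row", "col"]).any()


class TestErrorMatrix:
    def test_perfect_map_gives_diagonal_matrix(self):
        df = pd.DataFrame({"ref_label": [1, 1, 2, 3], "map_label": [1, 1, 2, 3]})
        m = ee.build_error_matrix(df)
        assert m.n == 4
        off = m.table.to_numpy() - np.diag(np.diag(m.table.to_numpy()))
        assert (off == 0).all()

    def test_single_confusion_lands_off_diagonal(self):
        df = pd.DataFrame({"ref_label": [1], "map_label": [2]})
        m = ee.build_error_matrix(df, labels=[1, 2])
        assert m.count(1, 2) == 1 and m.n == 1

    def test_label_outside_legend_rejected(self):
        df = pd.DataFrame({"ref_label": [1, 99], "map_label": [1, 1]})
        with pytest.raises(ValueError, match="99"):
            ee.build_error_matrix(df, labels=[1, 2])

    @given(st.lists(st.tuples(st.integers(1, 4), st.integers(1, 4)),
                    min_size=1, max_size=60))
    def test_matches_bruteforce_tally(self, pairs):
        df = pd.DataFrame(pairs, columns=["ref_label", "map_label"])
        m = ee.build_error_matrix(df, labels=[1, 2, 3, 4])
        for r in range(1, 5):
            for c in range(1, 5):
                expected = sum(1 for rr, cc in pairs if rr == r and cc == c)
                assert m.count(r, c) == expected
        assert m.n == len(pairs)


class TestAccuracyStats:
    def test_overall_from_500_samples_with_85_misses(self):
        # 500-sample design, 85 misclassified -> 83% overall
        table = pd.DataFrame([[415, 85], [0, 0]], index=[1, 2], columns=[1, 2])
        stats = ee.accuracy_stats(ee.ErrorMatrix(table))
        assert stats["overall"] * 100 == pytest.approx(83.0)

    def test_users_producers_on_toy_matrix(self):
        table = pd.DataFrame([[45, 5], [10, 40]], index=["a", "b"],
                             columns=["a", "b"])
        stats = ee.accuracy_stats(ee.ErrorMatrix(table))
        assert stats["per_class"]["a"]["producers"] == pytest.approx(0.90)
        assert stats["per_class"]["a"]["users"] == pytest.approx(45 / 55)
        assert stats["overall"] == pytest.approx(0.85)

    def test_perfect_matrix_all_statistics_100(self):
        table = pd.DataFrame(np.diag([10, 20, 30]), index=[1, 2, 3],
                             columns=[1, 2, 3])
        stats = ee.accuracy_stats(ee.ErrorMatrix(table))
        assert stats["overall"] == 1.0
        for v in stats["per_class"].values():
            assert v["users"] == 1.0 and v["producers"] == 1.0
            assert v["portmanteau"] == 1.0

    def test_portmanteau_of_two_class_matrix_equals_overall(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.integers(0, 50, (2, 2)) + 1, index=[1, 2],
                             columns=[1, 2])
        m = ee.ErrorMatrix(table)
        stats = ee.accuracy_stats(m)
        for label in (1, 2):
            assert stats["per_class"][label]["portmanteau"] == \
                pytest.approx(stats["overall"])

    def test_zero_marginal_is_nan_not_zero(self):
        table = pd.DataFrame([[5, 0], [3, 0]], index=[1, 2], columns=[1, 2])
        stats = ee.accuracy_stats(ee.ErrorMatrix(table))
        assert np.isnan(stats["per_class"][2]["users"])

    def test_class_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.integers(0, 30, (3, 3)), index=[1, 2, 3],
                             columns=[1, 2, 3])
        stats = ee.accuracy_stats(ee.ErrorMatrix(table))
        perm = [3, 1, 2]
        stats_p = ee.accuracy_stats(ee.ErrorMatrix(
            table.loc[perm, perm]))
        assert stats["overall"] == pytest.approx(stats_p["overall"])
        for label in (1, 2, 3):
            for key in ("users", "producers", "portmanteau"):
                a, b = stats["per_class"][label][key], stats_p["per_class"][label][key]
                assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)

    def test_wilson_interval_brackets_the_point_estimate(self):
        table = pd.DataFrame([[40, 10], [5, 45]], index=[1, 2], columns=[1, 2])
        stats = ee.accuracy_stats(ee.ErrorMatrix(table))
        lo, hi = stats["overall_ci"]
        assert 0 < lo < stats["overall"] < hi < 1


class TestAreas:
    def test_pixel_count_to_km2(self):
        values = np.ones((100, 100), np.uint8)  # 10,000 30-m pixels
        areas = ee.class_areas(_map_from(values))
        assert areas.km2("water_bodies") == pytest.approx(9.0)

    def test_flooded_forest_totals_add_up(self):
        summary = AreaSummary.from_km2({"permanent": 1218.0, "seasonal": 2517.0})
        assert summary.total_km2 == pytest.approx(3735.0)

    def test_extent_delta_against_reference_product(self):
        ours = AreaSummary.from_km2({"mangroves_wetlands": 223.51})
        ref = AreaSummary.from_km2({"mangroves_wetlands": 191.6})
        delta = ee.compare_areas(ours, ref, "mangroves_wetlands")
        assert round(delta, 1) == 31.9

    def test_mismatched_pixel_sizes_rejected(self):
        a = AreaSummary.from_km2({"x": 1.0}, pixel_size=30)
        b = AreaSummary.from_km2({"x": 1.0}, pixel_size=10)
        with pytest.raises(ValueError, match="pixel"):
            ee.compare_areas(a, b, "x")


def test_reference_labels_come_from_truth_raster(ten_class_map):
    samples = ee.stratified_sample(ten_class_map, 10, seed=0)
    labelled = label_from_reference(samples, ten_class_map.values)
    assert (labelled.ref_label == labelled.map_label).all()
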