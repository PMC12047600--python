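"""Feature construction: HR statistics, resizing, splitting, scaling."""
import numpy as np
import pytest

from ddfa_hrv import (
    FeatureConfig,
    RRISeries,
    build_features,
    density_surface,
    feature_length,
    hr_stats,
    hr_surface,
    impute_and_resize,
    minmax_fit_transform,
    split_rest_exercise,
)
from test_aggregation import fake_landscape


def _surface(alpha_value=1.0, hr=80.0, n_scales=4):
    landscape = fake_landscape(
        np.full((50, n_scales), alpha_value), np.full((50, n_scales), hr)
    )
    return hr_surface(landscape), density_surface(landscape)


class TestHRStats:
    def test_constant_series(self):
        stats = hr_stats(RRISeries.from_intervals("c", np.full(200, 800.0)))
        assert stats.mean_hr == pytest.approx(75.0)
        assert stats.sd_hr == 0.0
        assert stats.p1 == stats.p25 == stats.p75 == stats.p99 == pytest.approx(75.0)

    def test_six_entries(self):
        stats = hr_stats(RRISeries.from_intervals("c", np.full(200, 800.0)))
        assert stats.as_array().shape == (6,)

    def test_percentiles_match_linear_interpolation_oracle(self):
        rng = np.random.default_rng(0)
        intervals = rng.uniform(600.0, 1100.0, 101)
        stats = hr_stats(RRISeries.from_intervals("r", intervals))
        hr = np.sort(60000.0 / intervals)

        def percentile(q):  # independent: interpolate between order statistics
            pos = q / 100.0 * (hr.size - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            return hr[lo] * (1 - frac) + hr[min(lo + 1, hr.size - 1)] * frac

        for q, got in [(1, stats.p1), (25, stats.p25), (75, stats.p75), (99, stats.p99)]:
            assert got == pytest.approx(percentile(q), rel=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="100 beats"):
            hr_stats(RRISeries.from_intervals("s", np.full(50, 800.0)))


class TestResize:
    def test_constant_surface_stays_constant(self):
        out = impute_and_resize(np.full((5, 7), 1.3), (4, 9))
        np.testing.assert_allclose(out, 1.3)

    def test_2x2_to_3x3_center_is_corner_mean(self):
        m = np.array([[0.0, 1.0], [2.0, 3.0]])
        out = impute_and_resize(m, (3, 3))
        assert out[1, 1] == pytest.approx(m.mean())
        np.testing.assert_allclose(out[[0, 0, 2, 2], [0, 2, 0, 2]], [0, 1, 2, 3])

    def test_all_empty_surface_becomes_zero(self):
        out = impute_and_resize(np.full((6, 4), np.nan), (3, 3))
        np.testing.assert_array_equal(out, 0.0)

    def test_identity_when_size_matches_and_defined(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 2, (6, 5))
        np.testing.assert_allclose(impute_and_resize(m, (6, 5)), m, atol=1e-12)


class TestRestExerciseSplit:
    def test_default_split_gives_70_and_120_bins(self):
        surface, _ = _surface()
        rest, exercise = split_rest_exercise(surface, 100.0)
        assert rest.alpha_mean.shape[0] == 70  # 30..100 bpm
        assert exercise.alpha_mean.shape[0] == 120  # 100..220 bpm
        assert rest.hr_edges[-1] == 100.0 and exercise.hr_edges[0] == 100.0

    def test_rest_only_data_leaves_exercise_empty(self):
        surface, _ = _surface(hr=80.0)
        rest, exercise = split_rest_exercise(surface)
        assert np.isfinite(rest.alpha_mean).any()
        assert not np.isfinite(exercise.alpha_mean).any()

    def test_parts_reassemble_the_original(self):
        surface, _ = _surface()
        rest, exercise = split_rest_exercise(surface)
        glued = np.vstack([rest.alpha_mean, exercise.alpha_mean])
        np.testing.assert_array_equal(
            np.isnan(glued), np.isnan(surface.alpha_mean)
        )

    def test_threshold_off_an_edge_rejected(self):
        surface, _ = _surface()
        with pytest.raises(ValueError, match="bin edge"):
            split_rest_exercise(surface, 100.5)


class TestBuildFeatures:
    def test_default_length_is_198(self):
        surface, density = _surface()
        stats = hr_stats(RRISeries.from_intervals("c", np.full(200, 800.0)))
        vec = build_features(surface, density, stats, FeatureConfig())
        assert vec.values.size == 198 == feature_length(FeatureConfig())
        assert len(vec.names) == 198

    def test_length_is_config_function_only(self):
        config = FeatureConfig(
            rest_size=(4, 6), exercise_size=(3, 3), density_size=(2, 5),
            include_hr_stats=False,
        )
        assert feature_length(config) == 24 + 9 + 10
        surface, density = _surface(n_scales=7)
        vec = build_features(surface, density, None, config)
        assert vec.values.size == feature_length(config)

    def test_identical_subjects_identical_vectors(self):
        surface, density = _surface()
        stats = hr_stats(RRISeries.from_intervals("c", np.full(200, 800.0)))
        a = build_features(surface, density, stats, subject_id="a")
        b = build_features(surface, density, stats, subject_id="b")
        np.testing.assert_array_equal(a.values, b.values)


class TestMinMax:
    def test_train_feature_maps_to_unit_range(self):
        train = np.array([[2.0], [4.0], [6.0]])
        scaled, mins, maxs = minmax_fit_transform(train)
        np.testing.assert_allclose(scaled[:, 0], [0.0, 0.5, 1.0])
        assert mins[0] == 2.0 and maxs[0] == 6.0

    def test_constant_feature_maps_to_zero(self):
        scaled, _, _ = minmax_fit_transform(np.array([[5.0], [5.0]]))
        np.testing.assert_array_equal(scaled, 0.0)

    def test_test_values_are_not_clipped(self):
        train = np.array([[2.0], [4.0], [6.0]])
        scaled, _, _ = minmax_fit_transform(train, np.array([[0.0], [8.0]]))
        np.testing.assert_allclose(scaled[:, 0], [-0.5, 1.5])

    def test_ranges_fitted_on_training_data_only(self):
        rng = np.random.default_rng(0)
        train = rng.uniform(0, 1, (10, 3))
        _, mins_a, maxs_a = minmax_fit_transform(train, rng.uniform(0, 1, (5, 3)))
        _, mins_b, maxs_b = minmax_fit_transform(train, 100 * rng.uniform(0, 1, (5, 3)))
        np.testing.assert_array_equal(mins_a, mins_b)
        np.testing.assert_array_equal(maxs_a, maxs_b)
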