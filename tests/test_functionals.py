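"""Functional-bank tests: each family against hand-computed or constructed
oracles, plus the manifest composition and traceability invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crossaffect.functionals import (
    BLOCK_A,
    BLOCK_B,
    FEATURE_DIM,
    build_feature_index,
    delta_contour,
    extract_features,
    modulation_block,
    moments_block,
    peaks_block,
    percentiles_block,
    regression_block,
    temporal_block,
)

contours = st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=60).map(
    lambda v: np.asarray(v))


class TestDelta:
    def test_constant_contour_zero_delta(self):
        assert np.all(delta_contour(np.full(20, 3.3)) == 0)

    def test_linear_ramp_interior_delta_equals_slope(self):
        m = 0.7
        d = delta_contour(m * np.arange(30.0))
        np.testing.assert_allclose(d[2:-2], m, rtol=1e-12)

    @given(contours)
    def test_linearity(self, x):
        np.testing.assert_allclose(delta_contour(-x), -delta_contour(x),
                                   rtol=1e-9, atol=1e-9)

    def test_length_one_gives_zero(self):
        assert delta_contour(np.array([5.0])).tolist() == [0.0]


class TestPercentiles:
    def test_median_of_1_to_100_is_50_5(self):
        out = percentiles_block(np.arange(1.0, 101.0))
        assert out["quartile_2"] == pytest.approx(50.5)
        assert out["iqr_1_3"] == pytest.approx(out["quartile_3"]
                                               - out["quartile_1"])

    def test_constant_contour_collapses(self):
        out = percentiles_block(np.full(17, 2.5))
        assert out["quartile_1"] == out["percentile_99"] == 2.5
        assert out["iqr_1_3"] == 0.0
        assert out["range_1_99"] == 0.0


class TestMoments:
    def test_plus_minus_one(self):
        out = moments_block(np.array([-1.0, 1.0]))
        assert out["mean_arith"] == 0.0
        assert out["mean_rq"] == 1.0

    def test_hand_example(self):
        out = moments_block(np.array([0.0, 0.0, 0.0, 3.0]))
        assert out["mean_arith"] == pytest.approx(0.75)
        assert out["mean_rq"] == pytest.approx(1.5)

    def test_symmetric_contour_zero_skewness(self):
        x = np.concatenate([np.arange(10.0), np.arange(10.0)[::-1]])
        assert moments_block(x)["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_contour_convention(self):
        out = moments_block(np.full(9, 4.0))
        assert out["stddev"] == out["skewness"] == out["kurtosis"] == 0.0


class TestTemporal:
    def test_strictly_increasing_rise_duration_one(self):
        assert temporal_block(np.arange(20.0))["rise_dur"] == 1.0

    def test_constant_nonzero_contour(self):
        out = temporal_block(np.full(11, 3.0))
        assert out["nonzero_frac"] == 1.0
        assert out["range"] == 0.0

    def test_alternating_contour_segments(self):
        out = temporal_block(np.array([0.0, 1.0, 0.0, 1.0, 0.0]))
        # threshold min + 0.25*range = 0.25 -> two 1-frame runs
        assert out["seg_len_mean"] == 1.0
        assert out["seg_len_max"] == 1.0
        assert out["seg_len_std"] == 0.0

    def test_positions_normalized(self):
        x = np.zeros(11)
        x[3] = -1.0
        x[8] = 2.0
        out = temporal_block(x)
        assert out["pos_min"] == pytest.approx(0.3)
        assert out["pos_max"] == pytest.approx(0.8)


class TestPeaks:
    def test_sinusoid_period_recovered(self):
        p = 20
        x = np.sin(2 * np.pi * np.arange(5 * p) / p)
        out = peaks_block(x)
        assert abs(out["peak_dist_mean"] - p) <= 1
        assert out["peak_dist_std"] == pytest.approx(0.0, abs=1e-9)

    def test_monotone_contour_all_zero_peak_block(self):
        out = peaks_block(np.arange(30.0))
        for key in ("peak_val_mean", "peak_dist_mean", "peak_amp_range"):
            assert out[key] == 0.0

    def test_jittered_periods_raise_distance_sd(self):
        rng = np.random.default_rng(0)
        phases = np.cumsum(2 * np.pi / (20 * (1 + 0.2 * rng.uniform(
            -1, 1, 200))))
        x = np.sin(phases[:400])
        out = peaks_block(x)
        assert out["peak_dist_std"] > 0.5

    def test_plateau_peak_uses_earliest_frame(self):
        x = np.array([0.0, 1.0, 1.0, 0.0, 0.0])
        out = peaks_block(x)
        # single plateau peak of value 1 above the mean 0.4
        assert out["peak_val_mean"] == 1.0


class TestRegression:
    def test_line_recovered_exactly(self):
        t = np.linspace(0, 1, 50)
        out = regression_block(2.0 * t + 1.0)
        assert out["lin_slope"] == pytest.approx(2.0)
        assert out["lin_offset"] == pytest.approx(1.0)
        assert out["lin_err"] == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_parabola(self):
        t = np.linspace(0, 1, 41)
        x = 3.0 * (t - 0.5) ** 2 + 0.25
        out = regression_block(x)
        assert out["lin_slope"] == pytest.approx(0.0, abs=1e-9)
        assert out["quad_err"] == pytest.approx(0.0, abs=1e-15)
        assert out["quad_a"] == pytest.approx(3.0)

    def test_quadratic_offset_is_value_at_clip_start(self):
        # 5-point parabola fitted by hand: offset = fitted value at t=0
        x = np.array([1.0, 0.4, 0.2, 0.4, 1.0])
        out = regression_block(x)
        assert out["quad_offset"] == pytest.approx(1.0, abs=1e-9)


class TestModulation:
    def test_white_noise_lp(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(4000)
        out = modulation_block(x)
        assert out["lp_gain"] == pytest.approx(x.var(), rel=0.1)
        for k in range(1, 6):
            assert abs(out[f"lp_c{k}"]) < 0.1

    def test_periodic_contour_predictable(self):
        x = np.sin(2 * np.pi * np.arange(500) / 25)
        out = modulation_block(x)
        assert out["lp_gain"] < 0.05 * x.var()

    def test_short_contour_zeros(self):
        out = modulation_block(np.arange(4.0))
        assert all(v == 0.0 for v in out.values())


class TestFeatureIndex:
    def test_dimensionality_is_6373(self, feature_index):
        assert len(feature_index) == FEATURE_DIM == 6373

    def test_names_unique_and_traceable(self, feature_index):
        tab = feature_index.table
        assert tab["name"].is_unique
        assert set(tab["family"]) == {"percentiles", "moments", "temporal",
                                      "modulation", "peaks", "regression"}
        assert set(tab["lld_group"]) == {"prosodic", "spectral", "cepstral",
                                         "sound_quality"}
        # every dimension maps to exactly one (LLD, functional, delta) triple
        assert not tab.duplicated(["lld", "functional", "is_delta"]).any()

    def test_block_split_respected(self, feature_index):
        tab = feature_index.table
        # every LLD carries the full shared bank on contour and delta
        for is_delta in (False, True):
            sub = tab[(tab["functional"].isin(BLOCK_A))
                      & (tab["is_delta"] == is_delta)]
            assert len(sub) == 64 * len(BLOCK_A)
        # LLD-only functionals appear exactly once per LLD on the contour
        sub = tab[(tab["functional"].isin(BLOCK_B)) & (~tab["is_delta"])]
        assert len(sub) == 64 * len(BLOCK_B)


class TestExtractFeatures:
    def test_vector_matches_manifest_and_is_deterministic(self, tone_lld,
                                                          feature_index):
        a = extract_features(tone_lld, feature_index)
        b = extract_features(tone_lld, feature_index)
        assert a.values.shape == (6373,)
        np.testing.assert_array_equal(a.values, b.values)

    def test_loudness_mean_feature_equals_hand_mean(self, tone_lld,
                                                    feature_index):
        fv = extract_features(tone_lld, feature_index)
        pos = feature_index.names.index("loudness.mean_arith")
        assert fv.values[pos] == pytest.approx(
            tone_lld.contour("loudness").mean())

    def test_nan_raises_with_dimension_name(self, tone_lld, feature_index):
        broken = tone_lld
        vals = broken.values.copy()
        vals[0, 0] = np.nan
        broken = type(broken)(broken.frame_times, vals, broken.names,
                              broken.groups, broken.voiced_mask,
                              broken.voicing_prob, broken.clip_id)
        with pytest.raises(ValueError, match="loudness"):
            extract_features(broken, feature_index)

    @given(st.floats(-5, 5))
    def test_constant_contour_forced_values(self, c):
        x = np.full(30, c)
        assert moments_block(x)["mean_arith"] == pytest.approx(c)
        assert moments_block(x)["stddev"] == 0.0
        assert regression_block(x)["lin_slope"] == pytest.approx(0.0,
                                                                 abs=1e-9)
        assert peaks_block(x)["peak_val_mean"] == 0.0
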