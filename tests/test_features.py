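"""Transient feature extraction and cross-sensor normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from aossom.exceptions import DegenerateFeatureError, LengthError
from aossom.features import (FEATURE_NAMES, RawFeatureTable,
                             extract_features, feature_names_40,
                             features_to_frame, mdcv, normalize_features,
                             rav, vmax, vt)

float_series = hnp.arrays(
    dtype=np.float64, shape=st.integers(2, 200),
    elements=st.floats(-100, 100, allow_nan=False, width=64),
)


class TestVmax:
    def test_simple_maximum(self):
        assert vmax([0, 0.2, 0.1, 0.4]) == pytest.approx(0.4)

    def test_constant_series(self):
        assert vmax(np.full(10, 3.3)) == pytest.approx(3.3)

    def test_monotone_series_gives_last_element(self, rng):
        series = np.cumsum(rng.uniform(0, 1, 50))
        assert vmax(series) == pytest.approx(series[-1])

    def test_empty_series_rejected(self):
        with pytest.raises(LengthError):
            vmax([])


class TestMdcv:
    def test_constant_series_has_zero_slope(self):
        assert mdcv(np.full(100, 2.0), 0.1) == pytest.approx(0.0)

    def test_unit_ramp(self):
        dt = 0.1
        series = np.arange(3000) * dt
        assert mdcv(series, dt) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert mdcv([0, 0.2, 0.1, 0.4], 0.1) == pytest.approx(4 / 3)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(float_series, st.floats(1e-3, 10.0))
    def test_telescoping_identity(self, series, dt):
        expected = (series[-1] - series[0]) / ((len(series) - 1) * dt)
        assert mdcv(series, dt) == pytest.approx(expected, rel=1e-9,
                                                 abs=1e-6)

    def test_single_sample_rejected(self):
        with pytest.raises(LengthError):
            mdcv([1.0], 0.1)


class TestRav:
    def test_unit_rectangle_area(self):
        assert rav(np.ones(3000), 0.1) == pytest.approx(300.0)

    def test_zero_series(self):
        assert rav(np.zeros(50), 0.1) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert rav([0, 0.2, 0.1, 0.4], 0.1) == pytest.approx(0.07)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(float_series, st.floats(1e-3, 10.0), st.floats(0.1, 5.0))
    def test_scales_linearly_in_dt_and_amplitude(self, series, dt, scale):
        base = rav(series, dt)
        assert rav(series, 2 * dt) == pytest.approx(2 * base, rel=1e-9,
                                                    abs=1e-9)
        assert rav(scale * series, dt) == pytest.approx(scale * base,
                                                        rel=1e-9, abs=1e-6)

    def test_matches_brute_force_sum(self, rng):
        series = rng.normal(size=500)
        assert rav(series, 0.1) == pytest.approx(
            sum(float(d) * 0.1 for d in series))


class TestVt:
    def test_index_arithmetic_at_twenty_seconds(self):
        series = np.arange(1, 3001, dtype=float)  # D_i = i
        assert vt(series, t_target=20.0, dt=0.1) == pytest.approx(201.0)

    def test_time_zero_is_first_sample(self):
        assert vt([5.0, 6.0, 7.0], t_target=0.0, dt=0.1) == pytest.approx(5.0)

    def test_beyond_window_rejected(self):
        with pytest.raises(IndexError):
            vt(np.ones(100), t_target=20.0, dt=0.1)

    def test_off_grid_target_rejected(self):
        with pytest.raises(IndexError):
            vt(np.ones(300), t_target=0.15, dt=0.1)


class TestExtractFeatures:
    def test_ten_by_four_geometry(self, make_recording):
        table = extract_features(make_recording(n=300))
        assert table.values.shape == (10, 4)
        assert list(table.to_frame().columns) == list(FEATURE_NAMES)

    def test_identical_channels_give_identical_rows(self):
        from aossom.signal_io import SensorRecording
        channel = np.linspace(1.0, 3.0, 300)
        rec = SensorRecording("x", np.tile(channel, (10, 1)))
        table = extract_features(rec)
        assert np.ptp(table.values, axis=0) == pytest.approx(0.0)

    def test_channel_permutation_equivariance(self, make_recording):
        rec = make_recording(n=300)
        perm = np.array([2, 0, 1, 5, 9, 3, 4, 8, 7, 6])
        from aossom.signal_io import SensorRecording
        rec_p = SensorRecording("x", rec.channels[perm], dt=rec.dt)
        np.testing.assert_allclose(extract_features(rec_p).values,
                                   extract_features(rec).values[perm])

    def test_deterministic(self, make_recording):
        rec = make_recording(n=300)
        np.testing.assert_array_equal(extract_features(rec).values,
                                      extract_features(rec).values)


def _table_with_feature_column(values, fill=None, sample_id="s"):
    """A 10x4 table whose Vmax column is `values`; other columns random."""
    gen = np.random.default_rng(0)
    data = gen.uniform(1, 2, size=(10, 4)) if fill is None \
        else np.full((10, 4), fill)
    data[:, 0] = values
    return RawFeatureTable(sample_id=sample_id, values=data)


class TestNormalizeFeatures:
    def test_hand_arithmetic_one_to_ten(self):
        table = _table_with_feature_column(np.arange(1.0, 11.0))
        out = normalize_features(table).reshape(10, 4)
        # mean 5.5, n-1 variance 9.1667, first sensor -> -0.49091
        assert out[0, 0] == pytest.approx(-0.490909, abs=1e-6)
        assert out[:, 0].mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_feature_named_in_error(self):
        table = _table_with_feature_column(np.full(10, 2.0))
        with pytest.raises(DegenerateFeatureError, match="Vmax"):
            normalize_features(table)

    def test_cross_sensor_mean_is_zero_for_every_feature(self, rng):
        table = RawFeatureTable("s", rng.uniform(0.5, 3.0, size=(10, 4)))
        out = normalize_features(table).reshape(10, 4)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)

    def test_offset_invariance_and_reciprocal_scaling(self, rng):
        values = rng.uniform(1, 4, size=(10, 4))
        base = normalize_features(RawFeatureTable("s", values))
        shifted = normalize_features(RawFeatureTable("s", values + 7.5))
        np.testing.assert_allclose(shifted, base, atol=1e-9)
        # dividing by the variance: scaling inputs by c scales output by 1/c
        scaled = normalize_features(RawFeatureTable("s", 3.0 * values))
        np.testing.assert_allclose(scaled, base / 3.0, atol=1e-9)

    def test_sd_normalizer_is_scale_invariant(self, rng):
        values = rng.uniform(1, 4, size=(10, 4))
        base = normalize_features(RawFeatureTable("s", values), "sd")
        scaled = normalize_features(RawFeatureTable("s", 3.0 * values), "sd")
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_forty_vector_sensor_major_ordering(self):
        names = feature_names_40()
        assert len(names) == 40
        assert names[:5] == ["S1_Vmax", "S1_MDCV", "S1_RAV", "S1_Vt",
                             "S2_Vmax"]

    def test_features_to_frame_carries_ids_and_target(self, rng):
        tables = [RawFeatureTable(f"s{i}", rng.uniform(1, 2, (10, 4)))
                  for i in range(3)]
        frame = features_to_frame(tables, som=[20.0, 25.0, 30.0])
        assert frame.shape == (3, 41)
        assert list(frame.index) == ["s0", "s1", "s2"]
        assert frame["som_g_per_kg"].tolist() == [20.0, 25.0, 30.0]
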