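import io
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmcast import preprocess
from cgmcast.preprocess import (ScalerState, adf_check, apply_minmax,
                                fit_minmax, interpolate_missing, invert_minmax,
                                is_excluded, load_cgm_csv, missing_fraction,
                                resample_to_grid)
from conftest import make_series


class TestLoading:
    def _load(self, text):
        return load_cgm_csv(io.StringIO(textwrap.dedent(text)))

    def test_two_patients_two_series(self):
        series = self._load("""\
            patient_id,timestamp,glucose_mgdl,sensor
            P1,2023-03-01T00:00:00,100,sensor2
            P1,2023-03-01T00:15:00,110,sensor2
            P2,2023-03-01T00:00:00,120,sensor2
            """)
        assert [s.patient_id for s in series] == ["P1", "P2"]

    def test_duplicate_timestamps_collapse_to_mean(self):
        series = self._load("""\
            patient_id,timestamp,glucose_mgdl,sensor
            P1,2023-03-01T00:00:00,100,sensor2
            P1,2023-03-01T00:00:00,110,sensor2
            P1,2023-03-01T00:15:00,120,sensor2
            """)
        assert series[0].glucose[0] == 105.0

    def test_rows_sorted_by_timestamp(self):
        series = self._load("""\
            patient_id,timestamp,glucose_mgdl,sensor
            P1,2023-03-01T00:30:00,120,sensor2
            P1,2023-03-01T00:00:00,100,sensor2
            P1,2023-03-01T00:15:00,110,sensor2
            """)
        assert list(series[0].glucose) == [100.0, 110.0, 120.0]

    def test_empty_file_gives_empty_list(self):
        assert self._load("patient_id,timestamp,glucose_mgdl,sensor\n") == []

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing required columns"):
            self._load("patient_id,timestamp\nP1,2023-03-01\n")

    def test_unparseable_timestamp_rejected(self):
        with pytest.raises(ValueError, match="timestamp"):
            self._load("""\
                patient_id,timestamp,glucose_mgdl,sensor
                P1,not-a-time,100,sensor2
                """)


class TestExclusionRule:
    def make_with_missing(self, n, n_missing):
        g = np.full(n, 120.0)
        g[:n_missing] = np.nan
        return make_series(g)

    def test_sixty_percent_missing_excluded(self):
        assert is_excluded(self.make_with_missing(100, 60))

    def test_complete_series_retained(self):
        s = self.make_with_missing(100, 0)
        assert missing_fraction(s) == 0.0
        assert not is_excluded(s)

    def test_exactly_half_missing_retained(self):
        s = self.make_with_missing(100, 50)
        assert missing_fraction(s) == pytest.approx(0.5)
        assert not is_excluded(s)  # strict "> 50%" rule

    def test_empty_series_excluded(self):
        empty = make_series([])
        assert is_excluded(empty)

    def test_adding_observations_never_flips_to_excluded(self):
        rng = np.random.default_rng(0)
        g = np.full(200, 120.0)
        g[rng.choice(200, size=120, replace=False)] = np.nan
        s = make_series(g)
        fractions = []
        while np.isnan(s.glucose).any():
            i = np.flatnonzero(np.isnan(s.glucose))[0]
            g = s.glucose.copy()
            g[i] = 120.0
            s = make_series(g)
            fractions.append(missing_fraction(s))
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestResampling:
    def test_15min_pair_linear_upsample(self):
        s = make_series([100.0, 130.0], interval_min=15)
        out = resample_to_grid(s)
        assert np.allclose(out.glucose, [100, 110, 120, 130])
        assert out.native_interval == 5

    def test_1min_ramp_bin_means(self):
        s = make_series(100 + np.arange(15.0), interval_min=1)
        out = resample_to_grid(s)
        assert np.allclose(out.glucose, [102, 107, 112])

    @pytest.mark.parametrize("interval", [1, 5, 15])
    def test_constant_series_unchanged(self, interval):
        s = make_series(np.full(30, 100.0), interval_min=interval)
        assert np.allclose(resample_to_grid(s).glucose, 100.0)

    @pytest.mark.parametrize("slope,intercept", [(0.5, 90.0), (-0.2, 200.0), (2.0, 60.0)])
    def test_upsampling_exact_on_affine_signals(self, slope, intercept):
        t15 = np.arange(20) * 15.0
        s = make_series(intercept + slope * t15, interval_min=15)
        out = resample_to_grid(s)
        t5 = np.arange(len(out)) * 5.0
        assert np.abs(out.glucose - (intercept + slope * t5)).max() < 1e-9

    def test_missing_neighbour_keeps_gap_missing(self):
        s = make_series([100.0, np.nan, 130.0], interval_min=15)
        out = resample_to_grid(s)
        assert out.glucose[0] == 100.0
        assert np.isnan(out.glucose[1:6]).all()  # 5..25 min lack a neighbour
        assert out.glucose[6] == 130.0

    def test_decimation_option(self):
        s = make_series(100 + np.arange(10.0), interval_min=1)
        out = resample_to_grid(s, downsample="decimate")
        assert np.allclose(out.glucose, [100, 105])

    def test_unsupported_interval_rejected(self):
        s = make_series([100.0, 110.0], interval_min=5)
        object.__setattr__(s, "native_interval", 7)
        with pytest.raises(ValueError):
            resample_to_grid(s)


class TestImputation:
    def test_interior_gap_linear_fill(self):
        s = make_series([100.0, np.nan, 120.0])
        out = interpolate_missing(s)
        assert np.allclose(out.glucose, [100, 110, 120])
        assert list(out.interpolated) == [False, True, False]
        assert out.gaps == [(1, 1)]

    def test_no_missing_is_identity(self):
        s = make_series([100.0, 110.0, 120.0])
        out = interpolate_missing(s)
        assert np.array_equal(out.glucose, s.glucose)
        assert out.gaps == []

    def test_leading_and_trailing_missing_dropped(self):
        s = make_series([np.nan, 100.0, 110.0, np.nan])
        out = interpolate_missing(s)
        assert np.allclose(out.glucose, [100, 110])
        assert out.timestamps[0] == s.timestamps[1]

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="all samples missing"):
            interpolate_missing(make_series([np.nan, np.nan]))


class TestMinMaxScaler:
    def test_midpoint_maps_to_half(self):
        s = fit_minmax(np.array([70.0, 180.0]))
        assert apply_minmax(125.0, s) == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(40, 400), min_size=2, max_size=50).filter(
        lambda v: max(v) - min(v) > 1e-6))
    def test_roundtrip_identity(self, values):
        s = fit_minmax(np.array(values))
        x = np.linspace(min(values), max(values), 100)
        assert np.abs(invert_minmax(apply_minmax(x, s), s) - x).max() < 1e-9

    def test_training_data_maps_into_unit_interval(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(60, 350, size=500)
        s = fit_minmax(vals)
        scaled = apply_minmax(vals, s)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0

    def test_out_of_range_values_not_clipped(self):
        s = fit_minmax(np.array([100.0, 200.0]))
        assert apply_minmax(250.0, s) == pytest.approx(1.5)
        assert apply_minmax(50.0, s) == pytest.approx(-0.5)

    def test_degenerate_scaler_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            s = fit_minmax(np.array([100.0, 100.0]))
        assert np.all(apply_minmax(np.array([100.0, 150.0]), s) == 0.0)


class TestAdfCheck:
    def test_stationary_ar1_rejects_unit_root(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.empty(500)
            x[0] = 0.0
            for i in range(1, 500):
                x[i] = 0.5 * x[i - 1] + rng.normal()
            s = make_series(150 + 10 * x)
            if adf_check(s, max_lag=4).reject_unit_root:
                rejections += 1
        assert rejections >= 90

    def test_random_walk_rarely_rejects(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            walk = np.cumsum(rng.normal(size=500))
            s = make_series(10_000 + walk)
            if adf_check(s, max_lag=4).reject_unit_root:
                rejections += 1
        assert rejections <= 20

    def test_linear_trend_series_handled(self):
        s = make_series(100 + 0.1 * np.arange(200.0))
        result = adf_check(s, max_lag=4)
        assert np.isfinite(result.statistic)

    def test_short_series_flagged_invalid(self):
        result = adf_check(make_series(np.full(20, 120.0)))
        assert not result.valid and np.isnan(result.statistic)
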