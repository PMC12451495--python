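import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import scan_runs
from amphex.climate import (
    AnalysisConfig,
    SpeiCube,
    compute_percentile_threshold,
    detect_runs,
    drought_event_mask,
    monthly_event_counts,
)
from amphex.grid import GridSpec
from conftest import make_cube


class TestPercentileThreshold:
    def test_constant_series_returns_constant(self):
        cube = make_cube(np.full(40, 20.0))
        thr = compute_percentile_threshold(cube, 90, ("1980-01-01", "1980-02-09"))
        assert thr.values[0, 0] == pytest.approx(20.0)

    def test_linear_interpolation_estimator(self):
        cube = make_cube(np.arange(1.0, 101.0))
        thr = compute_percentile_threshold(cube, 90, ("1980-01-01", "1980-04-09"))
        assert thr.values[0, 0] == pytest.approx(90.1)

    def test_all_masked_cell_stays_masked(self):
        cube = make_cube(np.arange(40.0), mask=np.ones(40, bool))
        thr = compute_percentile_threshold(cube, 90, ("1980-01-01", "1980-02-09"))
        assert thr.mask[0, 0]
        assert not np.isfinite(thr.values[0, 0])

    def test_empty_window_errors(self):
        cube = make_cube(np.arange(40.0))
        with pytest.raises(ValueError, match="baseline window"):
            compute_percentile_threshold(cube, 90, ("1979-01-01", "1979-12-31"))

    def test_thin_cell_masked_with_warning(self):
        mask = np.ones(60, bool)
        mask[:20] = False  # 20 < 30 unmasked days
        cube = make_cube(np.arange(60.0), mask=mask)
        with pytest.warns(UserWarning, match="< 30 baseline days"):
            thr = compute_percentile_threshold(cube, 90, ("1980-01-01", "1980-02-29"))
        assert thr.mask[0, 0]


class TestDetectRuns:
    def test_only_long_run_detected(self):
        v = np.zeros(20)
        v[2:9] = 10  # days 3-9, 7 days
        v[11:16] = 10  # days 12-16, 5 days
        events = detect_runs(v, 5.0, "above", min_len=6)
        assert events == [(2, 7)]

    def test_no_exceedance_no_events(self):
        assert detect_runs(np.zeros(30), 5.0, "above", 6) == []

    def test_exact_boundary_length_counts(self):
        v = np.zeros(10)
        v[2:8] = 10
        assert detect_runs(v, 5.0, "above", 6) == [(2, 6)]

    def test_masked_day_breaks_run(self):
        v = np.full(12, 10.0)
        mask = np.zeros(12, bool)
        mask[5] = True  # splits 12 days into 5 + 6
        events = detect_runs(v, 5.0, "above", 6, mask=mask)
        assert events == [(6, 6)]

    def test_below_direction_is_strict(self):
        v = np.full(10, 5.0)
        assert detect_runs(v, 5.0, "below", 3) == []
        assert detect_runs(v - 0.1, 5.0, "below", 3) == [(0, 10)]

    @settings(max_examples=300, derandomize=True)
    @given(
        st.integers(50, 400),
        st.sampled_from([0.05, 0.1, 0.2, 0.3, 0.5]),
        st.integers(0, 2**31 - 1),
    )
    def test_agrees_with_exhaustive_scan(self, n, p, seed):
        rng = np.random.default_rng(seed)
        v = (rng.uniform(size=n) < p).astype(float)  # exceed when v > 0.5
        got = detect_runs(v, 0.5, "above", 6)
        assert got == scan_runs(v, 0.5, "above", 6)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_event_count_nonincreasing_in_min_len(self, seed):
        rng = np.random.default_rng(seed)
        v = (rng.uniform(size=200) < 0.3).astype(float)
        counts = [len(detect_runs(v, 0.5, "above", k)) for k in range(1, 12)]
        assert counts == sorted(counts, reverse=True)


class TestMonthlyCounts:
    def _cube_with_run(self, start_day, length, ndays=90):
        v = np.zeros(ndays)
        v[start_day : start_day + length] = 10
        return make_cube(v, start="1980-01-01")

    def _threshold(self, cube):
        from amphex.climate import ThresholdField

        return ThresholdField(
            cube.grid, 90.0, np.full(cube.grid.shape, 5.0),
            (cube.dates[0], cube.dates[-1]),
        )

    def test_run_crossing_month_counts_in_start_month(self):
        cube = self._cube_with_run(27, 8)  # starts Jan 28
        counts = monthly_event_counts(cube, self._threshold(cube), "above")
        jan = counts.months.get_loc(pd.Period("1980-01"))
        feb = counts.months.get_loc(pd.Period("1980-02"))
        assert counts.counts[jan, 0, 0] == 1
        assert counts.counts[feb, 0, 0] == 0

    def test_two_disjoint_runs_in_one_month(self):
        v = np.zeros(120)
        v[62:68] = 10  # two 6-day runs in March
        v[70:76] = 10
        cube = make_cube(v, start="1980-01-01")
        counts = monthly_event_counts(cube, self._threshold(cube), "above")
        mar = counts.months.get_loc(pd.Period("1980-03"))
        assert counts.counts[mar, 0, 0] == 2

    def test_sum_over_months_equals_total_runs(self):
        rng = np.random.default_rng(5)
        v = (rng.uniform(size=400) < 0.35).astype(float) * 10
        cube = make_cube(v)
        counts = monthly_event_counts(cube, self._threshold(cube), "above")
        assert counts.counts.sum() == len(detect_runs(v, 5.0, "above", 6))

    def test_masked_cell_all_zero_and_flagged(self):
        cube = self._cube_with_run(10, 8)
        thr = self._threshold(cube)
        thr.mask = np.ones(cube.grid.shape, bool)
        counts = monthly_event_counts(cube, thr, "above")
        assert counts.counts.sum() == 0
        assert counts.mask.all()

    def test_nonoverlapping_window_counting_variant(self):
        cube = self._cube_with_run(10, 13)  # one maximal 13-day run
        cfg = AnalysisConfig(event_counting="nonoverlapping_windows")
        counts = monthly_event_counts(cube, self._threshold(cube), "above", cfg)
        assert counts.counts.sum() == 2  # floor(13 / 6)
        default = monthly_event_counts(cube, self._threshold(cube), "above")
        assert default.counts.sum() == 1


class TestDroughtMask:
    def _spei(self, values):
        grid = GridSpec.regular(0, 0, 1, 1)
        months = pd.period_range("1980-01", periods=len(values), freq="M")
        return SpeiCube(grid, months, np.asarray(values, float)[:, None, None])

    def test_strictly_below_cutoff_is_event(self):
        counts = drought_event_mask(self._spei([-1.6, -1.5, -1.49, 0.0]), -1.5)
        assert counts.counts[:, 0, 0].tolist() == [1, 0, 0, 0]

    def test_lower_cutoff_never_increases_counts(self):
        rng = np.random.default_rng(11)
        spei = self._spei(rng.standard_normal(240))
        loose = drought_event_mask(spei, -1.5).counts.sum()
        strict = drought_event_mask(spei, -2.0).counts.sum()
        assert strict <= loose

    def test_masked_values_stay_masked(self):
        spei = self._spei([-2.0, -2.0])
        spei.mask[0] = True
        counts = drought_event_mask(spei)
        assert counts.mask[0, 0, 0] and counts.counts[0, 0, 0] == 0
        assert counts.counts[1, 0, 0] == 1
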