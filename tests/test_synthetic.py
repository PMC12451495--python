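import numpy as np
import pytest
import shapely
from scipy.stats import norm

from amphex.climate import compute_percentile_threshold, monthly_event_counts
from amphex.hazard import decadal_count, difference_field
from amphex.synthetic import (
    StatusModelParams,
    SyntheticScenario,
    gen_ranges,
    gen_spei_cube,
    gen_status_changes,
    gen_temperature_cube,
    gen_uniform_exposures,
)


def heat_difference(scenario):
    base = gen_temperature_cube(scenario, scenario.baseline_decade)
    recent = gen_temperature_cube(scenario, scenario.recent_decade)
    y0, y1 = scenario.baseline_decade
    thr = compute_percentile_threshold(base, 90, (f"{y0}-01-01", f"{y1}-12-31"))
    diff = difference_field(
        decadal_count(
            monthly_event_counts(recent, thr, "above"), scenario.recent_decade
        ),
        decadal_count(
            monthly_event_counts(base, thr, "above"), scenario.baseline_decade
        ),
    )
    return diff.values


class TestTemperature:
    def test_identical_seed_identical_cube(self, tiny_scenario):
        a = gen_temperature_cube(tiny_scenario, tiny_scenario.baseline_decade)
        b = gen_temperature_cube(tiny_scenario, tiny_scenario.baseline_decade)
        assert np.array_equal(a.values, b.values)

    def test_zero_trend_zero_noise_gives_zero_difference(self):
        sc = SyntheticScenario(
            seed=1, nlon=4, nlat=4, warming_c_per_decade=0.0,
            ar1_sigma_c=0.0, cell_temp_spread_c=0.0,
        )
        diff = heat_difference(sc)
        assert np.all(diff == 0)

    def test_warming_trend_raises_heat_events_in_most_cells(self):
        # sign test across seeds: a clear warming trend should leave the vast
        # majority of cells with a positive heat-event difference
        fractions = []
        for seed in range(6):
            sc = SyntheticScenario(seed=seed, nlon=6, nlat=6, warming_c_per_decade=1.0)
            diff = heat_difference(sc)
            fractions.append((diff > 0).mean())
        assert np.mean(fractions) >= 0.8


class TestSpei:
    def test_baseline_drought_frequency_matches_normal_tail(self):
        sc = SyntheticScenario(seed=3)
        cube = gen_spei_cube(sc, sc.baseline_decade)
        freq = (cube.values < -1.5).mean()
        assert freq == pytest.approx(norm.cdf(-1.5), abs=0.005)  # ~0.0668

    def test_drying_shift_raises_drought_frequency(self):
        sc = SyntheticScenario(seed=3, spei_drying_shift=-0.5)
        cube = gen_spei_cube(sc, sc.recent_decade)
        freq = (cube.values < -1.5).mean()
        assert freq == pytest.approx(norm.cdf(-1.0), abs=0.01)  # ~0.159

    def test_deterministic_under_fixed_seed(self):
        sc = SyntheticScenario(seed=9)
        a = gen_spei_cube(sc, sc.recent_decade)
        b = gen_spei_cube(sc, sc.recent_decade)
        assert np.array_equal(a.values, b.values)


class TestRanges:
    def test_ranges_lie_within_grid_extent(self, tiny_scenario):
        ranges, _ = gen_ranges(tiny_scenario)
        lon0, lat0, lon1, lat1 = tiny_scenario.grid.extent()
        for r in ranges:
            minx, miny, maxx, maxy = r.geometry.bounds
            assert minx >= lon0 - 1e-9 and maxx <= lon1 + 1e-9
            assert miny >= lat0 - 1e-9 and maxy <= lat1 + 1e-9

    def test_disjunct_part_areas_sum_to_total(self, tiny_scenario):
        ranges, _ = gen_ranges(tiny_scenario)
        multis = [r for r in ranges if r.geometry.geom_type == "MultiPolygon"]
        assert multis, "expected some disjunct ranges at default settings"
        for r in multis:
            parts = shapely.get_parts(r.geometry)
            assert sum(p.area for p in parts) == pytest.approx(r.geometry.area)

    def test_area_distribution_is_log_uniform(self):
        sc = SyntheticScenario(seed=5, n_species=1000, disjunct_prob=0.0)
        ranges, _ = gen_ranges(sc)
        log_areas = np.log([r.geometry.area for r in ranges])
        lo, hi = np.log(sc.min_range_area_deg2), np.log(sc.max_range_area_deg2)
        q = np.quantile((log_areas - lo) / (hi - lo), [0.25, 0.5, 0.75])
        assert q == pytest.approx([0.25, 0.5, 0.75], abs=0.05)

    def test_taxonomy_labels_complete(self, tiny_scenario):
        ranges, tax = gen_ranges(tiny_scenario)
        assert len(tax) == len(ranges)
        assert tax[["order", "family", "genus"]].notna().all().all()
        assert set(tax["order"]) <= {"Anura", "Caudata", "Gymnophiona"}


class TestStatusChanges:
    def test_outcome_frequencies_match_softmax_closed_form(self):
        # all odds ratios 1: P(no_change)=1/1.05, P(up)=0.03/1.05, P(down)=0.02/1.05
        params = StatusModelParams(
            intercept_odds={"uplisted": 0.03, "downlisted": 0.02},
            odds_ratios={
                "uplisted": dict.fromkeys(
                    ("heat_exposure", "drought_exposure", "cold_exposure"), 1.0
                ),
                "downlisted": dict.fromkeys(
                    ("heat_exposure", "drought_exposure", "cold_exposure"), 1.0
                ),
            },
        )
        rng = np.random.default_rng(7)
        exposures = gen_uniform_exposures(60000, rng)
        records = gen_status_changes(exposures, params, rng=rng)
        freq = records["outcome"].value_counts(normalize=True)
        assert freq["no_change"] == pytest.approx(1 / 1.05, abs=0.005)
        assert freq["uplisted"] == pytest.approx(0.03 / 1.05, abs=0.003)
        assert freq["downlisted"] == pytest.approx(0.02 / 1.05, abs=0.003)

    def test_huge_odds_ratio_forces_uplisting(self):
        params = StatusModelParams(
            intercept_odds={"uplisted": 0.03, "downlisted": 0.02},
            odds_ratios={
                "uplisted": {"heat_exposure": 1e12, "drought_exposure": 1.0, "cold_exposure": 1.0},
                "downlisted": {"heat_exposure": 1.0, "drought_exposure": 1.0, "cold_exposure": 1.0},
            },
        )
        exposures = gen_uniform_exposures(200, np.random.default_rng(1))
        exposures["heat_exposure"] = 1.0
        records = gen_status_changes(exposures, params, rng=3)
        assert (records["outcome"] == "uplisted").all()

    def test_deterministic_under_fixed_seed(self):
        exposures = gen_uniform_exposures(500, np.random.default_rng(2))
        a = gen_status_changes(exposures, rng=11)
        b = gen_status_changes(exposures, rng=11)
        assert a.equals(b)


class TestPlantedExposure:
    def test_forced_layer_reproduces_planted_labels(self, tiny_scenario):
        from amphex.exposure import SpeciesRange, classify_exposed, overlap_proportion
        from amphex.hazard import HazardLayer

        grid = tiny_scenario.grid
        inside = np.zeros(grid.shape, bool)
        inside[:, : grid.shape[1] // 2] = True  # western half is hazardous
        layer = HazardLayer(grid, inside, "heat_wave", 1.0, "ge_threshold")
        lon0, lat0, lon1, lat1 = grid.extent()
        mid = (lon0 + lon1) / 2
        in_sp = SpeciesRange("in", shapely.box(lon0 + 0.2, lat0 + 0.2, mid - 0.2, lat0 + 1.2))
        out_sp = SpeciesRange("out", shapely.box(mid + 0.2, lat0 + 0.2, lon1 - 0.2, lat0 + 1.2))
        assert classify_exposed(overlap_proportion(in_sp, layer)[2]) is True
        assert classify_exposed(overlap_proportion(out_sp, layer)[2]) is False
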