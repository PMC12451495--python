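import numpy as np
import pandas as pd
import pytest
import shapely

from amphex.aggregation import (
    country_summary,
    exposed_grid,
    multi_exposure,
    percent_exposed,
    percent_multi_exposed,
    richness_grid,
    taxon_summary,
)
from amphex.exposure import SpeciesRange


def exposure_df(rows):
    return pd.DataFrame(rows, columns=["species_id", "event_class", "exposed"]).assign(
        proportion=lambda d: d["exposed"].astype(float)
    )


class TestRichnessGrid:
    def test_wide_range_present_in_every_cell(self):
        sp = SpeciesRange("a", shapely.box(0, 0, 8, 8))
        summary = richness_grid([sp], cell_degrees=2, extent=(0, 0, 8, 8))
        assert np.all(summary.richness >= 1)

    def test_two_disjoint_single_cell_species(self):
        a = SpeciesRange("a", shapely.box(0.5, 0.5, 1.5, 1.5))
        b = SpeciesRange("b", shapely.box(6.5, 6.5, 7.5, 7.5))
        summary = richness_grid([a, b], cell_degrees=2, extent=(0, 0, 8, 8))
        assert summary.richness.sum() == 2
        assert summary.richness[0, 0] == 1 and summary.richness[3, 3] == 1

    def test_matches_pairwise_intersection_oracle(self):
        rng = np.random.default_rng(2)
        species = []
        for k in range(12):
            x0, y0 = rng.uniform(0, 6, 2)
            w, h = rng.uniform(0.5, 2.5, 2)
            species.append(SpeciesRange(f"s{k}", shapely.box(x0, y0, x0 + w, y0 + h)))
        summary = richness_grid(species, cell_degrees=2, extent=(0, 0, 8, 8))
        grid = summary.grid
        lonb, latb = grid.lon_bounds(), grid.lat_bounds()
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                cell = shapely.box(lonb[j, 0], latb[i, 0], lonb[j, 1], latb[i, 1])
                n = sum(cell.intersection(s.geometry).area > 0 for s in species)
                assert summary.richness[i, j] == n


class TestExposedGrid:
    def _species(self):
        geom = shapely.box(1, 1, 3, 3)
        return [SpeciesRange(f"s{k}", geom) for k in range(3)]

    def test_identical_ranges_two_of_three_exposed(self):
        species = self._species()
        df = exposure_df(
            [(f"s{k}", "heat_wave", k < 2) for k in range(3)]
        )
        summary = exposed_grid(species, df, cell_degrees=2, extent=(0, 0, 4, 4))
        prop = summary.exposed_proportion("heat_wave")
        occupied = summary.richness > 0
        assert np.allclose(prop[occupied], 2 / 3)

    def test_all_or_none_exposed(self):
        species = self._species()
        all_df = exposure_df([(f"s{k}", "drought", True) for k in range(3)])
        none_df = exposure_df([(f"s{k}", "drought", False) for k in range(3)])
        s_all = exposed_grid(species, all_df, cell_degrees=2, extent=(0, 0, 4, 4))
        s_none = exposed_grid(species, none_df, cell_degrees=2, extent=(0, 0, 4, 4))
        occ = s_all.richness > 0
        assert np.allclose(s_all.exposed_proportion("drought")[occ], 1.0)
        assert np.allclose(s_none.exposed_proportion("drought")[occ], 0.0)
        assert np.all(np.isnan(s_all.exposed_proportion("drought")[~occ]))


class TestTaxonSummary:
    def test_published_family_percentage_arithmetic(self):
        # 210 exposed of 215 species rounds to 98%
        assert round(percent_exposed(210, 215)) == 98
        df = exposure_df(
            [(f"s{k}", "heat_wave", k < 210) for k in range(215)]
        )
        tax = pd.DataFrame(
            {"species_id": [f"s{k}" for k in range(215)], "family": "Mantellidae"}
        )
        out = taxon_summary(df, tax, "family")
        row = out.iloc[0]
        assert row["n_exposed"] == 210 and row["n_species"] == 215
        assert round(row["percent_exposed"]) == 98

    def test_zero_and_fractional_percentages(self):
        assert percent_exposed(0, 50) == 0.0
        assert round(percent_exposed(2, 3), 1) == 66.7

    def test_unlabeled_species_collected_with_warning(self):
        df = exposure_df([("a", "drought", True), ("b", "drought", False)])
        tax = pd.DataFrame({"species_id": ["a", "b"], "family": ["F1", None]})
        with pytest.warns(UserWarning, match="UNASSIGNED"):
            out = taxon_summary(df, tax, "family")
        assert set(out["taxon"]) == {"F1", "UNASSIGNED"}


class TestCountrySummary:
    def test_membership_and_border_straddling(self):
        west = shapely.box(0, 0, 5, 10)
        east = shapely.box(5, 0, 10, 10)
        inside_west = SpeciesRange("w", shapely.box(1, 1, 2, 2))
        straddler = SpeciesRange("x", shapely.box(4, 4, 6, 6))
        df = exposure_df([("w", "heat_wave", True), ("x", "heat_wave", True)])
        out = country_summary(
            [inside_west, straddler], df, {"West": west, "East": east}
        )
        counts = out.set_index("country")["n_exposed"]
        assert counts["West"] == 2  # both species intersect the west country
        assert counts["East"] == 1  # only the straddler

    def test_unexposed_species_not_counted(self):
        west = shapely.box(0, 0, 5, 10)
        sp = SpeciesRange("w", shapely.box(1, 1, 2, 2))
        df = exposure_df([("w", "heat_wave", False)])
        out = country_summary([sp], df, {"West": west})
        assert out["n_exposed"].sum() == 0


class TestMultiExposure:
    def _records(self, n_total, n_multi, n_single):
        rows = []
        for k in range(n_total):
            heat = k < n_multi + n_single
            drought = k < n_multi
            rows += [
                (f"s{k}", "heat_wave", heat),
                (f"s{k}", "drought", drought),
                (f"s{k}", "cold_spell", False),
            ]
        return exposure_df(rows)

    def test_published_multi_exposure_percentage(self):
        combos = multi_exposure(self._records(7204, 618, 1000))
        assert round(percent_multi_exposed(combos), 1) == 8.6

    def test_combination_counts_partition_species(self):
        combos = multi_exposure(self._records(50, 7, 11))
        assert combos["n_species"].sum() == 50
        by = combos.set_index("combination")["n_species"]
        assert by["drought+heat_wave"] == 7
        assert by["heat_wave"] == 11
        assert by["(none)"] == 32

    def test_triple_exposure_in_triple_combination_only(self):
        rows = [
            ("a", "heat_wave", True),
            ("a", "drought", True),
            ("a", "cold_spell", True),
        ]
        combos = multi_exposure(exposure_df(rows))
        by = combos.set_index("combination")["n_species"]
        assert by["cold_spell+drought+heat_wave"] == 1
        assert combos.loc[combos["combination"] != "cold_spell+drought+heat_wave", "n_species"].sum() == 0

    def test_no_exposures_all_in_empty_combination(self):
        combos = multi_exposure(self._records(10, 0, 0))
        by = combos.set_index("combination")["n_species"]
        assert by["(none)"] == 10

    def test_duplicate_records_error(self):
        df = exposure_df([("a", "drought", True), ("a", "drought", True)])
        with pytest.raises(ValueError, match="duplicate"):
            multi_exposure(df)
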