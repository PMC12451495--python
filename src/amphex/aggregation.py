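"""Geographic and taxonomic tallies of exposed species.

Species counts are aggregated three ways: onto a coarse (default 2 degree)
lon/lat grid (richness, exposed counts, exposed proportion of richness), by
taxon (order/family/genus percentages), and by country polygons.  A species
belongs to a grid cell or country when its range has a positive-area
intersection with it — the "join attributes by location" rule — so a species
may legitimately count in several cells or countries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .exposure import SpeciesRange
from .geometry import cells_intersected, repair_geometry
from .grid import GridSpec

EVENT_CLASSES = ("heat_wave", "cold_spell", "drought")


@dataclass
class GridSummary:
    """Richness and per-event-class exposed counts on a coarse grid."""

    grid: GridSpec
    richness: np.ndarray
    exposed_counts: dict[str, np.ndarray] = field(default_factory=dict)

    def exposed_proportion(self, event_class: str) -> np.ndarray:
        """Exposed count / richness; NaN where richness is zero."""
        counts = self.exposed_counts[event_class]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.richness > 0, counts / self.richness, np.nan)
        return out


def coarse_grid(extent: tuple[float, float, float, float], cell_degrees: float = 2.0) -> GridSpec:
    """Aggregation grid of ``cell_degrees`` cells anchored at the extent's SW corner."""
    lon_min, lat_min, lon_max, lat_max = extent
    nlon = max(1, int(np.ceil((lon_max - lon_min) / cell_degrees - 1e-9)))
    nlat = max(1, int(np.ceil((lat_max - lat_min) / cell_degrees - 1e-9)))
    return GridSpec.regular(lon_min, lat_min, nlon, nlat, cell_degrees, cell_degrees)


def richness_grid(
    ranges: list[SpeciesRange],
    cell_degrees: float = 2.0,
    extent: tuple[float, float, float, float] | None = None,
) -> GridSummary:
    """Species richness per coarse cell (positive-area intersection rule)."""
    if extent is None:
        bounds = np.array([r.geometry.bounds for r in ranges])
        extent = (
            float(bounds[:, 0].min()),
            float(bounds[:, 1].min()),
            float(bounds[:, 2].max()),
            float(bounds[:, 3].max()),
        )
    grid = coarse_grid(extent, cell_degrees)
    richness = np.zeros(grid.shape, dtype=np.int64)
    for rng in ranges:
        richness += cells_intersected(grid, rng.geometry, rule="area")
    return GridSummary(grid, richness)


def exposed_grid(
    ranges: list[SpeciesRange],
    exposures: pd.DataFrame,
    cell_degrees: float = 2.0,
    extent: tuple[float, float, float, float] | None = None,
) -> GridSummary:
    """Richness plus exposed counts and proportions per event class."""
    summary = richness_grid(ranges, cell_degrees, extent)
    grid = summary.grid
    by_species = {r.species_id: r for r in ranges}
    for event_class, sub in exposures.groupby("event_class"):
        counts = np.zeros(grid.shape, dtype=np.int64)
        for sid in sub.loc[sub["exposed"], "species_id"]:
            counts += cells_intersected(grid, by_species[sid].geometry, rule="area")
        assert np.all(counts <= summary.richness), "exposed count exceeds richness"
        summary.exposed_counts[str(event_class)] = counts
    return summary


def taxon_summary(
    exposures: pd.DataFrame, taxonomy: pd.DataFrame, level: str = "family"
) -> pd.DataFrame:
    """Exposed counts and percentages per taxon at ``level`` and event class.

    ``taxonomy`` needs columns species_id and ``level``; species without a
    label are tallied under "UNASSIGNED" with a warning.  Percentages are
    stored at full precision; round only for display.
    """
    tax = taxonomy.set_index("species_id")[level].astype("string")
    missing = tax.isna() | (tax == "")
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} species lack a {level} label; "
            "tallied as UNASSIGNED",
            stacklevel=2,
        )
        tax = tax.where(~missing, "UNASSIGNED")
    df = exposures.copy()
    df["taxon"] = df["species_id"].map(tax)
    out = (
        df.groupby(["event_class", "taxon"], observed=True)
        .agg(n_species=("species_id", "nunique"), n_exposed=("exposed", "sum"))
        .reset_index()
    )
    out["n_exposed"] = out["n_exposed"].astype(int)
    out["percent_exposed"] = 100.0 * out["n_exposed"] / out["n_species"]
    out.insert(0, "level", level)
    return out


def country_summary(
    ranges: list[SpeciesRange],
    exposures: pd.DataFrame,
    countries: dict[str, BaseGeometry],
) -> pd.DataFrame:
    """Exposed species per country; a range straddling a border counts in both."""
    geoms = {
        name: repair_geometry(geom, f"country {name}")
        for name, geom in countries.items()
    }
    by_species = {r.species_id: r for r in ranges}
    rows = []
    for event_class, sub in exposures.groupby("event_class"):
        exposed_ids = sub.loc[sub["exposed"], "species_id"]
        tallies = dict.fromkeys(geoms, 0)
        for sid in exposed_ids:
            g = by_species[sid].geometry
            for name, cg in geoms.items():
                inter = g.intersection(cg)
                if not inter.is_empty and inter.area > 0:
                    tallies[name] += 1
        rows += [
            {"event_class": event_class, "country": name, "n_exposed": n}
            for name, n in tallies.items()
        ]
    return pd.DataFrame(rows)


def multi_exposure(exposures: pd.DataFrame) -> pd.DataFrame:
    """Species counts per combination of exposed event classes.

    Returns one row per combination (including the empty one), with the
    fraction of all species exposed to two or more classes available via
    :func:`percent_multi_exposed`.  Duplicate (species, event class) records
    are an error.
    """
    if exposures.duplicated(["species_id", "event_class"]).any():
        raise ValueError("duplicate (species_id, event_class) exposure records")
    sets = (
        exposures[exposures["exposed"]]
        .groupby("species_id")["event_class"]
        .agg(frozenset)
    )
    all_species = exposures["species_id"].unique()
    sets = sets.reindex(all_species).apply(
        lambda s: s if isinstance(s, frozenset) else frozenset()
    )
    classes = sorted(exposures["event_class"].unique())
    combos = [frozenset(c) for k in range(len(classes) + 1) for c in combinations(classes, k)]
    counts = sets.value_counts().to_dict()
    rows = [
        {
            "combination": "+".join(sorted(c)) if c else "(none)",
            "n_classes": len(c),
            "n_species": int(counts.get(c, 0)),
        }
        for c in combos
    ]
    out = pd.DataFrame(rows)
    assert out["n_species"].sum() == len(all_species), "combinations must partition species"
    return out


def percent_multi_exposed(combo_table: pd.DataFrame) -> float:
    """Percentage of species exposed to two or more event classes."""
    total = combo_table["n_species"].sum()
    multi = combo_table.loc[combo_table["n_classes"] >= 2, "n_species"].sum()
    return 100.0 * multi / total


def percent_exposed(n_exposed: int, n_species: int) -> float:
    """Plain percentage helper used in taxon and order tallies."""
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    return 100.0 * n_exposed / n_species
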