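"""Per-species overlap with hazard layers and excess-event zonal statistics.

A species range (possibly disjunct multipolygon, WGS84 lon/lat) is intersected
exactly with the hazard layer's grid cells; overlap and total range areas are
spherical-Earth areas in km^2 and their ratio is the exposure proportion.  A
species is classified exposed to an event class when the proportion strictly
exceeds the cutoff (default 0.5).  The excess-event statistics summarize the
decadal difference-in-counts field over the grid cells a range intersects
(zonal statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .geometry import (
    cell_intersection_areas,
    cells_intersected,
    repair_geometry,
    spherical_area_km2,
)
from .grid import GridSpec
from .hazard import EventDifferenceField, HazardLayer, RegionMask


@dataclass
class SpeciesRange:
    """A taxon-labelled distribution polygon (parts unioned on construction)."""

    species_id: str
    geometry: BaseGeometry
    order: str = ""
    family: str = ""
    genus: str = ""
    total_area_km2: float = field(init=False)

    def __post_init__(self) -> None:
        self.geometry = repair_geometry(self.geometry, self.species_id)
        self.total_area_km2 = spherical_area_km2(self.geometry)


@dataclass
class ExposureRecord:
    species_id: str
    event_class: str
    overlap_km2: float
    total_km2: float
    proportion: float
    exposed: bool
    excess_mean: float
    excess_sum: float
    excess_area_weighted_mean: float


def classify_exposed(proportion: float, cutoff: float = 0.5) -> bool:
    """Exposed iff proportion strictly exceeds the cutoff."""
    if not 0 <= proportion <= 1 + 1e-12:
        raise ValueError("proportion must be in [0, 1]")
    return proportion > cutoff


def overlap_proportion(
    rng: SpeciesRange, layer: HazardLayer
) -> tuple[float, float, float]:
    """(overlap_km2, total_km2, proportion) of a range against a hazard layer.

    Both areas are sums of exact cell-by-range spherical intersection areas —
    the total against the full grid footprint, the overlap against the layer's
    inside cells — so the ratio is internally consistent.
    """
    ii, jj, areas = cell_intersection_areas(layer.grid, rng.geometry)
    total = float(areas.sum())
    if total <= 0:
        raise ValueError(f"{rng.species_id}: range has zero area on the grid")
    overlap = float(areas[layer.inside[ii, jj]].sum())
    prop = min(overlap / total, 1.0)
    return overlap, total, prop


@dataclass
class ExcessStats:
    mean: float
    total: float
    area_weighted_mean: float
    n_cells: int

    @property
    def empty(self) -> bool:
        return self.n_cells == 0


def excess_events_in_range(
    rng: SpeciesRange,
    diff: EventDifferenceField,
    rule: str = "area",
) -> ExcessStats:
    """Zonal summary of the difference field over cells the range intersects.

    ``rule`` "area" (default) counts cells with any positive-area overlap;
    "center" counts cells whose center falls inside the range.  The
    area-weighted mean weights each cell by its overlap area with the range.
    """
    if rule == "area":
        ii, jj, areas = cell_intersection_areas(diff.grid, rng.geometry)
        keep = (areas > 0) & ~diff.mask[ii, jj]
        ii, jj, areas = ii[keep], jj[keep], areas[keep]
    else:
        member = cells_intersected(diff.grid, rng.geometry, rule=rule)
        member &= ~diff.mask
        ii, jj = np.nonzero(member)
        areas = diff.grid.area_grid()[ii, jj]
    if ii.size == 0:
        return ExcessStats(np.nan, np.nan, np.nan, 0)
    vals = diff.values[ii, jj].astype(float)
    return ExcessStats(
        mean=float(vals.mean()),
        total=float(vals.sum()),
        area_weighted_mean=float(np.average(vals, weights=areas)),
        n_cells=int(ii.size),
    )


def region_mask_from_ranges(
    ranges: list[SpeciesRange], grid: GridSpec
) -> RegionMask:
    """Union footprint of all ranges on the event grid (any overlap -> inside)."""
    inside = np.zeros(grid.shape, dtype=bool)
    for rng in ranges:
        inside |= cells_intersected(grid, rng.geometry, rule="area")
    return RegionMask(grid, inside)


def exposure_table(
    ranges: list[SpeciesRange],
    layers: dict[str, HazardLayer],
    diffs: dict[str, EventDifferenceField] | None = None,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """One ExposureRecord per (species, event class), as a tidy DataFrame."""
    rows = []
    diffs = diffs or {}
    for rng in ranges:
        for event_class, layer in layers.items():
            overlap, total, prop = overlap_proportion(rng, layer)
            if event_class in diffs:
                ex = excess_events_in_range(rng, diffs[event_class])
            else:
                ex = ExcessStats(np.nan, np.nan, np.nan, 0)
            rows.append(
                ExposureRecord(
                    species_id=rng.species_id,
                    event_class=event_class,
                    overlap_km2=overlap,
                    total_km2=total,
                    proportion=prop,
                    exposed=classify_exposed(prop, cutoff),
                    excess_mean=ex.mean,
                    excess_sum=ex.total,
                    excess_area_weighted_mean=ex.area_weighted_mean,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
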