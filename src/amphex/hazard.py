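"""Decadal event totals, difference-in-counts fields, and binary hazard layers.

For each event class the monthly counts are summed over a recent decade
(2010-2019) and a baseline decade (1980-1989); the cell-wise difference
(recent minus baseline) is thresholded into a binary hazard layer.  Heat-wave
and drought layers keep cells at or above a percentile (default 80th) of the
in-region difference distribution; the cold-spell layer keeps cells where the
count increased at all, because the 80th percentile of a mostly decreasing
field would include decreases.  All layer arithmetic is restricted to a region
mask (the union footprint of the species ranges under study).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .climate import EventClass, MonthlyEventCounts
from .grid import GridSpec, require_same_grid

ThresholdRule = Literal["ge_threshold", "increase_only"]


@dataclass
class DecadalEventCount:
    grid: GridSpec
    decade: tuple[int, int]
    counts: np.ndarray
    event_class: EventClass
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        if self.counts.shape != self.grid.shape:
            raise ValueError("counts shape must match grid")
        if np.any(self.counts[~self.mask] < 0):
            raise ValueError("decadal counts must be non-negative")


@dataclass
class EventDifferenceField:
    """Recent-minus-baseline decadal event counts (integer, may be negative)."""

    grid: GridSpec
    values: np.ndarray
    event_class: EventClass
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape must match grid")


@dataclass
class RegionMask:
    """Boolean in-region footprint (e.g. the global distribution of a class)."""

    grid: GridSpec
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.grid.shape:
            raise ValueError("inside shape must match grid")
        if not self.inside.any():
            raise ValueError("region mask must contain at least one cell")


@dataclass
class HazardLayer:
    """Binary exposure layer for one event class, with threshold provenance."""

    grid: GridSpec
    inside: np.ndarray
    event_class: EventClass
    threshold_value: float
    threshold_rule: str

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.grid.shape:
            raise ValueError("inside shape must match grid")

    @property
    def n_cells(self) -> int:
        return int(self.inside.sum())


def decadal_count(
    counts: MonthlyEventCounts, decade: tuple[int, int]
) -> DecadalEventCount:
    """Cell-wise sum of monthly counts over the 120 months of ``decade``.

    Raises if any month of the decade is missing from the input (partial
    coverage is never silently truncated).
    """
    y0, y1 = decade
    wanted = pd.period_range(f"{y0}-01", f"{y1}-12", freq="M")
    idx = counts.months.get_indexer(wanted)
    if np.any(idx < 0):
        missing = wanted[idx < 0]
        raise ValueError(
            f"decade {decade} not fully covered: {len(missing)} months missing "
            f"(first: {missing[0]})"
        )
    total = counts.counts[idx].sum(axis=0)
    cell_mask = counts.mask[idx].all(axis=0)
    return DecadalEventCount(counts.grid, decade, total, counts.event_class, cell_mask)


def difference_field(
    recent: DecadalEventCount, baseline: DecadalEventCount
) -> EventDifferenceField:
    """Exact integer cell-wise difference: recent minus baseline."""
    require_same_grid(recent.grid, baseline.grid, "recent and baseline counts")
    if recent.event_class != baseline.event_class:
        raise ValueError("event_class mismatch between decadal counts")
    diff = recent.counts.astype(np.int64) - baseline.counts.astype(np.int64)
    mask = recent.mask | baseline.mask
    return EventDifferenceField(recent.grid, diff, recent.event_class, mask)


def percentile_threshold(
    diff: EventDifferenceField, mask: RegionMask, q: float
) -> float:
    """``q``-th percentile (linear interpolation) of in-region difference values."""
    require_same_grid(diff.grid, mask.grid, "difference field and region mask")
    sel = mask.inside & ~diff.mask
    if not sel.any():
        raise ValueError("no unmasked in-region cells")
    return float(np.percentile(diff.values[sel].astype(float), q, method="linear"))


def binarize(
    diff: EventDifferenceField,
    mask: RegionMask,
    rule: ThresholdRule,
    threshold: float | None = None,
    include_zero: bool = False,
) -> HazardLayer:
    """Convert a difference field into a binary hazard layer.

    ``ge_threshold``: keep in-region cells with diff >= ``threshold``
    (inclusive, threshold stored unrounded).  ``increase_only``: keep in-region
    cells with diff > 0 (or >= 0 when ``include_zero``).
    """
    require_same_grid(diff.grid, mask.grid, "difference field and region mask")
    valid = mask.inside & ~diff.mask
    if rule == "ge_threshold":
        if threshold is None:
            raise ValueError("ge_threshold rule requires a threshold value")
        inside = valid & (diff.values >= threshold)
        tval = float(threshold)
    elif rule == "increase_only":
        inside = valid & (diff.values >= 0 if include_zero else diff.values > 0)
        tval = 0.0
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return HazardLayer(diff.grid, inside, diff.event_class, tval, rule)


def build_hazard_layer(
    diff: EventDifferenceField,
    mask: RegionMask,
    layer_percentile: float = 80.0,
    rule: ThresholdRule = "ge_threshold",
    include_zero: bool = False,
) -> HazardLayer:
    """Percentile-thresholded layer (heat, drought) or increase-only (cold)."""
    if rule == "ge_threshold":
        t = percentile_threshold(diff, mask, layer_percentile)
        return binarize(diff, mask, "ge_threshold", threshold=t)
    return binarize(diff, mask, "increase_only", include_zero=include_zero)
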