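"""Detection of heat-wave, cold-spell, and drought events on gridded climate data.

Heat waves and cold spells are runs of at least ``run_length_days`` (default 6)
consecutive days with temperature strictly beyond a per-cell climatological
percentile threshold (90th for heat, 10th for cold), computed from a baseline
decade.  One *maximal* qualifying run counts as one event, assigned to the
calendar month in which it starts.  Droughts are months in which the 3-month
standardized precipitation-evapotranspiration index (SPEI-3) falls strictly
below a severity cutoff (default -1.5, severe drought).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, require_same_grid

Direction = Literal["above", "below"]
EventClass = Literal["heat_wave", "cold_spell", "drought"]

#: minimum number of unmasked baseline days required to estimate a percentile
MIN_BASELINE_DAYS = 30


@dataclass
class AnalysisConfig:
    """All scalar constants of the exposure pipeline, with study defaults."""

    run_length_days: int = 6
    heat_q: float = 90.0
    cold_q: float = 10.0
    spei_cutoff: float = -1.5
    baseline_decade: tuple[int, int] = (1980, 1989)
    recent_decade: tuple[int, int] = (2010, 2019)
    layer_percentile: float = 80.0
    exposure_cutoff: float = 0.5
    aggregation_cell_degrees: float = 2.0
    #: "maximal_run" (one maximal run = one event) or
    #: "nonoverlapping_windows" (floor(run length / min length) events per run)
    event_counting: str = "maximal_run"
    #: include diff == 0 cells in the increase-only (cold spell) layer
    cold_include_zero: bool = False

    def __post_init__(self) -> None:
        if self.run_length_days < 1:
            raise ValueError("run_length_days must be >= 1")
        if not 0 < self.layer_percentile < 100:
            raise ValueError("layer_percentile must be in (0, 100)")
        if not 0 < self.exposure_cutoff < 1:
            raise ValueError("exposure_cutoff must be in (0, 1)")
        b0, b1 = self.baseline_decade
        r0, r1 = self.recent_decade
        if b1 < b0 or r1 < r0 or (b1 >= r0 and r1 >= b0):
            raise ValueError("decades must be well-formed and non-overlapping")
        if self.event_counting not in ("maximal_run", "nonoverlapping_windows"):
            raise ValueError(f"unknown event_counting rule {self.event_counting!r}")

    def replace(self, **kw) -> "AnalysisConfig":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass
class DailyTemperatureCube:
    """Gridded daily temperature (degC), shape (nday, nlat, nlon).

    ``mask`` is True where a value is missing; masked days break runs.
    """

    grid: GridSpec
    dates: pd.DatetimeIndex
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.dates = pd.DatetimeIndex(self.dates)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.dates),) + self.grid.shape:
            raise ValueError("values shape must be (nday, nlat, nlon)")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
        step = np.diff(self.dates.values.astype("datetime64[D]").astype(int))
        if len(self.dates) > 1 and not np.all(step == 1):
            raise ValueError("dates must be consecutive calendar days, gap-free")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("unmasked values must be finite")


@dataclass
class SpeiCube:
    """Gridded monthly SPEI-3 (unitless, ~standard normal)."""

    grid: GridSpec
    months: pd.PeriodIndex
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.months = pd.PeriodIndex(self.months, freq="M")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.months),) + self.grid.shape:
            raise ValueError("values shape must be (nmonth, nlat, nlon)")
        valid = self.values[~self.mask]
        if valid.size and np.nanmax(np.abs(valid)) >= 5:
            warnings.warn(
                "SPEI magnitudes >= 5 present; inputs may not be standardized",
                stacklevel=2,
            )


@dataclass
class ThresholdField:
    """Per-cell temperature threshold (degC) at percentile ``q`` of a baseline."""

    grid: GridSpec
    q: float
    values: np.ndarray
    baseline_window: tuple[pd.Timestamp, pd.Timestamp]
    mask: np.ndarray | None = None
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        if not 0 < self.q < 100:
            raise ValueError("q must be in (0, 100)")
        if self.values.shape != self.grid.shape:
            raise ValueError("threshold shape must match grid")


@dataclass
class MonthlyEventCounts:
    """Per-month, per-cell event counts for one event class."""

    grid: GridSpec
    months: pd.PeriodIndex
    counts: np.ndarray
    event_class: EventClass
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.months = pd.PeriodIndex(self.months, freq="M")
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.counts.shape != (len(self.months),) + self.grid.shape:
            raise ValueError("counts shape must be (nmonth, nlat, nlon)")
        if np.any(self.counts[~self.mask] < 0):
            raise ValueError("counts must be non-negative")


class RunEvent(NamedTuple):
    """One detected event: index of its first day and its run length."""

    start: int
    length: int


def detect_runs(
    series: Sequence[float] | np.ndarray,
    threshold: float,
    direction: Direction = "above",
    min_len: int = 6,
    mask: np.ndarray | None = None,
) -> list[RunEvent]:
    """Find maximal runs of consecutive days strictly beyond ``threshold``.

    A run qualifies when its length is at least ``min_len``; each maximal run
    is one event regardless of how long it is.  Masked (missing) days never
    exceed the threshold, so they terminate runs.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    v = np.asarray(series, dtype=float)
    if direction == "above":
        exceed = v > threshold
    elif direction == "below":
        exceed = v < threshold
    else:
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    exceed &= np.isfinite(v)
    if mask is not None:
        exceed &= ~np.asarray(mask, dtype=bool)
    return _runs_from_bool(exceed, min_len)


def _runs_from_bool(exceed: np.ndarray, min_len: int) -> list[RunEvent]:
    padded = np.concatenate(([False], exceed, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = ends - starts
    keep = lengths >= min_len
    return [RunEvent(int(s), int(l)) for s, l in zip(starts[keep], lengths[keep])]


def _events_per_run(length: int, min_len: int, counting: str) -> int:
    if counting == "nonoverlapping_windows":
        return length // min_len
    return 1


def compute_percentile_threshold(
    cube: DailyTemperatureCube,
    q: float,
    baseline_window: tuple[str | pd.Timestamp, str | pd.Timestamp],
) -> ThresholdField:
    """Per-cell ``q``-th percentile of unmasked daily temperatures in a window.

    The percentile pools all baseline days of a cell (no calendar-day
    windowing) and uses the linear-interpolation quantile estimator.  Cells
    with fewer than ``MIN_BASELINE_DAYS`` unmasked days are masked with a
    warning; all-masked cells stay masked.
    """
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    t0, t1 = (pd.Timestamp(t) for t in baseline_window)
    sel = (cube.dates >= t0) & (cube.dates <= t1)
    if not sel.any():
        raise ValueError("baseline window contains no days of the cube")
    vals = np.where(cube.mask[sel], np.nan, cube.values[sel])
    n_valid = np.sum(~cube.mask[sel], axis=0)
    out = np.full(cube.grid.shape, np.nan)
    ok = n_valid >= MIN_BASELINE_DAYS
    if ok.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            qv = np.nanpercentile(vals, q, axis=0, method="linear")
        out[ok] = qv[ok]
    n_thin = int(np.sum(~ok & (n_valid > 0)))
    if n_thin:
        warnings.warn(
            f"{n_thin} cells have < {MIN_BASELINE_DAYS} baseline days; masked",
            stacklevel=2,
        )
    return ThresholdField(cube.grid, q, out, (t0, t1), mask=~ok)


def monthly_event_counts(
    cube: DailyTemperatureCube,
    thresholds: ThresholdField,
    direction: Direction,
    config: AnalysisConfig | None = None,
) -> MonthlyEventCounts:
    """Count events per cell and month; an event belongs to its start month.

    Runs crossing a month boundary are counted once, in the month their first
    day falls in.
    """
    config = config or AnalysisConfig()
    require_same_grid(cube.grid, thresholds.grid, "cube and thresholds")
    periods = cube.dates.to_period("M")
    months = pd.period_range(periods[0], periods[-1], freq="M")
    if len(months) < 2 and periods[0] == periods[-1]:
        first = cube.dates[0]
        if not (first.day == 1 and cube.dates[-1] == first + pd.offsets.MonthEnd(0)):
            raise ValueError("date range must span at least one full month")
    month_of_day = months.get_indexer(periods)
    nlat, nlon = cube.grid.shape
    counts = np.zeros((len(months), nlat, nlon), dtype=np.int64)
    cell_masked = np.zeros((nlat, nlon), dtype=bool)
    event_class: EventClass = "heat_wave" if direction == "above" else "cold_spell"
    for i in range(nlat):
        for j in range(nlon):
            if thresholds.mask is not None and thresholds.mask[i, j]:
                cell_masked[i, j] = True
                continue
            runs = detect_runs(
                cube.values[:, i, j],
                float(thresholds.values[i, j]),
                direction,
                config.run_length_days,
                mask=cube.mask[:, i, j],
            )
            for start, length in runs:
                counts[month_of_day[start], i, j] += _events_per_run(
                    length, config.run_length_days, config.event_counting
                )
    mask3 = np.broadcast_to(cell_masked, counts.shape).copy()
    counts[mask3] = 0
    return MonthlyEventCounts(cube.grid, months, counts, event_class, mask=mask3)


def drought_event_mask(spei: SpeiCube, cutoff: float = -1.5) -> MonthlyEventCounts:
    """0/1 drought occurrence per month: 1 where SPEI is strictly below cutoff."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    with np.errstate(invalid="ignore"):
        counts = (spei.values < cutoff).astype(np.int64)
    counts[spei.mask] = 0
    return MonthlyEventCounts(
        spei.grid, spei.months, counts, "drought", mask=spei.mask.copy()
    )


def iter_cells(grid: GridSpec) -> Iterator[tuple[int, int]]:
    nlat, nlon = grid.shape
    for i in range(nlat):
        for j in range(nlon):
            yield i, j
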