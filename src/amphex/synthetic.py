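"""Synthetic study inputs with known ground truth.

Every pipeline stage can be exercised without external downloads: the
generator emits daily temperature cubes (per-cell climatology + seasonal
cycle + linear warming trend + AR(1) noise), monthly SPEI-like cubes
(standard-normal marginals, mean-shifted in the recent decade to emulate
drying), species multipolygon ranges with taxonomy (including disjunct
populations), and Red List status-change tables drawn from a multinomial
logit with configurable true odds ratios (defaulting to the fitted values of
the 2004-2022 reassessment analysis).

All outputs are deterministic functions of the scenario seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .climate import DailyTemperatureCube, SpeiCube
from .exposure import SpeciesRange
from .grid import GridSpec


@dataclass(frozen=True)
class StatusModelParams:
    """True multinomial-logit parameters: intercept odds and odds ratios."""

    intercept_odds: dict = field(
        default_factory=lambda: {"uplisted": 0.03, "downlisted": 0.02}
    )
    odds_ratios: dict = field(
        default_factory=lambda: {
            "uplisted": {"heat_exposure": 1.84, "drought_exposure": 1.66, "cold_exposure": 1.24},
            "downlisted": {"heat_exposure": 0.67, "drought_exposure": 0.18, "cold_exposure": 0.77},
        }
    )

    @property
    def predictors(self) -> list[str]:
        return list(next(iter(self.odds_ratios.values())).keys())

    def linear_predictors(self, exposures: pd.DataFrame) -> np.ndarray:
        """(n, K-1) linear predictors for the non-reference outcomes."""
        cols = []
        for outcome, ors in self.odds_ratios.items():
            eta = np.log(self.intercept_odds[outcome]) * np.ones(len(exposures))
            for pred, orat in ors.items():
                eta = eta + np.log(orat) * exposures[pred].to_numpy(dtype=float)
            cols.append(eta)
        return np.column_stack(cols)

    def outcome_probabilities(self, exposures: pd.DataFrame) -> pd.DataFrame:
        eta = self.linear_predictors(exposures)
        full = np.column_stack([np.zeros(len(exposures)), eta])
        full -= full.max(axis=1, keepdims=True)
        p = np.exp(full)
        p /= p.sum(axis=1, keepdims=True)
        return pd.DataFrame(p, columns=["no_change", *self.odds_ratios.keys()])


@dataclass(frozen=True)
class SyntheticScenario:
    """Desk-scale study conditions for the full pipeline.

    Defaults: a 20 x 20 grid of 0.5 degree cells over a tropical window, the
    two analysis decades, 300 species with log-uniform range areas, a 0.5
    degC/decade warming trend and a -0.5 mean SPEI shift in the recent decade.
    """

    seed: int = 0
    lon_min: float = -70.0
    lat_min: float = -10.0
    nlon: int = 20
    nlat: int = 20
    cell_degrees: float = 0.5
    baseline_decade: tuple[int, int] = (1980, 1989)
    recent_decade: tuple[int, int] = (2010, 2019)
    # temperature model
    mean_temp_c: float = 24.0
    cell_temp_spread_c: float = 1.5
    seasonal_amplitude_c: float = 4.0
    warming_c_per_decade: float = 0.5
    ar1_phi: float = 0.7
    ar1_sigma_c: float = 2.0
    # SPEI model: mean shift of the recent decade relative to N(0,1) baseline
    spei_drying_shift: float = -0.5
    # species ranges
    n_species: int = 300
    min_range_area_deg2: float = 0.25
    max_range_area_deg2: float = 25.0
    disjunct_prob: float = 0.25
    families_per_order: int = 8
    order_weights: dict = field(
        default_factory=lambda: {"Anura": 0.88, "Caudata": 0.10, "Gymnophiona": 0.02}
    )
    status_params: StatusModelParams = field(default_factory=StatusModelParams)

    def __post_init__(self) -> None:
        if abs(self.ar1_phi) >= 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.regular(
            self.lon_min, self.lat_min, self.nlon, self.nlat,
            self.cell_degrees, self.cell_degrees,
        )

    def rng(self, *stream) -> np.random.Generator:
        """Independent generator for a named stream, derived from the seed."""
        material = [self.seed] + [
            s if isinstance(s, (int, np.integer))
            else zlib.crc32(str(s).encode("utf8"))
            for s in stream
        ]
        return np.random.default_rng(material)

    def cell_climatology(self) -> np.ndarray:
        """Per-cell mean temperature (degC); identical across decades."""
        rng = self.rng("climatology")
        return self.mean_temp_c + self.cell_temp_spread_c * rng.standard_normal(
            (self.nlat, self.nlon)
        )


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float, shape) -> np.ndarray:
    """AR(1) noise along axis 0, stationary start."""
    innov = rng.standard_normal((n, *shape)) * sigma
    out = np.empty_like(innov)
    out[0] = innov[0] / np.sqrt(1 - phi**2)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + innov[t]
    return out


def gen_temperature_cube(
    scenario: SyntheticScenario, decade: tuple[int, int]
) -> DailyTemperatureCube:
    """Daily temperature for one decade: climatology + season + trend + AR(1).

    The warming trend is linear in time, referenced to the midpoint of the
    baseline decade, so the recent decade is offset by trend x (gap in
    decades) and recent heat events stochastically exceed baseline ones.
    """
    y0, y1 = decade
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    b0, b1 = scenario.baseline_decade
    ref = pd.Timestamp(f"{(b0 + b1 + 1) // 2}-01-01")  # baseline midpoint
    decades_since = (dates - ref).days.to_numpy() / 3652.5
    seasonal = scenario.seasonal_amplitude_c * np.sin(2 * np.pi * doy / 365.25)
    trend = scenario.warming_c_per_decade * decades_since
    base = scenario.cell_climatology()[None, :, :]
    noise = _ar1(
        scenario.rng("temperature", y0),
        len(dates),
        scenario.ar1_phi,
        scenario.ar1_sigma_c,
        (scenario.nlat, scenario.nlon),
    )
    values = base + (seasonal + trend)[:, None, None] + noise
    return DailyTemperatureCube(scenario.grid, dates, values)


def gen_spei_cube(
    scenario: SyntheticScenario, decade: tuple[int, int]
) -> SpeiCube:
    """Monthly SPEI-3-like values: N(0,1) baseline, mean-shifted recent decade."""
    y0, y1 = decade
    months = pd.period_range(f"{y0}-01", f"{y1}-12", freq="M")
    rng = scenario.rng("spei", y0)
    values = rng.standard_normal((len(months), scenario.nlat, scenario.nlon))
    if decade == scenario.recent_decade:
        values = values + scenario.spei_drying_shift
    return SpeiCube(scenario.grid, months, values)


def _random_rect(
    rng: np.random.Generator, area: float, extent: tuple[float, float, float, float]
):
    lon0, lat0, lon1, lat1 = extent
    aspect = rng.uniform(0.5, 2.0)
    w = min(np.sqrt(area * aspect), (lon1 - lon0) * 0.95)
    h = min(area / w, (lat1 - lat0) * 0.95)
    x = rng.uniform(lon0, lon1 - w)
    y = rng.uniform(lat0, lat1 - h)
    return shapely.box(x, y, x + w, y + h)


def gen_ranges(
    scenario: SyntheticScenario,
) -> tuple[list[SpeciesRange], pd.DataFrame]:
    """Species ranges (rectangles, some disjunct) plus a taxonomy table.

    Areas (in planar deg^2 before spherical weighting) are log-uniform
    between the configured bounds; a fraction of species get 2-3 disjoint
    parts whose areas sum to the species total.
    """
    rng = scenario.rng("ranges")
    extent = scenario.grid.extent()
    orders = list(scenario.order_weights)
    weights = np.array(list(scenario.order_weights.values()), dtype=float)
    weights /= weights.sum()
    ranges: list[SpeciesRange] = []
    tax_rows = []
    for s in range(scenario.n_species):
        area = np.exp(
            rng.uniform(
                np.log(scenario.min_range_area_deg2),
                np.log(scenario.max_range_area_deg2),
            )
        )
        n_parts = 1
        if rng.uniform() < scenario.disjunct_prob:
            n_parts = int(rng.integers(2, 4))
        parts = []
        for _ in range(n_parts):
            part_area = area / n_parts
            for _attempt in range(50):
                cand = _random_rect(rng, part_area, extent)
                if all(not cand.intersects(p) for p in parts):
                    parts.append(cand)
                    break
            else:  # could not place disjointly; fall back to fewer parts
                break
        geom = shapely.multipolygons(parts) if len(parts) > 1 else parts[0]
        order = orders[rng.choice(len(orders), p=weights)]
        family = f"{order[:4]}idae_{rng.integers(scenario.families_per_order) + 1:02d}"
        genus = f"Genus_{rng.integers(3 * scenario.families_per_order) + 1:03d}"
        sid = f"sp{s + 1:04d}"
        ranges.append(
            SpeciesRange(sid, geom, order=order, family=family, genus=genus)
        )
        tax_rows.append(
            {"species_id": sid, "order": order, "family": family, "genus": genus}
        )
    return ranges, pd.DataFrame(tax_rows)


def gen_uniform_exposures(
    n_species: int, rng: np.random.Generator, predictors=("heat_exposure", "drought_exposure", "cold_exposure")
) -> pd.DataFrame:
    """Independent Uniform(0, 1) exposure proportions per species."""
    data = {p: rng.uniform(size=n_species) for p in predictors}
    out = pd.DataFrame(data)
    out.insert(0, "species_id", [f"sp{i + 1:04d}" for i in range(n_species)])
    return out


def gen_status_changes(
    exposures: pd.DataFrame,
    params: StatusModelParams | None = None,
    rng: np.random.Generator | int | None = None,
    period: str = "2004-2022",
) -> pd.DataFrame:
    """Sample status-change outcomes from the multinomial logit ground truth.

    ``exposures`` must carry one row per species with the predictor columns;
    the outcome is drawn from softmax probabilities with the reference
    (no_change) linear predictor fixed at zero.
    """
    params = params or StatusModelParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    probs = params.outcome_probabilities(exposures)
    u = rng.uniform(size=len(exposures))
    cum = probs.to_numpy().cumsum(axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    outcomes = np.array(probs.columns)[idx]
    out = exposures.copy()
    out["period"] = period
    out["outcome"] = outcomes
    cols = ["species_id", "period", "outcome", *params.predictors]
    return out[[c for c in cols if c in out.columns]]


def or_recovery_experiment(
    n_replicates: int = 50,
    n_species: int = 7202,
    seed: int = 0,
    params: StatusModelParams | None = None,
) -> pd.DataFrame:
    """Simulate-and-refit experiment for odds-ratio recovery.

    Each replicate draws independent Uniform(0, 1) exposure proportions for
    ``n_species`` species, samples outcomes from the multinomial logit with
    ``params`` as ground truth, refits the model, and records the
    exponentiated coefficients.  Returns one row per replicate with a
    (outcome, predictor) column MultiIndex; averaging over rows gives the
    mean recovered odds ratios.
    """
    from .status import fit_multinomial

    params = params or StatusModelParams()
    rows = []
    for rep in range(1, n_replicates + 1):
        rng = np.random.default_rng([seed, rep])
        exposures = gen_uniform_exposures(n_species, rng)
        records = gen_status_changes(exposures, params, rng=rng)
        rows.append(fit_multinomial(records).odds_ratios)
    return pd.DataFrame(rows).reset_index(drop=True)


def exposures_wide(exposure_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the per-(species, event class) exposure table to one row/species."""
    mapping = {
        "heat_wave": "heat_exposure",
        "drought": "drought_exposure",
        "cold_spell": "cold_exposure",
    }
    wide = exposure_table.pivot(
        index="species_id", columns="event_class", values="proportion"
    )
    wide = wide.rename(columns=mapping).reset_index()
    for col in mapping.values():
        if col not in wide.columns:
            wide[col] = 0.0
    return wide[["species_id", *mapping.values()]]
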