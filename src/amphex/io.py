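"""File formats: CF-style NetCDF cubes and fields, GeoJSON ranges, CSV tables.

Gridded data travel as NetCDF (dimensions time/lat/lon, CF-ish attributes,
written with xarray's scipy backend); vector data as GeoJSON in geographic
WGS84; tabular data as CSV.  Every writer embeds enough metadata (units,
threshold values, CRS tag) for the corresponding reader to reconstruct the
in-memory object exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import xarray as xr

from .climate import DailyTemperatureCube, MonthlyEventCounts, SpeiCube
from .exposure import SpeciesRange
from .grid import GridSpec
from .hazard import EventDifferenceField, HazardLayer, RegionMask

_NC_KW = dict(engine="scipy", format="NETCDF3_64BIT")
_CRS = "EPSG:4326"


class FormatError(ValueError):
    pass


def _check_crs(attrs: dict) -> None:
    crs = attrs.get("crs", _CRS)
    if str(crs).upper() not in ("EPSG:4326", "WGS84", "CRS84", "OGC:CRS84"):
        raise FormatError(
            f"unsupported CRS {crs!r}: reproject to geographic WGS84 "
            "(EPSG:4326) before use"
        )


def _grid_from_coords(ds: xr.Dataset) -> GridSpec:
    return GridSpec(ds["lon"].values.astype(float), ds["lat"].values.astype(float))


def _grid_coords(grid: GridSpec) -> dict:
    return {"lat": ("lat", grid.lat_centers), "lon": ("lon", grid.lon_centers)}


# -- cubes --------------------------------------------------------------------


def write_temperature_cube(cube: DailyTemperatureCube, path: str | Path) -> None:
    vals = np.where(cube.mask, np.nan, cube.values)
    ds = xr.Dataset(
        {"temperature": (("time", "lat", "lon"), vals, {"units": "degC"})},
        coords={"time": cube.dates, **_grid_coords(cube.grid)},
        attrs={"crs": _CRS},
    )
    ds.to_netcdf(path, **_NC_KW)


def read_temperature_cube(path: str | Path) -> DailyTemperatureCube:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    _check_crs(ds.attrs)
    dates = pd.DatetimeIndex(ds["time"].values)
    step = np.diff(dates.values.astype("datetime64[D]").astype(int))
    if len(dates) > 1 and not np.all(step == 1):
        raise FormatError("ragged or gappy time axis: expected consecutive days")
    return DailyTemperatureCube(_grid_from_coords(ds), dates, ds["temperature"].values)


def write_spei_cube(cube: SpeiCube, path: str | Path) -> None:
    vals = np.where(cube.mask, np.nan, cube.values)
    ds = xr.Dataset(
        {"spei3": (("time", "lat", "lon"), vals, {"units": "1"})},
        coords={
            "time": cube.months.to_timestamp(),
            **_grid_coords(cube.grid),
        },
        attrs={"crs": _CRS},
    )
    ds.to_netcdf(path, **_NC_KW)


def read_spei_cube(path: str | Path) -> SpeiCube:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    _check_crs(ds.attrs)
    months = pd.DatetimeIndex(ds["time"].values).to_period("M")
    return SpeiCube(_grid_from_coords(ds), months, ds["spei3"].values)


def write_monthly_counts(counts: MonthlyEventCounts, path: str | Path) -> None:
    vals = counts.counts.astype(float)
    vals[counts.mask] = np.nan
    ds = xr.Dataset(
        {"events": (("time", "lat", "lon"), vals, {"units": "count"})},
        coords={"time": counts.months.to_timestamp(), **_grid_coords(counts.grid)},
        attrs={"crs": _CRS, "event_class": counts.event_class},
    )
    ds.to_netcdf(path, **_NC_KW)


def read_monthly_counts(path: str | Path) -> MonthlyEventCounts:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    _check_crs(ds.attrs)
    months = pd.DatetimeIndex(ds["time"].values).to_period("M")
    vals = ds["events"].values
    mask = ~np.isfinite(vals)
    counts = np.where(mask, 0, vals).astype(np.int64)
    return MonthlyEventCounts(
        _grid_from_coords(ds), months, counts, ds.attrs["event_class"], mask=mask
    )


# -- 2-D fields ---------------------------------------------------------------


def write_field(
    values: np.ndarray,
    grid: GridSpec,
    path: str | Path,
    name: str = "field",
    attrs: dict | None = None,
) -> None:
    """Write a single 2-D (nlat, nlon) field with metadata tags."""
    ds = xr.Dataset(
        {name: (("lat", "lon"), np.asarray(values, dtype=float))},
        coords=_grid_coords(grid),
        attrs={"crs": _CRS, **(attrs or {})},
    )
    ds.to_netcdf(path, **_NC_KW)


def read_field(path: str | Path) -> tuple[np.ndarray, GridSpec, dict]:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    _check_crs(ds.attrs)
    name = [v for v in ds.data_vars][0]
    return ds[name].values, _grid_from_coords(ds), dict(ds.attrs)


def write_difference_field(diff: EventDifferenceField, path: str | Path) -> None:
    vals = diff.values.astype(float)
    vals[diff.mask] = np.nan
    write_field(vals, diff.grid, path, "event_difference",
                {"event_class": diff.event_class})


def read_difference_field(path: str | Path) -> EventDifferenceField:
    vals, grid, attrs = read_field(path)
    mask = ~np.isfinite(vals)
    return EventDifferenceField(
        grid, np.where(mask, 0, vals).astype(np.int64), attrs["event_class"], mask
    )


def write_hazard_layer(layer: HazardLayer, path: str | Path) -> None:
    write_field(
        layer.inside.astype(float), layer.grid, path, "hazard",
        {
            "event_class": layer.event_class,
            "threshold_value": layer.threshold_value,
            "threshold_rule": layer.threshold_rule,
        },
    )


def read_hazard_layer(path: str | Path) -> HazardLayer:
    vals, grid, attrs = read_field(path)
    return HazardLayer(
        grid,
        vals > 0.5,
        attrs["event_class"],
        float(attrs["threshold_value"]),
        str(attrs["threshold_rule"]),
    )


def write_region_mask(mask: RegionMask, path: str | Path) -> None:
    write_field(mask.inside.astype(float), mask.grid, path, "region")


def read_region_mask(path: str | Path) -> RegionMask:
    vals, grid, _ = read_field(path)
    return RegionMask(grid, vals > 0.5)


# -- vector data --------------------------------------------------------------


def write_ranges(ranges: list[SpeciesRange], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "species_id": r.species_id,
                "order": r.order,
                "family": r.family,
                "genus": r.genus,
            },
            "geometry": shapely.geometry.mapping(r.geometry),
        }
        for r in ranges
    ]
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))


def read_ranges(path: str | Path) -> list[SpeciesRange]:
    """Read species ranges from GeoJSON (geographic WGS84 coordinates).

    Invalid geometries are repaired (with a warning) by SpeciesRange itself;
    features without a usable id raise.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    crs = doc.get("crs", {}).get("properties", {}).get("name", _CRS)
    _check_crs({"crs": str(crs).rsplit("::", 1)[-1].replace("urn:ogc:def:crs:", "")})
    out = []
    for feat in doc["features"]:
        props = feat.get("properties") or {}
        sid = props.get("species_id") or props.get("binomial")
        if not sid:
            raise FormatError("feature lacks species_id/binomial property")
        geom = shapely.geometry.shape(feat["geometry"])
        out.append(
            SpeciesRange(
                str(sid),
                geom,
                order=str(props.get("order", "")),
                family=str(props.get("family", "")),
                genus=str(props.get("genus", "")),
            )
        )
    return out


def read_country_polygons(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    out = {}
    for feat in doc["features"]:
        name = (feat.get("properties") or {}).get("name")
        if not name:
            raise FormatError("country feature lacks a name property")
        out[str(name)] = shapely.geometry.shape(feat["geometry"])
    return out


# -- tables -------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- run manifest -------------------------------------------------------------


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance for one output directory: config, seed, inputs, timings."""

    config: dict
    seed: int | None = None
    package_version: str = ""
    input_digests: dict = field(default_factory=dict)
    stage_timings_s: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__

    def add_inputs(self, *paths: str | Path) -> None:
        for p in paths:
            self.input_digests[Path(p).name] = file_digest(p)

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                manifest.stage_timings_s[name] = round(
                    time.perf_counter() - self.t0, 4
                )

        return _Timer()

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path

    @classmethod
    def read(cls, out_dir: str | Path) -> "RunManifest":
        data = json.loads((Path(out_dir) / "manifest.json").read_text())
        return cls(**data)
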