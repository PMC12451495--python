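"""Regular lon/lat grids and spherical cell areas.

All gridded inputs (daily temperature, monthly SPEI, event counts, hazard
layers) live on a cell-centered, regularly spaced geographic grid.  Areas are
computed on a sphere of radius ``EARTH_RADIUS_KM``; for a cell bounded by
longitudes [l0, l1] and latitudes [p0, p1],

    area = R^2 * (l1 - l0) * (sin p1 - sin p0)      (angles in radians)

which is exact on the sphere and is the weighting used everywhere a km^2
figure is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0

_SPACING_TOL = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """A regular, cell-centered lon/lat grid.

    Parameters
    ----------
    lon_centers, lat_centers
        Ascending 1-D arrays of cell-center coordinates in degrees east /
        degrees north.  Longitudes must lie in [-180, 180), latitudes in
        [-90, 90].
    """

    lon_centers: np.ndarray
    lat_centers: np.ndarray

    def __post_init__(self) -> None:
        lon = np.asarray(self.lon_centers, dtype=float)
        lat = np.asarray(self.lat_centers, dtype=float)
        object.__setattr__(self, "lon_centers", lon)
        object.__setattr__(self, "lat_centers", lat)
        for name, arr in (("lon_centers", lon), ("lat_centers", lat)):
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            if arr.size > 1:
                steps = np.diff(arr)
                if np.any(steps <= 0):
                    raise ValueError(f"{name} must be strictly ascending")
                if np.ptp(steps) > _SPACING_TOL:
                    raise ValueError(f"{name} spacing is not uniform")
        if lon[0] < -180.0 or lon[-1] >= 180.0:
            raise ValueError("lon_centers must lie in [-180, 180)")
        if lat[0] < -90.0 or lat[-1] > 90.0:
            raise ValueError("lat_centers must lie in [-90, 90]")

    @property
    def dlon(self) -> float:
        lon = self.lon_centers
        return float(lon[1] - lon[0]) if lon.size > 1 else float(self._fallback_dlon)

    @property
    def dlat(self) -> float:
        lat = self.lat_centers
        return float(lat[1] - lat[0]) if lat.size > 1 else float(self._fallback_dlat)

    # single-row/column grids cannot infer spacing from centers; default 0.5 deg
    _fallback_dlon: float = field(default=0.5, repr=False, compare=False)
    _fallback_dlat: float = field(default=0.5, repr=False, compare=False)

    @property
    def shape(self) -> tuple[int, int]:
        """(nlat, nlon) — the trailing axes of every field on this grid."""
        return self.lat_centers.size, self.lon_centers.size

    @classmethod
    def regular(
        cls,
        lon_min: float,
        lat_min: float,
        nlon: int,
        nlat: int,
        dlon: float = 0.5,
        dlat: float = 0.5,
    ) -> "GridSpec":
        """Grid whose south-west cell *corner* is (lon_min, lat_min)."""
        lons = lon_min + dlon * (np.arange(nlon) + 0.5)
        lats = lat_min + dlat * (np.arange(nlat) + 0.5)
        return cls(lons, lats, _fallback_dlon=dlon, _fallback_dlat=dlat)

    def lon_bounds(self) -> np.ndarray:
        """(nlon, 2) west/east cell edges in degrees."""
        half = self.dlon / 2.0
        return np.stack([self.lon_centers - half, self.lon_centers + half], axis=1)

    def lat_bounds(self) -> np.ndarray:
        half = self.dlat / 2.0
        return np.stack([self.lat_centers - half, self.lat_centers + half], axis=1)

    def cell_area(self, lat_index: int) -> float:
        """Spherical area (km^2) of any cell in latitude row ``lat_index``."""
        return float(self.row_areas()[lat_index])

    def row_areas(self) -> np.ndarray:
        """Spherical cell area (km^2) per latitude row, shape (nlat,)."""
        b = np.radians(self.lat_bounds())
        dlam = np.radians(self.dlon)
        return EARTH_RADIUS_KM**2 * dlam * (np.sin(b[:, 1]) - np.sin(b[:, 0]))

    def area_grid(self) -> np.ndarray:
        """Cell areas broadcast to the full (nlat, nlon) shape."""
        return np.repeat(self.row_areas()[:, None], self.lon_centers.size, axis=1)

    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) outer edges of the grid."""
        return (
            float(self.lon_centers[0] - self.dlon / 2),
            float(self.lat_centers[0] - self.dlat / 2),
            float(self.lon_centers[-1] + self.dlon / 2),
            float(self.lat_centers[-1] + self.dlat / 2),
        )

    def matches(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lon_centers, other.lon_centers, atol=tol)
            and np.allclose(self.lat_centers, other.lat_centers, atol=tol)
        )


def require_same_grid(a: GridSpec, b: GridSpec, what: str = "fields") -> None:
    if not a.matches(b):
        raise ValueError(f"grid mismatch between {what}")
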