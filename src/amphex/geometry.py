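"""Spherical-area geometry helpers for lon/lat vector data.

Polygons are in geographic WGS84 coordinates (degrees lon/lat).  Areas are
evaluated on a sphere of radius 6371 km by mapping coordinates through the
cylindrical equal-area projection x = lambda (rad), y = sin(phi): planar area
in that space times R^2 is the spherical area.  Because polygon edges are
straight in lon/lat space but curved in the projected space, edges are
densified to at most ``DENSIFY_DEG`` degrees before projecting; the residual
chord error is O(dphi^2) and far below every tolerance used here.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import EARTH_RADIUS_KM, GridSpec

DENSIFY_DEG = 0.01


def _equal_area(coords: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords[:, :2])
    out[:, 0] = np.radians(coords[:, 0])
    out[:, 1] = np.sin(np.radians(coords[:, 1]))
    return out


def spherical_area_km2(geoms) -> np.ndarray | float:
    """Spherical area (km^2) of lon/lat geometries (scalar in, scalar out)."""
    arr = np.asarray(geoms, dtype=object)
    scalar = arr.ndim == 0
    g = shapely.segmentize(arr if not scalar else arr[None], DENSIFY_DEG)
    g = shapely.transform(g, _equal_area)
    areas = shapely.area(g) * EARTH_RADIUS_KM**2
    return float(areas[0]) if scalar else areas


def repair_geometry(geom: BaseGeometry, label: str = "geometry") -> BaseGeometry:
    """Make a geometry valid, warn if repair was needed, and union its parts.

    Overlapping parts of a multipart geometry are unioned so that areas are
    never double counted.
    """
    if not geom.is_valid:
        warnings.warn(f"{label}: invalid geometry repaired", stacklevel=2)
        geom = shapely.make_valid(geom)
    merged = shapely.union_all(shapely.get_parts(geom))
    if merged.is_empty or shapely.area(merged) <= 0:
        raise ValueError(f"{label}: empty or zero-area geometry")
    return merged


def cell_boxes(grid: GridSpec, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """Shapely boxes for cells at (lat index ii, lon index jj)."""
    lonb = grid.lon_bounds()
    latb = grid.lat_bounds()
    return shapely.box(lonb[jj, 0], latb[ii, 0], lonb[jj, 1], latb[ii, 1])


def candidate_cells(grid: GridSpec, geom: BaseGeometry) -> tuple[np.ndarray, np.ndarray]:
    """(ii, jj) index arrays of cells whose bounds overlap ``geom``'s bbox."""
    minx, miny, maxx, maxy = geom.bounds
    lonb = grid.lon_bounds()
    latb = grid.lat_bounds()
    jj = np.flatnonzero((lonb[:, 1] > minx) & (lonb[:, 0] < maxx))
    ii = np.flatnonzero((latb[:, 1] > miny) & (latb[:, 0] < maxy))
    II, JJ = np.meshgrid(ii, jj, indexing="ij")
    return II.ravel(), JJ.ravel()


def cell_intersection_areas(
    grid: GridSpec, geom: BaseGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spherical area of cell-by-cell intersection with ``geom``.

    Returns (ii, jj, areas_km2) for candidate cells; cells that merely touch
    have zero area.
    """
    ii, jj = candidate_cells(grid, geom)
    if ii.size == 0:
        return ii, jj, np.zeros(0)
    boxes = cell_boxes(grid, ii, jj)
    shapely.prepare(geom)
    hits = shapely.intersects(boxes, geom)
    areas = np.zeros(ii.size)
    if hits.any():
        pieces = shapely.intersection(boxes[hits], geom)
        areas[hits] = spherical_area_km2(pieces)
    return ii, jj, areas


def cells_intersected(
    grid: GridSpec, geom: BaseGeometry, rule: str = "area"
) -> np.ndarray:
    """Boolean (nlat, nlon) membership of ``geom`` in grid cells.

    rule "area": positive-area intersection (boundary touches excluded);
    rule "center": the cell center lies within the geometry.
    """
    out = np.zeros(grid.shape, dtype=bool)
    if rule == "center":
        lon, lat = np.meshgrid(grid.lon_centers, grid.lat_centers)
        shapely.prepare(geom)
        out[:] = shapely.contains_xy(geom, lon.ravel(), lat.ravel()).reshape(grid.shape)
        return out
    if rule != "area":
        raise ValueError(f"unknown intersection rule {rule!r}")
    ii, jj = candidate_cells(grid, geom)
    if ii.size == 0:
        return out
    boxes = cell_boxes(grid, ii, jj)
    shapely.prepare(geom)
    hits = shapely.intersects(boxes, geom) & ~shapely.touches(boxes, geom)
    out[ii[hits], jj[hits]] = True
    return out
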