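"""Independent reference implementations used only to cross-check the package.

Each oracle takes a deliberately different route from the implementation it
checks: exhaustive day-by-day scanning for run detection, fine-subcell
quadrature for range/layer overlap, and grid-search-plus-polish likelihood
maximization for the binary logit.
"""

import numpy as np
import shapely
from scipy.optimize import minimize

from amphex.grid import EARTH_RADIUS_KM


def scan_runs(values, threshold, direction, min_len, mask=None):
    """Day-by-day scan for maximal exceedance runs of length >= min_len."""
    events = []
    run = 0
    start = None
    for i, v in enumerate(values):
        hit = not (mask is not None and mask[i]) and np.isfinite(v) and (
            v > threshold if direction == "above" else v < threshold
        )
        if hit:
            if run == 0:
                start = i
            run += 1
        else:
            if run >= min_len:
                events.append((start, run))
            run = 0
    if run >= min_len:
        events.append((start, run))
    return events


def fine_raster_overlap(geom, layer, sub_deg=0.02):
    """Overlap proportion by fine-subcell quadrature.

    The layer grid is subdivided into sub_deg subcells (an exact divisor of
    the cell size so each subcell has a single parent cell).  Each subcell
    contributes its planar overlap fraction with the geometry times its
    spherical area; overlap sums subcells of inside cells, the total sums all
    subcells on the grid.
    """
    grid = layer.grid
    factor = grid.dlon / sub_deg
    assert abs(factor - round(factor)) < 1e-9, "sub_deg must divide the cell size"
    lon0g, lat0g, lon1g, lat1g = grid.extent()
    minx, miny, maxx, maxy = geom.bounds
    minx, maxx = max(minx, lon0g), min(maxx, lon1g)
    miny, maxy = max(miny, lat0g), min(maxy, lat1g)
    i0 = int(np.floor((minx - lon0g) / sub_deg))
    i1 = int(np.ceil((maxx - lon0g) / sub_deg))
    j0 = int(np.floor((miny - lat0g) / sub_deg))
    j1 = int(np.ceil((maxy - lat0g) / sub_deg))
    xs = lon0g + sub_deg * np.arange(i0, i1)
    ys = lat0g + sub_deg * np.arange(j0, j1)
    X, Y = np.meshgrid(xs, ys)
    x0, y0 = X.ravel(), Y.ravel()
    boxes = shapely.box(x0, y0, x0 + sub_deg, y0 + sub_deg)
    shapely.prepare(geom)
    frac = shapely.area(shapely.intersection(boxes, geom)) / sub_deg**2
    # spherical area of each subcell
    lat_lo = np.radians(y0)
    lat_hi = np.radians(y0 + sub_deg)
    w = EARTH_RADIUS_KM**2 * np.radians(sub_deg) * (np.sin(lat_hi) - np.sin(lat_lo))
    contrib = frac * w
    # parent cell indices
    ci = np.clip(((y0 + sub_deg / 2 - lat0g) / grid.dlat).astype(int), 0, grid.shape[0] - 1)
    cj = np.clip(((x0 + sub_deg / 2 - lon0g) / grid.dlon).astype(int), 0, grid.shape[1] - 1)
    inside = layer.inside[ci, cj]
    total = contrib.sum()
    overlap = contrib[inside].sum()
    return float(overlap), float(total), float(overlap / total)


def binary_logit_mle(y, x):
    """Binary logit MLE by coarse grid search then simplex polish.

    y in {0, 1}; design is [1, x].  Returns (intercept, slope).
    """
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(y, dtype=float), np.asarray(x, float)])

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - y * eta))

    grid = np.linspace(-5, 5, 41)
    best = min(((nll([a, b]), (a, b)) for a in grid for b in grid), key=lambda t: t[0])
    res = minimize(nll, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return res.x
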