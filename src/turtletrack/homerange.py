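"""Kernel utilization distributions, isopleths, and minimum convex polygons.

The UD is a bivariate Gaussian kernel density on a regular grid in local
projected coordinates (meters).  The smoothing parameter can be chosen by the
contiguity rule: start from the reference value h0 = sigma * n^(-1/6) and
shrink it gradually, stopping at the smallest value whose 95% isopleth is
still a single connected region.  Isopleths are the smallest-area cell sets
containing the requested probability mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union

ISOPLETH_LEVELS = (0.25, 0.50, 0.90, 0.95)


@dataclass
class UDGrid:
    origin: Tuple[float, float]     # (x0, y0) of cell (0, 0) lower-left corner, m
    cell_size: float                # m
    density: np.ndarray             # (ny, nx), integrates to 1 over the plane
    h: float                        # smoothing parameter, m

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    @property
    def nx(self) -> int:
        return self.density.shape[1]

    @property
    def ny(self) -> int:
        return self.density.shape[0]

    def cell_mass(self) -> np.ndarray:
        return self.density * self.cell_area


@dataclass
class IsoplethPolygon:
    level: float
    polygon: MultiPolygon
    area_km2: float
    contiguous: bool
    n_parts: int


@dataclass
class MCPResult:
    hull: Polygon
    area_km2: float
    asymptote_reached: bool
    cumulative_days: np.ndarray = field(default=None)
    cumulative_area_km2: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# Kernel UD
# ---------------------------------------------------------------------------

def kde_ud(points_xy: np.ndarray, h: float, cell_size: float = 50.0,
           pad_factor: float = 3.0,
           bounds: Optional[Tuple[np.ndarray, np.ndarray]] = None) -> UDGrid:
    """Bivariate Gaussian kernel density of projected points on a grid.

    The grid extends ``pad_factor * h`` beyond the data bounding box (or uses
    explicit ``bounds`` = (lower-left, upper-right)).  The density is computed
    by binning the points and convolving with the Gaussian kernel, then
    normalized so that its integral over the grid is exactly 1.
    """
    pts = np.asarray(points_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 5:
        raise ValueError("need at least 5 points for a kernel UD")
    if h <= 0:
        raise ValueError("smoothing parameter h must be positive")
    if np.allclose(pts.std(axis=0), 0.0):
        raise ValueError("all points identical; supply a minimum h and jitter, "
                         "or use more points")

    if bounds is None:
        lo = pts.min(axis=0) - pad_factor * h
        hi = pts.max(axis=0) + pad_factor * h
    else:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    nx = max(int(np.ceil((hi[0] - lo[0]) / cell_size)), 8)
    ny = max(int(np.ceil((hi[1] - lo[1]) / cell_size)), 8)

    ix = np.clip(((pts[:, 0] - lo[0]) / cell_size).astype(int), 0, nx - 1)
    iy = np.clip(((pts[:, 1] - lo[1]) / cell_size).astype(int), 0, ny - 1)
    counts = np.zeros((ny, nx), dtype=float)
    np.add.at(counts, (iy, ix), 1.0)

    sigma_cells = h / cell_size
    dens = ndimage.gaussian_filter(counts, sigma=sigma_cells, mode="constant",
                                   truncate=6.0)
    total = dens.sum() * cell_size ** 2
    if total <= 0:
        raise ValueError("degenerate density")
    dens /= total
    return UDGrid(origin=(float(lo[0]), float(lo[1])), cell_size=cell_size,
                  density=dens, h=h)


def _mass_mask(ud: UDGrid, level: float) -> np.ndarray:
    """Boolean mask of the smallest cell set holding ``level`` of total mass."""
    mass = ud.cell_mass().ravel()
    order = np.argsort(mass)[::-1]
    cum = np.cumsum(mass[order])
    target = level * cum[-1]
    k = int(np.searchsorted(cum, target)) + 1
    k = min(k, mass.size)
    mask = np.zeros(mass.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(ud.density.shape)


def isopleth(ud: UDGrid, level: float) -> IsoplethPolygon:
    """Smallest-area region containing ``level`` of the UD mass.

    Cells are ranked by density; the region is the union of the top cells
    whose cumulative mass reaches ``level``.  Contiguity is judged by
    8-connectivity of the selected cells; the polygon is the union of the
    cell squares (projected meters), with area reported in km².
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    mask = _mass_mask(ud, level)
    n_cells = int(mask.sum())
    if n_cells == 0:
        raise ValueError("isopleth level unreachable on this grid")
    labels, n_parts = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    area_km2 = n_cells * ud.cell_area / 1e6

    x0, y0 = ud.origin
    cs = ud.cell_size
    ys, xs = np.nonzero(mask)
    boxes = [box(x0 + j * cs, y0 + i * cs, x0 + (j + 1) * cs, y0 + (i + 1) * cs)
             for i, j in zip(ys, xs)]
    geom = unary_union(boxes)
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    return IsoplethPolygon(level=level, polygon=geom, area_km2=area_km2,
                           contiguous=(n_parts == 1), n_parts=int(n_parts))


def isopleth_contiguous(ud: UDGrid, level: float = 0.95) -> bool:
    """Contiguity of the ``level`` mass region without polygonizing."""
    mask = _mass_mask(ud, level)
    _, n_parts = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return n_parts == 1


def reference_h(points_xy: np.ndarray) -> float:
    """Reference (ad hoc) smoothing h0 = sigma * n^(-1/6) with
    sigma = sqrt((var_x + var_y) / 2)."""
    pts = np.asarray(points_xy, dtype=float)
    sigma = float(np.sqrt(pts.var(axis=0, ddof=1).mean()))
    if sigma == 0:
        raise ValueError("degenerate point set")
    return sigma * len(pts) ** (-1.0 / 6.0)


def select_h_adhoc(points_xy: np.ndarray, level: float = 0.95,
                   shrink: float = 0.95, cell_size: float = 50.0,
                   min_h: Optional[float] = None) -> Tuple[float, bool]:
    """Contiguity-based smoothing selection.

    Starting from ``h0`` (see :func:`reference_h`), repeatedly multiply h by
    ``shrink`` while the ``level`` isopleth remains a single connected region;
    return the last contiguous h.  Returns ``(h, satisfied)`` where
    ``satisfied`` is False when even h0 gives a fragmented isopleth.
    """
    pts = np.asarray(points_xy, dtype=float)
    if len(pts) < 30:
        warnings.warn("select_h_adhoc: fewer than 30 points", stacklevel=2)
    h0 = reference_h(pts)
    if min_h is None:
        min_h = cell_size  # below one grid cell the contiguity test is meaningless
    ud = kde_ud(pts, h=h0, cell_size=cell_size)
    if not isopleth_contiguous(ud, level):
        return h0, False
    h = h0
    if shrink >= 1.0:
        return h0, True
    while True:
        h_next = h * shrink
        if h_next < min_h:
            break
        ud = kde_ud(pts, h=h_next, cell_size=cell_size)
        if not isopleth_contiguous(ud, level):
            break
        h = h_next
    return h, True


# ---------------------------------------------------------------------------
# Minimum convex polygon
# ---------------------------------------------------------------------------

def mcp(points_xy: np.ndarray, percent: float = 100.0,
        days: Optional[np.ndarray] = None,
        asymptote_tail: float = 0.10, asymptote_tol: float = 0.05) -> MCPResult:
    """Minimum convex polygon (total residence area) in km².

    ``percent`` < 100 trims the points farthest from the centroid before the
    hull is taken.  When per-point ``days`` (tracking day of each point) are
    given, a cumulative-area-by-day series is computed and the asymptote flag
    is set when the final ``asymptote_tail`` fraction of tracking days adds
    less than ``asymptote_tol`` of the final area.
    """
    pts = np.asarray(points_xy, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for an MCP")
    if percent < 100.0:
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        keep = d <= np.percentile(d, percent)
        pts = pts[keep]
        if days is not None:
            days = np.asarray(days)[keep]
    from shapely.geometry import MultiPoint

    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0.0:
        warnings.warn("collinear points: zero-area hull", stacklevel=2)
        hull = hull.buffer(0.0) if hull.geom_type == "Polygon" else Polygon()
        return MCPResult(hull=hull, area_km2=0.0, asymptote_reached=False)
    area_km2 = hull.area / 1e6

    cum_days = cum_area = None
    asymptote = False
    if days is not None:
        days = np.asarray(days, dtype=float)
        order = np.argsort(days)
        pts_o, days_o = pts[order], days[order]
        uniq = np.unique(days_o)
        areas = []
        for d in uniq:
            sub = pts_o[days_o <= d]
            if len(sub) >= 3:
                areas.append(MultiPoint(sub).convex_hull.area / 1e6)
            else:
                areas.append(0.0)
        cum_days, cum_area = uniq, np.maximum.accumulate(np.asarray(areas))
        span = uniq[-1] - uniq[0]
        cutoff = uniq[-1] - asymptote_tail * span
        before = cum_area[np.searchsorted(uniq, cutoff, side="right") - 1]
        final = cum_area[-1]
        if final > 0:
            asymptote = (final - before) / final < asymptote_tol
    return MCPResult(hull=hull, area_km2=area_km2, asymptote_reached=asymptote,
                     cumulative_days=cum_days, cumulative_area_km2=cum_area)


# ---------------------------------------------------------------------------
# Per-animal summary
# ---------------------------------------------------------------------------

def summarize_home_ranges(rows: Sequence[dict]) -> "pd.DataFrame":
    """Per-animal 25/50/90% UD and MCP areas with column means.

    ``rows`` are dicts with keys ``tag_id, ud25_km2, ud50_km2, ud90_km2,
    mcp_km2`` and an optional boolean ``post_migration``; flagged rows are
    listed but excluded from the mean row.
    """
    import pandas as pd

    if not rows:
        raise ValueError("no animals to summarize")
    df = pd.DataFrame(rows)
    if "post_migration" not in df.columns:
        df["post_migration"] = False
    df["post_migration"] = (df["post_migration"].astype("boolean")
                            .fillna(False).astype(bool))
    cols = ["ud25_km2", "ud50_km2", "ud90_km2", "mcp_km2"]
    means = df.loc[~df["post_migration"], cols].mean()
    mean_row = {"tag_id": "Mean", "post_migration": False, **means.to_dict()}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
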