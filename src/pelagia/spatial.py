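"""Spherical geometry, daily travel distances, and kernel utilization distributions.

Positions are geographic (longitude, latitude) in decimal degrees. Because the
North Pacific study region straddles the antimeridian, longitudes are folded
into [0, 360) before any gridding or projection so that tracks and density
surfaces never split at 180°.

The utilization distribution (UD) follows the classic kernel home-range
workflow: positions are projected with a Lambert cylindrical equal-area
projection, binned on a grid whose cells have the area of a 0.25° x 0.25° cell
at the equator, effort-normalized so that no single bird dominates a cell,
smoothed with 2-D Gaussian kernels whose bandwidth adapts to a pilot density
(Abramson's square-root law), and renormalized to a proper probability
surface. Contours at a level q are the smallest set of cells holding q of the
total density ("q% UD").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
#: nominal grid resolution: a 0.25 deg x 0.25 deg cell at the equator
DEFAULT_CELL_DEG = 0.25


def wrap360(lon):
    """Fold longitudes into [0, 360)."""
    return np.asarray(lon, dtype=float) % 360.0


def wrap180(lon):
    """Fold longitudes into [-180, 180)."""
    lon = np.asarray(lon, dtype=float) % 360.0
    return np.where(lon >= 180.0, lon - 360.0, lon)


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays. Symmetric, zero iff the points
    coincide, and insensitive to the longitude branch (wrapping).
    """
    lon1, lat1, lon2, lat2 = (np.asarray(a, dtype=float) for a in (lon1, lat1, lon2, lat2))
    if np.any(np.abs(np.concatenate([np.atleast_1d(lat1).ravel(), np.atleast_1d(lat2).ravel()])) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if not (np.all(np.isfinite(lon1)) and np.all(np.isfinite(lat1))
            and np.all(np.isfinite(lon2)) and np.all(np.isfinite(lat2))):
        raise ValueError("non-finite coordinate")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def destination_point(lon, lat, bearing_deg, distance_km):
    """Point reached travelling ``distance_km`` along the great circle with
    initial ``bearing_deg`` (clockwise from north) from (lon, lat)."""
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    theta = np.radians(bearing_deg)
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta))
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return (np.degrees(lam2) % 360.0), np.degrees(phi2)


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, degrees from north."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2, float) - np.asarray(lon1, float))
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return np.degrees(np.arctan2(y, x)) % 360.0


def daily_travel(track: pd.DataFrame) -> pd.Series:
    """Daily travel distance (km) between consecutive daily positions.

    ``track`` needs columns ``date`` (datelike), ``lon``, ``lat`` with at most
    one row per day. The first day and any day following a date gap (e.g. the
    equinox exclusion window) get NaN — gaps are never interpolated.
    """
    t = track.sort_values("date").reset_index(drop=True)
    dates = pd.to_datetime(t["date"])
    d = np.full(len(t), np.nan)
    if len(t) > 1:
        dist = great_circle_km(t["lon"].values[:-1], t["lat"].values[:-1],
                               t["lon"].values[1:], t["lat"].values[1:])
        contiguous = (dates.diff().dt.days.values[1:] == 1)
        d[1:] = np.where(contiguous, dist, np.nan)
    return pd.Series(d, index=t.index, name="daily_km")


# ---------------------------------------------------------------------------
# Equal-area projection
# ---------------------------------------------------------------------------

def lcea_project(lon, lat, lon0: float = 180.0, std_parallel: float = 0.0):
    """Lambert cylindrical equal-area projection to km.

    x = R (λ - λ0) cosφs,  y = R sinφ / cosφs.  With the default standard
    parallel φs = 0 a 0.25° x 0.25° cell at the equator maps to a square of
    side R·π/180·0.25 ≈ 27.8 km, and every projected cell of that side has
    identical true area (the defining property used by the UD grid).
    """
    lon = wrap360(lon)
    # center on lon0, keeping values continuous across the antimeridian
    dlam = (lon - lon0 + 180.0) % 360.0 - 180.0
    c = np.cos(np.radians(std_parallel))
    x = EARTH_RADIUS_KM * np.radians(dlam) * c
    y = EARTH_RADIUS_KM * np.sin(np.radians(lat)) / c
    return x, y


def lcea_unproject(x, y, lon0: float = 180.0, std_parallel: float = 0.0):
    c = np.cos(np.radians(std_parallel))
    lon = (np.degrees(np.asarray(x, float) / (EARTH_RADIUS_KM * c)) + lon0) % 360.0
    lat = np.degrees(np.arcsin(np.clip(np.asarray(y, float) * c / EARTH_RADIUS_KM, -1, 1)))
    return lon, lat


# ---------------------------------------------------------------------------
# Kernel utilization distribution
# ---------------------------------------------------------------------------

@dataclass
class UDGrid:
    """Effort-normalized kernel density surface on an equal-area grid.

    density[i, j] is the probability mass of cell (row i, col j); rows index
    the y (projected northing) axis. ``x_edges``/``y_edges`` are the cell
    boundaries in projected km; ``contributing_birds`` counts distinct birds
    with at least one raw fix in the cell; ``h_local`` is the adaptive
    bandwidth (km) attached to each input point.
    """

    density: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    lon0: float
    contributing_birds: np.ndarray
    h_local: np.ndarray
    cell_km: float

    @property
    def x_centers(self):
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self):
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def cell_lonlat(self):
        """Geographic coordinates of every cell center, shaped like density."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return lcea_unproject(xx, yy, lon0=self.lon0)

    def to_frame(self) -> pd.DataFrame:
        lon, lat = self.cell_lonlat()
        return pd.DataFrame({
            "lon": wrap180(lon.ravel()), "lat": lat.ravel(),
            "density": self.density.ravel(),
            "contributing_birds": self.contributing_birds.ravel(),
        })


@dataclass
class UDContours:
    """Nested highest-density cell sets at the requested levels."""

    levels: tuple
    masks: dict = field(default_factory=dict)      # level -> boolean array
    cell_area_km2: float = np.nan

    def area_km2(self, level) -> float:
        return float(self.masks[level].sum()) * self.cell_area_km2

    def polygons(self, grid: UDGrid):
        """Shapely (multi)polygon per level, unioned from member cell boxes."""
        from shapely.geometry import box
        from shapely.ops import unary_union
        out = {}
        for lev, mask in self.masks.items():
            ii, jj = np.nonzero(mask)
            boxes = [box(grid.x_edges[j], grid.y_edges[i],
                         grid.x_edges[j + 1], grid.y_edges[i + 1])
                     for i, j in zip(ii, jj)]
            out[lev] = unary_union(boxes) if boxes else None
        return out


def _silverman_h(xy: np.ndarray, weights: np.ndarray) -> float:
    """Weighted reference bandwidth; n^(-1/5) scaling deliberately
    undersmooths relative to the 2-D optimal rate to limit mass-spreading bias
    on the discrete grid."""
    n_eff = weights.sum() ** 2 / np.sum(weights ** 2)
    sd = np.sqrt(np.average((xy - np.average(xy, axis=0, weights=weights)) ** 2,
                            axis=0, weights=weights))
    sd = np.where(sd <= 0, np.nanmax([sd.max(), 1.0]), sd)
    return float(np.sqrt(sd[0] * sd[1])) * n_eff ** (-1.0 / 5.0)


def kde_ud(points: pd.DataFrame, cell_deg: float = DEFAULT_CELL_DEG,
           lon0: float | None = None, pad_cells: int = 12,
           adaptive: bool = True, alpha: float = 0.5,
           effort_normalize: bool = True,
           normalize_order: str = "before-smoothing") -> UDGrid:
    """Effort-normalized adaptive-kernel utilization distribution.

    Parameters
    ----------
    points : DataFrame with columns bird_id, lon, lat (one row per daily fix).
    cell_deg : nominal cell size; cells are squares in the equal-area plane
        with the area of a cell_deg x cell_deg cell at the equator.
    adaptive : use Abramson pilot-density bandwidths, h_i = h0 (f~(x_i)/g)^-alpha
        with g the geometric mean pilot density; alpha=0.5 is the square-root law.
    effort_normalize : weight each point by 1 / (number of distinct birds with
        a fix in its cell), so a cell visited by one prolific bird does not
        swamp cells shared by many.
    normalize_order : "before-smoothing" (default; weights applied to points,
        density remains a proper distribution) or "after-smoothing"
        (smooth raw counts, then divide the smoothed surface per cell —
        sensitivity variant).

    Returns a :class:`UDGrid` whose density sums to 1.
    """
    if len(points) == 0:
        raise ValueError("kde_ud needs at least one point")
    if normalize_order not in ("before-smoothing", "after-smoothing"):
        raise ValueError(f"unknown normalize_order {normalize_order!r}")
    lon = wrap360(points["lon"].values)
    lat = np.asarray(points["lat"].values, dtype=float)
    birds = points["bird_id"].values
    if lon0 is None:
        # circular-ish center: midpoint of the folded longitude range
        lon0 = float(0.5 * (lon.min() + lon.max()))
    x, y = lcea_project(lon, lat, lon0=lon0)

    cell_km = EARTH_RADIUS_KM * np.radians(cell_deg)
    pad = pad_cells * cell_km
    x_edges = np.arange(x.min() - pad, x.max() + pad + cell_km, cell_km)
    y_edges = np.arange(y.min() - pad, y.max() + pad + cell_km, cell_km)
    ix = np.clip(np.searchsorted(x_edges, x, side="right") - 1, 0, len(x_edges) - 2)
    iy = np.clip(np.searchsorted(y_edges, y, side="right") - 1, 0, len(y_edges) - 2)
    shape = (len(y_edges) - 1, len(x_edges) - 1)

    # distinct birds per cell
    cell_of = iy * shape[1] + ix
    per_cell_birds = pd.DataFrame({"cell": cell_of, "bird": birds}).groupby("cell")["bird"].nunique()
    contributing = np.zeros(shape[0] * shape[1], dtype=int)
    contributing[per_cell_birds.index.values] = per_cell_birds.values
    contributing = contributing.reshape(shape)

    if effort_normalize and normalize_order == "before-smoothing":
        w = 1.0 / contributing.reshape(-1)[cell_of].astype(float)
    else:
        w = np.ones(len(x))

    xy = np.column_stack([x, y])
    h0 = max(_silverman_h(xy, w), 0.5 * cell_km)
    if adaptive:
        pilot = _eval_kde_at_points(xy, xy, w, h0)
        pilot = np.maximum(pilot, np.finfo(float).tiny)
        g = np.exp(np.mean(np.log(pilot)))
        h_local = h0 * (pilot / g) ** (-alpha)
        # guard against unbounded bandwidths from isolated points
        h_local = np.clip(h_local, 0.25 * h0, 8.0 * h0)
    else:
        h_local = np.full(len(x), h0)

    density = _accumulate_kernels(x, y, w, h_local, x_edges, y_edges)

    if effort_normalize and normalize_order == "after-smoothing":
        density = density / np.maximum(contributing, 1)
    total = density.sum()
    if total <= 0:
        raise ValueError("degenerate density surface")
    density = density / total
    return UDGrid(density=density, x_edges=x_edges, y_edges=y_edges, lon0=lon0,
                  contributing_birds=contributing, h_local=h_local, cell_km=cell_km)


def _eval_kde_at_points(xy_eval, xy_data, w, h, block: int = 512):
    """Fixed-bandwidth weighted 2-D Gaussian KDE evaluated at points."""
    out = np.empty(len(xy_eval))
    norm = w.sum() * 2.0 * np.pi * h * h
    for s in range(0, len(xy_eval), block):
        d2 = ((xy_eval[s:s + block, None, :] - xy_data[None, :, :]) ** 2).sum(-1)
        out[s:s + block] = (w * np.exp(-0.5 * d2 / (h * h))).sum(1) / norm
    return out


def _accumulate_kernels(x, y, w, h, x_edges, y_edges):
    """Sum per-point Gaussian kernels over cell centers (truncated at 5h)."""
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    dens = np.zeros((len(yc), len(xc)))
    order = np.argsort(h)  # similar bandwidths together: better cache use
    for i in order:
        hi = h[i]
        r = 5.0 * hi
        j0, j1 = np.searchsorted(xc, [x[i] - r, x[i] + r])
        i0, i1 = np.searchsorted(yc, [y[i] - r, y[i] + r])
        if j0 == j1 or i0 == i1:
            continue
        gx = np.exp(-0.5 * ((xc[j0:j1] - x[i]) / hi) ** 2)
        gy = np.exp(-0.5 * ((yc[i0:i1] - y[i]) / hi) ** 2)
        dens[i0:i1, j0:j1] += (w[i] / (2 * np.pi * hi * hi)) * np.outer(gy, gx)
    return dens


def ud_contours(grid: UDGrid, levels=(0.25, 0.50, 0.75, 0.95)) -> UDContours:
    """Smallest cell sets containing each density level.

    Cells are ranked by descending density (ties broken by flat cell index so
    the result is deterministic); level q gets the shortest prefix whose
    cumulative density is >= q. Nesting across levels holds by construction.
    """
    levels = tuple(sorted(levels))
    for q in levels:
        if not (0.0 < q < 1.0):
            raise ValueError(f"contour level {q} outside (0, 1)")
    flat = grid.density.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    csum = np.cumsum(flat[order])
    masks = {}
    for q in levels:
        k = int(np.searchsorted(csum, q - 1e-9, side="left")) + 1
        m = np.zeros(flat.size, dtype=bool)
        m[order[:min(k, flat.size)]] = True
        masks[q] = m.reshape(grid.density.shape)
    return UDContours(levels=levels, masks=masks, cell_area_km2=grid.cell_km ** 2)
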