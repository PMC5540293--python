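"""Kernel utilization distributions and estuary-polygon delineation.

Space use is summarised as a fixed-kernel utilization distribution (UD): an
isotropic bivariate normal kernel is placed on each (projected, km-scale)
location and the summed density is evaluated on a regular grid. The
smoothing parameter is chosen by least-squares cross-validation (LSCV),
which minimises an unbiased estimate of the integrated squared error of the
density estimate. Probability contours (e.g. the 95% polygon) are the
smallest set of grid cells containing the stated fraction of UD mass.

The estuary polygon bounds the pre-migration locations with an alpha shape
(Delaunay triangles filtered by circumradius), which—unlike a convex
hull—excludes regions with no recorded locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import unary_union

__all__ = [
    "UDGrid",
    "ContourLevel",
    "lscv_bandwidth",
    "lscv_score",
    "kde_ud",
    "probability_contour",
    "probability_contours",
    "central_points",
    "estuary_polygon",
]


@dataclass(frozen=True)
class UDGrid:
    """Gridded utilization distribution in local km coordinates.

    ``density[iy, ix]`` is probability density per km² at the centre of the
    cell whose lower-left corner is ``(x0 + ix·cell_km, y0 + iy·cell_km)``.
    Total mass (Σ density × cell area) is 1 to within 1e-6.
    """

    x0: float
    y0: float
    cell_km: float
    density: np.ndarray = field(repr=False)
    crs_note: str = "local azimuthal equidistant, km"

    @property
    def cell_area(self) -> float:
        return self.cell_km**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.density.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.cell_km
        ys = self.y0 + (np.arange(ny) + 0.5) * self.cell_km
        return xs, ys

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)

    def to_esri_ascii(self) -> str:
        """ESRI ASCII grid text (row 1 = northernmost row)."""
        ny, nx = self.density.shape
        lines = [
            f"ncols {nx}",
            f"nrows {ny}",
            f"xllcorner {self.x0}",
            f"yllcorner {self.y0}",
            f"cellsize {self.cell_km}",
            "NODATA_value -9999",
        ]
        for row in self.density[::-1]:
            lines.append(" ".join(f"{v:.10g}" for v in row))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ContourLevel:
    level_pct: float
    mass: float
    area_km2: float
    polygon: object = field(repr=False)  # shapely (Multi)Polygon
    cell_mask: np.ndarray = field(repr=False)


def _pairwise_sq(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def lscv_score(points: np.ndarray, h: float, _d2=None) -> float:
    """Least-squares cross-validation criterion for an isotropic Gaussian KDE.

    ``LSCV(h) = ∫ f̂² − (2/n) Σ_i f̂₋ᵢ(xᵢ)``, both terms in closed form for
    the bivariate normal kernel (the convolution of two kernels of bandwidth
    h is a kernel of bandwidth h√2).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    d2 = _pairwise_sq(points) if _d2 is None else _d2
    int_f2 = np.exp(-d2 / (4.0 * h * h)).sum() / (n * n * 4.0 * np.pi * h * h)
    off = np.exp(-d2 / (2.0 * h * h)).sum() - n  # exclude the diagonal (=1 each)
    loo = off / (n * (n - 1) * 2.0 * np.pi * h * h)
    return float(int_f2 - 2.0 * loo)


def reference_bandwidth(points: np.ndarray) -> float:
    """Normal-reference (rule-of-thumb) bandwidth for a 2-D isotropic kernel,
    ``h_ref = σ n^{-1/6}`` with σ the mean of the axis SDs."""
    points = np.asarray(points, dtype=float)
    sigma = float(np.mean(points.std(axis=0, ddof=1)))
    return sigma * len(points) ** (-1.0 / 6.0)


def lscv_bandwidth(
    points: np.ndarray,
    search_range: tuple[float, float] = (0.05, 2.0),
    n_grid: int = 60,
) -> tuple[float, pd.DataFrame]:
    """LSCV-optimal bandwidth (km) and the criterion trace.

    The criterion is scanned on a log-spaced grid over
    ``search_range × h_ref`` and refined by bounded minimisation between the
    grid neighbours of the best point. Duplicate-heavy data can drive the
    criterion toward h → 0; the search then clamps to the lower bound with a
    warning rather than returning a degenerate bandwidth.
    """
    points = np.asarray(points, dtype=float)
    if len(np.unique(points, axis=0)) < 10:
        raise ValueError("need at least 10 distinct points for LSCV")
    from scipy.optimize import minimize_scalar

    href = reference_bandwidth(points)
    if href == 0:
        raise ValueError("degenerate point set (zero spread)")
    d2 = _pairwise_sq(points)
    hs = np.geomspace(search_range[0] * href, search_range[1] * href, n_grid)
    scores = np.array([lscv_score(points, h, _d2=d2) for h in hs])
    trace = pd.DataFrame({"h_km": hs, "lscv": scores})
    i = int(np.argmin(scores))
    if i == 0:
        warnings.warn("LSCV minimum at the lower search bound; bandwidth clamped")
        return float(hs[0]), trace
    if i == len(hs) - 1:
        warnings.warn("LSCV minimum at the upper search bound; bandwidth clamped")
        return float(hs[-1]), trace
    res = minimize_scalar(
        lambda h: lscv_score(points, h, _d2=d2),
        bounds=(hs[i - 1], hs[i + 1]),
        method="bounded",
        options={"xatol": 1e-4 * href},
    )
    return float(res.x), trace


def kde_ud(
    points: np.ndarray,
    h: float,
    cell_km: float = 1.0,
    margin_factor: float = 3.0,
    grid_spec: tuple | None = None,
    max_mass_deficit: float = 1e-3,
) -> UDGrid:
    """Normalized kernel UD on a regular grid.

    The grid either comes from ``grid_spec = (x0, y0, nx, ny)`` or is built
    automatically to cover the points with a ``margin_factor × h`` margin
    (enlarged until the un-normalised mass deficit from truncation is below
    ``max_mass_deficit``). Density is the exact kernel sum at each cell
    centre, then renormalised so Σ density × cell area = 1.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    if h <= 0:
        raise ValueError("bandwidth h must be positive")

    margin = margin_factor * h
    for _attempt in range(6):
        if grid_spec is not None:
            x0, y0, nx, ny = grid_spec
        else:
            x0 = np.floor((points[:, 0].min() - margin) / cell_km) * cell_km
            y0 = np.floor((points[:, 1].min() - margin) / cell_km) * cell_km
            nx = int(np.ceil((points[:, 0].max() + margin - x0) / cell_km))
            ny = int(np.ceil((points[:, 1].max() + margin - y0) / cell_km))
        xs = x0 + (np.arange(nx) + 0.5) * cell_km
        ys = y0 + (np.arange(ny) + 0.5) * cell_km
        dx2 = (xs[None, :] - points[:, 0][:, None]) ** 2  # (n, nx)
        dy2 = (ys[None, :] - points[:, 1][:, None]) ** 2  # (n, ny)
        # density(iy, ix) = mean_i k(dx)·k(dy) / (2π h²) — separable kernel
        gx = np.exp(-dx2 / (2.0 * h * h))
        gy = np.exp(-dy2 / (2.0 * h * h))
        dens = gy.T @ gx  # (ny, nx) separable kernel sum over points
        dens /= len(points) * 2.0 * np.pi * h * h
        raw_mass = dens.sum() * cell_km**2
        if grid_spec is not None or (1.0 - raw_mass) < max_mass_deficit:
            break
        margin *= 1.5
    else:
        warnings.warn("grid margin enlargement did not reach target mass")
    if grid_spec is not None and (1.0 - raw_mass) > max_mass_deficit:
        warnings.warn(
            f"supplied grid truncates {1.0 - raw_mass:.2e} of kernel mass"
        )
    dens = dens / raw_mass
    return UDGrid(x0=float(x0), y0=float(y0), cell_km=float(cell_km), density=dens)


def probability_contour(ud: UDGrid, level_pct: float) -> ContourLevel:
    """Smallest cell set holding ≥ ``level_pct``% of UD mass, polygonized.

    Cells are accumulated in descending density order until the mass target
    is reached, so the contained mass lies within one cell's mass above the
    target and contours at increasing levels are nested by construction.
    """
    if not 0 < level_pct < 100:
        raise ValueError("level_pct must be in (0, 100)")
    mass = ud.density.ravel() * ud.cell_area
    order = np.argsort(mass)[::-1]
    cum = np.cumsum(mass[order])
    k = int(np.searchsorted(cum, level_pct / 100.0) + 1)
    k = min(k, len(order))
    mask = np.zeros(ud.density.size, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.density.shape)
    iy, ix = np.nonzero(mask)
    boxes = [
        box(
            ud.x0 + j * ud.cell_km,
            ud.y0 + i * ud.cell_km,
            ud.x0 + (j + 1) * ud.cell_km,
            ud.y0 + (i + 1) * ud.cell_km,
        )
        for i, j in zip(iy, ix)
    ]
    poly = unary_union(boxes)
    return ContourLevel(
        level_pct=float(level_pct),
        mass=float(cum[k - 1]),
        area_km2=float(poly.area),
        polygon=poly,
        cell_mask=mask,
    )


def probability_contours(ud: UDGrid, levels=(25, 50, 75, 95)) -> list[ContourLevel]:
    return [probability_contour(ud, lv) for lv in sorted(levels)]


def central_points(
    points: np.ndarray, ud: UDGrid, level_pct: float = 95.0
) -> dict:
    """Two central-tendency summaries of space use, in km coordinates.

    ``geometric_mean``: per-axis geometric mean of the locations after a
    false-origin shift making every coordinate strictly positive (the shift
    is removed afterwards, and enlarged automatically if needed).
    ``center_of_mass``: density-weighted mean of cell centres over the
    ``level_pct`` contour of the UD.
    """
    points = np.asarray(points, dtype=float)
    out = {}
    gm = np.empty(2)
    for axis in range(2):
        c = points[:, axis]
        offset = 0.0
        if c.min() <= 0:
            offset = 1.0 - c.min()
        shifted = c + offset
        while (shifted <= 0).any():  # numerical safety: grow the false origin
            offset += 1.0
            shifted = c + offset
        gm[axis] = np.exp(np.mean(np.log(shifted))) - offset
    out["geometric_mean"] = (float(gm[0]), float(gm[1]))

    contour = probability_contour(ud, level_pct)
    xs, ys = ud.cell_centers()
    w = np.where(contour.cell_mask, ud.density, 0.0)
    total = w.sum()
    cx = float((w.sum(axis=0) * xs).sum() / total)
    cy = float((w.sum(axis=1) * ys).sum() / total)
    out["center_of_mass"] = (cx, cy)
    return out


def _alpha_shape(points: np.ndarray, alpha_km: float):
    from scipy.spatial import Delaunay, QhullError

    try:
        tri = Delaunay(points)
    except QhullError:
        return None
    triangles = []
    for simplex in tri.simplices:
        a, b, c = points[simplex]
        la, lb, lc = (
            np.linalg.norm(b - c),
            np.linalg.norm(c - a),
            np.linalg.norm(a - b),
        )
        s = 0.5 * (la + lb + lc)
        area2 = max(s * (s - la) * (s - lb) * (s - lc), 0.0)
        if area2 == 0.0:
            continue
        circumradius = la * lb * lc / (4.0 * np.sqrt(area2))
        if circumradius <= alpha_km:
            triangles.append(Polygon([a, b, c]))
    if not triangles:
        return None
    return unary_union(triangles)


def estuary_polygon(
    points: np.ndarray,
    alpha_km: float = 15.0,
    shoreline_line=None,
    axis_bearing_deg: float = 35.0,
    shore_buffer_km: float = 5.0,
) -> tuple[object, dict]:
    """Alpha-shape boundary of pre-migration locations, with a summary.

    ``alpha_km`` is the circumradius cutoff of the Delaunay filtering; as
    alpha → ∞ every triangle is kept and the result is exactly the convex
    hull. Degenerate geometry (collinear or too few points) falls back to
    the convex hull with a warning.

    Coordinates are local km with the river mouth at the origin. The summary
    reports the polygon area, the offshore extent — the boundary's maximum
    projection onto the seaward estuary axis (``axis_bearing_deg`` from
    north) — and, when a projected shoreline ``LineString`` (km) is given,
    the length of shoreline lying within ``shore_buffer_km`` of the polygon
    (the stretch of coast the occupied area abuts).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least 3 points to bound a region")
    poly = _alpha_shape(points, alpha_km)
    if poly is None or poly.is_empty or not poly.is_valid:
        warnings.warn("degenerate geometry; falling back to convex hull")
        poly = MultiPoint([tuple(p) for p in points]).convex_hull
    summary = {"area_km2": float(poly.area), "alpha_km": float(alpha_km)}
    if poly.geom_type == "Polygon":
        boundary_pts = np.asarray(poly.exterior.coords)
    elif poly.geom_type == "MultiPolygon":
        boundary_pts = np.vstack([np.asarray(g.exterior.coords) for g in poly.geoms])
    else:  # LineString/Point from a degenerate hull
        boundary_pts = np.asarray(poly.coords)
    brg = np.radians(axis_bearing_deg)
    u = np.array([np.sin(brg), np.cos(brg)])
    summary["offshore_extent_km"] = float((boundary_pts[:, :2] @ u).max())
    if shoreline_line is not None:
        near_shore = shoreline_line.intersection(poly.buffer(shore_buffer_km))
        summary["shoreline_km"] = float(near_shore.length)
    return poly, summary
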