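"""Extent of occurrence via iterative alpha-hulls.

A species' extent of occurrence (EOO) is the outer envelope of its known
occurrences. A convex hull bridges disjunct ranges (e.g. bipolar or
amphi-oceanic distributions), so the envelope is built instead as an
alpha-shape: the union of Delaunay triangles whose circumradius does not
exceed ``1/alpha`` (Edelsbrunner's parametrization). As ``alpha -> 0+`` the
shape is the convex hull; increasing ``alpha`` carves it tighter, possibly
into disjoint components, and may leave occurrences outside.

The working value of alpha is chosen per species by an iterative loop:
starting from a small alpha (0.001) and increasing in steps of 0.005, at
each step compute

    ratio = (relative hull-area reduction vs the previous hull)
            / (occurrences newly lost, relative to the total record count)

and stop at the first alpha where the ratio falls below 10: from there on,
tightening the hull discards occurrence records faster than it sheds area.
Steps that lose no occurrences leave the ratio undefined and are skipped.

The selected hull is rasterized on a fine grid (10x the analysis
resolution, i.e. 0.05 deg for a 0.5 deg analysis), aggregated to the
analysis grid, and clipped by the light-at-bottom mask to give the EOO
mask used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .grid import GridSpec


class AlphaHullError(ValueError):
    """Degenerate geometry or non-convergent alpha selection."""


@dataclass
class AlphaHull:
    """An alpha-shape of a point set, with containment bookkeeping."""

    alpha: float
    geometry: shapely.Geometry  # Polygon or MultiPolygon (possibly empty)
    n_contained: int
    n_points: int

    @property
    def contained_fraction(self) -> float:
        return self.n_contained / self.n_points

    @property
    def area(self) -> float:
        """Planar (degree^2) area of the hull polygons."""
        return self.geometry.area

    @property
    def polygons(self) -> list[Polygon]:
        if self.geometry.is_empty:
            return []
        if isinstance(self.geometry, Polygon):
            return [self.geometry]
        return list(self.geometry.geoms)


@dataclass
class EOOMask:
    """Rasterized, light-clipped extent of occurrence for one species."""

    species_id: str
    grid: GridSpec
    mask: np.ndarray = field(repr=False)
    alpha_final: float | None = None
    hull_wkt: str | None = field(default=None, repr=False)


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each triangle; inf for (near-)degenerate ones."""
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - \
            (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    area2 = np.abs(cross)  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def alpha_shape(points: np.ndarray, alpha: float) -> AlphaHull:
    """Alpha-shape of a 2-D point set.

    Keeps the Delaunay triangles whose circumradius is at most ``1/alpha``
    and unions them. Points on a polygon boundary count as contained.

    Raises :class:`AlphaHullError` for fewer than 3 distinct points or a
    collinear configuration (no 2-D triangulation exists).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    uniq = np.unique(points, axis=0)
    if len(uniq) < 3:
        raise AlphaHullError(f"need >=3 distinct points, got {len(uniq)}")
    try:
        tri = Delaunay(uniq)
    except QhullError as e:
        raise AlphaHullError(f"degenerate point configuration: {e}") from e
    keep = _circumradii(uniq, tri.simplices) <= 1.0 / alpha
    geom = _union_triangles(uniq, tri.simplices[keep])
    n_in = _count_contained(geom, points)
    return AlphaHull(alpha=alpha, geometry=geom,
                     n_contained=n_in, n_points=len(points))


def _union_triangles(points: np.ndarray, simplices: np.ndarray) -> shapely.Geometry:
    if len(simplices) == 0:
        return Polygon()
    tris = shapely.polygons(points[simplices])
    return unary_union(tris)


def _count_contained(geom: shapely.Geometry, points: np.ndarray) -> int:
    if geom.is_empty:
        return 0
    # intersects == covers for points; boundary points count as contained
    return int(np.count_nonzero(shapely.intersects_xy(geom, points[:, 0], points[:, 1])))


def fit_alpha(points: np.ndarray, alpha0: float = 0.001, step: float = 0.005,
              ratio_threshold: float = 10.0, max_iter: int = 1000) -> AlphaHull:
    """Select the working alpha for one species by the iterative tightening loop.

    Starting from ``alpha0`` and increasing by ``step``, each step compares
    the hull with the previous one: the relative area reduction divided by
    the fraction of the species' total records newly excluded. The loop
    stops at the first step where this ratio is defined (some records were
    lost) and falls below ``ratio_threshold``; the hull at that alpha is
    returned. If the hull would vanish entirely, the last non-empty hull is
    returned instead.
    """
    points = np.asarray(points, dtype=float)
    n_total = len(points)
    prev = alpha_shape(points, alpha0)
    for i in range(1, max_iter + 1):
        alpha = alpha0 + i * step
        cur = alpha_shape(points, alpha)
        if cur.geometry.is_empty:
            return prev
        lost_frac = (prev.n_contained - cur.n_contained) / n_total
        if lost_frac > 0 and prev.area > 0:
            ratio = ((prev.area - cur.area) / prev.area) / lost_frac
            if ratio < ratio_threshold:
                return cur
        prev = cur
    raise AlphaHullError(
        f"alpha selection did not converge within {max_iter} steps "
        f"(last alpha={alpha:.4g}, area={cur.area:.4g}, "
        f"contained={cur.contained_fraction:.3f})")


def rasterize_hull(geometry: shapely.Geometry, grid: GridSpec,
                   fine_factor: int = 10) -> np.ndarray:
    """Rasterize hull polygons onto ``grid``.

    The polygons are first sampled on a grid ``fine_factor`` times finer
    (cell true iff its center touches a polygon), then aggregated: a coarse
    cell is true iff any of its fine children is. This keeps thin hull
    slivers that a coarse center-test would drop.
    """
    if geometry.is_empty:
        return np.zeros(grid.shape, dtype=bool)
    fine = grid.refine(fine_factor)
    lon0, lat0 = fine.lon_min, fine.lat_min
    res = fine.resolution_deg
    minx, miny, maxx, maxy = geometry.bounds
    c0 = max(0, int(np.floor((minx - lon0) / res)) - 1)
    c1 = min(fine.n_cols, int(np.ceil((maxx - lon0) / res)) + 1)
    r0 = max(0, int(np.floor((miny - lat0) / res)) - 1)
    r1 = min(fine.n_rows, int(np.ceil((maxy - lat0) / res)) + 1)
    fine_mask = np.zeros(fine.shape, dtype=bool)
    if c1 > c0 and r1 > r0:
        lons = fine.lon_centers[c0:c1]
        lats = fine.lat_centers[r0:r1]
        glon, glat = np.meshgrid(lons, lats)
        hit = shapely.intersects_xy(geometry, glon.ravel(), glat.ravel())
        fine_mask[r0:r1, c0:c1] = hit.reshape(glat.shape)
    k = fine_factor
    coarse = fine_mask.reshape(grid.n_rows, k, grid.n_cols, k).any(axis=(1, 3))
    return coarse


def rasterize_and_clip(hull: AlphaHull, grid: GridSpec,
                       light_valid_mask: np.ndarray, species_id: str = "",
                       fine_factor: int = 10,
                       points: np.ndarray | None = None) -> EOOMask:
    """Rasterize a fitted hull and clip it by the light-at-bottom mask.

    If the generating ``points`` are supplied, the cells of points the hull
    contains are forced into the mask: a record inside the hull is part of
    the range by definition, even when its cell's fine-grid centers all
    fall just outside a hull edge.
    """
    mask = rasterize_hull(hull.geometry, grid, fine_factor)
    if points is not None and not hull.geometry.is_empty:
        points = np.asarray(points, dtype=float)
        inside = shapely.intersects_xy(hull.geometry, points[:, 0],
                                       points[:, 1])
        rows, cols = grid.cell_of(points[inside, 0], points[inside, 1])
        ok = rows >= 0
        mask[rows[ok], cols[ok]] = True
    mask &= light_valid_mask
    if not mask.any():
        warnings.warn(
            f"EOO for {species_id or 'species'} is empty after light clipping; "
            "it will contribute nothing downstream", stacklevel=2)
    return EOOMask(species_id=species_id, grid=grid, mask=mask,
                   alpha_final=hull.alpha, hull_wkt=hull.geometry.wkt)


def degenerate_eoo(points: np.ndarray, grid: GridSpec,
                   light_valid_mask: np.ndarray, species_id: str = "") -> EOOMask:
    """EOO for species whose points admit no 2-D hull (collinear or <3 unique).

    The mask is the union of the cells containing the points, buffered by
    one cell in each direction, then light-clipped.
    """
    points = np.asarray(points, dtype=float)
    mask = np.zeros(grid.shape, dtype=bool)
    rows, cols = grid.cell_of(points[:, 0], points[:, 1])
    for r, c in zip(rows, cols):
        if r < 0:
            continue
        mask[max(0, r - 1):r + 2, max(0, c - 1):c + 2] = True
    return EOOMask(species_id=species_id, grid=grid,
                   mask=mask & light_valid_mask, alpha_final=None)


def compute_eoo(points: np.ndarray, grid: GridSpec, light_valid_mask: np.ndarray,
                species_id: str = "", alpha0: float = 0.001, step: float = 0.005,
                ratio_threshold: float = 10.0, max_iter: int = 1000,
                fine_factor: int = 10) -> EOOMask:
    """Full per-species EOO: fit alpha, rasterize, clip; degenerate-safe."""
    try:
        hull = fit_alpha(points, alpha0=alpha0, step=step,
                         ratio_threshold=ratio_threshold, max_iter=max_iter)
    except AlphaHullError:
        return degenerate_eoo(points, grid, light_valid_mask, species_id)
    return rasterize_and_clip(hull, grid, light_valid_mask, species_id,
                              fine_factor=fine_factor, points=points)
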