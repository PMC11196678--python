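"""From-scratch alpha-shape reference used to cross-check the eoo module.

Deliberately independent of the package implementation: circumradii from
the law-of-sines formula, hull area as the plain sum of kept Delaunay
triangle areas (triangles of a triangulation are interior-disjoint), and
containment by vertex membership in the kept triangles.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay


def triangle_circumradius(a, b, c):
    la = np.hypot(*(b - c))
    lb = np.hypot(*(a - c))
    lc = np.hypot(*(a - b))
    double_area = abs((b[0] - a[0]) * (c[1] - a[1])
                      - (b[1] - a[1]) * (c[0] - a[0]))
    if double_area == 0:
        return np.inf
    return la * lb * lc / (2.0 * double_area)


def alpha_shape_reference(points: np.ndarray, alpha: float):
    """(area, n_points_contained) of the alpha-shape at this alpha."""
    points = np.asarray(points, dtype=float)
    uniq = np.unique(points, axis=0)
    tri = Delaunay(uniq)
    area = 0.0
    kept_vertices: set[int] = set()
    r_max = 1.0 / alpha
    for simplex in tri.simplices:
        a, b, c = uniq[simplex]
        if triangle_circumradius(a, b, c) <= r_max:
            area += 0.5 * abs((b[0] - a[0]) * (c[1] - a[1])
                              - (b[1] - a[1]) * (c[0] - a[0]))
            kept_vertices.update(simplex.tolist())
    if not kept_vertices:
        return 0.0, 0
    kept = uniq[sorted(kept_vertices)]
    # count original points (with multiplicity) matching kept vertices
    contained = sum(
        1 for p in points
        if np.any(np.all(kept == p, axis=1)))
    return area, contained


def fit_alpha_scan_reference(points: np.ndarray, alpha0=0.001, step=0.005,
                             ratio_threshold=10.0, max_iter=1000):
    """Brute-force scan over the alpha grid with the reference alpha-shape.

    Returns (alpha_final, hull_area). Mirrors the published procedure: stop
    at the first alpha where (relative area reduction) / (fraction of all
    records newly lost) is defined and drops below the threshold; steps
    losing no records are skipped; a vanishing hull returns the previous
    state.
    """
    points = np.asarray(points, dtype=float)
    n_total = len(points)
    prev_area, prev_n = alpha_shape_reference(points, alpha0)
    prev_alpha = alpha0
    for i in range(1, max_iter + 1):
        alpha = alpha0 + i * step
        area, n_in = alpha_shape_reference(points, alpha)
        if n_in == 0 or area == 0.0:
            return prev_alpha, prev_area
        lost = (prev_n - n_in) / n_total
        if lost > 0 and prev_area > 0:
            ratio = ((prev_area - area) / prev_area) / lost
            if ratio < ratio_threshold:
                return alpha, area
        prev_area, prev_n, prev_alpha = area, n_in, alpha
    raise RuntimeError("reference scan did not converge")


def random_point_set(rng: np.random.Generator, n: int) -> np.ndarray:
    """A clustered point cloud resembling an occurrence set."""
    k = int(rng.integers(1, 4))
    centers = rng.uniform(-20, 20, size=(k, 2))
    scales = rng.uniform(1.0, 5.0, size=k)
    picks = rng.integers(0, k, size=n)
    return centers[picks] + rng.normal(0, 1, size=(n, 2)) * scales[picks, None]
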