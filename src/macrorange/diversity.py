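"""Stacked-SDM diversity maps, change maps, trajectories, latitudinal profiles.

Species richness in a cell is the sum of the per-species probabilities of
occurrence (each clipped to the species' extent of occurrence) — the
stacked-SDM estimator. Change between two years is mapped as the log-e
percentage ``100 * ln(d_end / d_start)``, a symmetric gain/loss scale
(halving = -69.3, doubling = +69.3). Trajectories aggregate per-cell
changes into a mean with a normal-approximation 95% CI across cells,
binned at 5-year intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enm import SuitabilityMap
from .grid import GridSpec

#: diversity below this is treated as absence when forming ratios
EPSILON = 1e-6


@dataclass
class DiversityMap:
    group: str
    grid: GridSpec
    year: int
    scenario: str
    richness: np.ndarray = field(repr=False)


@dataclass
class TrajectorySeries:
    """5-year-binned mean trajectory with normal-approximation 95% CI."""

    group: str
    scenario: str
    statistic: str
    bins: list[int]  # bin start years
    mean: np.ndarray
    se: np.ndarray

    @property
    def ci95_low(self) -> np.ndarray:
        return self.mean - 1.96 * self.se

    @property
    def ci95_high(self) -> np.ndarray:
        return self.mean + 1.96 * self.se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.group, "scenario": self.scenario,
            "statistic": self.statistic, "bin": self.bins,
            "mean": self.mean, "se": self.se,
            "ci_low": self.ci95_low, "ci_high": self.ci95_high,
        })


def stack_richness(aoo_maps: list[SuitabilityMap], year: int,
                   group: str = "all") -> DiversityMap:
    """Richness = sum over species of clipped p, per cell."""
    if not aoo_maps:
        raise ValueError("no maps to stack")
    grid = aoo_maps[0].grid
    rich = np.zeros(grid.shape)
    scenario = aoo_maps[0].scenario
    for m in aoo_maps:
        if m.grid != grid:
            raise ValueError("suitability maps are on different grids")
        rich += m.p
    return DiversityMap(group=group, grid=grid, year=year,
                        scenario=scenario, richness=rich)


def log_pct_change(d_end: np.ndarray, d_start: np.ndarray,
                   epsilon: float = EPSILON) -> np.ndarray:
    """Log-e percentage change map; NaN where either side is below epsilon."""
    d_end = np.asarray(d_end, dtype=float)
    d_start = np.asarray(d_start, dtype=float)
    ok = (d_end > epsilon) & (d_start > epsilon)
    out = np.full(d_end.shape, np.nan)
    out[ok] = 100.0 * np.log(d_end[ok] / d_start[ok])
    return out


def fraction_losing(d_start: np.ndarray, d_end: np.ndarray,
                    loss_frac: float = 0.10) -> float:
    """Fraction of occupied localities losing at least ``loss_frac`` of richness.

    The denominator is the set of cells with any present-day richness
    (d_start > 0); a locality counts as losing if its relative decline
    ``(d_start - d_end)/d_start`` reaches ``loss_frac``.
    """
    d_start = np.asarray(d_start, dtype=float)
    d_end = np.asarray(d_end, dtype=float)
    occupied = d_start > 0
    n = int(occupied.sum())
    if n == 0:
        raise ValueError("no occupied localities")
    rel_loss = (d_start[occupied] - d_end[occupied]) / d_start[occupied]
    return float(np.count_nonzero(rel_loss >= loss_frac)) / n


def bin_5yearly(years: np.ndarray, values: np.ndarray,
                start: int = 2015) -> tuple[list[int], np.ndarray]:
    """Aggregate yearly values into 5-year bins [2015-2019], [2020-2024], ...

    Bin value = mean of the yearly values in the bin; bins labeled by start
    year.
    """
    years = np.asarray(years)
    values = np.asarray(values, dtype=float)
    bins = ((years - start) // 5) * 5 + start
    out_bins = sorted(set(bins.tolist()))
    out_vals = np.array([values[bins == b].mean() for b in out_bins])
    return out_bins, out_vals


def mean_local_change_trajectory(richness_by_year: dict[int, np.ndarray],
                                 group: str = "all", scenario: str = "",
                                 baseline_year: int = 2015,
                                 epsilon: float = EPSILON) -> TrajectorySeries:
    """Mean local log-e % diversity change vs baseline, binned 5-yearly.

    For each year, the change map vs the baseline is computed per occupied
    cell; the statistic is the mean across cells with a cross-cell standard
    error (cells are not spatially decorrelated).
    """
    base = richness_by_year[baseline_year]
    years = sorted(richness_by_year)
    means, ses = [], []
    for y in years:
        change = log_pct_change(richness_by_year[y], base, epsilon)
        vals = change[np.isfinite(change)]
        means.append(vals.mean() if len(vals) else np.nan)
        ses.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0)
    bins, mean_b = bin_5yearly(np.array(years), np.array(means))
    _, se_b = bin_5yearly(np.array(years), np.array(ses))
    return TrajectorySeries(group=group, scenario=scenario,
                            statistic="local_diversity_change_pct",
                            bins=bins, mean=mean_b, se=se_b)


def latitudinal_profile(change_map: np.ndarray, grid: GridSpec,
                        weights: np.ndarray | None = None) -> pd.DataFrame:
    """Mean of valid cells per latitude row (NaN rows masked).

    Unweighted by default; pass per-cell ``weights`` (e.g. cell areas) for
    an area-weighted profile. Within one latitude row of an equal-angle
    grid the two coincide, so weighting only matters for partial rows.
    """
    vals = np.asarray(change_map, dtype=float)
    finite = np.isfinite(vals)
    w = np.ones_like(vals) if weights is None else np.asarray(weights, float)
    w = np.where(finite, w, 0.0)
    count = w.sum(axis=1)
    total = np.where(finite, vals, 0.0) * w
    means = np.divide(total.sum(axis=1), count,
                      out=np.full(len(count), np.nan), where=count > 0)
    return pd.DataFrame({"latitude": grid.lat_centers, "mean_change": means})
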