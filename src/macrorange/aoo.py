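"""Per-species area-of-occupancy extents and group trajectories.

A species' area of occupancy (AOO) for a year is the probability-weighted
area inside its fixed present-day extent of occurrence:
``AOO = sum over EOO cells of p * cell_area`` — under the no-dispersal
assumption the AOO can change only through p within the EOO. The
proportional-expansion alternative scales the species' suitable area
``s_Y`` by the baseline occupied-to-suitable ratio
``R_2015 = AOO_2015 / s_2015``, allowing growth outside the EOO.

``s_Y`` is defined here with the same probability weighting as the AOO
(sum of p * cell_area over all light-valid cells); a thresholded variant
(area of cells with p >= 0.6) is available via ``suitable_mode``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import TrajectorySeries, bin_5yearly
from .enm import SuitabilityMap
from .eoo import EOOMask
from .grid import CellAreaField


def aoo_extent(suit: SuitabilityMap, eoo: EOOMask, areas: CellAreaField) -> float:
    """Probability-weighted occupied area (km^2) inside the EOO."""
    if suit.grid != eoo.grid:
        raise ValueError("suitability and EOO grids differ")
    if not eoo.mask.any():
        warnings.warn(f"{eoo.species_id}: empty EOO, AOO = 0", stacklevel=2)
        return 0.0
    sel = eoo.mask & suit.valid_mask
    return float((suit.p[sel] * areas.area_km2[sel]).sum())


def suitable_extent(suit: SuitabilityMap, light_valid_mask: np.ndarray,
                    areas: CellAreaField, mode: str = "weighted",
                    threshold: float = 0.6) -> float:
    """Species-level suitable area s_Y over all light-valid cells."""
    sel = light_valid_mask & suit.valid_mask
    if mode == "weighted":
        return float((suit.p[sel] * areas.area_km2[sel]).sum())
    if mode == "threshold":
        return float(areas.area_km2[sel & (suit.p >= threshold)].sum())
    raise ValueError(f"unknown suitable-area mode {mode!r}")


def proportional_expansion(aoo_2015: float, s_2015: float, s_year: float) -> float:
    """AOO under proportional expansion: (AOO_2015 / s_2015) * s_Y."""
    if s_2015 <= 0:
        raise ValueError("baseline suitable area must be positive")
    if s_year == s_2015:
        return aoo_2015  # exact identity at the baseline
    return (aoo_2015 / s_2015) * s_year


@dataclass
class AOOSeries:
    """Yearly AOO trajectory for one species under one scenario."""

    species_id: str
    scenario: str
    years: np.ndarray
    aoo_km2: np.ndarray  # no-dispersal
    aoo_expansion_km2: np.ndarray  # proportional expansion
    r_2015: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species_id": self.species_id, "scenario": self.scenario,
            "year": self.years, "aoo_km2": self.aoo_km2,
            "aoo_expansion_km2": self.aoo_expansion_km2,
            "r_2015": self.r_2015,
        })


def build_aoo_series(species_id: str, scenario: str,
                     suit_by_year: dict[int, SuitabilityMap], eoo: EOOMask,
                     light_valid_mask: np.ndarray, areas: CellAreaField,
                     suitable_mode: str = "weighted",
                     baseline_year: int = 2015) -> AOOSeries:
    """Assemble both AOO trajectories for one species."""
    years = np.array(sorted(suit_by_year))
    aoo = np.array([aoo_extent(suit_by_year[y], eoo, areas) for y in years])
    s = np.array([suitable_extent(suit_by_year[y], light_valid_mask, areas,
                                  mode=suitable_mode) for y in years])
    i0 = int(np.where(years == baseline_year)[0][0])
    s0, aoo0 = s[i0], aoo[i0]
    if s0 > 0:
        exp = np.array([proportional_expansion(aoo0, s0, sy) for sy in s])
        r = aoo0 / s0
    else:
        exp = np.full(len(years), np.nan)
        r = np.nan
    return AOOSeries(species_id=species_id, scenario=scenario, years=years,
                     aoo_km2=aoo, aoo_expansion_km2=exp, r_2015=float(r))


def _cross_species_trajectory(years: np.ndarray, mat: np.ndarray, group: str,
                              scenario: str, statistic: str) -> TrajectorySeries:
    mean_y = mat.mean(axis=0)
    se_y = (mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
            if mat.shape[0] > 1 else np.zeros(mat.shape[1]))
    bins, mean_b = bin_5yearly(years, mean_y)
    _, se_b = bin_5yearly(years, se_y)
    return TrajectorySeries(group=group, scenario=scenario, statistic=statistic,
                            bins=bins, mean=mean_b, se=np.asarray(se_b))


def mean_aoo_trajectory(series: list[AOOSeries], group: str = "all",
                        kind: str = "km2", expansion: bool = False
                        ) -> TrajectorySeries:
    """Group trajectory: mean and SE across species, 5-year binned.

    ``kind='km2'`` averages absolute extents; ``kind='pct'`` first converts
    each species to percent change relative to its own 2015 extent and then
    averages (mean of per-species percentages, not ratio of means).
    """
    if not series:
        raise ValueError("no species series")
    years = series[0].years
    vals = np.vstack([(s.aoo_expansion_km2 if expansion else s.aoo_km2)
                      for s in series])
    if kind == "pct":
        base = vals[:, list(years).index(2015)][:, None]
        vals = 100.0 * (vals - base) / base
        stat = "aoo_change_pct" + ("_expansion" if expansion else "")
    elif kind == "km2":
        stat = "aoo_km2" + ("_expansion" if expansion else "")
    else:
        raise ValueError(f"unknown kind {kind!r}")
    scenario = series[0].scenario
    return _cross_species_trajectory(years, vals, group, scenario, stat)


def per_species_loss_distribution(series: list[AOOSeries],
                                  end_year: int = 2100, n_bins: int = 20
                                  ) -> pd.DataFrame:
    """Histogram of per-species % AOO change at the end year, with skew.

    Returns the per-species change table with a binned count summary
    attached in ``DataFrame.attrs`` (keys ``bin_edges``, ``counts``,
    ``skew``).
    """
    rows = []
    for s in series:
        i0 = list(s.years).index(2015)
        i1 = list(s.years).index(end_year)
        if s.aoo_km2[i0] <= 0:
            continue
        rows.append({"species_id": s.species_id, "scenario": s.scenario,
                     "pct_change": 100.0 * (s.aoo_km2[i1] - s.aoo_km2[i0])
                     / s.aoo_km2[i0]})
    df = pd.DataFrame(rows)
    changes = df["pct_change"].to_numpy()
    counts, edges = np.histogram(changes, bins=n_bins)
    df.attrs["bin_edges"] = edges.tolist()
    df.attrs["counts"] = counts.tolist()
    if len(changes) > 2 and np.ptp(changes) > 0:
        df.attrs["skew"] = float(stats.skew(changes))
    else:
        df.attrs["skew"] = np.nan
    return df
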