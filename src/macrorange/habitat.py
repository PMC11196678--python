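"""Group-level habitat extent: thresholded areas, percent change, regional shares.

Habitat suitability maps are binarized at probability thresholds
(0.6/0.7/0.8/0.9 by default); the suitable area is the sum of the spherical
cell areas of the cells at or above the threshold, globally and within each
of 12 marine regions. A cell with p exactly at the threshold counts as
suitable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enm import SuitabilityMap
from .grid import CellAreaField, GridSpec

HABITAT_THRESHOLDS = (0.6, 0.7, 0.8, 0.9)


@dataclass
class RegionMask:
    """Integer label raster assigning ocean cells to marine regions (0 = none)."""

    grid: GridSpec
    labels: np.ndarray = field(repr=False)
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label raster shape mismatch")

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


def suitable_area(suit: SuitabilityMap, threshold: float,
                  light_valid_mask: np.ndarray, areas: CellAreaField) -> float:
    """Total km^2 of light-valid cells with p >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    sel = light_valid_mask & suit.valid_mask & (suit.p >= threshold)
    return float(areas.area_km2[sel].sum())


def pct_change_area(area_end: float, area_start: float) -> float:
    """100 * (area_end - area_start) / area_start."""
    if area_start <= 0:
        raise ValueError("baseline area must be positive")
    return 100.0 * (area_end - area_start) / area_start


def regional_shares(suit: SuitabilityMap, regions: RegionMask,
                    light_valid_mask: np.ndarray, areas: CellAreaField,
                    threshold: float = 0.6) -> pd.DataFrame:
    """Each region's percentage of the global suitable area at a threshold.

    Shares are computed over labeled suitable cells and sum to 100 when no
    suitable cell is unlabeled; any unlabeled suitable area is reported
    under region id 0. Columns: region, name, area_km2, share_pct,
    global_area_km2.
    """
    if regions.grid != suit.grid:
        raise ValueError("region mask grid differs from suitability grid")
    sel = light_valid_mask & suit.valid_mask & (suit.p >= threshold)
    total = float(areas.area_km2[sel].sum())
    if total <= 0:
        raise ValueError("no suitable cells at this threshold")
    labeled_total = float(areas.area_km2[sel & (regions.labels != 0)].sum())
    rows = []
    for rid in regions.region_ids + ([0] if (sel & (regions.labels == 0)).any()
                                     else []):
        a = float(areas.area_km2[sel & (regions.labels == rid)].sum())
        share = 100.0 * a / labeled_total if rid != 0 and labeled_total > 0 \
            else (np.nan if rid == 0 else 0.0)
        rows.append({"region": rid,
                     "name": regions.legend.get(rid, "unlabeled" if rid == 0
                                                else f"region_{rid}"),
                     "area_km2": a, "share_pct": share,
                     "global_area_km2": total})
    return pd.DataFrame(rows)
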