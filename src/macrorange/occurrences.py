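"""Occurrence records: reading, record-count filtering, and rasterization.

Records arrive as a tidy table (``species_id, longitude, latitude[, year]``).
Species with fewer than the minimum record count are dropped before any
range construction; the survivors' records are rasterized to boolean
presence grids (a cell is a presence cell if it hosts at least one record
and is light-valid). Group-level presence grids are the cell-wise union
over member species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species_id", "longitude", "latitude")


def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence CSV (UTF-8, header required)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence file {path} lacks columns {missing}")
    return df


@dataclass
class PresenceGrid:
    """Boolean presence raster for one species or group."""

    label: str  # species_id or group name
    grid: GridSpec
    presence: np.ndarray = field(repr=False)
    n_records: int = 0

    @property
    def n_cells(self) -> int:
        return int(self.presence.sum())


def filter_min_records(records: pd.DataFrame, min_n: int = 10
                       ) -> tuple[list[str], list[str]]:
    """Split species into retained (>= min_n records) and dropped lists.

    Records flagged upstream as outside a species' known distribution are
    assumed already removed (upstream-cleaning assumption).
    """
    if len(records) == 0:
        raise ValueError("no occurrence records supplied")
    counts = records.groupby("species_id").size().sort_index()
    retained = counts.index[counts >= min_n].tolist()
    dropped = counts.index[counts < min_n].tolist()
    logger.info("record filter (min_n=%d): retained %d species, dropped %d",
                min_n, len(retained), len(dropped))
    return retained, dropped


def rasterize_presence(records: pd.DataFrame, grid: GridSpec,
                       light_valid_mask: np.ndarray,
                       label: str | None = None) -> PresenceGrid:
    """Presence grid: cells hosting >= 1 record, restricted to light-valid cells.

    Records falling outside the grid or on invalid (land / light-limited)
    cells are dropped with a logged count, not snapped to the nearest valid
    cell.
    """
    if label is None:
        ids = records["species_id"].unique()
        label = ids[0] if len(ids) == 1 else "multi"
    presence = np.zeros(grid.shape, dtype=bool)
    rows, cols = grid.cell_of(records["longitude"].to_numpy(),
                              records["latitude"].to_numpy())
    inside = rows >= 0
    presence[rows[inside], cols[inside]] = True
    n_invalid = int(np.count_nonzero(presence & ~light_valid_mask)) \
        + int(np.count_nonzero(~inside))
    presence &= light_valid_mask
    if n_invalid:
        logger.info("%s: %d records/cells on invalid ground dropped",
                    label, n_invalid)
    return PresenceGrid(label=label, grid=grid, presence=presence,
                        n_records=len(records))


def group_presence(per_species: list[PresenceGrid], group_label: str
                   ) -> PresenceGrid:
    """Cell-wise OR of member species' presence grids."""
    if not per_species:
        raise ValueError("group must have at least one member species")
    grid = per_species[0].grid
    presence = np.zeros(grid.shape, dtype=bool)
    n_records = 0
    for pg in per_species:
        if pg.grid != grid:
            raise ValueError("member grids differ")
        presence |= pg.presence
        n_records += pg.n_records
    return PresenceGrid(label=group_label, grid=grid, presence=presence,
                        n_records=n_records)
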