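"""A synthetic virtual world for end-to-end validation of the pipeline.

Real inputs (CMIP6-style climate layers, bathymetry, light at bottom, and a
large presence-only occurrence dataset) are emulated here with known ground
truth so every downstream stage can be checked for recovery:

* :class:`EnvironmentSimulator` produces monthly environmental layers on a
  regular grid for 2015-2100 under a warming scenario: a latitude-graded
  sea-surface temperature with a seasonal cycle and a linear scenario trend,
  air temperature, salinity and productivity with weak regional trends,
  sea-ice cover confined poleward of a retreating edge, and static
  shortwave radiation, depth and light-at-bottom fields. Two meridional
  continents define the land mask; depth increases with distance from the
  coast, so light at bottom carves a contiguous coastal band that passes
  the 50 E m-2 yr-1 habitability mask.
* :class:`VirtualSpecies` carries a product-Gaussian niche over a chosen
  subset of variables; true suitability and deterministic true occupancy
  (suitability >= prevalence threshold, on light-valid cells) are computed
  from the noise-free expected fields, so ground truth is free of
  observation error.
* :func:`sample_occurrences` draws presence records from occupied cells
  with optional effort clustering (sampling hotspots), emulating the
  spatial bias of compiled occurrence datasets.

Layers are computed on demand from a deterministic function of
(seed, variable, year, month), so a full century of monthly fields never
needs to be held in memory, and any stage can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .grid import GridSpec, RasterLayer, light_mask

DYNAMIC_VARIABLES = ("sst", "air_temp", "salinity", "productivity", "ice_cover")
STATIC_VARIABLES = ("shortwave", "depth", "light_bottom")

#: surface PAR scale (E m-2 yr-1) and diffuse attenuation (m-1) used to
#: derive light at bottom from depth
_PAR_SURFACE = 12000.0
_ATTENUATION = 0.08


@dataclass(frozen=True)
class ScenarioParams:
    """Forcing trends for one emissions scenario.

    warming_rate is degC per decade added linearly to sst and air_temp from
    2015; ice_retreat_rate is the per-decade percentage-point decline in
    sea-ice cover at a fixed latitude (the ice edge drifts poleward
    accordingly); salinity_trend and productivity_trend are per-decade
    deltas modulated by a fixed regional sign pattern.
    """

    label: str = "SSP-like-4.5"
    warming_rate: float = 0.2
    ice_retreat_rate: float = 3.0
    salinity_trend: float = -0.05
    productivity_trend: float = 0.01
    seasonal_amplitude: float = 4.0
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "sst": 0.3, "air_temp": 0.5, "salinity": 0.1,
        "productivity": 0.02, "ice_cover": 2.0,
    })
    year_start: int = 2015
    year_end: int = 2100

    def __post_init__(self) -> None:
        if self.warming_rate < 0:
            raise ValueError("warming_rate must be >= 0")
        if self.year_end < self.year_start:
            raise ValueError("year range is empty")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


#: stand-ins for the three SSP scenarios, ordered by end-of-century forcing
SCENARIO_PRESETS = {
    "SSP-like-4.5": ScenarioParams("SSP-like-4.5", warming_rate=0.20,
                                   ice_retreat_rate=3.0),
    "SSP-like-7.0": ScenarioParams("SSP-like-7.0", warming_rate=0.35,
                                   ice_retreat_rate=5.0),
    "SSP-like-8.5": ScenarioParams("SSP-like-8.5", warming_rate=0.50,
                                   ice_retreat_rate=7.0),
}

_VAR_IDS = {v: i for i, v in enumerate(DYNAMIC_VARIABLES + STATIC_VARIABLES)}


class EnvironmentSimulator:
    """Deterministic lazy provider of environmental layers for one scenario.

    ``layer(var, year, month)`` returns the noisy field actually fed to the
    models; ``expected_layer`` returns the same field without noise and is
    the basis of all ground-truth computations.
    """

    def __init__(self, scenario: ScenarioParams, grid: GridSpec, seed: int,
                 shelf_slope_m_per_deg: float = 8.0):
        self.scenario = scenario
        self.grid = grid
        self.seed = int(seed)
        self.shelf_slope = shelf_slope_m_per_deg
        lat = grid.lat_centers[:, None]
        lon = grid.lon_centers[None, :]
        self._lat = np.broadcast_to(lat, grid.shape)
        self._lon = np.broadcast_to(lon, grid.shape)
        self.land_mask = self._make_land(self._lon, self._lat)
        self.ocean_mask = ~self.land_mask
        # distance (degrees) to the nearest land cell; drives depth and shelf
        dist_cells = distance_transform_edt(self.ocean_mask)
        self._coast_dist_deg = dist_cells * grid.resolution_deg
        self.depth = np.where(
            self.ocean_mask,
            np.minimum(5.0 + self.shelf_slope * self._coast_dist_deg, 5500.0),
            0.0)
        par0 = _PAR_SURFACE * (0.3 + 0.7 * np.cos(np.deg2rad(self._lat)))
        self.light_bottom = np.where(
            self.ocean_mask, par0 * np.exp(-_ATTENUATION * self.depth), 0.0)
        self.shortwave = 340.0 * (0.35 + 0.65 * np.cos(np.deg2rad(self._lat)))

    @staticmethod
    def _make_land(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Two meridional continents spanning most latitudes."""
        west = (lon >= -150) & (lon < -120) & (lat > -75) & (lat < 80)
        east = (lon >= 30) & (lon < 60) & (lat > -70) & (lat < 75)
        return west | east

    # -- expected (noise-free) fields -------------------------------------

    def _decades(self, year: int) -> float:
        return (year - self.scenario.year_start) / 10.0

    def _seasonal(self, month: int) -> np.ndarray:
        # peak in August north of the equator, February south of it
        phase = np.cos(2.0 * np.pi * (month - 8) / 12.0)
        amp = self.scenario.seasonal_amplitude * np.minimum(
            1.0, np.abs(self._lat) / 30.0)
        return np.sign(self._lat) * amp * phase

    def expected_field(self, variable: str, year: int, month: int) -> np.ndarray:
        sc = self.scenario
        t = self._decades(year)
        lat_rad = np.deg2rad(self._lat)
        lon_rad = np.deg2rad(self._lon)
        if variable == "sst":
            base = -2.0 + 30.0 * np.cos(lat_rad) ** 2
            return base + self._seasonal(month) + sc.warming_rate * t
        if variable == "air_temp":
            base = -15.0 + 45.0 * np.cos(lat_rad) ** 2
            return base + 1.5 * self._seasonal(month) + sc.warming_rate * t
        if variable == "salinity":
            pattern = np.sin(lon_rad)
            base = 35.0 + 2.0 * np.sin(2 * lon_rad) * np.cos(lat_rad)
            return base + sc.salinity_trend * t * pattern
        if variable == "productivity":
            base = 0.1 + 0.8 * np.exp(-self._coast_dist_deg / 6.0)
            out = base + sc.productivity_trend * t * np.cos(lat_rad)
            return np.maximum(out, 0.0)
        if variable == "ice_cover":
            # ice edge at +-65 deg in 2015, drifting poleward as cover declines
            gradient = 10.0  # percent cover per degree latitude
            edge = 65.0 + (sc.ice_retreat_rate / gradient) * t
            seasonal = 3.0 * np.sign(self._lat) * np.cos(2 * np.pi * (month - 2) / 12.0)
            cover = gradient * (np.abs(self._lat) - edge) + seasonal
            return np.clip(cover, 0.0, 100.0)
        if variable == "shortwave":
            return self.shortwave
        if variable == "depth":
            return self.depth
        if variable == "light_bottom":
            return self.light_bottom
        raise KeyError(f"unknown variable {variable!r}")

    # -- public layer access ----------------------------------------------

    def expected_layer(self, variable: str, year: int = 2015,
                       month: int = 1) -> RasterLayer:
        vals = self.expected_field(variable, year, month)
        return self._wrap(variable, vals, year, month)

    def layer(self, variable: str, year: int = 2015, month: int = 1) -> RasterLayer:
        """Noise-free static fields; dynamic fields plus seeded Gaussian noise."""
        vals = self.expected_field(variable, year, month).copy()
        if variable in DYNAMIC_VARIABLES:
            sd = self.scenario.noise_sd.get(variable, 0.0)
            if sd > 0:
                rng = np.random.default_rng(
                    [self.seed, _VAR_IDS[variable], year, month])
                noise = rng.normal(0.0, sd, size=vals.shape)
                if variable == "ice_cover":
                    noise[vals <= 0] = 0.0  # noise never creates ice
                vals = vals + noise
            if variable == "ice_cover":
                vals = np.clip(vals, 0.0, 100.0)
        return self._wrap(variable, vals, year, month)

    def _wrap(self, variable: str, vals: np.ndarray, year: int,
              month: int) -> RasterLayer:
        static = variable in STATIC_VARIABLES
        return RasterLayer(
            grid=self.grid, variable=variable,
            values=np.where(self.ocean_mask, vals, 0.0),
            valid_mask=self.ocean_mask,
            time=None if static else (year, month),
            scenario=self.scenario.label)

    def annual_mean_field(self, variable: str, year: int,
                          expected: bool = True) -> np.ndarray:
        get = self.expected_field if expected else \
            (lambda v, y, m: self.layer(v, y, m).values)
        return np.mean([get(variable, year, m) for m in range(1, 13)], axis=0)

    @property
    def light_valid(self) -> np.ndarray:
        """Ocean cells with enough light at the seabed for macrophytes."""
        return light_mask(self.expected_layer("light_bottom"))


def generate_environment(scenario: ScenarioParams, grid: GridSpec,
                         seed: int) -> EnvironmentSimulator:
    """Build the lazy layer provider for one scenario (see module docstring)."""
    return EnvironmentSimulator(scenario, grid, seed)


# ---------------------------------------------------------------------------
# virtual species


@dataclass
class VirtualSpecies:
    """Ground-truth niche: an independent Gaussian response per variable.

    True suitability is the product of the per-variable responses
    ``exp(-(x - mu)^2 / (2 sigma^2))``, in (0, 1]; true occupancy is the
    deterministic set of light-valid cells where suitability reaches
    ``prevalence_threshold``. ``detectability`` is the probability that an
    occupied cell is ever visited by sampling effort.
    """

    species_id: str
    niche: dict[str, tuple[float, float]]  # var -> (optimum mu, breadth sigma)
    prevalence_threshold: float = 0.4
    detectability: float = 1.0
    group: str = "brown_macroalgae"

    def __post_init__(self) -> None:
        for var, (_, sigma) in self.niche.items():
            if sigma <= 0:
                raise ValueError(f"{self.species_id}: sigma for {var} must be > 0")

    def true_suitability(self, env: EnvironmentSimulator, year: int) -> np.ndarray:
        """Noise-free suitability from annual-mean expected fields."""
        suit = np.ones(env.grid.shape)
        for var, (mu, sigma) in self.niche.items():
            if var in STATIC_VARIABLES:
                x = env.expected_field(var, year, 1)
            else:
                x = env.annual_mean_field(var, year)
            suit *= np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))
        return np.where(env.ocean_mask, suit, 0.0)

    def true_occupancy(self, env: EnvironmentSimulator, year: int) -> np.ndarray:
        suit = self.true_suitability(env, year)
        return (suit >= self.prevalence_threshold) & env.light_valid


def generate_species(n_species: int, grid: GridSpec, env: EnvironmentSimulator,
                     seed: int, niche_variables: tuple[str, ...] = (
                         "sst", "salinity", "light_bottom", "ice_cover"),
                     sst_sigma_range: tuple[float, float] = (3.0, 6.0),
                     prevalence_threshold: float = 0.4,
                     brown_fraction: float = 0.85,
                     min_occupied_cells: int = 20) -> list[VirtualSpecies]:
    """Sample virtual species whose optima sit on real habitat.

    Each species' optimum is anchored at a randomly chosen light-valid cell
    (its niche center), guaranteeing non-empty occupancy; breadths are drawn
    so ranges span contiguous latitude bands of the coastal strip. The
    ice-cover response is an exception: its optimum is pinned at zero cover
    (macrophytes are suppressed under ice), which plants the polar-expansion
    signal — as the ice edge retreats, truly occupiable polar habitat grows.
    Species with fewer than ``min_occupied_cells`` occupied cells at 2015
    are redrawn (up to a fixed retry budget) so every species can support
    model fitting.
    """
    rng = np.random.default_rng([seed, 101])
    valid = np.argwhere(env.light_valid)
    if len(valid) == 0:
        raise ValueError("no light-valid cells in this world")
    fields = {}
    for var in niche_variables:
        if var not in DYNAMIC_VARIABLES + STATIC_VARIABLES:
            raise KeyError(f"niche variable {var!r} not in environment")
        fields[var] = (env.expected_field(var, 2015, 1)
                       if var in STATIC_VARIABLES
                       else env.annual_mean_field(var, 2015))
    species: list[VirtualSpecies] = []
    n_brown = int(round(brown_fraction * n_species))
    attempts = 0
    while len(species) < n_species and attempts < 50 * n_species:
        attempts += 1
        r, c = valid[rng.integers(len(valid))]
        niche: dict[str, tuple[float, float]] = {}
        for var in niche_variables:
            x0 = fields[var][r, c]
            if var == "ice_cover":
                niche[var] = (0.0, float(rng.uniform(20.0, 50.0)))
                continue
            if var == "sst":
                sigma = rng.uniform(*sst_sigma_range)
            elif var == "salinity":
                sigma = rng.uniform(3.0, 8.0)
            elif var == "light_bottom":
                sigma = rng.uniform(3000.0, 8000.0)
            else:
                scale = max(1e-6, np.std(fields[var][env.light_valid]))
                sigma = rng.uniform(1.0, 3.0) * scale
            niche[var] = (float(x0), float(sigma))
        idx = len(species)
        sp = VirtualSpecies(
            species_id=f"sp{idx:03d}", niche=niche,
            prevalence_threshold=prevalence_threshold,
            group="brown_macroalgae" if idx < n_brown else "seagrasses")
        if sp.true_occupancy(env, 2015).sum() >= min_occupied_cells:
            species.append(sp)
    if len(species) < n_species:
        raise RuntimeError("could not draw enough species with viable ranges")
    return species


def ground_truth_richness(species: list[VirtualSpecies],
                          env: EnvironmentSimulator, year: int) -> np.ndarray:
    """Per-cell count of truly occupied species (the recovery target)."""
    rich = np.zeros(env.grid.shape)
    for sp in species:
        rich += sp.true_occupancy(env, year)
    return rich


# ---------------------------------------------------------------------------
# occurrence sampling


def sample_occurrences(species: VirtualSpecies, env: EnvironmentSimulator,
                       n_records: int, seed: int, bias_strength: float = 0.5,
                       years: tuple[int, int] = (2015, 2020),
                       hotspot_fraction: float = 0.05,
                       hotspot_scale_deg: float = 10.0) -> pd.DataFrame:
    """Draw presence records from a species' true occupancy.

    Cells are drawn i.i.d. (with replacement) from the union of occupied
    cells over the sampling window, with probability weights
    ``(1 - b) + b * exp(-d / L)`` where ``d`` is the distance to the nearest
    sampling hotspot — ``b = 0`` is spatially uniform effort, ``b = 1``
    fully clustered. The record point is placed uniformly inside the chosen
    cell. Returns a DataFrame with species_id, longitude, latitude, year.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if not 0.0 <= bias_strength <= 1.0:
        raise ValueError("bias_strength must be in [0, 1]")
    occ = np.zeros(env.grid.shape, dtype=bool)
    for y in range(years[0], years[1] + 1):
        occ |= species.true_occupancy(env, y)
    cells = np.argwhere(occ)
    if len(cells) == 0:
        raise ValueError(f"{species.species_id}: no occupied cells to sample from")
    rng = np.random.default_rng([seed, 211])
    if species.detectability < 1.0:
        keep = rng.random(len(cells)) < species.detectability
        if keep.any():
            cells = cells[keep]
    lat_c = env.grid.lat_centers[cells[:, 0]]
    lon_c = env.grid.lon_centers[cells[:, 1]]
    if bias_strength > 0 and len(cells) > 1:
        n_hot = max(1, int(round(hotspot_fraction * len(cells))))
        hot = rng.choice(len(cells), size=n_hot, replace=False)
        d = np.min(np.hypot(lat_c[:, None] - lat_c[hot][None, :],
                            lon_c[:, None] - lon_c[hot][None, :]), axis=1)
        w = (1.0 - bias_strength) + bias_strength * np.exp(-d / hotspot_scale_deg)
    else:
        w = np.ones(len(cells))
    w = w / w.sum()
    picks = rng.choice(len(cells), size=n_records, replace=True, p=w)
    res = env.grid.resolution_deg
    lon = env.grid.lon_edges[cells[picks, 1]] + rng.random(n_records) * res
    lat = env.grid.lat_edges[cells[picks, 0]] + rng.random(n_records) * res
    year = rng.integers(years[0], years[1] + 1, size=n_records)
    return pd.DataFrame({
        "species_id": species.species_id,
        "longitude": lon, "latitude": lat, "year": year,
    })


def make_region_labels(grid: GridSpec, ocean_mask: np.ndarray
                       ) -> tuple[np.ndarray, dict[int, str]]:
    """Twelve synthetic marine regions: six 30-deg latitude bands times two
    longitude halves, standing in for the world marine ecoregions."""
    lat = grid.lat_centers[:, None]
    lon = grid.lon_centers[None, :]
    band = np.clip(((lat + 90.0) // 30.0).astype(int), 0, 5)
    half = (lon >= 0).astype(int)
    labels = np.where(ocean_mask, band * 2 + half + 1, 0)
    band_names = ["S polar", "S temperate", "S tropical",
                  "N tropical", "N temperate", "N polar"]
    legend = {b * 2 + h + 1: f"{band_names[b]} {'E' if h else 'W'}"
              for b in range(6) for h in (0, 1)}
    return labels.astype(int), legend
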