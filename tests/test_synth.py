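"""The virtual world: environment trends, species truth, occurrence sampling."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from macrorange.grid import GridSpec
from macrorange.synth import (SCENARIO_PRESETS, ScenarioParams,
                              VirtualSpecies, generate_environment,
                              generate_species, make_region_labels,
                              sample_occurrences)

GRID = GridSpec(resolution_deg=4.0)


def quiet_scenario(**kw):
    defaults = dict(label="test", warming_rate=0.0, ice_retreat_rate=0.0,
                    noise_sd={})
    defaults.update(kw)
    return ScenarioParams(**defaults)


class TestEnvironment:
    def test_no_trend_no_noise_is_time_invariant(self):
        env = generate_environment(quiet_scenario(), GRID, seed=1)
        a = env.layer("sst", 2015, 7).values
        b = env.layer("sst", 2077, 7).values
        assert np.array_equal(a, b)

    def test_linear_warming_trend_in_global_mean(self):
        env = generate_environment(quiet_scenario(warming_rate=0.3), GRID,
                                   seed=1)
        ocean = env.ocean_mask
        d = (env.layer("sst", 2100, 6).values[ocean]
             - env.layer("sst", 2015, 6).values[ocean])
        assert d.mean() == pytest.approx(0.3 * 8.5, rel=1e-12)

    def test_same_seed_bit_identical_layers(self):
        e1 = generate_environment(SCENARIO_PRESETS["SSP-like-4.5"], GRID, 42)
        e2 = generate_environment(SCENARIO_PRESETS["SSP-like-4.5"], GRID, 42)
        for var in ("sst", "salinity", "ice_cover", "light_bottom"):
            assert np.array_equal(e1.layer(var, 2050, 3).values,
                                  e2.layer(var, 2050, 3).values)

    def test_scenario_ordering_by_end_of_century_warmth(self):
        means = {}
        for label in ("SSP-like-4.5", "SSP-like-7.0", "SSP-like-8.5"):
            sc = dataclasses.replace(SCENARIO_PRESETS[label], noise_sd={})
            env = generate_environment(sc, GRID, seed=1)
            means[label] = env.annual_mean_field("sst", 2100)[
                env.ocean_mask].mean()
        assert means["SSP-like-4.5"] < means["SSP-like-7.0"] \
            < means["SSP-like-8.5"]

    def test_layer_physical_invariants(self):
        env = generate_environment(SCENARIO_PRESETS["SSP-like-8.5"], GRID, 5)
        ice = env.layer("ice_cover", 2040, 1).values
        assert ice.min() >= 0 and ice.max() <= 100
        light = env.layer("light_bottom").values
        assert light.min() >= 0
        # ice only poleward of a retreating edge: none in the tropics
        lat = np.abs(GRID.lat_centers)
        assert ice[lat < 40, :].max() == 0

    def test_coastal_band_passes_light_mask(self):
        env = generate_environment(quiet_scenario(), GRID, seed=1)
        assert env.light_valid.sum() > 0
        assert not (env.light_valid & env.land_mask).any()


class TestVirtualSpecies:
    def test_true_suitability_matches_product_formula(self):
        env = generate_environment(quiet_scenario(), GRID, seed=1)
        sp = VirtualSpecies("v", niche={"sst": (10.0, 4.0),
                                        "salinity": (35.0, 3.0)})
        suit = sp.true_suitability(env, 2015)
        sst = env.annual_mean_field("sst", 2015)
        sal = env.annual_mean_field("salinity", 2015)
        expected = np.exp(-((sst - 10) ** 2) / (2 * 16)) \
            * np.exp(-((sal - 35) ** 2) / (2 * 9))
        ocean = env.ocean_mask
        assert np.allclose(suit[ocean], expected[ocean])
        assert (suit[~ocean] == 0).all()

    def test_impossible_niche_is_empty_everywhere(self):
        env = generate_environment(quiet_scenario(), GRID, seed=1)
        sp = VirtualSpecies("v", niche={"sst": (-80.0, 1.0)})
        assert not sp.true_occupancy(env, 2015).any()

    def test_infinite_breadth_occupies_whole_light_valid_band(self):
        env = generate_environment(quiet_scenario(), GRID, seed=1)
        sp = VirtualSpecies("v", niche={"sst": (0.0, 1e9),
                                        "light_bottom": (0.0, 1e12)})
        assert np.array_equal(sp.true_occupancy(env, 2015), env.light_valid)

    def test_generated_species_have_viable_ranges(self):
        env = generate_environment(SCENARIO_PRESETS["SSP-like-4.5"], GRID, 2)
        sps = generate_species(8, GRID, env, seed=9, min_occupied_cells=10)
        assert len(sps) == 8
        assert len({s.species_id for s in sps}) == 8
        for sp in sps:
            assert sp.true_occupancy(env, 2015).sum() >= 10
        assert {s.group for s in sps} == {"brown_macroalgae", "seagrasses"}

    def test_cold_adapted_species_contracts_under_warming(self):
        env = generate_environment(SCENARIO_PRESETS["SSP-like-8.5"], GRID, 2)
        sst15 = env.annual_mean_field("sst", 2015)
        cold_opt = np.quantile(sst15[env.light_valid], 0.05)
        sp = VirtualSpecies("cold", niche={"sst": (float(cold_opt), 3.0)})
        a0 = sp.true_occupancy(env, 2015).sum()
        a1 = sp.true_occupancy(env, 2100).sum()
        assert a1 <= a0


class TestSampleOccurrences:
    def setup_method(self):
        self.env = generate_environment(SCENARIO_PRESETS["SSP-like-4.5"],
                                        GRID, 3)
        self.sp = generate_species(1, GRID, self.env, seed=4)[0]

    def test_exact_record_count_and_support(self):
        recs = sample_occurrences(self.sp, self.env, n_records=57, seed=1)
        assert len(recs) == 57
        occ = np.zeros(GRID.shape, dtype=bool)
        for y in range(2015, 2021):
            occ |= self.sp.true_occupancy(self.env, y)
        rows, cols = GRID.cell_of(recs["longitude"].to_numpy(),
                                  recs["latitude"].to_numpy())
        assert occ[rows, cols].all()

    def test_deterministic_given_seed(self):
        r1 = sample_occurrences(self.sp, self.env, n_records=40, seed=8)
        r2 = sample_occurrences(self.sp, self.env, n_records=40, seed=8)
        assert r1.equals(r2)

    def test_unbiased_sampling_is_uniform_over_occupied_cells(self):
        """bias_strength=0: cell counts consistent with a uniform multinomial."""
        occ = np.zeros(GRID.shape, dtype=bool)
        for y in range(2015, 2021):
            occ |= self.sp.true_occupancy(self.env, y)
        n_cells = int(occ.sum())
        recs = sample_occurrences(self.sp, self.env, n_records=60 * n_cells,
                                  seed=2, bias_strength=0.0)
        rows, cols = GRID.cell_of(recs["longitude"].to_numpy(),
                                  recs["latitude"].to_numpy())
        flat = rows * GRID.n_cols + cols
        occupied_flat = np.flatnonzero(occ.ravel())
        counts = np.array([(flat == f).sum() for f in occupied_flat])
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_zero_occupancy_is_an_error(self):
        ghost = VirtualSpecies("ghost", niche={"sst": (-80.0, 0.5)})
        with pytest.raises(ValueError, match="no occupied cells"):
            sample_occurrences(ghost, self.env, n_records=5, seed=1)


class TestRegions:
    def test_twelve_regions_partition_ocean(self):
        env = generate_environment(quiet_scenario(), GRID, seed=1)
        labels, legend = make_region_labels(GRID, env.ocean_mask)
        assert set(legend) == set(range(1, 13))
        assert (labels[~env.ocean_mask] == 0).all()
        assert (labels[env.ocean_mask] > 0).all()  # every ocean cell labeled
        assert len(set(legend.values())) == 12
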