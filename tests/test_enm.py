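"""Pseudo-absence sampling, feature construction, variable elimination,
and suitability projection."""

import numpy as np
import pandas as pd
import pytest

from macrorange.enm import (FeatureBuilder, FeatureTable,
                            HabitatSuitabilityModel, ModelError,
                            build_feature_table, sample_pseudo_absences)
from macrorange.grid import GridSpec, RasterLayer
from macrorange.occurrences import PresenceGrid

GRID = GridSpec(resolution_deg=1.0, lat_min=0, lat_max=20,
                lon_min=0, lon_max=20)


def presence_grid(n_cells, rng):
    presence = np.zeros(GRID.shape, dtype=bool)
    idx = rng.choice(GRID.n_rows * GRID.n_cols, size=n_cells, replace=False)
    presence.ravel()[idx] = True
    return PresenceGrid(label="s", grid=GRID, presence=presence,
                        n_records=n_cells)


class ToyProvider:
    """Minimal layer provider: deterministic gradients per variable/month."""

    grid = GRID

    def layer(self, variable, year=2015, month=1):
        lat = GRID.lat_centers[:, None]
        lon = GRID.lon_centers[None, :]
        if variable == "depth":
            vals = np.broadcast_to(lon * 10.0, GRID.shape)
        elif variable == "shortwave":
            vals = np.full(GRID.shape, 300.0)
        else:
            vals = lat + 0.1 * month + 0.01 * (year - 2015) + np.zeros(GRID.shape)
        return RasterLayer(grid=GRID, variable=variable, values=vals,
                           valid_mask=np.ones(GRID.shape, dtype=bool))


class TestPseudoAbsences:
    def test_equal_count_disjoint_and_deterministic(self, rng):
        pres = presence_grid(40, rng)
        cand = np.ones(GRID.shape, dtype=bool)
        a1 = sample_pseudo_absences(pres, cand, seed=5)
        a2 = sample_pseudo_absences(pres, cand, seed=5)
        assert len(a1) == 40
        assert np.array_equal(a1, a2)
        assert not pres.presence[a1[:, 0], a1[:, 1]].any()

    def test_insufficient_candidates_is_an_error(self, rng):
        pres = presence_grid(40, rng)
        cand = np.zeros(GRID.shape, dtype=bool)
        with pytest.raises(ModelError, match="40"):
            sample_pseudo_absences(pres, cand, seed=1)


class TestFeatureTable:
    def test_feature_count_and_names(self):
        b = FeatureBuilder(ToyProvider())
        # 5 dynamic variables x 12 months + 2 static = 62
        assert len(b.feature_names) == 62
        assert "sst_m01" in b.feature_names and "depth" in b.feature_names

    def test_constant_variable_has_constant_monthly_features(self, rng):
        b = FeatureBuilder(ToyProvider(), dynamic_variables=(),
                           static_variables=("shortwave",))
        pres = presence_grid(10, rng)
        absc = sample_pseudo_absences(pres, np.ones(GRID.shape, bool), seed=2)
        tab = build_feature_table(np.argwhere(pres.presence), absc, b)
        assert (tab.X["shortwave"] == 300.0).all()

    def test_missing_feature_cells_are_excluded(self, rng):
        class HoleyProvider(ToyProvider):
            def layer(self, variable, year=2015, month=1):
                la = super().layer(variable, year, month)
                la.valid_mask = la.valid_mask.copy()
                la.valid_mask[0, 0] = False
                return la

        b = FeatureBuilder(HoleyProvider())
        cells = np.array([[0, 0], [5, 5], [7, 7]])
        tab = build_feature_table(cells, np.array([[9, 9], [3, 3]]), b)
        assert len(tab.X) == 4  # the masked cell dropped, labels realigned
        assert tab.y.tolist() == [1, 1, 0, 0]

    def test_nan_features_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(ModelError):
            FeatureTable(label="t", X=X, y=np.array([0, 1]),
                         cells=np.zeros((2, 2), dtype=int))


def planted_table(n=400, n_features=12, seed=0, driver="f00"):
    """Label depends only on one feature; the rest is noise."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, n_features)),
                     columns=[f"f{i:02d}" for i in range(n_features)])
    y = (X[driver] > 0).astype(int).to_numpy()
    return FeatureTable(label="planted", X=X, y=y,
                        cells=np.zeros((n, 2), dtype=int))


class TestElimination:
    def test_planted_driver_survives_and_oob_holds(self):
        tab = planted_table()
        fit = HabitatSuitabilityModel(tab, rf_params={"n_estimators": 200},
                                      seed=1).fit(drop_per_iter=4)
        assert "f00" in fit.selected_features
        full_oob = fit.oob_trace[0][1]
        assert fit.oob_score >= full_oob - 0.02

    def test_large_drop_keeps_only_full_model(self):
        tab = planted_table(n_features=8)
        fit = HabitatSuitabilityModel(tab, rf_params={"n_estimators": 100},
                                      seed=1).fit(drop_per_iter=20)
        assert len(fit.oob_trace) == 1
        assert fit.selected_features == list(tab.X.columns)

    def test_same_seed_same_selection(self):
        tab = planted_table()
        kw = dict(rf_params={"n_estimators": 100}, seed=7)
        f1 = HabitatSuitabilityModel(tab, **kw).fit(drop_per_iter=4)
        f2 = HabitatSuitabilityModel(tab, **kw).fit(drop_per_iter=4)
        assert f1.selected_features == f2.selected_features
        assert f1.oob_score == f2.oob_score

    def test_single_class_table_rejected(self):
        tab = planted_table()
        tab.y[:] = 1
        with pytest.raises(ModelError):
            HabitatSuitabilityModel(tab)

    def test_summary_reports_fit(self):
        fit = HabitatSuitabilityModel(planted_table(),
                                      rf_params={"n_estimators": 100},
                                      seed=1).fit(drop_per_iter=4)
        text = fit.summary()
        assert "OOB accuracy" in text and "planted" in text


@pytest.fixture(scope="module")
def world_fit(env2, species2):
    """One virtual species fitted with the default forest settings."""
    from macrorange.occurrences import rasterize_presence
    from macrorange.synth import sample_occurrences
    # the widest-ranged species, sampled densely
    sp = max(species2, key=lambda s: s.true_occupancy(env2, 2015).sum())
    recs = sample_occurrences(sp, env2, n_records=700, seed=21)
    pres = rasterize_presence(recs, env2.grid, env2.light_valid)
    absc = sample_pseudo_absences(pres, env2.light_valid, seed=22)
    b = FeatureBuilder(env2)
    tab = build_feature_table(np.argwhere(pres.presence), absc, b,
                              sp.species_id)
    fit = HabitatSuitabilityModel(tab, seed=23).fit()
    return sp, pres, b, fit


class TestVirtualWorldModel:

    def test_oob_accuracy_at_default_settings(self, world_fit):
        _, pres, _, fit = world_fit
        assert pres.n_cells >= 200
        assert fit.oob_score >= 0.8

    def test_suitability_tracks_planted_niche(self, world_fit, env2):
        sp, _, b, fit = world_fit
        sm = fit.project(b, year=None, domain_mask=env2.light_valid)
        mu, sigma = sp.niche["sst"]
        sst = env2.annual_mean_field("sst", 2015)
        near = env2.light_valid & (np.abs(sst - mu) <= sigma)
        far = env2.light_valid & (np.abs(sst - mu) >= 3 * sigma)
        assert near.any() and far.any()
        assert sm.p[near].mean() > sm.p[far].mean()

    def test_refit_with_other_seed_is_stable(self, world_fit):
        _, _, _, fit = world_fit
        other = HabitatSuitabilityModel(fit.model.table, seed=99).fit()
        assert abs(other.oob_score - fit.oob_score) < 0.05


class TestProjection:
    def fit_toy(self, rng):
        b = FeatureBuilder(ToyProvider())
        pres = presence_grid(60, rng)
        absc = sample_pseudo_absences(pres, np.ones(GRID.shape, bool), seed=3)
        tab = build_feature_table(np.argwhere(pres.presence), absc, b, "s")
        fit = HabitatSuitabilityModel(tab, rf_params={"n_estimators": 100},
                                      seed=2).fit()
        return b, tab, fit

    def test_probabilities_bounded_and_valid_mask_respected(self, rng):
        b, _, fit = self.fit_toy(rng)
        sm = fit.project(b, year=2050)
        assert sm.p.min() >= 0.0 and sm.p.max() <= 1.0
        dom = np.zeros(GRID.shape, dtype=bool)
        dom[:5] = True
        sm2 = fit.project(b, year=2050, domain_mask=dom)
        assert (sm2.p[~dom] == 0).all()

    def test_projection_onto_calibration_matches_training_predictions(
            self, rng):
        b, tab, fit = self.fit_toy(rng)
        sm = fit.project(b, year=None)
        p_cells = sm.p[tab.cells[:, 0], tab.cells[:, 1]]
        assert np.allclose(p_cells, fit.predict(tab.X))

    def test_all_masked_year_gives_all_masked_map(self, rng):
        class DeadProvider(ToyProvider):
            def layer(self, variable, year=2015, month=1):
                la = super().layer(variable, year, month)
                if year == 2099:
                    la.valid_mask = np.zeros(GRID.shape, dtype=bool)
                return la

        b = FeatureBuilder(DeadProvider())
        pres = presence_grid(60, rng)
        absc = sample_pseudo_absences(pres, np.ones(GRID.shape, bool), seed=3)
        tab = build_feature_table(np.argwhere(pres.presence), absc, b, "s")
        fit = HabitatSuitabilityModel(tab, rf_params={"n_estimators": 50},
                                      seed=2).fit()
        sm = fit.project(b, year=2099)
        assert not sm.valid_mask.any()
        assert (sm.p == 0).all()
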