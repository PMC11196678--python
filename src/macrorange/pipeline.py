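"""End-to-end orchestration of the forecasting analysis on the virtual world.

``run_pipeline`` executes the stages in dependency order — simulate the
environment and species, sample occurrences, filter and rasterize them,
build each species' alpha-hull extent of occurrence, fit the
random-forest niche models (per species and per group) under each
scenario, project suitability for every year, and derive the diversity,
habitat-extent and area-of-occupancy products — persisting every
intermediate as a tidy CSV or NetCDF file in the run directory, together
with a JSON manifest (config hash, seeds, headline numbers). Reruns with
the same config and seed reproduce every output exactly.

Ground-truth summaries from the virtual species (true richness change,
true fraction of localities losing >=10% of species, true per-species
range change) are written alongside, so recovery of the planted signals
can be checked from files alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aoo as aoo_mod
from . import diversity as div_mod
from . import habitat as hab_mod
from .enm import (FeatureBuilder, HabitatSuitabilityModel, SuitabilityMap,
                  build_feature_table, sample_pseudo_absences)
from .eoo import compute_eoo
from .grid import GridSpec, cell_area
from .io import save_field
from .occurrences import (filter_min_records, group_presence,
                          rasterize_presence)
from .synth import (SCENARIO_PRESETS, ScenarioParams, generate_environment,
                    generate_species, make_region_labels, sample_occurrences)

logger = logging.getLogger(__name__)

GROUPS = ("brown_macroalgae", "seagrasses")
#: combined group over every retained species (stable recovery statistics)
ALL_GROUP = "all_macrophytes"


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    resolution_deg: float = 2.0
    lat_min: float = -90.0
    lat_max: float = 90.0
    lon_min: float = -180.0
    lon_max: float = 180.0
    scenarios: list[str] = field(default_factory=lambda: list(SCENARIO_PRESETS))
    n_species: int = 10
    n_records_range: tuple[int, int] = (300, 800)
    bias_strength: float = 0.5
    min_records: int = 10
    calibration_years: tuple[int, int] = (2015, 2020)
    year_start: int = 2015
    year_end: int = 2100
    rf_params: dict = field(default_factory=dict)
    drop_per_iter: int = 10
    thresholds: tuple[float, ...] = hab_mod.HABITAT_THRESHOLDS
    alpha0: float = 0.001
    alpha_step: float = 0.005
    ratio_threshold: float = 10.0
    suitable_mode: str = "weighted"
    seed: int = 0
    write_maps: bool = True

    @property
    def grid(self) -> GridSpec:
        return GridSpec(resolution_deg=self.resolution_deg,
                        lat_min=self.lat_min, lat_max=self.lat_max,
                        lon_min=self.lon_min, lon_max=self.lon_max)

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    def scenario_params(self, label: str) -> ScenarioParams:
        if label not in SCENARIO_PRESETS:
            raise KeyError(f"unknown scenario {label!r}; presets: "
                           f"{sorted(SCENARIO_PRESETS)}")
        sc = SCENARIO_PRESETS[label]
        return dataclasses.replace(sc, year_start=self.year_start,
                                   year_end=self.year_end)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["n_records_range"] = list(self.n_records_range)
        d["calibration_years"] = list(self.calibration_years)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("n_records_range", "calibration_years", "thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def recovery_config(seed: int = 0) -> RunConfig:
    """Configuration for the virtual-world recovery analysis.

    Twenty virtual species (the upper end of what group-mean statistics
    need for stability at this grid scale) under the intermediate-high
    warming scenario that the headline projections are quoted for; record
    density follows the occurrence dataset the generator emulates (records
    roughly twice the number of occupied cells per species).
    """
    return RunConfig(scenarios=["SSP-like-7.0"], n_species=20,
                     n_records_range=(300, 800), seed=seed)


def _child_seed(master: int, *tags) -> int:
    """Stable per-stage child seed below 2**31."""
    h = hashlib.sha256(("/".join(map(str, (master, *tags)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class PipelineResult:
    """Paths plus in-memory headline tables from one run."""

    outdir: Path
    summary: dict
    tables: dict[str, pd.DataFrame]


def simulate_world(config: RunConfig):
    """Environment per scenario, shared species, shared occurrence records."""
    grid = config.grid
    envs = {label: generate_environment(config.scenario_params(label), grid,
                                        _child_seed(config.seed, 1))
            for label in config.scenarios}
    base_env = envs[config.scenarios[0]]
    species = generate_species(config.n_species, grid, base_env,
                               seed=_child_seed(config.seed, 2))
    rng = np.random.default_rng([_child_seed(config.seed, 3)])
    frames = []
    for i, sp in enumerate(species):
        n = int(rng.integers(config.n_records_range[0],
                             config.n_records_range[1] + 1))
        frames.append(sample_occurrences(
            sp, base_env, n_records=n, bias_strength=config.bias_strength,
            seed=_child_seed(config.seed, 4, i),
            years=config.calibration_years))
    records = pd.concat(frames, ignore_index=True)
    return envs, species, records


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    grid = config.grid
    areas = cell_area(grid)

    logger.info("stage simulate: %d species, %d scenarios, %.1f deg grid",
                config.n_species, len(config.scenarios), config.resolution_deg)
    envs, species, records = simulate_world(config)
    base_env = envs[config.scenarios[0]]
    light_valid = base_env.light_valid
    records.to_csv(outdir / "occurrences.csv", index=False)

    # --- occurrences: filter and rasterize ------------------------------
    retained, dropped = filter_min_records(records, min_n=config.min_records)
    species = [sp for sp in species if sp.species_id in set(retained)]
    by_id = {sp.species_id: sp for sp in species}
    presence = {}
    for sid in retained:
        recs = records[records["species_id"] == sid]
        presence[sid] = rasterize_presence(recs, grid, light_valid, label=sid)
    group_members = {g: [sid for sid in retained if by_id[sid].group == g]
                     for g in GROUPS}
    group_members[ALL_GROUP] = list(retained)
    group_pres = {g: group_presence([presence[s] for s in members], g)
                  for g, members in group_members.items() if members}

    # --- extent of occurrence -------------------------------------------
    logger.info("stage eoo: fitting alpha-hulls for %d species", len(retained))
    eoo_rows, eoos = [], {}
    for sid in retained:
        recs = records[records["species_id"] == sid]
        pts = recs[["longitude", "latitude"]].to_numpy()
        eoos[sid] = compute_eoo(pts, grid, light_valid, species_id=sid,
                                alpha0=config.alpha0, step=config.alpha_step,
                                ratio_threshold=config.ratio_threshold)
        eoo_rows.append({"species_id": sid, "n_records": len(recs),
                         "alpha_final": eoos[sid].alpha_final,
                         "eoo_cells": int(eoos[sid].mask.sum()),
                         "eoo_km2": float(areas.area_km2[eoos[sid].mask].sum()),
                         "hull_wkt": eoos[sid].hull_wkt})
    eoo_table = pd.DataFrame(eoo_rows)
    eoo_table.to_csv(outdir / "eoo_summary.csv", index=False)

    regions = hab_mod.RegionMask(grid, *make_region_labels(grid,
                                                           base_env.ocean_mask))
    pd.DataFrame([{"region": k, "name": v} for k, v in regions.legend.items()]
                 ).to_csv(outdir / "region_legend.csv", index=False)

    tables: dict[str, list[pd.DataFrame]] = {k: [] for k in (
        "diversity_trajectories", "latitudinal_profiles", "habitat_areas",
        "regional_shares", "aoo_series", "aoo_trajectories",
        "species_change_2100", "model_diagnostics", "ground_truth")}
    summary: dict = {"scenarios": {}}

    for label in config.scenarios:
        env = envs[label]
        res = _run_scenario(config, label, env, species, retained, by_id,
                            presence, group_pres, group_members, eoos,
                            regions, areas, light_valid, outdir)
        for key, df in res["tables"].items():
            tables[key].append(df)
        summary["scenarios"][label] = res["summary"]

    cat = {k: pd.concat(v, ignore_index=True) for k, v in tables.items() if v}
    for key, df in cat.items():
        df.to_csv(outdir / f"{key}.csv", index=False)

    summary["n_species_retained"] = len(retained)
    summary["n_species_dropped"] = len(dropped)
    summary["runtime_s"] = round(time.time() - t0, 1)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished in %.1f s", summary["runtime_s"])
    return PipelineResult(outdir=outdir, summary=summary, tables=cat)


def _run_scenario(config, label, env, species, retained, by_id, presence,
                  group_pres, group_members, eoos, regions, areas,
                  light_valid, outdir):
    grid = config.grid
    builder = FeatureBuilder(env, calibration_years=config.calibration_years)
    logger.info("scenario %s: fitting %d species + %d group models", label,
                len(retained), len(group_pres))

    # --- fit niche models (per species and per group) --------------------
    results = {}
    diag_rows = []
    for i, key in enumerate(list(retained) + list(group_pres)):
        pres = presence[key] if key in presence else group_pres[key]
        seed = _child_seed(config.seed, 5, label, i)
        # species models: absences from the light-valid band (within-niche
        # contrast); group models exhaust the band, so they draw ocean-wide
        candidates = light_valid if key in presence else env.ocean_mask
        absences = sample_pseudo_absences(pres, candidates, seed=seed)
        table = build_feature_table(np.argwhere(pres.presence), absences,
                                    builder, label=key)
        model = HabitatSuitabilityModel(table, rf_params=config.rf_params,
                                        seed=seed)
        fit = model.fit(drop_per_iter=config.drop_per_iter)
        results[key] = fit
        diag_rows.append({
            "scenario": label, "label": key,
            "n_presence_cells": pres.n_cells,
            "n_features_selected": len(fit.selected_features),
            "oob_score": fit.oob_score,
            "seed": seed,
            "oob_trace": ";".join(f"{n}:{s:.4f}" for n, s in fit.oob_trace),
            "selected_features": ";".join(fit.selected_features)})
    diagnostics = pd.DataFrame(diag_rows)

    # --- project all years, accumulating per-species p inside EOO --------
    # Feature values are extracted once per year at the light-valid cells
    # (everything downstream lives on the light-valid band), and each model
    # predicts all years in one batched call.
    years = list(config.years)
    feature_names = builder.feature_names
    per_year_X, per_year_dom = {}, {}
    for year in years:
        cube, valid = builder.cube(year=year)
        dom = valid & light_valid
        cells = np.argwhere(dom)
        per_year_X[year] = cube[:, cells[:, 0], cells[:, 1]].T
        per_year_dom[year] = dom
    suit_maps: dict[str, dict[int, SuitabilityMap]] = {}
    for key in list(retained) + list(group_pres):
        fit = results[key]
        idx = [feature_names.index(f) for f in fit.selected_features]
        Xcat = np.vstack([per_year_X[y][:, idx] for y in years])
        proba = fit.forest.predict_proba(Xcat)[
            :, list(fit.forest.classes_).index(1)]
        suit_maps[key] = {}
        off = 0
        for year in years:
            dom = per_year_dom[year]
            n = int(dom.sum())
            p = np.zeros(grid.shape)
            p[dom] = proba[off:off + n]
            off += n
            suit_maps[key][year] = SuitabilityMap(
                label=key, grid=grid, year=year, scenario=label,
                p=p, valid_mask=dom)
    sp_aoo_suits = {sid: {y: _clip_to_eoo(suit_maps[sid][y], eoos[sid])
                          for y in years} for sid in retained}
    group_rich: dict[str, dict[int, np.ndarray]] = {g: {} for g in group_pres}
    habitat_rows, shares_frames = [], []
    for g in group_pres:
        for year in years:
            rich = np.zeros(grid.shape)
            for sid in group_members[g]:
                rich += sp_aoo_suits[sid][year].p
            group_rich[g][year] = rich
            gm = suit_maps[g][year]
            for thr in config.thresholds:
                habitat_rows.append({
                    "group": g, "scenario": label, "threshold": thr,
                    "year": year,
                    "area_km2": hab_mod.suitable_area(gm, thr, light_valid,
                                                      areas)})
            if year in (years[0], years[-1]):
                sh = hab_mod.regional_shares(gm, regions, light_valid, areas)
                sh.insert(0, "year", year)
                sh.insert(0, "scenario", label)
                sh.insert(0, "group", g)
                shares_frames.append(sh)

    # --- diversity products ----------------------------------------------
    div_traj, prof_frames, gt_rows = [], [], []
    scen_summary: dict = {}
    y0, y1 = years[0], years[-1]
    for g in group_rich:
        rich = group_rich[g]
        traj = div_mod.mean_local_change_trajectory(
            rich, group=g, scenario=label, baseline_year=y0)
        div_traj.append(traj.to_frame())
        change = div_mod.log_pct_change(rich[y1], rich[y0])
        prof = div_mod.latitudinal_profile(change, grid)
        prof.insert(0, "scenario", label)
        prof.insert(0, "group", g)
        prof_frames.append(prof)
        frac = div_mod.fraction_losing(rich[y0], rich[y1])
        finite = change[np.isfinite(change)]
        scen_summary[g] = {
            "mean_local_diversity_change_pct_2100": float(finite.mean()),
            "fraction_localities_losing_10pct": frac,
        }
        if config.write_maps:
            for y in (y0, y1):
                save_field(outdir / f"richness_{g}_{label}_{y}.nc",
                           "richness", rich[y], grid,
                           attrs={"group": g, "scenario": label, "year": y})

    # --- habitat summary --------------------------------------------------
    habitat = pd.DataFrame(habitat_rows)
    for g in group_rich:
        for thr in config.thresholds:
            sub = habitat[(habitat["group"] == g)
                          & (habitat["threshold"] == thr)]
            a0 = float(sub[sub["year"] == y0]["area_km2"].iloc[0])
            a1 = float(sub[sub["year"] == y1]["area_km2"].iloc[0])
            scen_summary[g][f"habitat_pct_change_p{thr}"] = (
                hab_mod.pct_change_area(a1, a0) if a0 > 0 else None)
    shares = pd.concat(shares_frames, ignore_index=True)
    polar = shares[shares["name"].str.contains("polar")]
    for g in group_rich:
        sub = polar[polar["group"] == g]
        scen_summary[g]["polar_share_pct_2015"] = float(
            sub[sub["year"] == y0]["share_pct"].sum())
        scen_summary[g]["polar_share_pct_2100"] = float(
            sub[sub["year"] == y1]["share_pct"].sum())

    # --- area of occupancy -----------------------------------------------
    series = []
    for sid in retained:
        series.append(aoo_mod.build_aoo_series(
            sid, label, sp_aoo_suits[sid], eoos[sid], light_valid, areas,
            suitable_mode=config.suitable_mode, baseline_year=y0))
    aoo_frames = [s.to_frame() for s in series]
    aoo_traj_frames = []
    for g in group_rich:
        gs = (series if g == ALL_GROUP else
              [s for s in series if by_id[s.species_id].group == g])
        if len(gs) < 2:
            continue
        for kind in ("km2", "pct"):
            for expansion in (False, True):
                tr = aoo_mod.mean_aoo_trajectory(gs, group=g, kind=kind,
                                                 expansion=expansion)
                aoo_traj_frames.append(tr.to_frame())
        pct = aoo_mod.mean_aoo_trajectory(gs, group=g, kind="pct")
        scen_summary[g]["mean_aoo_change_pct_2100"] = float(pct.mean[-1])
        scen_summary[g]["mean_aoo_change_se_2100"] = float(pct.se[-1])
    loss = aoo_mod.per_species_loss_distribution(series, end_year=y1)

    # --- ground truth (planted signals) -----------------------------------
    # The pipeline's core assumption is no dispersal (suitability clipped to
    # the present-day EOO), so the planted truth is evaluated under the same
    # assumption: a species can persist in year Y only on cells it truly
    # occupied at the baseline. The unrestricted range change (allowing
    # expansion) is reported alongside for context.
    occ_base = {sid: by_id[sid].true_occupancy(env, y0) for sid in retained}
    occ_end_nd = {sid: by_id[sid].true_occupancy(env, y1) & occ_base[sid]
                  for sid in retained}
    occ_end_free = {sid: by_id[sid].true_occupancy(env, y1) for sid in retained}
    for g in group_rich:
        members = group_members[g]  # ALL_GROUP = everyone
        gt0 = sum(occ_base[sid].astype(float) for sid in members)
        gt1 = sum(occ_end_nd[sid].astype(float) for sid in members)
        gt_change = div_mod.log_pct_change(gt1, gt0)
        gt_finite = gt_change[np.isfinite(gt_change)]
        sp_area0 = np.array([areas.area_km2[occ_base[sid]].sum()
                             for sid in members])
        sp_area_nd = np.array([areas.area_km2[occ_end_nd[sid]].sum()
                               for sid in members])
        sp_area_free = np.array([areas.area_km2[occ_end_free[sid]].sum()
                                 for sid in members])
        ok = sp_area0 > 0
        gt_rows.append({
            "scenario": label, "group": g,
            "true_mean_local_diversity_change_pct": float(gt_finite.mean())
            if len(gt_finite) else np.nan,
            "true_fraction_losing_10pct": div_mod.fraction_losing(gt0, gt1),
            "true_mean_range_change_pct": float(np.mean(
                100.0 * (sp_area_nd[ok] - sp_area0[ok]) / sp_area0[ok])),
            "true_mean_range_change_pct_with_expansion": float(np.mean(
                100.0 * (sp_area_free[ok] - sp_area0[ok]) / sp_area0[ok])),
        })
    ground_truth = pd.DataFrame(gt_rows)

    return {
        "tables": {
            "diversity_trajectories": pd.concat(div_traj, ignore_index=True),
            "latitudinal_profiles": pd.concat(prof_frames, ignore_index=True),
            "habitat_areas": habitat,
            "regional_shares": shares,
            "aoo_series": pd.concat(aoo_frames, ignore_index=True),
            "aoo_trajectories": pd.concat(aoo_traj_frames, ignore_index=True),
            "species_change_2100": loss,
            "model_diagnostics": diagnostics,
            "ground_truth": ground_truth,
        },
        "summary": scen_summary,
    }


def _clip_to_eoo(suit, eoo):
    """Area-of-occupancy map: suitability zeroed outside the species' EOO."""
    p = np.where(eoo.mask, suit.p, 0.0)
    return dataclasses.replace(suit, p=p, valid_mask=suit.valid_mask & eoo.mask)
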