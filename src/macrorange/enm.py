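"""Random-forest habitat-suitability models with iterative variable selection.

The niche model follows a Model/Results split: a
:class:`HabitatSuitabilityModel` is built from a presence/pseudo-absence
feature table, and its :meth:`~HabitatSuitabilityModel.fit` runs the
variable-selection loop — fit the full forest, iteratively drop the ten
least-important features (mean impurity decrease), refit, track the
out-of-bag (OOB) accuracy of every candidate — and returns a
:class:`HabitatSuitabilityResults` carrying the most accurate forest, the
surviving features, the OOB trace and importances. Projection onto any
year/scenario layer stack produces a per-cell probability-of-occurrence
map (p in [0, 1]).

Feature construction: one feature per (dynamic variable, calendar month) —
the mean of that calendar month over the calibration window (2015-2020 by
default) — plus the static variables once. Projection for a later year
rebuilds the same features from that year's monthly layers, so the feature
space is identical at calibration and projection time.

Pseudo-absences are sampled uniformly without replacement from light-valid
ocean cells holding no occurrence record, in equal number to the presence
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .grid import GridSpec
from .occurrences import PresenceGrid

DEFAULT_RF_PARAMS = dict(n_estimators=500, max_features="sqrt")


class ModelError(ValueError):
    pass


def sample_pseudo_absences(presence: PresenceGrid, candidate_mask: np.ndarray,
                           seed: int, n: int | None = None) -> np.ndarray:
    """Draw ``n`` absence cells (default: one per presence cell).

    Candidates are the cells of ``candidate_mask`` minus the presence cells;
    sampling is uniform without replacement and reproducible from ``seed``.
    """
    if n is None:
        n = presence.n_cells
    pool = np.argwhere(candidate_mask & ~presence.presence)
    if len(pool) < n:
        raise ModelError(
            f"{presence.label}: need {n} pseudo-absence cells but only "
            f"{len(pool)} candidates remain")
    rng = np.random.default_rng([seed, 307])
    picks = rng.choice(len(pool), size=n, replace=False)
    return pool[np.sort(picks)]


class FeatureBuilder:
    """Builds the (variable x calendar month) feature cube from a layer provider.

    ``provider.layer(var, year, month)`` must return a RasterLayer; this is
    satisfied by the synthetic :class:`~macrorange.synth.EnvironmentSimulator`
    and by any loader of real layer files with the same signature.
    """

    def __init__(self, provider, dynamic_variables=("sst", "air_temp", "salinity",
                                                    "productivity", "ice_cover"),
                 static_variables=("shortwave", "depth"),
                 calibration_years: tuple[int, int] = (2015, 2020)):
        self.provider = provider
        self.dynamic_variables = tuple(dynamic_variables)
        self.static_variables = tuple(static_variables)
        self.calibration_years = calibration_years

    @property
    def feature_names(self) -> list[str]:
        names = [f"{v}_m{m:02d}" for v in self.dynamic_variables
                 for m in range(1, 13)]
        return names + list(self.static_variables)

    def cube(self, year: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Feature stack (n_features, n_rows, n_cols) and validity mask.

        ``year=None`` builds calibration features (per-calendar-month means
        over the calibration window); an explicit year uses that single
        year's monthly layers.
        """
        years = (range(self.calibration_years[0], self.calibration_years[1] + 1)
                 if year is None else [year])
        planes: list[np.ndarray] = []
        valid: np.ndarray | None = None
        for var in self.dynamic_variables:
            for m in range(1, 13):
                layers = [self.provider.layer(var, y, m) for y in years]
                plane = np.mean([la.values for la in layers], axis=0)
                v = np.logical_and.reduce([la.valid_mask for la in layers])
                planes.append(plane)
                valid = v if valid is None else (valid & v)
        for var in self.static_variables:
            la = self.provider.layer(var)
            planes.append(la.values)
            valid = la.valid_mask if valid is None else (valid & la.valid_mask)
        cube = np.stack(planes)
        valid = valid & np.isfinite(cube).all(axis=0)
        return cube, valid


@dataclass
class FeatureTable:
    """Training rows (presence + pseudo-absence cells) for one model."""

    label: str
    X: pd.DataFrame  # index: row id; columns: feature names
    y: np.ndarray  # 1 = presence, 0 = pseudo-absence
    cells: np.ndarray  # (n, 2) row/col of each training cell

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ModelError("X and y length mismatch")
        if self.X.isna().any().any():
            raise ModelError("feature table contains missing values")


def build_feature_table(presence_cells: np.ndarray, absence_cells: np.ndarray,
                        builder: FeatureBuilder, label: str = "") -> FeatureTable:
    """Assemble the training table from presence and pseudo-absence cells.

    Cells with any missing feature are excluded (with their labels) rather
    than imputed.
    """
    cube, valid = builder.cube(year=None)
    cells = np.vstack([presence_cells, absence_cells])
    y = np.concatenate([np.ones(len(presence_cells), dtype=int),
                        np.zeros(len(absence_cells), dtype=int)])
    ok = valid[cells[:, 0], cells[:, 1]]
    cells, y = cells[ok], y[ok]
    X = pd.DataFrame(cube[:, cells[:, 0], cells[:, 1]].T,
                     columns=builder.feature_names)
    return FeatureTable(label=label, X=X, y=y, cells=cells)


@dataclass
class SuitabilityMap:
    """Per-cell probability of occurrence for one species/group, year, scenario."""

    label: str
    grid: GridSpec
    year: int
    scenario: str
    p: np.ndarray = field(repr=False)
    valid_mask: np.ndarray = field(repr=False)


class HabitatSuitabilityModel:
    """Presence/pseudo-absence random-forest niche model for one species or group.

    Parameters
    ----------
    table : FeatureTable
        Training data (both classes must be present).
    rf_params : dict, optional
        Forwarded to :class:`sklearn.ensemble.RandomForestClassifier`;
        defaults to 500 trees with sqrt-features splits.
    seed : int
        Seeds every forest refit, making selection deterministic.
    """

    def __init__(self, table: FeatureTable, rf_params: dict | None = None,
                 seed: int = 0):
        if len(np.unique(table.y)) < 2:
            raise ModelError(f"{table.label}: training table has a single class")
        self.table = table
        self.rf_params = {**DEFAULT_RF_PARAMS, **(rf_params or {})}
        self.seed = int(seed)

    def _fit_forest(self, features: list[str]) -> RandomForestClassifier:
        rf = RandomForestClassifier(oob_score=True, random_state=self.seed,
                                    n_jobs=1, **self.rf_params)
        rf.fit(self.table.X[features].to_numpy(), self.table.y)
        return rf

    def fit(self, drop_per_iter: int = 10) -> "HabitatSuitabilityResults":
        """Iterative variable elimination; returns the most accurate model.

        Starting from the full feature set, each iteration drops the
        ``drop_per_iter`` features with the lowest mean impurity decrease
        (ties broken by feature name) and refits, until no more than
        ``drop_per_iter`` features remain. The candidate with the highest
        OOB accuracy wins; ties go to the smaller feature set.
        """
        features = list(self.table.X.columns)
        trace: list[tuple[list[str], float]] = []
        forests: list[RandomForestClassifier] = []
        while True:
            rf = self._fit_forest(features)
            trace.append((list(features), float(rf.oob_score_)))
            forests.append(rf)
            if len(features) <= drop_per_iter:
                break
            imp = pd.Series(rf.feature_importances_, index=features)
            order = sorted(features, key=lambda f: (imp[f], f))
            drop = set(order[:drop_per_iter])
            features = [f for f in features if f not in drop]
        best = max(range(len(trace)),
                   key=lambda i: (trace[i][1], -len(trace[i][0])))
        sel_features, oob = trace[best]
        rf = forests[best]
        return HabitatSuitabilityResults(
            model=self, forest=rf, selected_features=sel_features,
            oob_score=oob,
            oob_trace=[(len(f), s) for f, s in trace],
            importances=pd.Series(rf.feature_importances_, index=sel_features))


@dataclass
class HabitatSuitabilityResults:
    """Fitted niche model: the winning forest and its selection diagnostics."""

    model: HabitatSuitabilityModel
    forest: RandomForestClassifier
    selected_features: list[str]
    oob_score: float
    oob_trace: list[tuple[int, float]]  # (n_features, oob accuracy) per step
    importances: pd.Series

    @property
    def label(self) -> str:
        return self.model.table.label

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of presence for rows with the selected features."""
        proba = self.forest.predict_proba(X[self.selected_features].to_numpy())
        return proba[:, list(self.forest.classes_).index(1)]

    def project(self, builder: FeatureBuilder, year: int | None = None,
                scenario: str = "", domain_mask: np.ndarray | None = None
                ) -> SuitabilityMap:
        """Suitability map for one year (None = calibration climatology).

        ``domain_mask`` optionally restricts prediction to a subset of cells
        (e.g. the light-valid band) to save time; cells outside it, and
        cells with missing inputs, are masked with p = 0.
        """
        cube, valid = builder.cube(year=year)
        return self.project_from_cube(
            cube, valid, builder.feature_names, getattr(builder.provider, "grid"),
            year if year is not None else builder.calibration_years[0],
            scenario, domain_mask)

    def project_from_cube(self, cube: np.ndarray, valid: np.ndarray,
                          feature_names: list[str], grid: GridSpec, year: int,
                          scenario: str = "",
                          domain_mask: np.ndarray | None = None) -> SuitabilityMap:
        """Project from a prebuilt feature cube (shared across models/years)."""
        if domain_mask is not None:
            valid = valid & domain_mask
        idx = [feature_names.index(f) for f in self.selected_features]
        cells = np.argwhere(valid)
        p = np.zeros(valid.shape)
        if len(cells):
            X = cube[idx][:, cells[:, 0], cells[:, 1]].T
            proba = self.forest.predict_proba(X)
            p[cells[:, 0], cells[:, 1]] = proba[:, list(self.forest.classes_).index(1)]
        return SuitabilityMap(label=self.label, grid=grid, year=year,
                              scenario=scenario, p=p, valid_mask=valid)

    def summary(self) -> str:
        """Plain-text summary of the selection run."""
        lines = [
            f"Habitat suitability model: {self.label}",
            f"  training rows: {len(self.model.table.y)} "
            f"({int(self.model.table.y.sum())} presences)",
            f"  selected features: {len(self.selected_features)}",
            f"  OOB accuracy: {self.oob_score:.3f}",
            "  elimination trace (n_features -> OOB):",
        ]
        lines += [f"    {n:4d} -> {s:.3f}" for n, s in self.oob_trace]
        top = self.importances.sort_values(ascending=False).head(10)
        lines.append("  top importances:")
        lines += [f"    {name:<18s} {v:.4f}" for name, v in top.items()]
        return "\n".join(lines)
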