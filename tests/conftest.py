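"""Shared fixtures.

The two pipeline runs (default config and the recovery configuration) are
session-scoped and built lazily, so unit-test-only sessions never pay for
them; the acceptance tests share them instead of re-running the pipeline
per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from macrorange import (GridSpec, SCENARIO_PRESETS, generate_environment,
                        generate_species)
from macrorange.pipeline import RunConfig, recovery_config, run_pipeline

#: fixed seed for every seeded fixture in the suite
SUITE_SEED = 11


@pytest.fixture(scope="session")
def grid2() -> GridSpec:
    return GridSpec(resolution_deg=2.0)


@pytest.fixture(scope="session")
def env2(grid2):
    """Strong-warming environment on the 2-degree world."""
    return generate_environment(SCENARIO_PRESETS["SSP-like-8.5"], grid2,
                                seed=SUITE_SEED)


@pytest.fixture(scope="session")
def species2(grid2, env2):
    return generate_species(6, grid2, env2, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default configuration."""
    cfg = RunConfig(seed=SUITE_SEED)
    out = tmp_path_factory.mktemp("default_run")
    return cfg, run_pipeline(cfg, out)


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """One full pipeline run on the recovery configuration."""
    cfg = recovery_config(seed=SUITE_SEED)
    out = tmp_path_factory.mktemp("recovery_run")
    return cfg, run_pipeline(cfg, out)


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
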