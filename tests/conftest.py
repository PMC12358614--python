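"""Shared fixtures: parameter blocks, synthetic populations, short runs.

Expensive simulation fixtures are session-scoped so the equilibrated
snapshot and the short logged run are computed once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from codevo import (
    FisheryConfig,
    FixtureSpec,
    ModelConfig,
    RunSpec,
    get_scenario,
    make_population,
    spin_up,
)
from codevo.engine import RunLog, run_replicate


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def desk_config() -> ModelConfig:
    """Reduced-scale configuration (~2000 individuals at equilibrium)."""
    cfg = ModelConfig().scaled(0.4)
    cfg.run.spinup_years = 600
    cfg.run.seed = 3
    return cfg


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def small_pop():
    return make_population(FixtureSpec(n=200, seed=7))


@pytest.fixture(scope="session")
def equilibrated(desk_config):
    """Session-wide spun-up snapshot at F_max = 0.2 and 4 deg C."""
    pop, diag = spin_up(desk_config, seed=3)
    return pop, diag


@pytest.fixture(scope="session")
def short_run(desk_config, equilibrated):
    """One logged 120-year replicate at baseline climate, F_max = 0.2."""
    pop, _ = equilibrated
    spec = RunSpec(
        config=desk_config,
        scenario=get_scenario("baseline", noise_sd=0.5),
        fishery=FisheryConfig(f_max=0.2),
        years=120,
        replicates=1,
        seed=21,
        initial=pop,
    )
    final_pop, log = run_replicate(spec, 0)
    return final_pop, log
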