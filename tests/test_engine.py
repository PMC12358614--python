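"""Annual cycle, spin-up and replicated runs: ordering, conservation,
determinism, demographic bookkeeping."""

import numpy as np
import pytest

from codevo import (
    ConfigurationError,
    FisheryConfig,
    FixtureSpec,
    ModelConfig,
    Population,
    RunSpec,
    annual_step,
    energy_budgets,
    get_scenario,
    make_population,
)
from codevo.engine import RunLog, run_replicate, run_scenario


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestEnergyBudgets:
    def test_per_individual_energy_conservation(self, config):
        pop = make_population(FixtureSpec(n=2000, seed=3, maturity_fraction=0.5))
        for temp in (4.0, 7.0, 12.4):
            b = energy_budgets(pop, temp, config)
            closure = b["realized"] - b["cost"] - b["soma"] - b["gonad"] + b["deficit"]
            scale = np.maximum(np.abs(b["realized"]), np.abs(b["cost"]))
            assert np.all(np.abs(closure) <= 1e-9 * scale)

    def test_oxygen_usage_capped_to_unit_interval(self, config):
        pop = make_population(FixtureSpec(n=2000, seed=3))
        for temp in (4.0, 7.0, 12.4):
            usage = energy_budgets(pop, temp, config)["usage"]
            assert np.all((usage >= 0) & (usage <= 1.0))

    def test_realized_intake_never_exceeds_target(self, config):
        pop = make_population(FixtureSpec(n=2000, seed=5))
        b = energy_budgets(pop, 4.0, config)
        assert np.all(b["realized"] <= b["target"] * (1 + 1e-12))


class TestAnnualStep:
    def test_no_fishing_means_zero_fishing_rates(self, config):
        pop = make_population(FixtureSpec(n=500, seed=1, maturity_fraction=0.5))
        log = RunLog()
        annual_step(pop, 4.0, FisheryConfig(f_max=0.0), config, _rng(), log=log)
        assert log.summaries[-1].mean_rate_fishing == 0.0
        mort = log.mortality_frame()
        assert (mort.loc[mort.component == "fishing", "mean_rate"] == 0).all()

    def test_empty_population_stays_empty(self, config):
        out = annual_step(Population.empty(year=3), 4.0, FisheryConfig(), config, _rng())
        assert out.n == 0 and out.year == 4

    def test_max_age_cull_empties_population_without_recruitment(self, config):
        pop = make_population(FixtureSpec(n=50, age_min=20, age_max=20,
                                          maturity_fraction=0.0, seed=2))
        out = annual_step(pop, 4.0, FisheryConfig(f_max=0.0), config, _rng())
        assert out.n == 0

    def test_recruits_enter_next_year_at_age_one(self, config):
        # mature adults only; recruits appear with the configured entry size
        pop = make_population(FixtureSpec(n=400, age_min=6, age_max=10,
                                          length_min=80, length_max=110,
                                          maturity_fraction=1.0, seed=8))
        out = annual_step(pop, 4.0, FisheryConfig(f_max=0.0), config, _rng())
        recruits = out.filter(out.age == 1)
        assert recruits.n > 0
        lp = config.life_history
        assert np.all(recruits.length == lp.recruit_length)
        assert np.all(recruits.weight == lp.recruit_weight)
        assert not np.any(recruits.mature)

    def test_ages_stay_within_bounds(self, desk_config, short_run):
        final_pop, log = short_run
        assert np.all((final_pop.age >= 1) & (final_pop.age <= desk_config.life_history.max_age))

    def test_census_matches_state(self, short_run):
        final_pop, log = short_run
        last = log.summaries[-1]
        assert last.n == final_pop.n
        assert last.biomass == pytest.approx(final_pop.total_biomass)

    def test_maturity_is_absorbing(self, desk_config, equilibrated):
        pop, _ = equilibrated
        rng = _rng(42)
        mature_ids: set[int] = set(pop.id[pop.mature])
        for _ in range(25):
            pop = annual_step(pop, 4.0, FisheryConfig(f_max=0.2), desk_config, rng)
            still_here = np.isin(pop.id, list(mature_ids))
            assert np.all(pop.mature[still_here]), "a mature fish reverted to immature"
            mature_ids = set(pop.id[pop.mature])


class TestRunsAndDeterminism:
    def test_same_seed_same_replicate_is_bit_identical(self, desk_config, equilibrated):
        pop, _ = equilibrated
        spec = RunSpec(config=desk_config, scenario=get_scenario("baseline", noise_sd=0.5),
                       fishery=FisheryConfig(f_max=0.2), years=15, replicates=1,
                       seed=99, initial=pop)
        pop_a, log_a = run_replicate(spec, 0)
        pop_b, log_b = run_replicate(spec, 0)
        assert pop_a.to_dataframe().equals(pop_b.to_dataframe())
        assert log_a.summary_frame().equals(log_b.summary_frame())

    def test_different_replicates_differ(self, desk_config, equilibrated):
        pop, _ = equilibrated
        spec = RunSpec(config=desk_config, scenario=get_scenario("baseline", noise_sd=0.5),
                       fishery=FisheryConfig(f_max=0.2), years=15, replicates=2,
                       seed=99, initial=pop)
        (p0, _), (p1, _) = run_scenario(spec)
        assert not p0.to_dataframe().equals(p1.to_dataframe())

    def test_run_outputs_written(self, desk_config, equilibrated, tmp_path):
        pop, _ = equilibrated
        spec = RunSpec(config=desk_config, scenario=get_scenario("baseline", noise_sd=0.5),
                       fishery=FisheryConfig(f_max=0.2), years=5, replicates=2,
                       seed=1, initial=pop)
        run_scenario(spec, out_dir=tmp_path)
        for rep in ("rep_00", "rep_01"):
            for name in ("summary.csv", "age_structure.csv",
                         "mortality_decomposition.csv", "parent_offspring.csv",
                         "snapshot_final.csv"):
                assert (tmp_path / rep / name).exists()
        assert (tmp_path / "manifest.json").exists()

    def test_missing_initial_population_rejected(self, desk_config):
        with pytest.raises(ConfigurationError):
            RunSpec(config=desk_config, scenario=get_scenario("baseline"),
                    fishery=FisheryConfig(), years=10, replicates=1, seed=0,
                    initial=Population.empty())


class TestSpinUpDiagnostics:
    def test_spinup_reports_stationarity_and_state(self, equilibrated):
        pop, diag = equilibrated
        assert pop.n > 500
        for key in ("mean_appetite_gv_trend", "mean_pmrn_intercept_gv_trend",
                    "final_n", "final_biomass"):
            assert key in diag
        assert diag["final_n"] == pop.n


class TestConfigRoundtrip:
    def test_yaml_roundtrip_preserves_all_blocks(self, tmp_path):
        cfg = ModelConfig()
        cfg.fishery.f_max = 0.3
        cfg.scenario.name = "SSP2"
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = ModelConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()

    def test_scaled_config_shrinks_recruitment_and_density_jointly(self):
        cfg = ModelConfig()
        small = cfg.scaled(0.4)
        assert small.life_history.bh_beta == pytest.approx(0.4 * cfg.life_history.bh_beta)
        assert small.bioenergetics.b_half == pytest.approx(0.4 * cfg.bioenergetics.b_half)
        # per-capita constants untouched
        assert small.bioenergetics.c_smr == cfg.bioenergetics.c_smr
        with pytest.raises(ConfigurationError):
            cfg.scaled(0.0)
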