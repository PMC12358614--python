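"""Annual cycle orchestration, spin-up and replicated scenario runs.

One model year executes, in order: density-dependent foraging with oxygen
capping -> metabolic costs -> energy allocation and growth -> maturation
trials -> the six mortality components and survival -> egg production,
Beverton-Holt recruitment, gonad-weighted parent selection and
inheritance -> ageing (death past the maximum age).  Recruits enter the
population after survival is resolved and first experience mortality as
one-year-olds the following year.

Gonads built in a year determine that year's reproductive mortality and,
among survivors, the parental selection weights; they are spent at
spawning and reset to zero.

Randomness is hierarchical: a master seed spawns one independent
generator per replicate, so replicate results do not depend on execution
order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import bioenergetics as be
from . import life_history as lh
from . import mortality as mo
from . import scenarios as sc
from .config import ConfigurationError, FisheryConfig, ModelConfig
from .population import Population

__all__ = [
    "AnnualSummary",
    "RunLog",
    "RunSpec",
    "ExtinctionError",
    "annual_step",
    "energy_budgets",
    "spin_up",
    "run_replicate",
    "run_scenario",
]

_TINY = 1e-12


class ExtinctionError(RuntimeError):
    """Population went extinct where the protocol requires persistence."""


@dataclass
class AnnualSummary:
    """Per-year scalar aggregates (age-resolved tables live in RunLog)."""

    year: int
    temperature: float
    n: int
    biomass: float
    recruits: int
    mean_appetite_gv: float
    mean_pmrn_intercept_gv: float
    mean_appetite_phen: float
    mean_pmrn_intercept_phen: float
    n_newly_mature: int
    mean_age_at_maturation: float
    mean_length_at_maturation: float
    mean_rate_fixed: float
    mean_rate_predation: float
    mean_rate_foraging: float
    mean_rate_reproduction: float
    mean_rate_respiration: float
    mean_rate_fishing: float
    deaths: int
    deaths_starvation: int


@dataclass
class RunLog:
    """Accumulated per-year logs of one simulation run."""

    summaries: list[AnnualSummary] = field(default_factory=list)
    #: rows (year, age, n, mean_length, sd_length, prop_mature)
    age_rows: list[tuple] = field(default_factory=list)
    #: rows (year, age, component, mean_rate, deaths)
    mortality_rows: list[tuple] = field(default_factory=list)
    #: rows (year, midparent/offspring phenotypes per trait)
    parent_offspring_rows: list[tuple] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.summaries])

    def age_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.age_rows,
            columns=["year", "age", "n", "mean_length", "sd_length", "prop_mature"],
        )

    def mortality_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.mortality_rows,
            columns=["year", "age", "component", "mean_rate", "deaths"],
        )

    def parent_offspring_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.parent_offspring_rows,
            columns=[
                "year",
                "midparent_appetite",
                "offspring_appetite",
                "midparent_pmrn_intercept",
                "offspring_pmrn_intercept",
            ],
        )

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary_frame().to_csv(out / "summary.csv", index=False)
        self.age_frame().to_csv(out / "age_structure.csv", index=False)
        self.mortality_frame().to_csv(out / "mortality_decomposition.csv", index=False)
        self.parent_offspring_frame().to_csv(out / "parent_offspring.csv", index=False)

    @classmethod
    def load(cls, run_dir: str | Path) -> dict[str, pd.DataFrame]:
        run_dir = Path(run_dir)
        return {
            "summary": pd.read_csv(run_dir / "summary.csv"),
            "age_structure": pd.read_csv(run_dir / "age_structure.csv"),
            "mortality": pd.read_csv(run_dir / "mortality_decomposition.csv"),
            "parent_offspring": pd.read_csv(run_dir / "parent_offspring.csv"),
        }


def _empty_summary(year: int, temperature: float) -> AnnualSummary:
    return AnnualSummary(
        year=year, temperature=temperature, n=0, biomass=0.0, recruits=0,
        mean_appetite_gv=np.nan, mean_pmrn_intercept_gv=np.nan,
        mean_appetite_phen=np.nan, mean_pmrn_intercept_phen=np.nan,
        n_newly_mature=0, mean_age_at_maturation=np.nan,
        mean_length_at_maturation=np.nan,
        mean_rate_fixed=np.nan, mean_rate_predation=np.nan,
        mean_rate_foraging=np.nan, mean_rate_reproduction=np.nan,
        mean_rate_respiration=np.nan, mean_rate_fishing=np.nan,
        deaths=0, deaths_starvation=0,
    )


def energy_budgets(pop: Population, temperature: float, config: ModelConfig) -> dict[str, np.ndarray]:
    """Per-individual annual energy and oxygen budgets (no state change).

    Computes, in order: food availability from total biomass, desired
    effort for the phenotypic target intake, the oxygen-capped effort,
    realised intake, metabolic cost, net energy and its soma/gonad split.
    The budget closes exactly for every individual:
    ``realized = cost + soma + gonad - deficit``.
    """
    bp = config.bioenergetics
    lp = config.life_history
    avail = be.density_factor(pop.total_biomass, bp.b_half)
    w = pop.weight
    i_unit = bp.c_intake * w**bp.b_intake
    target = pop.appetite_phen * i_unit
    smr = be.smr(w, temperature, bp)
    mmr = be.mmr_energy(w, temperature, bp)
    effort_cap = np.minimum(bp.effort_cap, be.max_effort_for_oxygen(w, temperature, bp))
    realized, effort = be.forage(target, avail, effort_cap, i_unit)
    cost = smr * (1.0 + bp.c_act * effort)
    usage = np.minimum(cost / mmr, 1.0)
    net = realized - cost
    soma, gonad = be.allocate(net, pop.mature, pop.years_post_maturation,
                              lp.r_initial, lp.r_slope, lp.r_cap)
    deficit = np.where(net < 0, -net, 0.0)
    return {
        "availability": avail, "target": target, "effort": effort,
        "realized": realized, "cost": cost, "usage": usage, "net": net,
        "soma": soma, "gonad": gonad, "deficit": deficit,
    }


def annual_step(
    pop: Population,
    temperature: float,
    fishery: FisheryConfig,
    config: ModelConfig,
    rng: np.random.Generator,
    log: RunLog | None = None,
) -> Population:
    """Advance the population one year; optionally append to ``log``.

    Returns the next year's population (survivors aged one year plus new
    age-1 recruits).  An empty population stays empty — extinction is a
    valid, logged outcome.
    """
    bp = config.bioenergetics
    lp = config.life_history
    mp = config.mortality
    year = pop.year

    if pop.n == 0:
        out = Population.empty(year=year + 1, next_id=pop.next_id)
        if log is not None:
            log.summaries.append(_empty_summary(year, temperature))
        return out

    # --- energy acquisition under density dependence and the oxygen cap
    budget = energy_budgets(pop, temperature, config)
    w = pop.weight
    effort = budget["effort"]
    usage = budget["usage"]
    soma, gonad_e = budget["soma"], budget["gonad"]
    deficit = budget["deficit"]

    # --- starvation and growth
    new_w = w + (soma - deficit) / bp.e_soma
    starved = new_w < bp.condition_floor * bp.k_cond * pop.length**3
    new_w = np.maximum(new_w, _TINY)
    new_l = np.maximum(pop.length, (new_w / bp.k_cond) ** (1.0 / 3.0))
    gonad_mass = gonad_e / bp.e_gonad

    # --- maturation trials (immature only; maturity is absorbing)
    pmrn = lh.PMRNParams(slope=lp.pmrn_slope, envelope_width=lp.pmrn_width)
    newly_mature = np.zeros(pop.n, dtype=bool)
    imm = ~pop.mature
    if imm.any():
        newly_mature[imm] = lh.maturation_trial(
            new_l[imm], pop.age[imm], pop.pmrn_intercept_phen[imm], pmrn, rng
        )

    # --- six mortality components
    gsi = gonad_mass / (new_w + gonad_mass)
    gear_is_trawl = mo.assign_gear(fishery.trawl_fraction, rng, size=pop.n)
    sel = mo.gear_selectivity(new_l, gear_is_trawl, fishery)
    comp = np.column_stack([
        np.full(pop.n, mp.m_fixed),
        mo.predation_mortality(new_l, mp),
        mo.foraging_mortality(effort, new_l, mp),
        mo.reproductive_mortality(gsi, mp),
        mo.respiration_mortality(usage, mp),
        mo.fishing_mortality(fishery.f_max, sel),
    ])
    total = comp.sum(axis=1)
    survive_draw = rng.random(pop.n) < mo.survival_probability(total)
    alive = survive_draw & ~starved
    died_risk = ~survive_draw & ~starved

    # --- reproduction among survivors
    recruits = 0
    rec_pop = None
    rp = lh.RecruitmentParams(
        bh_alpha=lp.bh_alpha, bh_beta=lp.bh_beta, egg_energy=lp.egg_energy,
        recruit_length=lp.recruit_length, recruit_weight=lp.recruit_weight,
    )
    eligible = alive & pop.mature & (gonad_mass > 0)
    if eligible.any():
        total_eggs = float(lh.egg_production(gonad_e[alive].sum(), lp.egg_energy))
        recruits = lh.realized_recruits(total_eggs, rp, rng)
        if recruits > 0:
            idx = np.flatnonzero(eligible)
            pa, pb = lh.select_parents(gonad_mass[idx], recruits, rng)
            pa, pb = idx[pa], idx[pb]
            app_gv = lh.inherit(pop.appetite_gv[pa], pop.appetite_gv[pb],
                                lp.appetite_noise_sd, rng)
            pmrn_gv = lh.inherit(pop.pmrn_intercept_gv[pa], pop.pmrn_intercept_gv[pb],
                                 lp.pmrn_noise_sd, rng)
            app_ph = np.maximum(app_gv + rng.normal(0, lp.appetite_env_sd, recruits),
                                lh.TRAIT_FLOOR)
            pmrn_ph = np.maximum(pmrn_gv + rng.normal(0, lp.pmrn_env_sd, recruits),
                                 lh.TRAIT_FLOOR)
            ids = np.arange(pop.next_id, pop.next_id + recruits, dtype=np.int64)
            rec_pop = Population(
                id=ids,
                age=np.ones(recruits, dtype=np.int64),
                length=np.full(recruits, lp.recruit_length),
                weight=np.full(recruits, lp.recruit_weight),
                gonad_mass=np.zeros(recruits),
                mature=np.zeros(recruits, dtype=bool),
                years_post_maturation=np.zeros(recruits, dtype=np.int64),
                appetite_gv=app_gv if recruits > 1 else np.array([app_gv]).ravel(),
                pmrn_intercept_gv=pmrn_gv if recruits > 1 else np.array([pmrn_gv]).ravel(),
                appetite_phen=app_ph,
                pmrn_intercept_phen=pmrn_ph,
                year=year + 1,
                next_id=int(ids[-1]) + 1,
            )
            if log is not None:
                mid_app = (pop.appetite_phen[pa] + pop.appetite_phen[pb]) / 2.0
                mid_pmrn = (pop.pmrn_intercept_phen[pa] + pop.pmrn_intercept_phen[pb]) / 2.0
                log.parent_offspring_rows.extend(
                    zip([year] * recruits, mid_app, app_ph, mid_pmrn, pmrn_ph)
                )

    # --- logging on the at-risk population (pre-survival state)
    if log is not None:
        _log_year(
            log, pop, year, temperature, new_l, comp, alive, died_risk, starved,
            newly_mature, recruits, rng,
        )

    # --- ageing; spent gonads reset; recruits appended
    prev_mature = pop.mature.copy()
    next_pop = Population(
        id=pop.id,
        age=pop.age + 1,
        length=new_l,
        weight=new_w,
        gonad_mass=np.zeros(pop.n),
        mature=pop.mature | newly_mature,
        years_post_maturation=pop.years_post_maturation + prev_mature.astype(np.int64),
        appetite_gv=pop.appetite_gv,
        pmrn_intercept_gv=pop.pmrn_intercept_gv,
        appetite_phen=pop.appetite_phen,
        pmrn_intercept_phen=pop.pmrn_intercept_phen,
        year=year + 1,
        next_id=pop.next_id,
    ).filter(alive & (pop.age + 1 <= lp.max_age))
    if rec_pop is not None:
        next_pop = next_pop.extend(rec_pop)

    if log is not None and log.summaries:
        # patch end-of-year census into the summary written by _log_year
        s = log.summaries[-1]
        s.n = next_pop.n
        s.biomass = next_pop.total_biomass
    return next_pop


def _log_year(log, pop, year, temperature, new_l, comp, alive, died_risk, starved,
              newly_mature, recruits, rng):
    n = pop.n
    s = AnnualSummary(
        year=year,
        temperature=temperature,
        n=0,  # patched to the end-of-year census by the caller
        biomass=0.0,
        recruits=recruits,
        mean_appetite_gv=float(pop.appetite_gv.mean()),
        mean_pmrn_intercept_gv=float(pop.pmrn_intercept_gv.mean()),
        mean_appetite_phen=float(pop.appetite_phen.mean()),
        mean_pmrn_intercept_phen=float(pop.pmrn_intercept_phen.mean()),
        n_newly_mature=int(newly_mature.sum()),
        mean_age_at_maturation=float(pop.age[newly_mature].mean()) if newly_mature.any() else np.nan,
        mean_length_at_maturation=float(new_l[newly_mature].mean()) if newly_mature.any() else np.nan,
        mean_rate_fixed=float(comp[:, 0].mean()),
        mean_rate_predation=float(comp[:, 1].mean()),
        mean_rate_foraging=float(comp[:, 2].mean()),
        mean_rate_reproduction=float(comp[:, 3].mean()),
        mean_rate_respiration=float(comp[:, 4].mean()),
        mean_rate_fishing=float(comp[:, 5].mean()),
        deaths=int((~alive).sum()),
        deaths_starvation=int(starved.sum()),
    )
    log.summaries.append(s)

    cause = mo.attribute_deaths(comp, died_risk, rng)
    mature_now = pop.mature | newly_mature
    for age in np.unique(pop.age):
        m = pop.age == age
        lengths = new_l[m]
        log.age_rows.append((
            year, int(age), int(m.sum()), float(lengths.mean()),
            float(lengths.std(ddof=0)), float(mature_now[m].mean()),
        ))
        for k, name in enumerate(mo.COMPONENTS):
            log.mortality_rows.append((
                year, int(age), name, float(comp[m, k].mean()),
                int(((cause == k) & m).sum()),
            ))


@dataclass
class RunSpec:
    """One scenario experiment: climate x fishery, replicated."""

    config: ModelConfig
    scenario: sc.TemperatureScenario
    fishery: FisheryConfig
    years: int
    replicates: int
    seed: int
    initial: Population

    def __post_init__(self) -> None:
        if self.years < 1 or self.replicates < 1:
            raise ConfigurationError("years and replicates must be >= 1")
        if self.initial is None or self.initial.n == 0:
            raise ConfigurationError("an initial population snapshot is required")


def spin_up(
    config: ModelConfig,
    seed: int | None = None,
    initial: Population | None = None,
    log: RunLog | None = None,
) -> tuple[Population, dict]:
    """Equilibrate a founder population at constant temperature and F_max.

    Runs ``config.run.spinup_years`` years at the spin-up temperature and
    fishing pressure, starting from ``initial`` (or a synthetic founder
    population).  Returns the final population and stationarity
    diagnostics: the linear trend of each genetic trait mean over the
    final 10% of years, with its standard error.

    Raises :class:`ExtinctionError` if the population dies out.
    """
    rc = config.run
    rng = np.random.default_rng(np.random.SeedSequence(rc.seed if seed is None else seed))
    if initial is None:
        from .fixtures import FixtureSpec, make_population

        # juvenile-dominated founders: low biomass avoids a transient
        # density-dependence overshoot before recruitment equilibrates
        initial = make_population(FixtureSpec(
            n=rc.n_init, age_max=8, length_max=70.0, maturity_fraction=0.25,
            seed=int(rng.integers(2**31)),
        ))
    fishery = FisheryConfig(
        f_max=rc.spinup_f_max,
        l_max_sel=config.fishery.l_max_sel,
        sigma_rel=config.fishery.sigma_rel,
        trawl_fraction=config.fishery.trawl_fraction,
    )
    log = RunLog() if log is None else log
    pop = initial
    for _ in range(rc.spinup_years):
        pop = annual_step(pop, rc.spinup_temperature, fishery, config, rng, log=log)
        if pop.n == 0:
            raise ExtinctionError(
                f"population extinct in spin-up year {pop.year}; check calibration"
            )
    diag = _stationarity(log, tail_fraction=0.1)
    diag["final_n"] = pop.n
    diag["final_biomass"] = pop.total_biomass
    return pop, diag


def _stationarity(log: RunLog, tail_fraction: float = 0.1) -> dict:
    df = log.summary_frame()
    tail = df.iloc[-max(3, int(len(df) * tail_fraction)):]
    out: dict = {}
    for trait in ("mean_appetite_gv", "mean_pmrn_intercept_gv"):
        res = stats.linregress(tail["year"], tail[trait])
        out[f"{trait}_trend"] = float(res.slope)
        out[f"{trait}_trend_se"] = float(res.stderr)
    return out


def run_replicate(spec: RunSpec, replicate: int) -> tuple[Population, RunLog]:
    """Run one replicate of a scenario from the shared initial snapshot."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(replicate,)))
    pop = spec.initial.filter(np.ones(spec.initial.n, dtype=bool))  # fresh copy
    pop.year = 0
    log = RunLog()
    temps = sc.scenario_trajectory(spec.scenario, spec.years, rng)
    for y in range(spec.years):
        pop = annual_step(pop, float(temps[y]), spec.fishery, spec.config, rng, log=log)
    return pop, log


def run_scenario(spec: RunSpec, out_dir: str | Path | None = None):
    """Run all replicates; optionally write one output directory each.

    Replicates share the configuration and initial population and differ
    only in their random stream.  Returns ``[(final_population, log), ...]``.
    """
    results = []
    for rep in range(spec.replicates):
        pop, log = run_replicate(spec, rep)
        results.append((pop, log))
        if out_dir is not None:
            rep_dir = Path(out_dir) / f"rep_{rep:02d}"
            log.save(rep_dir)
            pop.save(rep_dir / "snapshot_final.csv")
    if out_dir is not None:
        manifest = {
            "scenario": spec.scenario.id,
            "f_max": spec.fishery.f_max,
            "years": spec.years,
            "replicates": spec.replicates,
            "seed": spec.seed,
            "config": spec.config.to_dict(),
        }
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
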