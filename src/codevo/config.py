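"""Model configuration: one parameter block per process module.

All tunable constants of the simulator live here, grouped the way the
processes are grouped (bioenergetics, life history, mortality, fishery,
climate scenario, run control).  Blocks are plain dataclasses so a config
round-trips losslessly through YAML and is cheap to copy per replicate.

Absolute population size in the model is set by the joint scale of the
Beverton-Holt recruitment ceiling and the density-dependence
half-saturation biomass; :meth:`ModelConfig.scaled` shrinks or enlarges
both together so per-capita dynamics (effort, mortality, growth) are
preserved while the number of simulated individuals changes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "BioenergeticsParams",
    "LifeHistoryParams",
    "MortalityParams",
    "FisheryConfig",
    "ScenarioConfig",
    "RunControl",
    "ModelConfig",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised for an invalid or inconsistent configuration."""


@dataclass
class BioenergeticsParams:
    """Energy and oxygen budget constants.

    Energy flows are annual (J yr^-1); masses in kg; lengths in cm;
    temperatures in deg C; oxygen in mg O2 yr^-1.
    """

    #: intake per unit foraging effort at food availability 1, J yr^-1 kg^-b_intake
    c_intake: float = 1.3e7
    #: allometric exponent of the intake baseline
    b_intake: float = 0.70
    #: standard metabolic rate coefficient, J yr^-1 kg^-b_smr at t_ref
    c_smr: float = 6.0e6
    b_smr: float = 0.85
    #: Q10 of standard metabolism
    q10: float = 2.0
    #: reference temperature for the Q10 term, deg C
    t_ref: float = 4.0
    #: activity cost per unit foraging effort, as a multiple of SMR
    c_act: float = 0.25
    #: maximum metabolic rate coefficient (energy-equivalent), J yr^-1 kg^-b_mmr
    c_mmr: float = 4.17e7
    b_mmr: float = 0.8
    #: temperature of peak aerobic capacity, deg C
    t_peak: float = 14.0
    #: width (SD) of the dome-shaped MMR temperature multiplier, deg C
    t_width: float = 6.0
    #: oxycalorific coefficient, J per mg O2
    q_oxycal: float = 13.6
    #: hard ceiling on foraging effort (dimensionless)
    effort_cap: float = 6.0
    #: energy cost of building somatic tissue, J per kg wet mass
    e_soma: float = 7.0e6
    #: energy content of gonad tissue, J per kg
    e_gonad: float = 6.0e6
    #: condition factor of the cubic length-weight relation, kg cm^-3
    k_cond: float = 1.0e-5
    #: fraction of the condition-expected weight below which a fish starves
    condition_floor: float = 0.4
    #: half-saturation population biomass of food availability, kg
    b_half: float = 1.5e4


@dataclass
class LifeHistoryParams:
    """Maturation, reproduction and inheritance constants."""

    #: PMRN midpoint shift per year of age, cm yr^-1 (negative: easier with age)
    pmrn_slope: float = -2.0
    #: PMRN envelope width (length span from 25% to 75% probability), cm
    pmrn_width: float = 20.0
    #: founding genetic means
    appetite_init: float = 1.0
    pmrn_intercept_init: float = 90.0
    #: inheritance (segregation) noise SD per trait
    appetite_noise_sd: float = 0.05
    pmrn_noise_sd: float = 1.5
    #: environmental (phenotypic expression) deviation SD per trait.
    #: With mid-parent inheritance the equilibrium genetic variance is about
    #: twice the segregation variance, so env variance = 8x segregation
    #: variance centres the mid-parent/offspring regression slope near 0.2.
    appetite_env_sd: float = 0.1414
    pmrn_env_sd: float = 4.243
    #: gonadal allocation fraction in the first year after maturation
    r_initial: float = 0.30
    #: yearly increase of the gonadal fraction post maturation
    r_slope: float = 0.02
    #: ceiling of the gonadal fraction
    r_cap: float = 0.60
    #: energy content of one egg, J
    egg_energy: float = 1.2
    #: Beverton-Holt: recruits per egg at low density
    bh_alpha: float = 4.0e-6
    #: Beverton-Holt: half-saturation total egg number
    bh_beta: float = 3.0e8
    #: size of a 1-year-old recruit
    recruit_length: float = 20.0
    recruit_weight: float = 0.08
    max_age: int = 20


@dataclass
class MortalityParams:
    """Constants of the five natural mortality components (yr^-1 scales)."""

    #: size-independent background mortality
    m_fixed: float = 0.02
    #: predation at the reference length
    c_pred: float = 0.07
    #: size-scaling exponent of predation
    gamma_pred: float = 1.7
    #: reference length, cm
    l_ref: float = 50.0
    #: asymptotic predation floor for very large fish
    pred_floor: float = 0.01
    #: foraging mortality per unit effort, as a multiple of predation
    c_forage: float = 0.08
    #: effort exponent of foraging mortality
    psi: float = 2.0
    #: reproductive mortality at GSI = 1
    c_repro: float = 0.80
    #: GSI exponent
    eta: float = 2.0
    #: respiration (exhaustion) mortality at full oxygen usage
    c_resp: float = 0.05
    #: oxygen-usage exponent (> 1: negligible at low usage, steep near 1)
    theta: float = 3.0


@dataclass
class FisheryConfig:
    """Fishing pressure and gear selectivity.

    ``sigma_rel`` expresses the Gaussian selectivity width relative to the
    length of maximum selectivity: sigma = sigma_rel * l_max_sel.
    """

    f_max: float = 0.2
    l_max_sel: float = 110.0
    sigma_rel: float = 0.28
    trawl_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.f_max < 0:
            raise ConfigurationError("f_max must be >= 0")
        if self.l_max_sel <= 0 or self.sigma_rel <= 0:
            raise ConfigurationError("l_max_sel and sigma_rel must be > 0")
        if not 0.0 <= self.trawl_fraction <= 1.0:
            raise ConfigurationError("trawl_fraction must be in [0, 1]")

    @property
    def sigma(self) -> float:
        """Absolute selectivity width, cm."""
        return self.sigma_rel * self.l_max_sel


@dataclass
class ScenarioConfig:
    """Climate scenario selection (see :mod:`codevo.scenarios`)."""

    name: str = "baseline"
    noise_sd: float = 0.5
    #: optional override of the scenario's default ramp length, years
    ramp_years: int | None = None


@dataclass
class RunControl:
    """Run-length, replication and initial-population bookkeeping."""

    years: int = 2000
    replicates: int = 20
    seed: int = 0
    #: initial founder count for spin-up (before equilibration)
    n_init: int = 1500
    #: spin-up length, years
    spinup_years: int = 5000
    #: spin-up fishing pressure
    spinup_f_max: float = 0.2
    #: spin-up temperature, deg C
    spinup_temperature: float = 4.0


@dataclass
class ModelConfig:
    """Complete simulator configuration."""

    bioenergetics: BioenergeticsParams = field(default_factory=BioenergeticsParams)
    life_history: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    fishery: FisheryConfig = field(default_factory=FisheryConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    run: RunControl = field(default_factory=RunControl)

    # -- scaling ---------------------------------------------------------
    def scaled(self, factor: float) -> "ModelConfig":
        """Return a copy with population scale multiplied by ``factor``.

        Shrinks (or grows) the Beverton-Holt half-saturation egg number and
        the density-dependence half-saturation biomass together, which
        changes equilibrium abundance while leaving per-capita rates,
        growth trajectories and selection pressures unchanged.
        """
        if factor <= 0:
            raise ConfigurationError("scale factor must be > 0")
        cfg = self.copy()
        cfg.life_history.bh_beta *= factor
        cfg.bioenergetics.b_half *= factor
        cfg.run.n_init = max(2, int(round(cfg.run.n_init * factor)))
        return cfg

    def copy(self) -> "ModelConfig":
        return ModelConfig.from_dict(self.to_dict())

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config block(s): {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            block = d.get(f.name)
            if block is None:
                continue
            factory = f.default_factory  # type: ignore[union-attr]
            try:
                kwargs[f.name] = factory(**block) if isinstance(block, dict) else block
            except TypeError as exc:
                raise ConfigurationError(f"bad '{f.name}' block: {exc}") from exc
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)
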