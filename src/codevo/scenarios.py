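"""Climate warming scenarios: Barents Sea temperature trajectories.

Four scenarios are modelled: a no-warming ``baseline`` holding the
present-day mean of 4.0 deg C, and three warming trajectories patterned on
the IPCC shared socioeconomic pathways, stabilising at 4.8 (SSP1),
7.0 (SSP2) and 12.4 deg C (SSP3) within 100-500 years.  The mean
trajectory rises from the baseline along a saturating exponential

    T(y) = T_inf - (T_inf - T0) * exp(-3 y / ramp_years),

reaching ~95% of the total increase at ``ramp_years``; interannual
variability is added as i.i.d. Gaussian noise around the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, ScenarioConfig

__all__ = ["TemperatureScenario", "temperature_at", "scenario_trajectory", "SCENARIOS"]

#: steepness such that exp(-RAMP_RATE) of the increase remains at ramp_years
RAMP_RATE = 3.0


@dataclass(frozen=True)
class TemperatureScenario:
    """A parametric warming trajectory with interannual noise.

    Parameters
    ----------
    id : str
        One of ``baseline``, ``SSP1``, ``SSP2``, ``SSP3``.
    t0 : float
        Pre-warming mean temperature, deg C.
    t_inf : float
        Stabilised mean temperature, deg C (equals ``t0`` for baseline).
    ramp_years : int
        Years to ~95% of the stabilised increase.
    noise_sd : float
        SD of interannual deviations, deg C.
    """

    id: str
    t0: float = 4.0
    t_inf: float = 4.0
    ramp_years: int = 100
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.t_inf < self.t0:
            raise ConfigurationError("t_inf must be >= t0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.t_inf > self.t0 and not 100 <= self.ramp_years <= 500:
            raise ConfigurationError("ramp_years must lie in [100, 500] for warming scenarios")

    def mean_at(self, year: int | np.ndarray) -> float | np.ndarray:
        """Deterministic mean temperature at ``year`` (year 0 = start)."""
        y = np.asarray(year, dtype=float)
        if np.any(y < 0):
            raise ValueError("year must be >= 0")
        t = self.t_inf - (self.t_inf - self.t0) * np.exp(-RAMP_RATE * y / self.ramp_years)
        return float(t) if np.isscalar(year) else t


#: default scenario table; ramp lengths span the stated 100-500 year window
_SCENARIO_DEFS = {
    "baseline": dict(t0=4.0, t_inf=4.0, ramp_years=100),
    "SSP1": dict(t0=4.0, t_inf=4.8, ramp_years=100),
    "SSP2": dict(t0=4.0, t_inf=7.0, ramp_years=250),
    "SSP3": dict(t0=4.0, t_inf=12.4, ramp_years=500),
}

SCENARIOS = tuple(_SCENARIO_DEFS)


def get_scenario(name: str, noise_sd: float = 0.5, ramp_years: int | None = None) -> TemperatureScenario:
    """Look up a named scenario, optionally overriding noise and ramp length."""
    key = {s.lower(): s for s in _SCENARIO_DEFS}.get(str(name).lower())
    if key is None:
        raise ConfigurationError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    d = dict(_SCENARIO_DEFS[key])
    if ramp_years is not None:
        d["ramp_years"] = ramp_years
    return TemperatureScenario(id=key, noise_sd=noise_sd, **d)


def from_config(cfg: ScenarioConfig) -> TemperatureScenario:
    return get_scenario(cfg.name, noise_sd=cfg.noise_sd, ramp_years=cfg.ramp_years)


def temperature_at(
    scenario: TemperatureScenario, year: int, rng: np.random.Generator | None = None
) -> float:
    """Temperature in year ``year``: scenario mean plus a noise draw.

    With ``noise_sd == 0`` (or no ``rng``) this is the deterministic mean.
    """
    if year < 0:
        raise ValueError("year must be >= 0")
    t = scenario.mean_at(year)
    if scenario.noise_sd > 0 and rng is not None:
        t += rng.normal(0.0, scenario.noise_sd)
    return float(t)


def scenario_trajectory(
    scenario: TemperatureScenario, horizon: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Length-``horizon`` temperature series for years 0..horizon-1."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    t = scenario.mean_at(np.arange(horizon))
    if scenario.noise_sd > 0 and rng is not None:
        t = t + rng.normal(0.0, scenario.noise_sd, size=horizon)
    return np.asarray(t, dtype=float)
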