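"""Annual energy acquisition, metabolism, allocation, growth and oxygen.

The budget follows the Wisconsin bioenergetics tradition at an annual time
step.  Each fish carries a heritable appetite that sets a target annual
energy intake; foraging effort needed to realise it rises when population
biomass depresses food availability.  Standard metabolism scales
allometrically with mass and with temperature through a Q10 term; activity
adds a cost proportional to effort.  Surplus energy is split between soma
and gonads.  A parallel oxygen budget converts energy metabolised to
oxygen demand and compares it with a maximum uptake whose temperature
multiplier is dome-shaped, peaking above the present-day Barents Sea mean
so that aerobic scope *rises* with warming over the modelled range
(4-12.4 deg C) — the mechanism by which warming relaxes exhaustion
mortality in this model.

All functions are ufunc-like: scalars in, scalar out; arrays broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import BioenergeticsParams

__all__ = [
    "EnergyBudget",
    "OxygenBudget",
    "density_factor",
    "forage",
    "metabolic_cost",
    "smr",
    "mmr_energy",
    "temperature_scope_multiplier",
    "allocate",
    "grow",
    "oxygen_budget",
    "max_effort_for_oxygen",
]


@dataclass
class EnergyBudget:
    """One individual-year of energy flow, J yr^-1.

    ``starvation_deficit`` is the part of metabolic cost not covered by
    intake (paid from somatic reserves), so the budget closes exactly:
    realized_intake = metabolic_cost + soma_alloc + gonad_alloc - starvation_deficit.
    """

    target_intake: float
    realized_intake: float
    foraging_effort: float
    metabolic_cost: float
    net_energy: float
    soma_alloc: float
    gonad_alloc: float
    starvation_deficit: float = 0.0


@dataclass
class OxygenBudget:
    """Annual oxygen demand vs. maximum uptake, mg O2 yr^-1."""

    o2_demand: float
    o2_max: float

    @property
    def usage_ratio(self) -> float:
        return self.o2_demand / self.o2_max


def density_factor(total_biomass, half_saturation_biomass):
    """Food availability multiplier a(B) = 1 / (1 + B / B_half) in (0, 1].

    Hyperbolically decreasing in population biomass: doubling the
    competitor biomass roughly doubles the effort needed for the same
    intake once B >> B_half.
    """
    b = np.asarray(total_biomass, dtype=float)
    if np.any(b < 0):
        raise ValueError("total_biomass must be >= 0")
    if np.any(np.asarray(half_saturation_biomass) <= 0):
        raise ValueError("half_saturation_biomass must be > 0")
    out = 1.0 / (1.0 + b / half_saturation_biomass)
    return float(out) if out.ndim == 0 else out


def forage(target_intake, availability, effort_cap, intake_per_effort):
    """Foraging outcome given food availability and an effort ceiling.

    Effort is what the fish controls; intake per unit effort is
    ``availability * intake_per_effort``.  Returns
    ``(realized_intake, effort)``; realized equals target whenever the cap
    does not bind and never exceeds it.
    """
    target = np.asarray(target_intake, dtype=float)
    needed = target / (np.asarray(availability, dtype=float) * intake_per_effort)
    effort = np.minimum(needed, effort_cap)
    realized = effort * availability * intake_per_effort
    if np.ndim(realized) == 0:
        return float(realized), float(effort)
    return realized, effort


def smr(weight, temperature, p: BioenergeticsParams):
    """Standard metabolic rate, J yr^-1: allometric mass term times Q10."""
    w = np.asarray(weight, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weight must be > 0")
    out = p.c_smr * w**p.b_smr * p.q10 ** ((np.asarray(temperature, float) - p.t_ref) / 10.0)
    return float(out) if np.ndim(out) == 0 else out


def metabolic_cost(weight, temperature, p: BioenergeticsParams, effort=0.0):
    """Total metabolic cost: SMR plus an activity term proportional to effort."""
    base = smr(weight, temperature, p)
    out = base * (1.0 + p.c_act * np.asarray(effort, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def temperature_scope_multiplier(temperature, p: BioenergeticsParams):
    """Dome-shaped temperature multiplier of maximum metabolic rate.

    Gaussian in temperature with mode ``t_peak`` (above the modelled range's
    upper end) and width ``t_width``; normalised to 1 at the peak.  Because
    the peak sits near 13 deg C, the multiplier is increasing over
    4-12.4 deg C and aerobic scope widens with warming, tightening again
    as the warmest scenario approaches the peak.
    """
    t = np.asarray(temperature, dtype=float)
    out = np.exp(-((t - p.t_peak) ** 2) / (2.0 * p.t_width**2))
    return float(out) if np.ndim(out) == 0 else out


def mmr_energy(weight, temperature, p: BioenergeticsParams):
    """Maximum aerobic energy throughput, J yr^-1 (MMR in energy units)."""
    w = np.asarray(weight, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weight must be > 0")
    out = p.c_mmr * w**p.b_mmr * temperature_scope_multiplier(temperature, p)
    return float(out) if np.ndim(out) == 0 else out


def oxygen_budget(energy_metabolized, weight, temperature, p: BioenergeticsParams) -> OxygenBudget:
    """Oxygen demand of the energy metabolised vs. maximum uptake.

    Demand converts energy through the oxycalorific coefficient; maximum
    uptake is the energy-equivalent MMR divided by the same coefficient.
    If demand exceeds the maximum the caller must scale back foraging
    effort until the usage ratio is at most 1
    (:func:`max_effort_for_oxygen` gives the admissible effort).
    """
    e = np.asarray(energy_metabolized, dtype=float)
    if np.any(e < 0):
        raise ValueError("energy_metabolized must be >= 0")
    o2_max = mmr_energy(weight, temperature, p) / p.q_oxycal
    if np.any(np.asarray(o2_max) <= 0):
        raise ValueError("o2_max must be > 0; check MMR parameterization")
    demand = e / p.q_oxycal
    if np.ndim(demand) == 0 and np.ndim(o2_max) == 0:
        return OxygenBudget(float(demand), float(o2_max))
    return OxygenBudget(demand, o2_max)


def max_effort_for_oxygen(weight, temperature, p: BioenergeticsParams):
    """Largest foraging effort whose metabolic cost stays within MMR.

    Solves smr * (1 + c_act * e) = mmr for e; zero when even standard
    metabolism saturates the oxygen budget.
    """
    ratio = mmr_energy(weight, temperature, p) / smr(weight, temperature, p)
    out = np.maximum(0.0, (ratio - 1.0) / p.c_act)
    return float(out) if np.ndim(out) == 0 else out


def allocate(net_energy, mature, years_post_maturation, r0: float, r_slope: float, r_cap: float):
    """Split net energy between soma and gonads.

    Immature fish put everything into soma.  Mature fish allocate a gonad
    fraction that starts at ``r0`` the first year after maturing and rises
    by ``r_slope`` per year post maturation, capped at ``r_cap``.  A
    non-positive net energy allocates nothing (starvation is handled by
    the caller through the budget's deficit).
    """
    net = np.asarray(net_energy, dtype=float)
    ypm = np.asarray(years_post_maturation, dtype=float)
    if np.any(ypm < 0):
        raise ValueError("years_post_maturation must be >= 0")
    r = np.where(np.asarray(mature, bool), np.minimum(r0 + r_slope * ypm, r_cap), 0.0)
    pos = net > 0
    soma = np.where(pos, (1.0 - r) * net, 0.0)
    gonad = np.where(pos, r * net, 0.0)
    if np.ndim(soma) == 0:
        return float(soma), float(gonad)
    return soma, gonad


def grow(length, weight, soma_energy, p: BioenergeticsParams):
    """Convert somatic energy to new weight and length.

    Weight gains soma_energy / e_soma.  Length follows the cubic
    condition relation L = (W / k_cond)^(1/3) but never shrinks: length is
    structural, so weight loss shows up as poorer condition instead.
    """
    if np.any(np.asarray(soma_energy, dtype=float) < 0):
        raise ValueError("soma_energy must be >= 0")
    new_w = np.asarray(weight, dtype=float) + np.asarray(soma_energy, dtype=float) / p.e_soma
    new_l = np.maximum(np.asarray(length, dtype=float), (new_w / p.k_cond) ** (1.0 / 3.0))
    if np.ndim(new_w) == 0:
        return float(new_l), float(new_w)
    return new_l, new_w
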