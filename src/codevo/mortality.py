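"""Six instantaneous mortality components and annual survival.

Mortality is decomposed into fixed (background), predation, foraging,
reproductive, respiration (exhaustion) and fishing components, all as
instantaneous rates (yr^-1).  Components add as competing risks and the
annual survival probability is exp(-total).

Fishing is gear-selective.  Each year every individual is independently
exposed to either the trawl fleet (probability ``trawl_fraction``, 0.7
for the Northeast Arctic cod fishery) or the gillnet fleet.  Gillnet
selectivity is a Gaussian bell around the length of maximum selectivity

    U_G(L) = exp(-(L - L_max)^2 / (2 sigma^2)),

which leaves a size refugium for very large fish; trawl selectivity uses
the left half of the same Gaussian and is 1 at and above L_max, making
the two gears directly comparable.  Realised fishing mortality is
F = F_max * U(L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FisheryConfig, MortalityParams

__all__ = [
    "MortalityRates",
    "COMPONENTS",
    "gillnet_selectivity",
    "trawl_selectivity",
    "fishing_mortality",
    "assign_gear",
    "predation_mortality",
    "foraging_mortality",
    "reproductive_mortality",
    "respiration_mortality",
    "total_and_survive",
    "survival_probability",
]

COMPONENTS = ("fixed", "predation", "foraging", "reproduction", "respiration", "fishing")


@dataclass
class MortalityRates:
    """Per-individual instantaneous rates, yr^-1."""

    fixed: float
    predation: float
    foraging: float
    reproduction: float
    respiration: float
    fishing: float

    @property
    def total(self) -> float:
        return (
            self.fixed + self.predation + self.foraging
            + self.reproduction + self.respiration + self.fishing
        )

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in COMPONENTS}


def gillnet_selectivity(length, l_max_sel: float, sigma: float):
    """Bell-shaped gillnet selectivity in [0, 1], peaking at ``l_max_sel``."""
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("length must be > 0")
    if sigma <= 0 or l_max_sel <= 0:
        raise ValueError("l_max_sel and sigma must be > 0")
    u = np.exp(-((length - l_max_sel) ** 2) / (2.0 * sigma**2))
    return float(u) if np.ndim(u) == 0 else u


def trawl_selectivity(length, l_max_sel: float, sigma: float):
    """Sigmoidal trawl selectivity: gillnet curve below ``l_max_sel``, 1 above."""
    u = gillnet_selectivity(length, l_max_sel, sigma)
    out = np.where(np.asarray(length, dtype=float) < l_max_sel, u, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def fishing_mortality(f_max: float, selectivity):
    """F = F_max * U(L), in [0, F_max]."""
    if f_max < 0:
        raise ValueError("f_max must be >= 0")
    sel = np.asarray(selectivity, dtype=float)
    if np.any((sel < 0) | (sel > 1)):
        raise ValueError("selectivity must lie in [0, 1]")
    out = f_max * sel
    return float(out) if out.ndim == 0 else out


def assign_gear(trawl_fraction: float, rng: np.random.Generator, size=None):
    """Annual gear exposure draw(s): True = trawl, False = gillnet."""
    if not 0.0 <= trawl_fraction <= 1.0:
        raise ValueError("trawl_fraction must be in [0, 1]")
    draw = rng.random(size) < trawl_fraction
    return bool(draw) if size is None else draw


def gear_selectivity(length, gear_is_trawl, fishery: FisheryConfig):
    """Selectivity under the assigned gear(s)."""
    u_g = gillnet_selectivity(length, fishery.l_max_sel, fishery.sigma)
    u_t = trawl_selectivity(length, fishery.l_max_sel, fishery.sigma)
    out = np.where(np.asarray(gear_is_trawl, bool), u_t, u_g)
    return float(out) if np.ndim(out) == 0 else out


def predation_mortality(length, p: MortalityParams):
    """Size-dependent predation: power-law decline to an asymptotic floor."""
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("length must be > 0")
    out = p.c_pred * (length / p.l_ref) ** (-p.gamma_pred) + p.pred_floor
    return float(out) if out.ndim == 0 else out


def foraging_mortality(effort, length, p: MortalityParams):
    """Exposure risk of active foraging, scaled by predation pressure.

    Zero at zero effort; rises with effort (exponent ``psi``) and inherits
    the predation size-scaling, so large fish forage more safely.
    """
    e = np.asarray(effort, dtype=float)
    if np.any(e < 0):
        raise ValueError("effort must be >= 0")
    out = predation_mortality(length, p) * p.c_forage * e**p.psi
    return float(out) if np.ndim(out) == 0 else out


def reproductive_mortality(gsi, p: MortalityParams):
    """Cost of carrying gonads and courtship, rising with the gonadosomatic index."""
    g = np.asarray(gsi, dtype=float)
    if np.any((g < 0) | (g >= 1)):
        raise ValueError("gsi must lie in [0, 1)")
    out = p.c_repro * g**p.eta
    return float(out) if out.ndim == 0 else out


def respiration_mortality(usage_ratio, p: MortalityParams):
    """Exhaustion risk as oxygen demand approaches maximum uptake.

    Convex power of the usage ratio (theta > 1): negligible with ample
    aerobic scope, steep as the ratio approaches 1.
    """
    u = np.asarray(usage_ratio, dtype=float)
    if np.any((u < 0) | (u > 1.0 + 1e-9)):
        raise ValueError("usage_ratio must lie in [0, 1]; oxygen capping failed upstream")
    out = p.c_resp * np.minimum(u, 1.0) ** p.theta
    return float(out) if out.ndim == 0 else out


def survival_probability(total_rate):
    """Annual survival under competing instantaneous risks: exp(-total)."""
    r = np.asarray(total_rate, dtype=float)
    if np.any(r < 0):
        raise ValueError("total mortality rate must be >= 0")
    out = np.exp(-r)
    return float(out) if out.ndim == 0 else out


def total_and_survive(rates: MortalityRates, rng: np.random.Generator) -> bool:
    """Resolve one individual-year: Bernoulli survival at exp(-total)."""
    return bool(rng.random() < survival_probability(rates.total))


def attribute_deaths(component_rates: np.ndarray, died: np.ndarray, rng: np.random.Generator):
    """Attribute each death to one component, proportional to its rate.

    ``component_rates`` has shape (n_individuals, n_components).  Returns
    an integer component index per individual (-1 for survivors).  Used
    for the mortality-decomposition log only; survival itself is resolved
    from the total rate.
    """
    n, k = component_rates.shape
    out = np.full(n, -1, dtype=int)
    idx = np.flatnonzero(died)
    if idx.size == 0:
        return out
    rates = component_rates[idx]
    totals = rates.sum(axis=1)
    totals[totals <= 0] = 1.0  # dead with zero rate cannot occur; guard division
    cum = np.cumsum(rates / totals[:, None], axis=1)
    u = rng.random(idx.size)
    out[idx] = (u[:, None] < cum).argmax(axis=1)
    return out
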