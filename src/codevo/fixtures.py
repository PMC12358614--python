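"""Deterministic synthetic populations and logs for fast tests.

Everything here is generated programmatically from a seed — no stored
data.  Fixture populations satisfy the same invariants as engine-produced
states (cubic length-weight consistency, positive traits, absorbing
maturity bookkeeping), so any module can be exercised in milliseconds
without running the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import Population

__all__ = ["FixtureSpec", "make_population", "make_parent_offspring_log"]


@dataclass
class FixtureSpec:
    """Recipe for a synthetic population."""

    n: int = 1000
    age_min: int = 1
    age_max: int = 12
    length_min: float = 20.0
    length_max: float = 110.0
    appetite_mean: float = 1.0
    appetite_sd: float = 0.15
    pmrn_intercept_mean: float = 90.0
    pmrn_intercept_sd: float = 4.5
    maturity_fraction: float = 0.4
    k_cond: float = 1.0e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.age_min < 1 or self.age_max < self.age_min:
            raise ValueError("invalid age range")
        if self.length_min <= 0 or self.length_max < self.length_min:
            raise ValueError("invalid length range")
        if not 0.0 <= self.maturity_fraction <= 1.0:
            raise ValueError("maturity_fraction must be in [0, 1]")


def make_population(spec: FixtureSpec) -> Population:
    """Build a seeded synthetic population.

    Ages are uniform over the range; length interpolates the range along a
    saturating curve of age with mild jitter; weight follows the cubic
    condition relation.  Genetic trait values are Gaussian around the
    spec means (exactly the means when the SD is 0 or ``n`` is 1), and
    phenotypes equal genetic values here — environmental deviations are
    the engine's job at recruitment, not the fixture's.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if n == 1:
        age = np.array([(spec.age_min + spec.age_max) // 2])
        app = np.array([spec.appetite_mean])
        pmrn = np.array([spec.pmrn_intercept_mean])
    else:
        age = rng.integers(spec.age_min, spec.age_max + 1, size=n)
        app = rng.normal(spec.appetite_mean, spec.appetite_sd, size=n)
        pmrn = rng.normal(spec.pmrn_intercept_mean, spec.pmrn_intercept_sd, size=n)
    app = np.maximum(app, 1e-6)
    pmrn = np.maximum(pmrn, 1e-6)

    # saturating length-at-age across the requested span, ~10% jitter
    span = max(spec.age_max, 1)
    frac = 1.0 - np.exp(-2.5 * age / span)
    frac /= 1.0 - np.exp(-2.5)
    length = spec.length_min + (spec.length_max - spec.length_min) * np.clip(frac, 0, 1)
    if n > 1:
        length = length * rng.normal(1.0, 0.05, size=n)
    length = np.clip(length, spec.length_min, spec.length_max)
    weight = spec.k_cond * length**3

    mature = (
        np.zeros(n, dtype=bool)
        if spec.maturity_fraction == 0
        else (rng.random(n) < spec.maturity_fraction) & (age > spec.age_min)
    )
    ypm = np.where(mature, rng.integers(0, 4, size=n), 0)

    return Population(
        id=np.arange(n, dtype=np.int64),
        age=age.astype(np.int64),
        length=length,
        weight=weight,
        gonad_mass=np.zeros(n),
        mature=mature,
        years_post_maturation=ypm.astype(np.int64),
        appetite_gv=app,
        pmrn_intercept_gv=pmrn,
        appetite_phen=app,
        pmrn_intercept_phen=pmrn,
    )


def make_parent_offspring_log(n: int, h2_true: float, seed: int = 0) -> pd.DataFrame:
    """Synthetic mid-parent/offspring pairs with known regression slope.

    offspring = h2_true * midparent deviation + independent noise, so the
    least-squares slope of offspring on midparent is ``h2_true`` in
    expectation regardless of the noise level chosen (here set so total
    offspring variance matches the parental variance, as in an
    equilibrium population).
    """
    if not 0.0 <= h2_true <= 1.0:
        raise ValueError("h2_true must be in [0, 1]")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    mid = rng.normal(0.0, 1.0, size=n)
    resid_sd = np.sqrt(max(1.0 - h2_true**2, 0.0))
    off = h2_true * mid + rng.normal(0.0, resid_sd, size=n)
    return pd.DataFrame({"midparent": mid, "offspring": off})
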