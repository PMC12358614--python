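"""Maturation, reproduction and inheritance.

Maturation follows a probabilistic maturation reaction norm (PMRN): the
probability that an immature fish matures this year is a logistic
function of its length relative to an age-dependent midpoint
``Lp50(age) = intercept + slope * age``.  The intercept is the heritable
trait; a higher intercept means later maturation at larger size.  The
envelope width is the length span between 25% and 75% maturation
probability.

Recruitment converts the population's total gonadal energy to eggs and
eggs to one-year-old recruits through a Beverton-Holt function.  For each
recruit two parents are drawn from the mature population with probability
proportional to current gonad mass; offspring genetic values are the
mid-parent values plus Gaussian segregation noise, and phenotypes add an
environmental deviation drawn once for life.  The emergent mid-parent /
offspring regression slope (narrow-sense heritability) is calibrated to
sit near 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = [
    "Genome",
    "Phenotype",
    "PMRNParams",
    "RecruitmentParams",
    "maturation_probability",
    "maturation_trial",
    "egg_production",
    "beverton_holt",
    "expected_recruits",
    "select_parents",
    "inherit",
    "estimate_heritability",
]

#: logistic scale s.t. p = 0.75 at half the envelope width above the midpoint
_WIDTH_TO_SCALE = 1.0 / (2.0 * np.log(3.0))

#: lower clamp applied to inherited trait values (both traits are positive)
TRAIT_FLOOR = 1e-6


@dataclass(frozen=True)
class Genome:
    """Heritable trait values: appetite scaling and PMRN intercept (cm)."""

    appetite_gv: float
    pmrn_intercept_gv: float

    def __post_init__(self) -> None:
        if self.appetite_gv <= 0 or self.pmrn_intercept_gv <= 0:
            raise ValueError("genetic trait values must be > 0")


@dataclass(frozen=True)
class Phenotype:
    """Expressed trait values, fixed at recruitment for life."""

    appetite: float
    pmrn_intercept: float


@dataclass(frozen=True)
class PMRNParams:
    """Population-level PMRN shape (only the intercept evolves)."""

    slope: float = -2.0
    envelope_width: float = 20.0

    def __post_init__(self) -> None:
        if self.envelope_width <= 0:
            raise ValueError("envelope_width must be > 0")


@dataclass(frozen=True)
class RecruitmentParams:
    """Egg-to-recruit conversion constants."""

    bh_alpha: float
    bh_beta: float
    egg_energy: float
    recruit_length: float
    recruit_weight: float

    def __post_init__(self) -> None:
        for name in ("bh_alpha", "bh_beta", "egg_energy", "recruit_length", "recruit_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def maturation_probability(length, age, pmrn_intercept, pmrn: PMRNParams):
    """Probability that an immature fish of this length and age matures.

    Logistic in length around Lp50 = intercept + slope * age, with scale
    set so the probability spans 0.25 to 0.75 over ``envelope_width``.
    """
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("length must be > 0")
    if np.any(np.asarray(age) < 1):
        raise ValueError("age must be >= 1")
    lp50 = np.asarray(pmrn_intercept, dtype=float) + pmrn.slope * np.asarray(age, dtype=float)
    scale = pmrn.envelope_width * _WIDTH_TO_SCALE
    p = expit((length - lp50) / scale)
    return float(p) if np.ndim(p) == 0 else p


def maturation_trial(length, age, pmrn_intercept, pmrn: PMRNParams, rng: np.random.Generator):
    """Bernoulli maturation draw(s) for immature fish; maturity is absorbing."""
    p = maturation_probability(length, age, pmrn_intercept, pmrn)
    draw = rng.random(np.shape(p)) < p
    return bool(draw) if np.ndim(draw) == 0 else draw


def egg_production(gonad_energy, egg_energy: float):
    """Eggs spawned from gonadal energy (continuous-valued)."""
    g = np.asarray(gonad_energy, dtype=float)
    if np.any(g < 0):
        raise ValueError("gonad_energy must be >= 0")
    out = g / egg_energy
    return float(out) if out.ndim == 0 else out


def beverton_holt(total_eggs: float, p: RecruitmentParams) -> float:
    """Expected recruits R = alpha E / (1 + E / beta); saturates at alpha*beta."""
    if total_eggs < 0:
        raise ValueError("total_eggs must be >= 0")
    return p.bh_alpha * total_eggs / (1.0 + total_eggs / p.bh_beta)


# alias used in a couple of call sites where the name reads better
expected_recruits = beverton_holt


def realized_recruits(total_eggs: float, p: RecruitmentParams, rng: np.random.Generator) -> int:
    """Integer recruit count: expected value rounded stochastically.

    Floor plus a Bernoulli draw on the fractional part, which leaves the
    expectation unbiased instead of systematically rounding down.
    """
    r = beverton_holt(total_eggs, p)
    base = int(np.floor(r))
    return base + int(rng.random() < (r - base))


def select_parents(gonad_masses, n_pairs: int, rng: np.random.Generator):
    """Draw ``n_pairs`` parent pairs weighted by gonad mass.

    The two draws per pair are independent with replacement, so a single
    eligible spawner can be both parents.  Returns two integer index
    arrays of length ``n_pairs``.  Raises ``ValueError`` if no candidate
    has positive gonad mass (recruitment fails that year).
    """
    g = np.asarray(gonad_masses, dtype=float)
    if np.any(g < 0):
        raise ValueError("gonad masses must be >= 0")
    total = g.sum()
    if g.size == 0 or total <= 0:
        raise ValueError("no eligible parent with positive gonad mass")
    prob = g / total
    a = rng.choice(g.size, size=n_pairs, p=prob)
    b = rng.choice(g.size, size=n_pairs, p=prob)
    return a, b


def inherit(values_a, values_b, noise_sd: float, rng: np.random.Generator):
    """Mid-parent inheritance with Gaussian segregation noise.

    offspring = (a + b) / 2 + N(0, noise_sd), clamped to positive support.
    Accepts scalars or aligned arrays (one offspring per element).
    """
    mid = (np.asarray(values_a, dtype=float) + np.asarray(values_b, dtype=float)) / 2.0
    out = mid + rng.normal(0.0, noise_sd, size=np.shape(mid)) if noise_sd > 0 else mid
    out = np.maximum(out, TRAIT_FLOOR)
    return float(out) if np.ndim(out) == 0 else out


def inherit_genomes(
    genome_a: Genome, genome_b: Genome, appetite_noise_sd: float, pmrn_noise_sd: float,
    rng: np.random.Generator,
) -> Genome:
    """Object-level convenience wrapper around :func:`inherit`."""
    return Genome(
        appetite_gv=inherit(genome_a.appetite_gv, genome_b.appetite_gv, appetite_noise_sd, rng),
        pmrn_intercept_gv=inherit(
            genome_a.pmrn_intercept_gv, genome_b.pmrn_intercept_gv, pmrn_noise_sd, rng
        ),
    )


def estimate_heritability(midparent_values, offspring_values) -> float:
    """Narrow-sense heritability as the mid-parent/offspring regression slope.

    Ordinary least squares of offspring phenotype on mid-parent phenotype;
    the slope estimates h2 directly (no doubling, since the predictor is
    the mid-parent rather than a single parent).
    """
    x = np.asarray(midparent_values, dtype=float)
    y = np.asarray(offspring_values, dtype=float)
    if x.size != y.size:
        raise ValueError("midparent and offspring arrays must align")
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 distinct midparent values to regress")
    return float(stats.linregress(x, y).slope)
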