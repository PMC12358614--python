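"""Gear selectivity, the six mortality components, and survival."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codevo import FisheryConfig, MortalityParams
from codevo.mortality import (
    MortalityRates,
    assign_gear,
    attribute_deaths,
    fishing_mortality,
    foraging_mortality,
    gear_selectivity,
    gillnet_selectivity,
    predation_mortality,
    reproductive_mortality,
    respiration_mortality,
    survival_probability,
    total_and_survive,
    trawl_selectivity,
)

L_MAX = 110.0
SIGMA = 0.28 * L_MAX
MP = MortalityParams()


def gaussian_oracle(length: float) -> float:
    """Independent scalar evaluation of the bell selectivity curve."""
    return math.exp(-((length - L_MAX) ** 2) / (2.0 * SIGMA**2))


class TestSelectivity:
    def test_gillnet_peaks_at_unity_at_target_length(self):
        assert gillnet_selectivity(L_MAX, L_MAX, SIGMA) == 1.0

    def test_gillnet_one_sigma_below_target(self):
        u = gillnet_selectivity(L_MAX - SIGMA, L_MAX, SIGMA)
        assert u == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_gillnet_negligible_for_tiny_fish(self):
        assert gillnet_selectivity(1.0, L_MAX, SIGMA) < 0.002

    def test_trawl_saturates_above_target_length(self):
        assert trawl_selectivity(110.0, L_MAX, SIGMA) == 1.0
        assert trawl_selectivity(120.0, L_MAX, SIGMA) == 1.0

    def test_trawl_matches_gillnet_below_target(self):
        u = trawl_selectivity(L_MAX - SIGMA, L_MAX, SIGMA)
        assert u == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_curves_match_independent_oracle(self):
        rng = np.random.default_rng(2)
        lengths = rng.uniform(1.0, 200.0, size=500)
        for length in lengths:
            expected = gaussian_oracle(length)
            assert gillnet_selectivity(length, L_MAX, SIGMA) == pytest.approx(expected, abs=1e-12)
            expected_t = expected if length < L_MAX else 1.0
            assert trawl_selectivity(length, L_MAX, SIGMA) == pytest.approx(expected_t, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(length=st.floats(0.1, 500.0))
    def test_selectivities_bounded_and_ordered(self, length):
        u_g = gillnet_selectivity(length, L_MAX, SIGMA)
        u_t = trawl_selectivity(length, L_MAX, SIGMA)
        assert 0.0 <= u_g <= 1.0
        assert 0.0 <= u_t <= 1.0
        assert u_t >= u_g

    def test_trawl_monotone_gillnet_unimodal(self):
        lengths = np.linspace(1.0, 250.0, 400)
        u_t = trawl_selectivity(lengths, L_MAX, SIGMA)
        assert np.all(np.diff(u_t) >= -1e-15)
        u_g = gillnet_selectivity(lengths, L_MAX, SIGMA)
        peak = np.argmax(u_g)
        assert np.all(np.diff(u_g[: peak + 1]) >= 0)
        assert np.all(np.diff(u_g[peak:]) <= 0)


class TestFishing:
    @pytest.mark.parametrize(
        "f_max,sel,expected", [(0.2, 1.0, 0.2), (0.5, 0.0, 0.0), (0.3, 0.5, 0.15)]
    )
    def test_fishing_mortality_product(self, f_max, sel, expected):
        assert fishing_mortality(f_max, sel) == pytest.approx(expected)

    def test_gear_assignment_shares(self, rng):
        draws = assign_gear(0.7, rng, size=100_000)
        assert draws.mean() == pytest.approx(0.7, abs=0.004)
        assert np.all(assign_gear(1.0, rng, size=100))
        assert not np.any(assign_gear(0.0, rng, size=100))

    def test_gear_selectivity_dispatch(self):
        fishery = FisheryConfig(f_max=0.2)
        length = 60.0
        assert gear_selectivity(length, True, fishery) == trawl_selectivity(length, L_MAX, SIGMA)
        assert gear_selectivity(length, False, fishery) == gillnet_selectivity(length, L_MAX, SIGMA)

    def test_realized_fishing_deaths_match_rate(self, rng):
        # homogeneous cohort dying only of fishing: kill fraction ~ 1 - exp(-F)
        n, f = 200_000, 0.25
        survive = rng.random(n) < survival_probability(np.full(n, f))
        expected = 1.0 - math.exp(-f)
        se = math.sqrt(expected * (1 - expected) / n)
        assert (~survive).mean() == pytest.approx(expected, abs=4 * se)


class TestNaturalComponents:
    def test_predation_declines_with_size_to_floor(self):
        assert predation_mortality(20.0, MP) > predation_mortality(80.0, MP)
        assert predation_mortality(MP.l_ref, MP) == pytest.approx(MP.c_pred + MP.pred_floor)
        assert predation_mortality(1e6, MP) == pytest.approx(MP.pred_floor, abs=1e-6)

    def test_foraging_zero_at_rest_and_scales_with_predation(self):
        assert foraging_mortality(0.0, 50.0, MP) == 0.0
        assert foraging_mortality(2.0, 30.0, MP) > foraging_mortality(2.0, 90.0, MP)

    def test_foraging_linear_when_exponent_is_one(self):
        p1 = MortalityParams(psi=1.0)
        assert foraging_mortality(2.0, 50.0, p1) == pytest.approx(
            2 * foraging_mortality(1.0, 50.0, p1)
        )

    def test_reproductive_rises_with_gsi_from_zero(self):
        assert reproductive_mortality(0.0, MP) == 0.0
        assert reproductive_mortality(0.2, MP) > reproductive_mortality(0.1, MP)

    def test_respiration_convex_in_usage(self):
        assert respiration_mortality(0.0, MP) == 0.0
        assert respiration_mortality(1.0, MP) == pytest.approx(MP.c_resp)
        assert respiration_mortality(0.9, MP) > 2 * respiration_mortality(0.5, MP)

    def test_respiration_rejects_uncapped_usage(self):
        with pytest.raises(ValueError):
            respiration_mortality(1.2, MP)


class TestSurvival:
    def test_survival_closed_form(self):
        assert survival_probability(0.0) == 1.0
        assert survival_probability(math.log(2)) == pytest.approx(0.5)
        assert survival_probability(50.0) < 1e-20

    def test_total_is_component_sum(self):
        rates = MortalityRates(0.05, 0.1, 0.02, 0.01, 0.03, 0.2)
        assert rates.total == pytest.approx(0.41)
        assert sum(rates.as_dict().values()) == pytest.approx(rates.total)

    def test_zero_rate_always_survives(self, rng):
        rates = MortalityRates(0, 0, 0, 0, 0, 0)
        assert all(total_and_survive(rates, rng) for _ in range(100))

    def test_death_attribution_proportional_to_rates(self, rng):
        n = 30_000
        comp = np.tile([0.1, 0.3, 0.0, 0.0, 0.0, 0.0], (n, 1))
        died = np.ones(n, dtype=bool)
        cause = attribute_deaths(comp, died, rng)
        assert set(np.unique(cause)) == {0, 1}
        assert (cause == 1).mean() == pytest.approx(0.75, abs=0.01)

    def test_survivors_get_no_attribution(self, rng):
        comp = np.tile([0.1] * 6, (10, 1))
        cause = attribute_deaths(comp, np.zeros(10, dtype=bool), rng)
        assert np.all(cause == -1)
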