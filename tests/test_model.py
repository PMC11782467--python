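import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pairbond import (
    COMPARTMENTS,
    ParameterSet,
    PopulationState,
    derive_rates,
    female_death_rate,
    male_death_rate,
    rhs,
    theft_probability,
)

from _oracles import birth_death_tally, flux_rhs, rates_from_params
from conftest import random_params, random_state

CARER_NAMES = ("FMm", "FGg", "FGm", "FMg", "PGg", "PMm", "PMg", "Xg", "Xm")


class TestPopulationState:
    def test_default_initial_condition(self):
        s = PopulationState.default_initial()
        assert (s.FM, s.FG, s.M, s.G) == (0.5, 0.5, 0.5, 0.5)
        assert s.total() == pytest.approx(2.0)
        assert sum(s.values) == pytest.approx(2.0)

    def test_pairs_count_twice_in_total(self):
        s = PopulationState(PG=1.0, M=1.0)
        assert s.total() == pytest.approx(3.0)

    def test_small_negative_clamped_to_zero(self):
        vec = np.zeros(17)
        vec[0] = -5e-11
        assert PopulationState(vec).FM == 0.0

    def test_large_negative_rejected_naming_compartment(self):
        vec = np.zeros(17)
        vec[3] = -1e-8
        with pytest.raises(ValueError, match="G"):
            PopulationState(vec)

    def test_non_finite_rejected(self):
        vec = np.zeros(17)
        vec[2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            PopulationState(vec)

    def test_unknown_compartment_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PopulationState(FZ=1.0)


class TestMortality:
    def test_baseline_rate_when_no_carers(self, human_params):
        s = PopulationState(FM=1.0, M=1.0)
        assert female_death_rate(s, human_params) == pytest.approx(1 / 38)

    def test_density_dependent_branch_dominates(self, human_params):
        # carer sum 1.0 spread over several carer compartments
        s = PopulationState(FMm=0.4, PGg=0.3, Xg=0.3)
        assert female_death_rate(s, human_params) == pytest.approx(0.125)

    def test_baseline_branch_dominates_at_low_density(self):
        p = ParameterSet(L=22, beta=0.2)
        s = PopulationState(FGg=0.1)
        assert female_death_rate(s, p) == pytest.approx(1 / 22)

    def test_only_carers_enter_the_density_term(self, human_params):
        crowded_non_carers = PopulationState(FM=5.0, X=5.0, Y=5.0, PG=5.0)
        assert female_death_rate(
            crowded_non_carers, human_params) == pytest.approx(1 / 38)

    def test_male_rate_is_scaled_female_rate(self, human_params):
        s = PopulationState(FMm=1.0)
        assert male_death_rate(s, human_params) == pytest.approx(
            1.09 * female_death_rate(s, human_params))
        p_equal = human_params.with_updates(male_mortality_factor=1.0)
        assert male_death_rate(s, p_equal) == female_death_rate(s, p_equal)


class TestTheftProbability:
    def test_proportional_to_multiple_mater_share(self):
        p = ParameterSet(q_star=0.2)
        assert theft_probability(
            PopulationState(M=0.5, G=0.5), p) == pytest.approx(0.1)

    def test_all_males_are_thieves(self):
        p = ParameterSet(q_star=0.2)
        assert theft_probability(
            PopulationState(M=0.7), p) == pytest.approx(0.2)

    def test_no_thieves_no_theft(self):
        p = ParameterSet(q_star=0.9)
        assert theft_probability(PopulationState(G=1.0), p) == 0.0

    def test_no_males_at_all_defined_as_zero(self):
        p = ParameterSet(q_star=0.9)
        assert theft_probability(PopulationState(FM=1.0), p) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(m=st.floats(0, 10), g=st.floats(0, 10), qs=st.floats(0, 1))
    def test_bounded_by_success_rate(self, m, g, qs):
        p = ParameterSet(q_star=qs)
        q = theft_probability(PopulationState(M=m, G=g), p)
        assert 0.0 <= q <= qs


# Derivative of the canonical initial state (FM=FG=M=G=0.5) at the
# reference human parameters, frozen from the event-based oracle and
# hand-checked term by term against the per-compartment equations.
_INITIAL_DERIVATIVE = {
    "FM": -1.5323886639676112, "FG": -1.5323886639676112,
    "M": -0.022565789473684213, "G": -1.5225657894736842,
    "FMm": 0.75, "FGg": 0.375, "FGm": 0.375, "FMg": 0.0,
    "PGg": 0.75, "PG": 0.0, "PMm": 0.375, "PMg": 0.375, "PM": 0.0,
    "X": 0.038461538461538464, "Xm": 0.0, "Xg": 0.0,
    "Y": 0.01644736842105263,
}


class TestRightHandSide:
    def test_zero_state_has_zero_derivative(self, human_params):
        d = rhs(PopulationState(np.zeros(17)), human_params)
        assert np.allclose(d.values, 0.0)

    def test_retired_males_decay_alone(self, human_params):
        """With only retired males left, the sole flux is their death."""
        d = rhs(PopulationState(Y=1.0), human_params)
        expected = np.zeros(17)
        expected[COMPARTMENTS.index("Y")] = -1.09 / 38
        assert np.allclose(d.values, expected)

    def test_initial_state_derivative_matches_frozen_oracle(
            self, human_params, default_init):
        d = rhs(default_init, human_params).to_dict()
        for name, expected in _INITIAL_DERIVATIVE.items():
            assert d[name] == pytest.approx(expected, abs=1e-12), name

    def test_matches_event_oracle_at_random_states(self, rng):
        """Closed-form equations agree with the event-by-event tally."""
        for _ in range(50):
            params = random_params(rng)
            state = random_state(rng, scale=2.0)
            d_pkg = rhs(state, params).values
            d_orc = flux_rhs(state.values, **rates_from_params(params))
            np.testing.assert_allclose(d_pkg, d_orc, atol=1e-12)

    def test_without_theft_no_guard_to_multiple_flux(self, rng):
        """q_star=0: dM/dt reduces to son maturation minus male losses."""
        params = ParameterSet(q_star=0.0, L=30, beta=0.2, chi=0.1)
        for _ in range(20):
            state = random_state(rng)
            d = rhs(state, params)
            m_carers = state.FMm + state.FGm + state.PMm + state.Xm
            der = derive_rates(params)
            mu_m = male_death_rate(state, params)
            expected = (0.5 * params.beta * m_carers
                        - (der.omega_M + mu_m) * state.M)
            assert d.M == pytest.approx(expected, abs=1e-12)

    def test_bookkeeping_births_minus_deaths(self, rng):
        """dN/dt (pairs twice) equals the explicit birth-death tally."""
        for _ in range(200):
            params = random_params(rng)
            state = random_state(rng, scale=3.0)
            d = rhs(state, params)
            n_dot, expected = birth_death_tally(
                state.values, d.values, params.beta, params.L,
                params.male_mortality_factor)
            assert n_dot == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(vec=st.lists(st.floats(0, 5), min_size=17, max_size=17),
           qs=st.floats(0, 1), chi=st.floats(0, 1), k=st.floats(1, 2))
    def test_bookkeeping_holds_everywhere(self, vec, qs, chi, k):
        params = ParameterSet(q_star=qs, chi=chi, k=k, L=30, beta=0.2)
        state = PopulationState(np.array(vec))
        d = rhs(state, params)
        n_dot, expected = birth_death_tally(
            state.values, d.values, params.beta, params.L)
        assert n_dot == pytest.approx(expected, abs=1e-9)
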