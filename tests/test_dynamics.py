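import json
import math

import numpy as np
import pytest

from pairbond import (
    Dominance,
    IntegrationSettings,
    ParameterSet,
    PopulationState,
    classify_dominance,
    find_equilibrium,
    integrate,
    sex_ratios,
)

from _oracles import rates_from_params, rk4_fixed


class TestIntegrate:
    def test_zero_initial_state_stays_zero(self, human_params):
        traj = integrate(human_params, init=PopulationState(np.zeros(17)),
                         t_max=100.0)
        assert np.all(traj.states == 0.0)

    def test_retired_males_decay_exponentially(self, human_params):
        """Closed form: Y(t) = exp(-1.09 t / 38) when no one else is left."""
        traj = integrate(human_params, init=PopulationState(Y=1.0),
                         t_max=38.0, n_points=200)
        expected = np.exp(-1.09 * traj.t / 38.0)
        y_col = traj.states[:, -1]  # Y is the last compartment
        np.testing.assert_allclose(y_col, expected, atol=1e-6)

    def test_outputs_are_dense_enough_to_plot(self, human_params):
        traj = integrate(human_params, t_max=50.0, n_points=50)
        assert len(traj.t) >= 200

    def test_matches_fixed_step_oracle(self, human_params, default_init):
        traj = integrate(human_params, init=default_init, t_max=50.0,
                         n_points=201)
        y_oracle = rk4_fixed(default_init.values,
                             rates_from_params(human_params), 50.0, 1e-3)
        np.testing.assert_allclose(traj.states[-1], y_oracle, atol=1e-6)

    def test_compiled_stepper_agrees_with_lsoda(self, chimp_params,
                                                default_init):
        """The packaged RK45 and scipy's LSODA are independent routes."""
        fast = integrate(chimp_params, init=default_init, t_max=50.0)
        lsoda = integrate(
            chimp_params, init=default_init, t_max=50.0,
            settings=IntegrationSettings(method="LSODA", rtol=1e-10,
                                         atol=1e-12))
        np.testing.assert_allclose(fast.states[-1], lsoda.states[-1],
                                   atol=1e-6)

    def test_trajectory_dataframe_layout(self, human_params):
        df = integrate(human_params, t_max=10.0).to_dataframe()
        assert list(df.columns[:1]) == ["t"]
        assert {"FM", "PGg", "Y", "asr", "osr"} <= set(df.columns)
        assert len(df) >= 200


class TestDominanceClassification:
    def test_only_multiple_maters_survive(self):
        s = PopulationState(M=0.5, FM=0.3, X=0.2)
        assert classify_dominance(s) is Dominance.MULTIPLE_MATING

    def test_only_guarding_lineage_survives(self):
        s = PopulationState(G=0.2, PGg=0.3, FG=0.4)
        assert classify_dominance(s) is Dominance.GUARDING

    def test_paired_males_count_as_guarding(self):
        s = PopulationState(PM=0.5, FM=0.5)
        assert classify_dominance(s) is Dominance.GUARDING

    def test_empty_population_is_extinct(self):
        assert classify_dominance(
            PopulationState(np.zeros(17))) is Dominance.EXTINCT

    def test_both_lineages_above_threshold_coexist(self):
        s = PopulationState(M=0.5, G=0.5)
        assert classify_dominance(s) is Dominance.COEXISTENCE

    def test_threshold_is_relative_to_total(self):
        s = PopulationState(M=1.0, G=1e-7)
        assert classify_dominance(s, 1e-6) is Dominance.MULTIPLE_MATING
        assert classify_dominance(s, 1e-8) is Dominance.COEXISTENCE


class TestSexRatios:
    def test_operational_ratio_counts_free_adults(self):
        r = sex_ratios(PopulationState(M=3.0, G=1.0, FM=0.5, FG=0.5))
        assert r.osr == pytest.approx(4.0)

    def test_pairs_enter_adult_ratio_only(self):
        r = sex_ratios(PopulationState(M=1.0, G=1.0, FM=1.0, FG=1.0,
                                       PG=1.0))
        assert r.osr == pytest.approx(1.0)
        assert r.asr == pytest.approx(1.0)

    def test_post_fertile_females_excluded_from_both(self):
        with_x = PopulationState(M=1.0, FM=1.0, X=5.0, Y=0.0)
        without = PopulationState(M=1.0, FM=1.0)
        assert sex_ratios(with_x).osr == sex_ratios(without).osr
        assert sex_ratios(with_x).asr == sex_ratios(without).asr

    def test_zero_denominators_flagged_not_raised(self):
        r = sex_ratios(PopulationState(M=1.0))
        assert not r.osr_defined and not r.asr_defined
        assert math.isnan(r.osr) and math.isnan(r.asr)

    def test_without_pairs_ratio_numerators_coincide(self, rng):
        for _ in range(20):
            vec = rng.uniform(0, 2, 17)
            for i in (8, 9, 10, 11, 12):  # pair compartments
                vec[i] = 0.0
            s = PopulationState(vec)
            r = sex_ratios(s)
            assert r.osr * (s.FM + s.FG) == pytest.approx(
                r.asr * (s.FM + s.FG + s.FGm + s.FMm + s.FGg + s.FMg))


class TestFindEquilibrium:
    def test_short_lifespan_favours_multiple_mating(self, chimp_params):
        """L=22, interbirth 5: multiple mating alone survives."""
        res = find_equilibrium(chimp_params)
        assert res.dominance is Dominance.MULTIPLE_MATING
        assert res.converged
        assert res.residual < 1e-8

    def test_long_lifespan_favours_guarding(self, human_params):
        """L=38, interbirth 4: guarding alone survives."""
        res = find_equilibrium(human_params)
        assert res.dominance is Dominance.GUARDING
        assert res.converged
        assert res.final_state.M < 1e-6 * sum(res.final_state.values)

    def test_outcome_invariant_to_strategy_mix_at_start(self, human_params):
        """Off the boundary the attained equilibrium is unique."""
        doms = set()
        for m0, g0 in [(0.8, 0.2), (0.2, 0.8)]:
            init = PopulationState(FM=0.5, FG=0.5, M=m0, G=g0)
            doms.add(find_equilibrium(human_params, init=init).dominance)
        assert doms == {Dominance.GUARDING}

    def test_records_initial_scale(self, chimp_params):
        res = find_equilibrium(chimp_params)
        assert res.initial_total == pytest.approx(2.0)

    def test_result_serialises_to_json(self, tmp_path, chimp_params):
        res = find_equilibrium(chimp_params)
        path = tmp_path / "eq.json"
        res.to_json(path)
        data = json.loads(path.read_text())
        assert data["dominance"] == "multiple_mating"
        assert data["ratios"]["osr"] == pytest.approx(res.ratios.osr)
        assert set(data["final_state"]) == {
            "FM", "FG", "M", "G", "FMm", "FGg", "FGm", "FMg", "PGg", "PG",
            "PMm", "PMg", "PM", "X", "Xm", "Xg", "Y"}


class TestIntegrationSettings:
    def test_rejects_nonpositive_controls(self):
        with pytest.raises(ValueError):
            IntegrationSettings(t_max=0)
        with pytest.raises(ValueError):
            IntegrationSettings(convergence_tol=-1)

    def test_rejects_degenerate_extinction_threshold(self):
        with pytest.raises(ValueError):
            IntegrationSettings(extinction_threshold=0.5)
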