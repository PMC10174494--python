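"""Payoff matrix, expected payoffs, gaps and regime classification."""

import numpy as np
import pytest

from recyclegame import (
    PROFILES,
    Regime,
    StrategyProfile,
    build_payoff_matrix,
    check_regime_flags,
    classify_regime,
    expected_payoffs,
    gap_thresholds,
    payoff_gaps,
)
from conftest import random_parameters, random_state


class TestPayoffMatrix:
    def test_zero_parameters_give_zero_payoffs(self, zero_params):
        for _, triple in build_payoff_matrix(zero_params).items():
            assert triple == (0.0, 0.0, 0.0)

    def test_government_cells_against_hand_substitution(self, scenario_specs):
        # R5=30, R6=14 with the baseline values
        m = build_payoff_matrix(scenario_specs["s6_1"].params).as_dict()
        saa = m[StrategyProfile("strong", "active", "active")]
        assert saa.gov == 30 - 5 - 5 - 3 - 4 - 2
        wpp = m[StrategyProfile("weak", "passive", "passive")]
        assert wpp.gov == 14 - 4 - 3 - 2

    def test_firm_and_consumer_cells_against_hand_substitution(self, scenario_specs):
        m = build_payoff_matrix(scenario_specs["s6_1"].params).as_dict()
        # firm active under strong regulation: R1 - C1 + A1 + B1
        assert m[StrategyProfile("strong", "active", "active")].firm == 10 - 5 + 5 + 3
        # passive firm fined under strong regulation, loses M4 to passive consumer
        assert m[StrategyProfile("strong", "passive", "passive")].firm == 12 - 4 + 3 - 3 - 1
        # consumer active under weak regulation against passive firm: R2 - C2 - M2
        assert m[StrategyProfile("weak", "passive", "active")].consumer == 6 - 4 - 1
        # passive consumer under strong regulation keeps the lump subsidy B2
        assert m[StrategyProfile("strong", "active", "passive")].consumer == 8 - 3 + 2

    def test_regeneration_is_bit_identical(self, baseline):
        assert build_payoff_matrix(baseline) == build_payoff_matrix(baseline)

    def test_has_exactly_eight_profiles(self, baseline):
        assert [p for p, _ in build_payoff_matrix(baseline).items()] == list(PROFILES)
        assert len(PROFILES) == 8


class TestExpectedPayoffs:
    def test_vertex_state_selects_single_cell(self, baseline):
        m = build_payoff_matrix(baseline).as_dict()
        for prof in PROFILES:
            state = (
                1.0 if prof.gov == "strong" else 0.0,
                1.0 if prof.firm == "active" else 0.0,
                1.0 if prof.consumer == "active" else 0.0,
            )
            ep = expected_payoffs(baseline, state)
            gov = ep.gov_strong if prof.gov == "strong" else ep.gov_weak
            firm = ep.firm_active if prof.firm == "active" else ep.firm_passive
            cons = ep.consumer_active if prof.consumer == "active" else ep.consumer_passive
            assert (gov, firm, cons) == pytest.approx(tuple(m[prof]), abs=0)

    def test_uniform_state_averages_the_four_cells(self, scenario_specs):
        p = scenario_specs["s6_1"].params
        m = build_payoff_matrix(p).as_dict()
        ep = expected_payoffs(p, (0.5, 0.5, 0.5))
        strong_cells = [t.gov for prof, t in m.items() if prof.gov == "strong"]
        assert ep.gov_strong == pytest.approx(np.mean(strong_cells))

    def test_means_are_probability_weighted(self, baseline):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x, y, z = random_state(rng)
            ep = expected_payoffs(baseline, (x, y, z))
            assert ep.gov_mean == pytest.approx(x * ep.gov_strong + (1 - x) * ep.gov_weak)
            assert ep.firm_mean == pytest.approx(y * ep.firm_active + (1 - y) * ep.firm_passive)
            assert ep.consumer_mean == pytest.approx(
                z * ep.consumer_active + (1 - z) * ep.consumer_passive)

    def test_state_outside_cube_rejected(self, baseline):
        with pytest.raises(ValueError, match="unit cube"):
            expected_payoffs(baseline, (1.2, 0.5, 0.5))


class TestPayoffGaps:
    def test_hand_evaluated_gaps_at_center(self, scenario_specs):
        gaps = payoff_gaps(scenario_specs["s6_1"].params, (0.5, 0.5, 0.5))
        assert gaps == pytest.approx((7.0, 1.0, -1.0), abs=0)

    def test_zero_parameters_give_zero_gaps(self, zero_params):
        rng = np.random.default_rng(3)
        for _ in range(5):
            assert payoff_gaps(zero_params, random_state(rng)) == (0.0, 0.0, 0.0)

    def test_gap_equals_expected_payoff_difference(self):
        # aggregation identity: closed-form gaps vs bilinear matrix aggregation
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = random_parameters(rng)
            s = random_state(rng)
            gov, firm, cons = payoff_gaps(p, s)
            ep = expected_payoffs(p, s)
            assert gov == pytest.approx(ep.gov_strong - ep.gov_weak, rel=1e-10, abs=1e-9)
            assert firm == pytest.approx(ep.firm_active - ep.firm_passive, rel=1e-10, abs=1e-9)
            assert cons == pytest.approx(
                ep.consumer_active - ep.consumer_passive, rel=1e-10, abs=1e-9)


class TestRegimes:
    def test_baseline_thresholds(self, baseline):
        # lower C5-C6+B1+B2-F1 = 3, upper C5-C6+B1+B2+A1+A2 = 15
        assert gap_thresholds(baseline) == (3.0, 15.0)

    def test_scenario_flags(self, scenario_specs):
        f1 = check_regime_flags(scenario_specs["s6_1"].params)
        assert f1.opportunism_under_weak and f1.regulation_effective
        assert f1.relative_gain_position == "above_upper"
        f2 = check_regime_flags(scenario_specs["s6_2"].params)
        assert f2.high_opportunity_cost
        f3 = check_regime_flags(scenario_specs["s6_3"].params)
        assert f3.regulation_insufficient

    @pytest.mark.parametrize(
        "name, label, vertex",
        [
            ("s6_1", Regime.T1_ALL_COOPERATE, (1, 1, 1)),
            ("s6_2", Regime.T3_WEAK_GOV_COOP, (0, 1, 1)),
            ("s6_3", Regime.T4_STRONG_GOV_DEFECT, (1, 0, 0)),
        ],
    )
    def test_scenarios_classify_to_stated_stable_vertices(
        self, scenario_specs, name, label, vertex
    ):
        result = classify_regime(scenario_specs[name].params)
        assert result.label is label
        assert result.predicted_stable_vertices == {vertex}

    def test_window_parameters_have_no_predicted_ess(self, baseline):
        # relative gain strictly between the thresholds 3 and 15
        p = baseline.replace(R5=14 + 9.0)
        result = classify_regime(p)
        assert result.label is Regime.NO_ESS_WINDOW
        assert result.predicted_stable_vertices == frozenset()

    def test_threshold_equality_is_unclassified(self, baseline):
        p = baseline.replace(R5=14 + 15.0)  # exactly at the upper threshold
        assert classify_regime(p).label is Regime.UNCLASSIFIED

    def test_flags_are_scale_invariant(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            p = random_parameters(rng)
            scaled = p.replace(**{k: 7.5 * v for k, v in p})
            a, b = check_regime_flags(p), check_regime_flags(scaled)
            assert (a.opportunism_under_weak, a.regulation_effective,
                    a.high_opportunity_cost, a.regulation_insufficient,
                    a.relative_gain_position) == (
                b.opportunism_under_weak, b.regulation_effective,
                b.high_opportunity_cost, b.regulation_insufficient,
                b.relative_gain_position)
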