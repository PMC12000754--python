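"""Tornado, probabilistic sensitivity analysis, CEAC and scenarios."""

import numpy as np
import pytest

from subtypecea import (
    CostEffectivenessModel,
    ParameterSet,
    Strategy,
    ValidationError,
    ceac,
    default_schedules,
    default_wtp_grid,
    one_way_tornado,
    run_psa,
    run_scenario,
    sample_parameter,
    sample_parameters,
)
from subtypecea.params import Parameter
from subtypecea.sensitivity import COMPLEMENT_PAIRS, PSAResult

from conftest import all_fixed


class TestSampleParameter:
    def test_fixed_returns_point_always(self):
        p = Parameter("cost_rc", 14711, 13240, 17653, "cost", "fixed")
        rng = np.random.default_rng(0)
        assert all(sample_parameter(p, rng) == 14711 for _ in range(20))

    def test_beta_draws_stay_in_unit_interval(self):
        p = Parameter("u_cystectomy", 0.8, 0.6, 1.0, "utility", "beta")
        rng = np.random.default_rng(1)
        draws = np.array([sample_parameter(p, rng) for _ in range(2000)])
        assert ((draws >= 0) & (draws <= 1)).all()

    def test_gamma_mean_matches_point(self):
        p = Parameter("cost_rc", 14711, 13240, 17653, "cost", "gamma")
        rng = np.random.default_rng(2)
        n = 10_000
        draws = np.array([sample_parameter(p, rng) for _ in range(n)])
        sd = (17653 - 13240) / (2 * 1.96)
        assert draws.mean() == pytest.approx(14711, abs=3 * sd / np.sqrt(n))

    def test_beta_mean_matches_point(self):
        p = Parameter("p_basq", 0.303, 0.220, 0.349, "probability", "beta")
        rng = np.random.default_rng(3)
        n = 10_000
        draws = np.array([sample_parameter(p, rng) for _ in range(n)])
        sd = (0.349 - 0.220) / (2 * 1.96)
        assert draws.mean() == pytest.approx(0.303, abs=3 * sd / np.sqrt(n))

    def test_infeasible_beta_falls_back_to_uniform(self, caplog):
        # sd implied by the range exceeds what a beta with this mean supports
        p = Parameter("p_poor_current", 0.02, 0.0, 1.0, "probability", "beta")
        rng = np.random.default_rng(4)
        with caplog.at_level("WARNING"):
            draws = [sample_parameter(p, rng) for _ in range(200)]
        assert any("uniform" in r.message for r in caplog.records)
        assert all(0.0 <= d <= 1.0 for d in draws)
        assert max(draws) > 0.5  # clearly uniform, not a tight beta

    def test_complement_pairs_sum_to_one(self, params):
        rng = np.random.default_rng(5)
        for _ in range(50):
            drawn = sample_parameters(params, rng)
            for a, b in COMPLEMENT_PAIRS:
                assert drawn.value(a) + drawn.value(b) == pytest.approx(1.0)


class TestRunPSA:
    def test_same_seed_gives_identical_result(self, model):
        r1 = run_psa(model, horizon=5, n=50, seed=11)
        r2 = run_psa(model, horizon=5, n=50, seed=11)
        for s in r1.costs:
            assert np.array_equal(r1.costs[s], r2.costs[s])
            assert np.array_equal(r1.qalys[s], r2.qalys[s])

    def test_all_fixed_degenerates_to_base_case(self, schedules, params):
        fixed_model = CostEffectivenessModel(schedules, params=all_fixed(params))
        base = fixed_model.evaluate(5)
        psa = run_psa(fixed_model, horizon=5, n=7, seed=0)
        for s, outcome in base.items():
            assert np.allclose(psa.costs[s], outcome.total_cost)
            assert np.allclose(psa.qalys[s], outcome.total_qaly)

    def test_variance_propagates_through_additive_test_cost(self, schedules, params):
        """With only the subtype-test cost sampled, var(dCost) equals the
        sampled parameter's variance (it enters one strategy additively)."""
        from dataclasses import replace

        fixed = [
            p if p.name == "cost_subtype_id" else replace(p, distribution="fixed")
            for p in params.values()
        ]
        m = CostEffectivenessModel(schedules, params=ParameterSet(fixed))
        n = 4_000
        psa = run_psa(m, horizon=5, n=n, seed=42)
        assert np.allclose(np.diff(psa.delta_qaly), 0.0)
        sd = (409 - 273) / (2 * 1.96)
        assert psa.delta_cost.var(ddof=1) == pytest.approx(sd**2, rel=0.15)

    def test_invalid_iteration_count_rejected(self, model):
        with pytest.raises(ValidationError):
            run_psa(model, horizon=5, n=0, seed=0)


def _toy_psa(pairs, base_cost=10_000.0, base_qaly=2.0):
    """PSAResult from hand-set (delta_cost, delta_qaly) pairs."""
    dc = np.array([p[0] for p in pairs], dtype=float)
    dq = np.array([p[1] for p in pairs], dtype=float)
    n = len(pairs)
    return PSAResult(
        n_iterations=n,
        seed=0,
        horizon=5,
        costs={"CURRENT_PRACTICE": np.full(n, base_cost),
               "SUBTYPE_BASED": base_cost + dc},
        qalys={"CURRENT_PRACTICE": np.full(n, base_qaly),
               "SUBTYPE_BASED": base_qaly + dq},
    )


class TestCEAC:
    def test_hand_counted_fractions(self):
        psa = _toy_psa([(1000, 0.5), (-500, -0.1), (2000, 0.1), (500, 0.0)])
        points = ceac(psa, [0, 5000, 10000])
        probs = {p.wtp: p.probability_cost_effective for p in points}
        # w=0: only iterations with dCost < 0 win
        assert probs[0] == 1 / 4
        # w=5000: NMB = (1500, -0, -1500, -500) -> wins: 1st; 2nd is an
        # exact tie (5000*-0.1 = -500) and ties count as not cost-effective
        assert probs[5000] == 1 / 4
        # w=10000: NMB = (4000, -500, -1000, -500) -> 1 win
        assert probs[10000] == 1 / 4

    def test_limit_cases(self):
        psa = _toy_psa([(1000, 0.5), (-500, -0.1), (2000, 0.1), (500, 0.0)])
        assert ceac(psa, [0])[0].probability_cost_effective == pytest.approx(
            np.mean(psa.delta_cost < 0)
        )
        big = ceac(psa, [1e12])[0].probability_cost_effective
        assert big == pytest.approx(np.mean(psa.delta_qaly > 0))

    def test_monotone_when_all_gains_nonnegative(self):
        psa = _toy_psa([(1000, 0.5), (500, 0.0), (2000, 0.1), (100, 0.2)])
        grid = [0, 1000, 5000, 10000, 50000]
        probs = [p.probability_cost_effective for p in ceac(psa, grid)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_probability_is_exact_empirical_fraction(self):
        psa = _toy_psa([(100, 0.1)] * 3 + [(100, -0.1)] * 5)
        p = ceac(psa, [10_000])[0].probability_cost_effective
        assert p == 3 / 8

    def test_grid_validation(self):
        psa = _toy_psa([(0, 0.1)])
        with pytest.raises(ValidationError):
            ceac(psa, [])
        with pytest.raises(ValidationError):
            ceac(psa, [-5.0])

    def test_default_grid_contains_thresholds(self):
        grid = default_wtp_grid()
        assert 7_427.0 in grid and 10_000.0 in grid
        assert grid.min() == 0.0 and grid.max() == 50_000.0

    def test_seeds_give_statistically_compatible_curves(self, model):
        grid = [0, 5_000, 7_427, 10_000, 20_000, 50_000, 2e5, 1e6]
        n = 800
        c1 = [p.probability_cost_effective
              for p in run_psa(model, 5, n, seed=1).ceac(grid)]
        c2 = [p.probability_cost_effective
              for p in run_psa(model, 5, n, seed=2).ceac(grid)]
        assert max(abs(a - b) for a, b in zip(c1, c2)) < 0.08


class TestTornadoAndScenario:
    def test_degenerate_range_gives_zero_span(self, model):
        entries = {e.parameter: e for e in one_way_tornado(model, 5)}
        wtp_entry = entries["wtp"]  # fixed: low == point == high
        assert wtp_entry.span == 0.0

    def test_endpoints_equal_single_override_scenarios(self, model):
        entries = one_way_tornado(model, 5)
        for e in entries[:6]:
            spec = model.params[e.parameter]
            low = run_scenario(model, {e.parameter: spec.low}, 5)
            high = run_scenario(model, {e.parameter: spec.high}, 5)
            assert e.icer_at_low == low.icer
            assert e.icer_at_high == high.icer

    def test_sorted_by_decreasing_span(self, model):
        spans = [e.span for e in one_way_tornado(model, 5) if not np.isnan(e.span)]
        assert spans == sorted(spans, reverse=True)

    def test_test_cost_moves_delta_cost_only(self, model):
        base = run_scenario(model, {}, 5)
        shifted = run_scenario(model, {"cost_subtype_id": 441.0}, 5)
        assert shifted.delta_cost - base.delta_cost == pytest.approx(100.0)
        assert shifted.delta_qaly == pytest.approx(base.delta_qaly)

    def test_two_parameter_toy_corners_match_brute_force(self, schedules, params):
        """Tornado spans equal hand-evaluated ICERs at the range endpoints."""
        model = CostEffectivenessModel(schedules, params=params)

        def icer_at(overrides):
            out = model.evaluate(5, params=params.with_overrides(overrides))
            a = out[Strategy.CURRENT_PRACTICE.value]
            b = out[Strategy.SUBTYPE_BASED.value]
            return (b.total_cost - a.total_cost) / (b.total_qaly - a.total_qaly)

        entries = {e.parameter: e for e in one_way_tornado(model, 5)}
        for name in ("cost_subtype_id", "cost_nac"):
            spec = params[name]
            assert entries[name].icer_at_low == pytest.approx(
                icer_at({name: spec.low})
            )
            assert entries[name].icer_at_high == pytest.approx(
                icer_at({name: spec.high})
            )

    def test_empty_override_equals_base_case(self, model):
        base = model.fit().comparisons[5]
        scen = run_scenario(model, {}, 5)
        assert scen.delta_cost == pytest.approx(base.delta_cost)
        assert scen.delta_qaly == pytest.approx(base.delta_qaly)

    def test_unknown_override_lists_valid_names(self, model):
        with pytest.raises(KeyError, match="p_nac_rc_current"):
            run_scenario(model, {"nonexistent": 0.5}, 5)

    def test_nac_uptake_scenario_changes_current_arm_only(self, model):
        base_out = model.evaluate(5)
        scen_params = model.params.with_overrides(
            {"p_nac_rc_current": 0.74, "p_rc_only_current": 0.26}
        )
        scen_out = model.evaluate(5, params=scen_params)
        sb = Strategy.SUBTYPE_BASED.value
        cp = Strategy.CURRENT_PRACTICE.value
        assert scen_out[sb].total_cost == pytest.approx(base_out[sb].total_cost)
        assert scen_out[sb].total_qaly == pytest.approx(base_out[sb].total_qaly)
        assert scen_out[cp].total_cost != pytest.approx(base_out[cp].total_cost)
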