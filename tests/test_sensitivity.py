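"""One-way, scenario, and probabilistic sensitivity analyses."""

import itertools

import numpy as np
import pytest

from mobcea import (
    ceac,
    ceaf,
    default_lambda_grid,
    evaluate_config,
    one_way,
    run_psa,
    run_scenario,
    tornado,
)
from mobcea.errors import DomainError
from mobcea.sensitivity import SCENARIO_PRESETS, AcceptabilityCurve, PSAResult
from mobcea.synthetic import GeneratorSpec, random_model_config

CHEMO = "CTX 4 g/m2 + G-CSF ± on-demand PLX"
FREE = "G-CSF ± on-demand PLX"


class TestOneWay:
    def test_varying_a_cost_only_parameter_leaves_effect_unchanged(self, base_config, base_result):
        for bound in ("low", "high"):
            result = one_way(base_config, "sessions_chemo", bound)
            assert result.delta_effect == pytest.approx(base_result.delta_effect)
            assert result.delta_cost != pytest.approx(base_result.delta_cost)

    def test_degenerate_bounds_reproduce_base_case(self, base_config, base_result):
        params = dict(base_config.parameters)
        p = params["sessions_free"]
        params["sessions_free"] = p.model_copy(update={"ci_low": p.mean, "ci_high": p.mean})
        cfg = base_config.model_copy(update={"parameters": params})
        for bound in ("low", "high"):
            result = one_way(cfg, "sessions_free", bound)
            assert result.delta_cost == pytest.approx(base_result.delta_cost)
            assert result.delta_effect == pytest.approx(base_result.delta_effect)

    def test_shared_parameter_moves_both_arms(self, base_config):
        result = one_way(base_config, "e_without_plx", "low")
        lo = base_config.parameters["e_without_plx"].ci_low
        # both mixtures rebuilt from the same lowered parameter
        assert result.effect_treatment == pytest.approx(0.47 * 0.838 + 0.53 * lo)
        assert result.effect_comparator == pytest.approx(0.09 * 0.838 + 0.91 * lo)

    def test_parameter_without_ci_is_rejected(self, base_config):
        with pytest.raises(DomainError, match="uc_fbc"):
            one_way(base_config, "uc_fbc", "low")


class TestTornado:
    def test_bars_sorted_widest_first(self, base_config):
        entries = tornado(base_config)
        widths = []
        for _, group in itertools.groupby(entries, key=lambda e: e.parameter):
            widths.append(max(abs(e.pct_deviation) for e in group))
        assert widths == sorted(widths, reverse=True)

    def test_ordering_matches_brute_force_on_synthetic_config(self):
        cfg = random_model_config(GeneratorSpec(seed=5, n_cost_items=(2, 3)))
        entries = tornado(cfg)
        base, _ = evaluate_config(cfg)
        widths = {}
        for name, p in cfg.parameters.items():
            if not p.has_ci or p.ci_low == p.ci_high:
                continue
            devs = []
            for bound in ("low", "high"):
                r = one_way(cfg, name, bound)
                if r.icer_ratio is not None and base.icer_ratio:
                    devs.append(abs(100 * (r.icer_ratio - base.icer_ratio) / abs(base.icer_ratio)))
            widths[name] = max(devs) if devs else float("inf")
        expected_order = sorted(widths, key=lambda k: (-widths[k], k))
        got_order = list(dict.fromkeys(e.parameter for e in entries))
        assert got_order == expected_order

    def test_cost_only_parameters_never_move_delta_effect(self, base_config, base_result):
        for e in tornado(base_config):
            if e.parameter in ("sessions_free", "missed_chemo", "fn_days", "rbc_units"):
                result = one_way(base_config, e.parameter, e.bound)
                assert result.delta_effect == pytest.approx(base_result.delta_effect)


class TestScenarios:
    def test_same_effectiveness_is_weakly_dominant(self, base_config):
        r = run_scenario(base_config, "same_effectiveness")
        assert r.delta_effect == 0.0
        assert r.icer == "weakly_dominant"
        assert r.delta_cost == pytest.approx(-1198.59, abs=0.02)

    def test_reversed_effectiveness_icer(self, base_config):
        r = run_scenario(base_config, "reversed_effectiveness")
        assert r.icer == pytest.approx(23_049.81, abs=0.5)

    def test_ctx_day_hospital_uses_published_totals(self, base_config):
        r = run_scenario(base_config, "ctx_day_hospital")
        assert r.cost_comparator == 8438.32
        assert r.cost_treatment == 8708.42
        assert r.icer == pytest.approx(5226.29, rel=1e-3)

    def test_outpatient_apheresis_increment(self, base_config):
        r = run_scenario(base_config, "outpatient_apheresis_chemo")
        assert r.delta_cost == pytest.approx(-1102.41, abs=0.02)
        assert r.icer == "strongly_dominant"

    def test_remaining_presets_keep_strong_dominance(self, base_config):
        for name in ("reversed_neutropenia_setting", "cvc_for_chemo_free"):
            assert run_scenario(base_config, name).icer == "strongly_dominant"

    def test_unknown_preset_lists_the_alternatives(self, base_config):
        with pytest.raises(DomainError, match="same_effectiveness"):
            run_scenario(base_config, "no_such_scenario")


class TestPSA:
    def test_degenerate_distributions_reduce_to_base_case(self, base_config):
        params = {
            name: p.model_copy(update={"dist": "fixed"})
            for name, p in base_config.parameters.items()
        }
        cfg = base_config.model_copy(update={"parameters": params})
        psa = run_psa(cfg, n=1, seed=0)
        assert psa.delta_cost[0] == pytest.approx(-1198.59, abs=0.02)
        assert psa.delta_effect[0] == pytest.approx(0.05168, abs=1e-9)

    def test_reproducible_given_n_and_seed(self, base_config):
        a = run_psa(base_config, n=500, seed=7)
        b = run_psa(base_config, n=500, seed=7)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_effect, b.delta_effect)
        c = run_psa(base_config, n=500, seed=8)
        assert not np.array_equal(a.delta_cost, c.delta_cost)

    def test_adding_a_parameter_does_not_perturb_other_streams(self, base_config):
        from mobcea.synthetic import perturb

        a = run_psa(base_config, n=200, seed=3)
        b = run_psa(perturb(base_config, "add_common_item", 50.0), n=200, seed=3)
        assert np.array_equal(a.delta_effect, b.delta_effect)
        assert np.allclose(a.delta_cost, b.delta_cost)  # fixed item cancels in the increment

    def test_quadrant_shares_partition_the_draws(self, base_config):
        psa = run_psa(base_config, n=2_000, seed=1)
        counts = {q: int(round(s * psa.n)) for q, s in psa.quadrant_shares.items()}
        assert sum(counts.values()) == psa.n

    def test_parameter_means_recovered(self, base_config):
        psa = run_psa(base_config, n=10_000, seed=2)
        for name, p in base_config.parameters.items():
            draws = psa.parameter_draws[name]
            if np.ptp(draws) == 0:  # fixed parameter: a point mass at the mean
                assert draws[0] == p.mean
            else:
                se = draws.std() / np.sqrt(psa.n)
                assert abs(draws.mean() - p.mean) < 3 * se, name

    def test_zero_iterations_rejected(self, base_config):
        with pytest.raises(DomainError):
            run_psa(base_config, n=0, seed=0)


class TestCEAC:
    def _toy_psa(self, pairs):
        dc = np.array([p[0] for p in pairs], dtype=float)
        de = np.array([p[1] for p in pairs], dtype=float)
        from mobcea.sensitivity import _classify_quadrants

        return PSAResult(n=len(pairs), seed=0, delta_cost=dc, delta_effect=de,
                         quadrant=_classify_quadrants(dc, de))

    def test_lambda_zero_counts_cost_savings(self):
        psa = self._toy_psa([(-1, 0.1), (1, 0.1), (-2, -0.1)])
        curve = ceac(psa, [0.0])
        assert curve.p_treatment[0] == pytest.approx(2 / 3)
        assert curve.p_comparator[0] == pytest.approx(1 / 3)

    def test_large_lambda_counts_effect_gains(self):
        psa = self._toy_psa([(-1, 0.1), (1, 0.1), (-2, -0.1), (3, -0.2)])
        curve = ceac(psa, [1e12])
        assert curve.p_treatment[0] == pytest.approx(0.5)

    def test_probabilities_complementary_on_fixture(self, base_config):
        psa = run_psa(base_config, n=2_000, seed=4)
        curve = ceac(psa, default_lambda_grid())
        assert np.allclose(curve.p_treatment + curve.p_comparator, 1.0)
        assert np.all((curve.p_treatment >= 0) & (curve.p_treatment <= 1))

    def test_empty_grid_rejected(self, base_config):
        psa = run_psa(base_config, n=10, seed=0)
        with pytest.raises(DomainError):
            ceac(psa, [])


class TestCEAF:
    def test_fixture_frontier_prefers_treatment_from_zero(self, base_config):
        psa = run_psa(base_config, n=2_000, seed=5)
        assert psa.mean_delta_cost < 0 and psa.mean_delta_effect > 0
        curve = ceac(psa, default_lambda_grid())
        frontier = ceaf(curve, psa)
        assert frontier.treatment_optimal_from == 0.0
        assert set(frontier.strategy) == {"treatment"}
        assert np.array_equal(frontier.probability, curve.p_treatment)

    def test_switch_point_at_mean_ratio_for_costly_effective_treatment(self):
        dc = np.array([100.0, 120.0])
        de = np.array([0.01, 0.015])
        from mobcea.sensitivity import _classify_quadrants

        psa = PSAResult(n=2, seed=0, delta_cost=dc, delta_effect=de,
                        quadrant=_classify_quadrants(dc, de))
        lam_star = psa.mean_delta_cost / psa.mean_delta_effect  # 8800
        grid = np.arange(0.0, 20_001.0, 100.0)
        frontier = ceaf(ceac(psa, grid), psa)
        expected = grid[grid > lam_star][0]  # strict inequality: ties to comparator
        assert frontier.treatment_optimal_from == expected

    def test_single_iteration_frontier_follows_that_draw(self, base_config):
        psa = run_psa(base_config, n=1, seed=9)
        curve = ceac(psa, [0.0])
        frontier = ceaf(curve, psa)
        expected = "treatment" if psa.delta_cost[0] < 0 else "comparator"
        assert frontier.strategy[0] == expected
        assert frontier.probability[0] == 1.0

    def test_mismatched_runs_rejected(self, base_config):
        psa = run_psa(base_config, n=50, seed=0)
        other = run_psa(base_config, n=50, seed=1)
        curve = ceac(psa, [0.0, 1000.0])
        with pytest.raises(DomainError, match="run"):
            ceaf(curve, other)


def test_default_lambda_grid_contains_quoted_thresholds():
    grid = default_lambda_grid()
    for anchor in (0.0, 25_000.0, 40_000.0):
        assert anchor in grid
    assert np.all(np.diff(grid) > 0)
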