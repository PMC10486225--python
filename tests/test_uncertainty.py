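"""PSA sampling, Monte Carlo summaries, scenarios and threshold searches."""

import numpy as np
import pandas as pd
import pytest

from aftercare_cea import (
    ParameterDraw,
    apply_overrides,
    ceac_curve,
    evaluate_model,
    run_psa,
    run_scenarios,
    sample_parameters,
    scenario_config,
    threshold_search,
)

from conftest import make_single_stratum_config


def _all_point_config(base_config):
    """Config with every distribution collapsed to its point value."""
    data = base_config.model_dump(mode="python", exclude_none=True)
    for group, keys in (
        ("effect", ["odds_ratio"]),
        (
            "costs",
            [
                "intervention_unit_cost",
                "healthcare_cost_per_selfharm_episode",
                "suicide_death_cost",
                "vsl",
            ],
        ),
        ("utilities", ["u_no_selfharm", "u_selfharm"]),
    ):
        for key in keys:
            node = data[group][key]
            data[group][key] = {"kind": "point", "point_value": node["point_value"]}
    return type(base_config).model_validate(data)


class TestSampleParameters:
    def test_all_point_distributions_return_the_point_set(self, base_config):
        cfg = _all_point_config(base_config)
        draw = sample_parameters(cfg, np.random.default_rng(0))
        point = ParameterDraw.point(cfg)
        assert draw.odds_ratio == point.odds_ratio
        assert draw.unit_cost == point.unit_cost
        assert draw.suicide_death_cost == point.suicide_death_cost
        # the joint utility rule re-derives u_no from the sampled u_selfharm
        assert draw.u_selfharm == point.u_selfharm
        assert draw.u_no_selfharm == pytest.approx(point.u_selfharm + 0.1)

    def test_utility_gap_and_cost_bounds_hold_in_every_draw(self, base_config):
        rng = np.random.default_rng(7)
        for _ in range(500):
            d = sample_parameters(base_config, rng)
            assert d.u_no_selfharm - d.u_selfharm == pytest.approx(0.1, abs=1e-12)
            assert 0.0 <= d.u_selfharm <= d.u_no_selfharm <= 1.0
            assert 615 * 0.8 <= d.unit_cost <= 615 * 1.2

    def test_same_stream_reproduces_the_draw(self, base_config):
        d1 = sample_parameters(base_config, np.random.default_rng(42))
        d2 = sample_parameters(base_config, np.random.default_rng(42))
        assert d1.odds_ratio == d2.odds_ratio
        assert d1.unit_cost == d2.unit_cost
        assert d1.u_selfharm == d2.u_selfharm

    def test_or_quantile_recovery_at_modest_n(self, base_config):
        rng = np.random.default_rng(11)
        draws = base_config.effect.odds_ratio.sample(rng, size=20_000)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(0.55, abs=0.02)
        assert hi == pytest.approx(0.87, abs=0.02)


class TestRunPsa:
    def test_degenerate_distributions_collapse_to_the_base_case(self, base_config):
        cfg = _all_point_config(base_config)
        # align the deterministic utilities with the constrained sampling rule
        cfg.utilities.u_no_selfharm.point_value = 0.64
        cfg.utilities.u_selfharm.point_value = 0.54
        psa = run_psa(cfg, seed=3, iterations=20)
        det = evaluate_model(cfg)
        assert np.allclose(psa.iterations["delta_cost"], det.net_cost)
        assert np.allclose(psa.iterations["delta_qaly"], det.incremental_qalys)
        s = psa.summaries["delta_qaly"]
        assert s["ui_low"] == pytest.approx(s["ui_high"]) == pytest.approx(s["mean"])

    def test_same_seed_is_bitwise_identical(self, base_config):
        a = run_psa(base_config, seed=5, iterations=40)
        b = run_psa(base_config, seed=5, iterations=40)
        pd.testing.assert_frame_equal(a.iterations, b.iterations)
        assert a.summaries == b.summaries

    def test_iteration_count_honoured(self, base_config):
        assert run_psa(base_config, seed=1, iterations=25).n_iterations == 25

    def test_first_iterations_stable_under_extension(self, base_config):
        """Child streams: iteration i is the same whatever the total count."""
        short = run_psa(base_config, seed=9, iterations=10)
        longer = run_psa(base_config, seed=9, iterations=20)
        pd.testing.assert_frame_equal(short.iterations, longer.iterations.iloc[:10])

    def test_deterministic_base_case_inside_every_interval(self, base_config):
        psa = run_psa(base_config, seed=13, iterations=400)
        det = evaluate_model(base_config)
        checks = {
            "intervention_cost": det.intervention_cost,
            "total_savings": det.total_savings,
            "delta_cost": det.net_cost,
            "delta_qaly": det.incremental_qalys,
            "roi": det.roi,
            "nmb": det.nmb,
        }
        for col, value in checks.items():
            s = psa.summaries[col]
            assert s["ui_low"] <= value <= s["ui_high"], col

    def test_probability_cost_effective_is_an_nmb_recount(self, base_config):
        psa = run_psa(base_config, seed=2, iterations=200)
        recount = float((psa.iterations["nmb"] > 0).mean())
        assert psa.probability_cost_effective == recount
        assert 0.0 <= psa.probability_cost_effective <= 1.0

    def test_percentiles_are_order_statistics_of_the_records(self, base_config):
        psa = run_psa(base_config, seed=4, iterations=150)
        for col, s in psa.summaries.items():
            if col == "icer":
                continue
            vals = psa.iterations[col].to_numpy()
            assert s["ui_low"] == pytest.approx(np.percentile(vals, 2.5))
            assert s["ui_high"] == pytest.approx(np.percentile(vals, 97.5))


class TestCeac:
    def test_wtp_zero_counts_strict_cost_savers(self, base_config):
        psa = run_psa(base_config, seed=6, iterations=120)
        curve = ceac_curve(psa, [0.0])
        expected = float((psa.iterations["delta_cost"] < 0).mean())
        assert curve["probability_cost_effective"].iloc[0] == expected

    def test_huge_wtp_counts_positive_qaly_gains(self, base_config):
        psa = run_psa(base_config, seed=6, iterations=120)
        curve = ceac_curve(psa, [1e12])
        expected = float((psa.iterations["delta_qaly"] > 0).mean())
        assert curve["probability_cost_effective"].iloc[0] == expected

    def test_recount_oracle_on_a_grid(self, base_config):
        psa = run_psa(base_config, seed=6, iterations=120)
        grid = [0, 10_000, 50_000, 100_000]
        curve = ceac_curve(psa, grid)
        dq = psa.iterations["delta_qaly"].to_numpy()
        dc = psa.iterations["delta_cost"].to_numpy()
        for w, p in zip(grid, curve["probability_cost_effective"]):
            brute = sum(1 for q, c in zip(dq, dc) if w * q - c > 0) / len(dq)
            assert p == pytest.approx(brute)

    def test_non_decreasing_when_all_qaly_gains_positive(self, base_config):
        psa = run_psa(base_config, seed=6, iterations=120)
        if (psa.iterations["delta_qaly"] >= 0).all():
            grid = np.linspace(0, 200_000, 21)
            probs = ceac_curve(psa, grid)["probability_cost_effective"].to_numpy()
            assert np.all(np.diff(probs) >= 0)

    def test_empty_grid_rejected(self, base_config):
        psa = run_psa(base_config, seed=6, iterations=10)
        with pytest.raises(ValueError):
            ceac_curve(psa, [])


class TestScenarios:
    def test_table_has_base_case_plus_five_scenarios(self, base_config):
        table = run_scenarios(base_config)
        assert len(table) == 6
        assert table["scenario"].iloc[0] == "base_case"

    def test_cost_scenarios_bracket_base_roi(self, base_config):
        table = run_scenarios(base_config).set_index("scenario")
        assert (
            table.loc["cost_minus_20pct", "roi"]
            > table.loc["base_case", "roi"]
            > table.loc["cost_plus_20pct", "roi"]
        )

    def test_vsl_valuation_raises_roi(self, base_config):
        table = run_scenarios(base_config).set_index("scenario")
        assert table.loc["vsl_valuation", "roi"] > table.loc["base_case", "roi"]

    def test_one_year_effect_lowers_qaly_gain(self, base_config):
        table = run_scenarios(base_config).set_index("scenario")
        assert (
            table.loc["one_year_effect", "incremental_qalys"]
            < table.loc["base_case", "incremental_qalys"]
        )

    def test_population_norm_utility_raises_qaly_gain(self, base_config):
        table = run_scenarios(base_config).set_index("scenario")
        assert (
            table.loc["population_norm_utility", "incremental_qalys"]
            > table.loc["base_case", "incremental_qalys"]
        )

    def test_unknown_scenario_rejected(self, base_config):
        with pytest.raises(KeyError):
            scenario_config(base_config, "does_not_exist")

    def test_unknown_override_path_rejected(self, base_config):
        with pytest.raises(KeyError, match="unknown parameter path"):
            apply_overrides(base_config, {"costs.not_a_field": 1})

    def test_override_multiplier_syntax(self, base_config):
        cfg = apply_overrides(
            base_config, {"costs.intervention_unit_cost.point_value": "*0.8"}
        )
        assert cfg.costs.intervention_unit_cost.point_value == pytest.approx(615 * 0.8)


class TestThresholdSearch:
    def test_fixed_point_net_cost_zero(self, base_config):
        res = threshold_search(base_config, "net_cost_zero")
        assert res.bracketed
        redo = evaluate_model(
            base_config,
            ParameterDraw.point(base_config).with_odds_ratio(res.odds_ratio_star),
        )
        assert abs(redo.net_cost - 0.0) <= res.tolerance
        assert res.achieved_metric == pytest.approx(redo.net_cost)

    def test_fixed_point_icer_at_wtp(self, base_config):
        res = threshold_search(base_config, "icer_at_wtp")
        assert res.bracketed
        redo = evaluate_model(
            base_config,
            ParameterDraw.point(base_config).with_odds_ratio(res.odds_ratio_star),
        )
        achieved_icer = redo.net_cost / redo.incremental_qalys
        assert abs(achieved_icer - 50_000) <= res.tolerance

    def test_cost_saving_binds_before_cost_effectiveness(self, base_config):
        """The OR that ends cost-saving is below the OR that ends
        cost-effectiveness, mirroring the published 0.80 < 0.88 ordering."""
        or_save = threshold_search(base_config, "net_cost_zero").odds_ratio_star
        or_ce = threshold_search(base_config, "icer_at_wtp").odds_ratio_star
        assert or_save < or_ce

    def test_bisection_matches_fine_grid_scan(self, base_config):
        """Coarse-grid oracle here; the 0.001-step scan runs in acceptance."""
        res = threshold_search(base_config, "net_cost_zero", tol=1e-6)
        point = ParameterDraw.point(base_config)
        grid = np.arange(0.01, 1.0, 0.01)
        net = [
            evaluate_model(base_config, point.with_odds_ratio(o)).net_cost for o in grid
        ]
        crossing = grid[int(np.searchsorted(np.sign(net), 0.5))]
        assert abs(res.odds_ratio_star - crossing) <= 0.01

    def test_unbracketed_target_flags_no_solution(self, base_config):
        cfg = base_config.model_copy(deep=True)
        # with negligible cost offsets the intervention can never be cost-saving
        cfg.costs.healthcare_cost_per_selfharm_episode.point_value = 0.01
        cfg.costs.suicide_death_cost.point_value = 0.01
        res = threshold_search(cfg, "net_cost_zero")
        assert not res.bracketed
        assert np.isnan(res.odds_ratio_star)

    def test_lowering_or_strictly_lowers_net_cost_and_icer(self, base_config):
        point = ParameterDraw.point(base_config)
        results = [
            evaluate_model(base_config, point.with_odds_ratio(o))
            for o in (0.95, 0.97, 0.99)
        ]
        net = [r.net_cost for r in results]
        icers = [r.net_cost / r.incremental_qalys for r in results]
        assert net == sorted(net)
        assert icers == sorted(icers)
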