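"""Scenario orchestration: replication, pairing, aggregation, gaps."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from upfsim import (
    PolicyScenario,
    PopulationConfig,
    RunResult,
    ScenarioConfig,
    equity_report,
    run_replicate,
    run_scenario,
    scenario_grid,
)


def test_single_replicate_equals_run_replicate(small_scenario):
    cfg = dataclasses.replace(small_scenario, n_replicates=1)
    result = run_scenario(cfg)
    child = np.random.SeedSequence(cfg.master_seed).spawn(1)[0]
    rep = run_replicate(cfg, child)
    np.testing.assert_array_equal(result.population_mean, rep["population_mean"])


def test_paired_seed_prepolicy_identity(small_scenario):
    """Scenarios differing only in policy share pre-policy trajectories."""
    taxed = dataclasses.replace(
        small_scenario,
        policy=dataclasses.replace(small_scenario.policy, tax_rate=0.20),
    )
    r0 = run_scenario(small_scenario)
    r1 = run_scenario(taxed)
    act = small_scenario.policy.activation_step
    np.testing.assert_array_equal(
        r0.population_mean[:act], r1.population_mean[:act]
    )
    assert not np.allclose(r0.population_mean[act:], r1.population_mean[act:])


def test_no_policy_equilibrium_stability(small_scenario):
    result = run_scenario(small_scenario)
    act = small_scenario.policy.activation_step
    final = small_scenario.total_steps
    assert abs(result.mean_at(final) / result.mean_at(act) - 1.0) < 0.01


def test_tax_reduction_matches_price_factor(small_scenario):
    """Post-policy level settles at the analytic price factor of the tax."""
    taxed = dataclasses.replace(
        small_scenario,
        policy=dataclasses.replace(small_scenario.policy, tax_rate=0.20),
    )
    result = run_scenario(taxed)
    act = taxed.policy.activation_step
    assert result.mean_at(taxed.total_steps) == pytest.approx(
        0.76 * result.mean_at(act), rel=0.01
    )


def test_flat_trajectory_without_dynamics_or_policy(small_scenario):
    frozen = dataclasses.replace(
        small_scenario,
        dynamics=dataclasses.replace(small_scenario.dynamics, conformity_resistance=0.0),
        n_replicates=1,
    )
    result = run_scenario(frozen)
    assert np.ptp(result.population_mean) == pytest.approx(0.0)


def test_scenario_grid_cardinality_pairing_and_monotonicity(small_scenario):
    results = scenario_grid(small_scenario, [0.0, 0.08, 0.20], [False, True], [0.0])
    assert len(results) == 6
    null = results["none"]
    act = small_scenario.policy.activation_step
    spread = null.replicate_spread[-1] / np.sqrt(small_scenario.n_replicates)
    assert abs(null.mean_at(small_scenario.total_steps) - null.mean_at(act)) \
        <= max(2 * spread, 1e-9) + 1e-6 * null.mean_at(act)
    for label in (False, True):
        reductions = [
            results[PolicyScenario(tax_rate=t, label_active=label).name].reduction_pct()
            for t in (0.0, 0.08, 0.20)
        ]
        assert reductions == sorted(reductions)


def test_scenario_grid_rejects_duplicates_and_empty(small_scenario):
    with pytest.raises(ValueError):
        scenario_grid(small_scenario, [0.08, 0.08], [False], [0.0])
    with pytest.raises(ValueError):
        scenario_grid(small_scenario, [], [False], [0.0])


def test_stratum_means_reconstruct_population_mean(small_scenario):
    """Pooled stratum means weighted by pooled sizes give the population
    mean at every recorded step, for income and education alike."""
    result = run_scenario(small_scenario)
    n_total = result.income_counts.sum()
    for frame, counts in (
        (result.income_means, result.income_counts),
        (result.education_means, result.education_counts),
    ):
        weighted = (
            frame["low"].to_numpy() * counts[0] + frame["high"].to_numpy() * counts[1]
        ) / n_total
        np.testing.assert_allclose(weighted, result.population_mean, atol=1e-6)


def test_replicate_spread_scales_inverse_sqrt():
    """The spread of R-replicate scenario means shrinks like 1/sqrt(R)."""
    cfg = ScenarioConfig(
        population=PopulationConfig(n_agents=150),
        policy=PolicyScenario(activation_step=20),
        burn_in_steps=20,
        total_steps=60,
        n_replicates=384,
        master_seed=11,
    )
    finals = run_scenario(cfg).replicate_population_means[:, -1]

    def group_sd(R):
        groups = finals[: (len(finals) // R) * R].reshape(-1, R).mean(axis=1)
        return groups.std(ddof=1)

    ratio = group_sd(4) / group_sd(16)
    assert 1.4 < ratio < 2.8  # expected 2 under 1/sqrt(R) scaling


def test_full_determinism(small_scenario):
    r1 = run_scenario(small_scenario)
    r2 = run_scenario(small_scenario)
    np.testing.assert_array_equal(r1.population_mean, r2.population_mean)
    pd.testing.assert_frame_equal(r1.income_means, r2.income_means)
    pd.testing.assert_frame_equal(r1.to_frame(), r2.to_frame())


def _fabricated_result(low, high, name="synthetic"):
    """Minimal RunResult with constant stratum means (synthetic stand-in)."""
    steps = np.arange(1, 61)
    pop_mean = np.full(60, (low + high) / 2)
    frame = pd.DataFrame({"low": np.full(60, low), "high": np.full(60, high)},
                         index=steps)
    cfg = ScenarioConfig(
        population=PopulationConfig(n_agents=100),
        policy=PolicyScenario(activation_step=52),
        burn_in_steps=0, total_steps=60, n_replicates=1, master_seed=0,
    )
    return RunResult(
        scenario_name=name, config=cfg, steps=steps,
        population_mean=pop_mean, replicate_spread=np.zeros(60),
        replicate_population_means=pop_mean[None, :],
        income_means=frame, education_means=frame,
        income_counts=np.array([50.0, 50.0]), education_counts=np.array([50.0, 50.0]),
    )


def test_equity_report_gap_definitions():
    """Worked gap example: 3000 vs 2862 gives 138 kcal and 4.6 % of 3000."""
    identical = _fabricated_result(2900.0, 2900.0)
    worked = _fabricated_result(3000.0, 2862.0)
    table = equity_report(identical, worked, step=60)
    assert table.loc["pre_transition", "gap_absolute"] == pytest.approx(0.0)
    assert table.loc["pre_transition", "gap_relative_pct"] == pytest.approx(0.0)
    assert table.loc["post_transition", "gap_absolute"] == pytest.approx(138.0)
    assert table.loc["post_transition", "gap_relative_pct"] == pytest.approx(4.6)
    with pytest.raises(ValueError):
        equity_report(identical, worked, step=200)


def test_gap_matches_bruteforce_from_export(small_scenario):
    """Gap statistics agree with recomputation from the tidy export."""
    result = run_scenario(small_scenario)
    df = result.to_frame()
    step = small_scenario.total_steps
    row = df.loc[df["step"] == step].iloc[0]
    expected_abs = abs(row["income_low_mean"] - row["income_high_mean"])
    expected_rel = 100 * expected_abs / max(row["income_low_mean"],
                                            row["income_high_mean"])
    assert result.gap_absolute(step) == pytest.approx(expected_abs)
    assert result.gap_relative(step) == pytest.approx(expected_rel)


def test_config_validation():
    with pytest.raises(ValueError):
        ScenarioConfig(policy=PolicyScenario(activation_step=300), total_steps=208)
    with pytest.raises(ValueError):
        ScenarioConfig(n_replicates=0)
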