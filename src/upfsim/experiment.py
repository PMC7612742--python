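"""Scenario orchestration: burn-in, policy activation, replication, summaries.

A scenario run regenerates the population and network for every replicate
(replicate-level structural variation), burns in 100 weeks of social
dynamics off the reporting clock, then records weeks 1..208.  The policy
is applied once, immediately after the dynamics of its activation week
(week 52 by default), so the recorded week-52 mean is the pre-policy
level.  Replicate seeds are spawned deterministically from the master
seed, which makes paired-seed comparisons exact: two scenarios that
differ only in policy share identical pre-policy trajectories.

Stratum trajectories are pooled over replicates (total kcal divided by
total agents in the stratum), so stratum means weighted by pooled stratum
sizes reconstruct the pooled population mean exactly at every step.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import DynamicsConfig, step_population
from .network import NetworkConfig, build_network
from .policy import EffectParameters, PolicyScenario, apply_policy
from .population import Education, IncomeCategory, PopulationConfig, generate_population

__all__ = [
    "ScenarioConfig",
    "RunResult",
    "run_replicate",
    "run_scenario",
    "scenario_grid",
    "equity_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulation experiment."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    effects: EffectParameters = field(default_factory=EffectParameters)
    policy: PolicyScenario = field(default_factory=PolicyScenario)
    burn_in_steps: int = 100
    total_steps: int = 208
    n_replicates: int = 200
    master_seed: int = 0

    def __post_init__(self):
        if self.burn_in_steps < 0:
            raise ValueError("burn_in_steps must be non-negative")
        if self.total_steps < 1:
            raise ValueError("total_steps must be positive")
        if not self.policy.activation_step < self.total_steps:
            raise ValueError("policy.activation_step must be below total_steps")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


def run_replicate(config: ScenarioConfig, replicate_seed) -> dict:
    """Run one replicate and return its per-step trajectories.

    ``replicate_seed`` may be an integer or a ``numpy.random.SeedSequence``;
    separate child streams drive population and network generation.
    Returned arrays are indexed by reporting week 1..total_steps.
    """
    ss = (
        replicate_seed
        if isinstance(replicate_seed, np.random.SeedSequence)
        else np.random.SeedSequence(replicate_seed)
    )
    pop_seed, net_seed = ss.spawn(2)
    population = generate_population(config.population, pop_seed)
    network = build_network(population, config.network, net_seed)

    for _ in range(config.burn_in_steps):
        step_population(population, network, config.dynamics)

    T = config.total_steps
    pop_mean = np.empty(T)
    income_mean = np.full((len(IncomeCategory), T), np.nan)
    edu_mean = np.full((len(Education), T), np.nan)
    inc_labels = population.income_cat.astype(int)
    edu_labels = population.education.astype(int)
    income_counts = np.bincount(inc_labels, minlength=len(IncomeCategory))
    edu_counts = np.bincount(edu_labels, minlength=len(Education))

    for t in range(1, T + 1):
        step_population(population, network, config.dynamics)
        x = population.upf_kcal_week
        pop_mean[t - 1] = x.mean()
        income_mean[:, t - 1] = population.group_means(inc_labels, len(IncomeCategory))
        edu_mean[:, t - 1] = population.group_means(edu_labels, len(Education))
        if t == config.policy.activation_step:
            apply_policy(population, config.policy, config.effects)

    if not np.all(np.isfinite(pop_mean)):
        raise FloatingPointError("non-finite simulation output")
    return {
        "population_mean": pop_mean,
        "income_mean": income_mean,
        "education_mean": edu_mean,
        "income_counts": income_counts,
        "education_counts": edu_counts,
    }


@dataclass
class RunResult:
    """Replicate-aggregated trajectories and summary statistics.

    ``income_means`` / ``education_means`` hold pooled stratum means
    (columns ``low``/``high``), indexed by reporting week.  The relative
    income gap uses the larger stratum mean as the denominator.
    """

    scenario_name: str
    config: ScenarioConfig
    steps: np.ndarray
    population_mean: np.ndarray
    replicate_spread: np.ndarray
    replicate_population_means: np.ndarray  # (n_replicates, total_steps)
    income_means: pd.DataFrame
    education_means: pd.DataFrame
    income_counts: np.ndarray
    education_counts: np.ndarray

    def _step_index(self, step: int) -> int:
        if not 1 <= step <= len(self.steps):
            raise ValueError(f"step {step} outside 1..{len(self.steps)}")
        return step - 1

    def mean_at(self, step: int) -> float:
        return float(self.population_mean[self._step_index(step)])

    def reduction_pct(self, from_step: int | None = None, to_step: int | None = None) -> float:
        """Percent change in mean purchasing, positive for a reduction."""
        from_step = from_step or self.config.policy.activation_step
        to_step = to_step or len(self.steps)
        m0, m1 = self.mean_at(from_step), self.mean_at(to_step)
        return 100.0 * (m0 - m1) / m0

    def gap_absolute(self, step: int) -> float:
        i = self._step_index(step)
        row = self.income_means.iloc[i]
        return float(abs(row["low"] - row["high"]))

    def gap_relative(self, step: int) -> float:
        i = self._step_index(step)
        row = self.income_means.iloc[i]
        larger = max(row["low"], row["high"])
        return 100.0 * abs(row["low"] - row["high"]) / larger

    def summary(self) -> dict:
        act = self.config.policy.activation_step
        final = int(self.steps[-1])
        return {
            "scenario": self.scenario_name,
            "n_replicates": self.config.n_replicates,
            "mean_pre_policy": self.mean_at(act),
            "mean_final": self.mean_at(final),
            "reduction_pct": self.reduction_pct(),
            "gap_absolute_pre_policy": self.gap_absolute(act),
            "gap_absolute_final": self.gap_absolute(final),
            "gap_relative_pre_policy": self.gap_relative(act),
            "gap_relative_final": self.gap_relative(final),
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-step table: population and stratum means plus spread."""
        df = pd.DataFrame(
            {
                "scenario": self.scenario_name,
                "step": self.steps,
                "population_mean": self.population_mean,
                "replicate_sd": self.replicate_spread,
                "income_low_mean": self.income_means["low"].to_numpy(),
                "income_high_mean": self.income_means["high"].to_numpy(),
                "education_low_mean": self.education_means["low"].to_numpy(),
                "education_high_mean": self.education_means["high"].to_numpy(),
            }
        )
        return df


def run_scenario(config: ScenarioConfig) -> RunResult:
    """Run all replicates of a scenario and aggregate.

    Any replicate failure aborts with the offending replicate seed in the
    exception message.
    """
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(config.n_replicates)
    T = config.total_steps
    rep_means = np.empty((config.n_replicates, T))
    inc_kcal = np.zeros((len(IncomeCategory), T))
    edu_kcal = np.zeros((len(Education), T))
    inc_total = np.zeros(len(IncomeCategory))
    edu_total = np.zeros(len(Education))

    for r, child in enumerate(children):
        try:
            rep = run_replicate(config, child)
        except Exception as exc:  # identify the failing replicate
            raise RuntimeError(
                f"replicate {r} (seed {child.entropy}, key {child.spawn_key}) failed"
            ) from exc
        rep_means[r] = rep["population_mean"]
        ic = rep["income_counts"].astype(float)
        ec = rep["education_counts"].astype(float)
        inc_kcal += np.nan_to_num(rep["income_mean"]) * ic[:, None]
        edu_kcal += np.nan_to_num(rep["education_mean"]) * ec[:, None]
        inc_total += ic
        edu_total += ec

    with np.errstate(invalid="ignore"):
        income_means = inc_kcal / inc_total[:, None]
        education_means = edu_kcal / edu_total[:, None]
    steps = np.arange(1, T + 1)
    spread = rep_means.std(axis=0, ddof=1) if config.n_replicates > 1 else np.zeros(T)
    result = RunResult(
        scenario_name=config.policy.name,
        config=config,
        steps=steps,
        population_mean=rep_means.mean(axis=0),
        replicate_spread=spread,
        replicate_population_means=rep_means,
        income_means=pd.DataFrame(
            {"low": income_means[int(IncomeCategory.LOW)],
             "high": income_means[int(IncomeCategory.HIGH)]},
            index=steps,
        ),
        education_means=pd.DataFrame(
            {"low": education_means[int(Education.LOW)],
             "high": education_means[int(Education.HIGH)]},
            index=steps,
        ),
        income_counts=inc_total,
        education_counts=edu_total,
    )
    logger.info(
        "scenario %s: %d replicates, seed %d, %.1f s, reduction %.2f%%",
        result.scenario_name, config.n_replicates, config.master_seed,
        time.perf_counter() - t0, result.reduction_pct(),
    )
    return result


def scenario_grid(
    base_config: ScenarioConfig,
    taxes,
    label_options,
    advertising_levels,
) -> dict[str, RunResult]:
    """Run the cartesian product of policy options with a shared master seed.

    Sharing the master seed makes grid cells paired: their pre-policy
    trajectories are identical, so differences after the activation step
    are pure policy effects.
    """
    taxes = list(taxes)
    label_options = list(label_options)
    advertising_levels = list(advertising_levels)
    if not (taxes and label_options and advertising_levels):
        raise ValueError("option lists must be non-empty")
    results: dict[str, RunResult] = {}
    for tax in taxes:
        for label in label_options:
            for adv in advertising_levels:
                policy = replace(
                    base_config.policy,
                    tax_rate=tax,
                    label_active=label,
                    advertising_change=adv,
                )
                if policy.name in results:
                    raise ValueError(f"duplicate scenario name {policy.name!r}")
                cfg = replace(base_config, policy=policy)
                results[policy.name] = run_scenario(cfg)
    return results


def equity_report(
    result_pre: RunResult, result_post: RunResult, step: int
) -> pd.DataFrame:
    """Income-strata gap table at ``step`` for both transition scenarios.

    Rows are the pre- and post-transition runs; columns give the absolute
    (kcal/week) and relative (% of the larger stratum mean) gaps at the
    requested step, the same gaps at the pre-policy step, and the changes.
    """
    rows = {}
    for label, res in (("pre_transition", result_pre), ("post_transition", result_post)):
        act = res.config.policy.activation_step
        gap_abs = res.gap_absolute(step)
        gap_rel = res.gap_relative(step)
        base_abs = res.gap_absolute(act)
        base_rel = res.gap_relative(act)
        rows[label] = {
            "gap_absolute": gap_abs,
            "gap_relative_pct": gap_rel,
            "gap_absolute_pre_policy": base_abs,
            "gap_relative_pre_policy_pct": base_rel,
            "change_absolute": gap_abs - base_abs,
            "change_relative_pct": gap_rel - base_rel,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
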