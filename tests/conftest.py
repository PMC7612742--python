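"""Shared fixtures: small populations, graphs and scaled-down configs."""
from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pytest

from upfsim import (
    DynamicsConfig,
    NetworkConfig,
    PolicyScenario,
    Population,
    PopulationConfig,
    ScenarioConfig,
    SocialNetwork,
    generate_population,
)


def single_stratum_config(n: int, baseline: float = 3000.0) -> PopulationConfig:
    """All agents middle-aged, low-education, low-income: one norms stratum."""
    return PopulationConfig(
        n_agents=n,
        age_proportions=(0.0, 1.0, 0.0),
        p_high_education=0.0,
        income_threshold=1e9,
        baseline_mean_by_income={"low": baseline, "high": baseline},
    )


def manual_population(upf_values, config: PopulationConfig) -> Population:
    """Population with prescribed purchasing values in one stratum."""
    n = len(upf_values)
    return Population(
        age_group=np.ones(n, dtype=int),
        education=np.zeros(n, dtype=int),
        income_continuous=np.full(n, 500.0),
        income_category=np.zeros(n, dtype=int),
        upf_kcal_week=np.asarray(upf_values, dtype=float),
        config=config,
    )


def wrap_graph(graph: nx.Graph, **config_kwargs) -> SocialNetwork:
    defaults = dict(target_mean_degree=3.0, min_degree=1, max_degree=100)
    defaults.update(config_kwargs)
    return SocialNetwork(graph, NetworkConfig(**defaults))


@pytest.fixture
def pop_1000():
    return generate_population(PopulationConfig(), seed=42)


@pytest.fixture
def small_scenario():
    """Scaled-down scenario config for fast experiment tests."""
    return ScenarioConfig(
        population=PopulationConfig(n_agents=250),
        policy=PolicyScenario(activation_step=40),
        burn_in_steps=30,
        total_steps=80,
        n_replicates=4,
        master_seed=7,
    )


def replace(config, **kwargs):
    return dataclasses.replace(config, **kwargs)
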