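"""Config-file serialisation and named scenario presets.

A scenario is specified as one YAML (or JSON) document with sections
mirroring :class:`~upfsim.experiment.ScenarioConfig`:

.. code-block:: yaml

    population:
      n_agents: 1000
      scenario: pre_transition
    network:
      homophily_weight: 6.0
    dynamics: {}
    effects: {}
    policy:
      tax_rate: 0.20
      label_active: true
    burn_in_steps: 100
    total_steps: 208
    n_replicates: 200
    master_seed: 7

Omitted keys take the study defaults.  Presets cover every policy cell of
the reported grid: taxes 0/8/20/50 % x label on/off x advertising change
-50/-25/0/+25/+50 %.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .dynamics import DynamicsConfig
from .experiment import ScenarioConfig
from .network import NetworkConfig
from .policy import EffectParameters, PolicyScenario
from .population import IncomeCategory, PopulationConfig

__all__ = [
    "PRESET_TAXES",
    "PRESET_ADVERTISING",
    "preset_policies",
    "base_config",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
]

PRESET_TAXES = (0.0, 0.08, 0.20, 0.50)
PRESET_ADVERTISING = (-0.50, -0.25, 0.0, 0.25, 0.50)


def preset_policies(activation_step: int = 52) -> dict[str, PolicyScenario]:
    """All reported policy combinations, keyed by scenario name."""
    presets = {}
    for tax in PRESET_TAXES:
        for label in (False, True):
            for adv in PRESET_ADVERTISING:
                policy = PolicyScenario(
                    tax_rate=tax,
                    label_active=label,
                    advertising_change=adv,
                    activation_step=activation_step,
                )
                presets[policy.name] = policy
    return presets


def base_config(transition: str = "pre_transition", **overrides) -> ScenarioConfig:
    """Study-default scenario config for one transition stage."""
    population = overrides.pop("population", PopulationConfig(scenario=transition))
    return ScenarioConfig(population=population, **overrides)


def config_to_dict(config: ScenarioConfig) -> dict:
    pop = dataclasses.asdict(config.population)
    pop["baseline_mean_by_income"] = {
        cat.label: value for cat, value in config.population.baseline_mean_by_income.items()
    }
    return {
        "population": pop,
        "network": dataclasses.asdict(config.network),
        "dynamics": dataclasses.asdict(config.dynamics),
        "effects": dataclasses.asdict(config.effects),
        "policy": dataclasses.asdict(config.policy),
        "burn_in_steps": config.burn_in_steps,
        "total_steps": config.total_steps,
        "n_replicates": config.n_replicates,
        "master_seed": config.master_seed,
    }


def config_from_dict(data: dict) -> ScenarioConfig:
    data = dict(data)
    pop = dict(data.pop("population", {}))
    if "age_proportions" in pop:
        pop["age_proportions"] = tuple(pop["age_proportions"])
    for key in ("income_low_ed", "income_high_ed"):
        if key in pop:
            pop[key] = tuple(pop[key])
    if pop.get("baseline_mean_by_income"):
        pop["baseline_mean_by_income"] = {
            IncomeCategory[k.upper()]: float(v)
            for k, v in pop["baseline_mean_by_income"].items()
        }
    return ScenarioConfig(
        population=PopulationConfig(**pop),
        network=NetworkConfig(**data.pop("network", {})),
        dynamics=DynamicsConfig(**data.pop("dynamics", {})),
        effects=EffectParameters(**data.pop("effects", {})),
        policy=PolicyScenario(**data.pop("policy", {})),
        **data,
    )


def load_config(path) -> ScenarioConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(data or {})


def save_config(config: ScenarioConfig, path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
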