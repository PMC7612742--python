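"""Tax, labelling and advertising policy effects on UPF purchasing.

Each policy instrument maps to a multiplicative factor on an agent's
weekly purchasing:

* **tax** — a linear own-price elasticity response,
  ``1 + price_elasticity * tax_rate`` (elasticity −1.2: a 20 % tax gives
  factor 0.76, a 50 % tax gives 0.40);
* **front-of-package warning label** — an education-stratified level
  shift, −22 % for low-education and −29 % for high-education agents
  (factors 0.78 and 0.71) while a label policy is active;
* **advertising** — ``1 + advertising_elasticity * change`` with
  elasticity 0.113 (a ±50 % change in advertising gives 1.0565 / 0.9435).

Multiple instruments compose multiplicatively by default (an ``additive``
mode, ``1 + sum of individual effects``, is kept for sensitivity
analysis).  Policies act as a one-time level shift applied at their
activation step; social dynamics then continue on the shifted values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import Education, Population

__all__ = [
    "PolicyScenario",
    "EffectParameters",
    "price_factor",
    "label_factor",
    "advertising_factor",
    "combined_factor",
    "apply_policy",
]


@dataclass(frozen=True)
class PolicyScenario:
    """A (tax, label, advertising-change) triple with an activation week."""

    tax_rate: float = 0.0
    label_active: bool = False
    advertising_change: float = 0.0
    activation_step: int = 52

    def __post_init__(self):
        if self.tax_rate < 0:
            raise ValueError("tax_rate must be non-negative")
        if not -1.0 <= self.advertising_change <= 1.0:
            raise ValueError("advertising_change must lie in [-1, 1]")
        if self.activation_step < 1:
            raise ValueError("activation_step must be a positive week index")

    @property
    def is_null(self) -> bool:
        return (
            self.tax_rate == 0.0
            and not self.label_active
            and self.advertising_change == 0.0
        )

    @property
    def name(self) -> str:
        parts = []
        if self.tax_rate > 0:
            parts.append(f"tax{self.tax_rate * 100:g}")
        if self.label_active:
            parts.append("label")
        if self.advertising_change != 0:
            parts.append(f"adv{self.advertising_change * 100:+g}")
        return "_".join(parts) if parts else "none"


@dataclass(frozen=True)
class EffectParameters:
    """Externally sourced policy effect sizes.

    ``composition`` selects how simultaneous instruments combine:
    ``"multiplicative"`` (default) multiplies the per-instrument factors;
    ``"additive"`` sums the individual proportional effects.
    """

    price_elasticity: float = -1.2
    label_effect_low_education: float = -0.22
    label_effect_high_education: float = -0.29
    advertising_elasticity: float = 0.113
    composition: str = "multiplicative"

    def __post_init__(self):
        if self.price_elasticity >= 0:
            raise ValueError("price_elasticity must be negative")
        for eff in (self.label_effect_low_education, self.label_effect_high_education):
            if not -1.0 < eff <= 0.0:
                raise ValueError("label effects must lie in (-1, 0]")
        if self.advertising_elasticity < 0:
            raise ValueError("advertising_elasticity must be non-negative")
        if self.composition not in ("multiplicative", "additive"):
            raise ValueError("composition must be 'multiplicative' or 'additive'")

    def label_effect(self, education: Education) -> float:
        if education == Education.LOW:
            return self.label_effect_low_education
        if education == Education.HIGH:
            return self.label_effect_high_education
        raise ValueError(f"unknown education level {education!r}")


def price_factor(tax_rate: float, params: EffectParameters) -> float:
    """Purchasing multiplier of a price increase of ``tax_rate`` (linear elasticity)."""
    if tax_rate < 0:
        raise ValueError("tax_rate must be non-negative")
    factor = 1.0 + params.price_elasticity * tax_rate
    if factor <= 0:
        raise ValueError(
            f"tax_rate {tax_rate} drives the price factor non-positive "
            f"(limit {-1.0 / params.price_elasticity:.4f})"
        )
    return factor


def label_factor(education, label_active: bool, params: EffectParameters) -> float:
    """Purchasing multiplier of a warning-label policy for one education level."""
    education = Education(education) if not isinstance(education, Education) else education
    if not label_active:
        # still validates the education level
        params.label_effect(education)
        return 1.0
    return 1.0 + params.label_effect(education)


def advertising_factor(advertising_change: float, params: EffectParameters) -> float:
    """Purchasing multiplier of a proportional change in advertising exposure."""
    factor = 1.0 + params.advertising_elasticity * advertising_change
    if factor <= 0:
        raise ValueError("advertising_change drives the factor non-positive")
    return factor


def combined_factor(agent, scenario: PolicyScenario, params: EffectParameters) -> float:
    """Joint purchasing multiplier of all instruments in a scenario.

    Multiplicative composition (default) is the product of the component
    factors; additive composition is one plus the sum of the individual
    proportional effects, floored just above zero.
    """
    factors = (
        price_factor(scenario.tax_rate, params),
        label_factor(agent.education, scenario.label_active, params),
        advertising_factor(scenario.advertising_change, params),
    )
    if params.composition == "multiplicative":
        out = factors[0] * factors[1] * factors[2]
    else:
        out = 1.0 + sum(f - 1.0 for f in factors)
        out = max(out, 1e-12)
    return float(out)


def _factor_vector(population: Population, scenario: PolicyScenario,
                   params: EffectParameters) -> np.ndarray:
    """Per-agent combined factors, vectorised over education."""
    base = np.empty(len(population))
    for level in Education:
        f_label = label_factor(level, scenario.label_active, params)
        f_price = price_factor(scenario.tax_rate, params)
        f_adv = advertising_factor(scenario.advertising_change, params)
        if params.composition == "multiplicative":
            f = f_price * f_label * f_adv
        else:
            f = max(1.0 + (f_price - 1.0) + (f_label - 1.0) + (f_adv - 1.0), 1e-12)
        base[population.education == int(level)] = f
    return base


def apply_policy(
    population: Population, scenario: PolicyScenario, params: EffectParameters
) -> Population:
    """Apply a scenario's one-time level shift to every agent, in place.

    Raises if the same scenario has already been applied to this
    population (the shift must happen exactly once, at the activation
    step).
    """
    key = (scenario.tax_rate, scenario.label_active,
           scenario.advertising_change, scenario.activation_step)
    if key in population._applied_policies:
        raise RuntimeError(f"policy scenario {scenario.name!r} already applied")
    population._applied_policies.add(key)
    if scenario.is_null:
        return population
    population.upf_kcal_week[:] = population.upf_kcal_week * _factor_vector(
        population, scenario, params
    )
    return population
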