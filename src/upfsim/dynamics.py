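"""Weekly social-influence updates to UPF purchasing.

Each time step (one week) an agent makes two adjustments, in order:

* **social signal** — toward the mean purchasing of her direct network
  neighbours, representing peer influence between friends;
* **social norms** — toward the mean purchasing of all agents sharing her
  age group, income category and education, representing group-level norms.

Each adjustment is gated by a perception threshold (default 50 kcal/week,
representing uncertainty about friends' true purchasing): a difference at
or below the threshold produces no change, a larger difference moves the
agent a fraction (default 10 %) of the way toward the reference.
``conformity_resistance`` multiplies that fraction and is a calibrated
knob; 1.0 recovers the literal 10 % rule.

Updates are synchronous: both references are computed from the
start-of-step snapshot of purchasing values, and every agent is updated
before the next step begins, making the result independent of agent
iteration order.  The signal sub-update is applied first; the norms
sub-update then moves the post-signal value toward the snapshot stratum
mean.  Purchasing is floored at zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SocialNetwork
from .population import N_STRATA, Population

__all__ = ["DynamicsConfig", "signal_adjustment", "step_population"]


@dataclass(frozen=True)
class DynamicsConfig:
    """Parameters of the weekly adjustment rule.

    perception_threshold : kcal/week below which differences are ignored.
    adjustment_fraction : fraction of the perceived difference closed per
        sub-update (0.10 in the study configuration).
    conformity_resistance : calibrated multiplier on the fraction, in
        [0, 1]; values below 1 slow conformity.
    """

    perception_threshold: float = 50.0
    adjustment_fraction: float = 0.10
    conformity_resistance: float = 1.0

    def __post_init__(self):
        if self.perception_threshold < 0:
            raise ValueError("perception_threshold must be non-negative")
        if not 0.0 < self.adjustment_fraction <= 1.0:
            raise ValueError("adjustment_fraction must lie in (0, 1]")
        if not 0.0 <= self.conformity_resistance <= 1.0:
            raise ValueError("conformity_resistance must lie in [0, 1]")

    @property
    def step_fraction(self) -> float:
        return self.adjustment_fraction * self.conformity_resistance


def signal_adjustment(own: float, reference: float, config: DynamicsConfig) -> float:
    """One threshold-gated partial adjustment of ``own`` toward ``reference``.

    Returns ``own`` unchanged when ``|own - reference|`` is at or below the
    perception threshold, otherwise
    ``own + adjustment_fraction * conformity_resistance * (reference - own)``,
    floored at zero.  The same rule serves both the social-signal and the
    social-norms sub-update.
    """
    if own < 0 or reference < 0:
        raise ValueError("purchasing values must be non-negative")
    if abs(own - reference) <= config.perception_threshold:
        return float(own)
    return float(max(own + config.step_fraction * (reference - own), 0.0))


def _vector_adjust(x: np.ndarray, ref: np.ndarray, config: DynamicsConfig) -> np.ndarray:
    delta = ref - x
    move = np.where(np.abs(delta) > config.perception_threshold,
                    config.step_fraction * delta, 0.0)
    return np.maximum(x + move, 0.0)


def step_population(
    population: Population, network: SocialNetwork, config: DynamicsConfig
) -> Population:
    """Advance the population one week in place and return it.

    Both sub-updates use the start-of-step snapshot for their references;
    the norms sub-update is applied to the post-signal values.
    """
    if network.n_nodes != len(population):
        raise ValueError("network does not cover the population")
    x0 = population.upf_kcal_week.copy()

    neighbor_mean = network.adjacency_csr() @ x0 / network.degrees
    x1 = _vector_adjust(x0, neighbor_mean, config)

    codes = population.stratum_codes
    counts = population.stratum_counts.astype(float)
    sums = np.bincount(codes, weights=x0, minlength=N_STRATA)
    with np.errstate(invalid="ignore"):
        stratum_mean = sums / counts
    x2 = _vector_adjust(x1, stratum_mean[codes], config)

    population.upf_kcal_week[:] = x2
    return population
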