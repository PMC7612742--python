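"""Synthetic population of adult female household food purchasers.

The simulated population mirrors the socio-demographic structure of adult
women who act as the primary food purchaser in Mexican households: a
three-way age split (one quarter younger, one half middle-aged, one quarter
older), a 27 % share with at least a high-school education, and
education-specific log-normal household income distributions (natural-scale
mean/SD of 889/911 pesos per week for the low-education group and 2044/2225
for the high-education group).  Agents above an income threshold of 1890
pesos per week form the high-income category.

Each agent carries one behavioural state variable: her weekly
ultra-processed-food (UPF) purchasing in kcal/week.  It is initialised from
income-group means that differ between two baseline scenarios representing
stages of the "social transition" in UPF purchasing:

``pre_transition``
    purchasing is highest among high-income households (Mexico-like);
    group means 3446 (high income) and 2966 (low income) kcal/week.
``post_transition``
    purchasing is highest among low-income households (Chile-like);
    group means 2620 (high income) and 3100 (low income) kcal/week.

Categorical attribute counts are allocated deterministically by
largest-remainder rounding, so a 1000-agent population always contains
exactly 270 high-education, 250 younger, 500 middle-aged and 250 older
agents; only the pairing of attributes, incomes and purchasing draws vary
with the seed.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AgeGroup",
    "Education",
    "IncomeCategory",
    "Agent",
    "PopulationConfig",
    "Population",
    "N_STRATA",
    "generate_population",
    "income_category",
    "stratum_means",
    "lognormal_params",
    "largest_remainder_counts",
]


class AgeGroup(enum.IntEnum):
    """Qualitative life-stage categories (roughly 20-30, 31-50, >50 years)."""

    YOUNGER = 0
    MIDDLE = 1
    OLDER = 2

    @property
    def label(self) -> str:
        return self.name.lower()


class Education(enum.IntEnum):
    """Educational attainment: below high school (LOW) or at least high school (HIGH)."""

    LOW = 0
    HIGH = 1

    @property
    def label(self) -> str:
        return self.name.lower()


class IncomeCategory(enum.IntEnum):
    """Household income category relative to the threshold."""

    LOW = 0
    HIGH = 1

    @property
    def label(self) -> str:
        return self.name.lower()


#: number of (age x income x education) strata used for social norms
N_STRATA = len(AgeGroup) * len(IncomeCategory) * len(Education)

_SCENARIOS = ("pre_transition", "post_transition")

_BASELINE_MEANS = {
    "pre_transition": {IncomeCategory.HIGH: 3446.0, IncomeCategory.LOW: 2966.0},
    "post_transition": {IncomeCategory.HIGH: 2620.0, IncomeCategory.LOW: 3100.0},
}


def largest_remainder_counts(n: int, proportions) -> np.ndarray:
    """Allocate ``n`` units to categories by largest-remainder rounding.

    Guarantees the counts sum to ``n`` exactly and are within one unit of
    ``n * p`` for every category, independent of any random seed.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    quota = p * n
    counts = np.floor(quota).astype(int)
    shortfall = n - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:shortfall]] += 1
    return counts


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Convert a natural-scale (mean, sd) pair to log-normal ``(mu, sigma)``.

    Uses the standard moment inversion ``sigma^2 = ln(1 + (sd/mean)^2)``,
    ``mu = ln(mean) - sigma^2 / 2``, so the analytic mean and SD of the
    resulting log-normal reproduce the inputs exactly.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be strictly positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def income_category(income: float, threshold: float) -> IncomeCategory:
    """Classify a weekly income as LOW or HIGH relative to ``threshold``.

    The boundary convention is strict: an income exactly at the threshold
    is classified LOW ("above a threshold value" read literally).
    """
    if income <= 0:
        raise ValueError("income must be strictly positive")
    if threshold <= 0:
        raise ValueError("threshold must be strictly positive")
    return IncomeCategory.HIGH if income > threshold else IncomeCategory.LOW


@dataclass(frozen=True)
class Agent:
    """Immutable per-agent view: one household food purchaser.

    ``upf_kcal_week`` is a snapshot of her current weekly UPF purchasing;
    the mutable state lives in the :class:`Population` arrays.
    """

    id: int
    age_group: AgeGroup
    education: Education
    income_continuous: float
    income_category: IncomeCategory
    upf_kcal_week: float


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the synthetic population.

    Parameters
    ----------
    n_agents : int
        Population size (1000 in the study configuration).
    age_proportions : tuple of float
        Simplex over (younger, middle, older); default (0.25, 0.50, 0.25).
    p_high_education : float
        Share with at least high-school education (default 0.27).
    income_low_ed, income_high_ed : (mean, sd)
        Natural-scale weekly-income moments per education group, pesos/week.
    income_threshold : float
        Incomes strictly above this are high-income (default 1890 pesos/week).
    scenario : str
        ``"pre_transition"`` or ``"post_transition"``; selects the default
        income-group baseline purchasing means.
    baseline_mean_by_income : mapping, optional
        Override of the kcal/week baseline means, keyed by
        :class:`IncomeCategory` (or ``"low"``/``"high"`` strings).
    baseline_dispersion : float
        Coefficient of variation of the initial purchasing draw within each
        income group (log-normal shape; default 0.30).
    """

    n_agents: int = 1000
    age_proportions: tuple[float, float, float] = (0.25, 0.50, 0.25)
    p_high_education: float = 0.27
    income_low_ed: tuple[float, float] = (889.0, 911.0)
    income_high_ed: tuple[float, float] = (2044.0, 2225.0)
    income_threshold: float = 1890.0
    scenario: str = "pre_transition"
    baseline_mean_by_income: Mapping | None = None
    baseline_dispersion: float = 0.30

    def __post_init__(self):
        if self.n_agents <= 0:
            raise ValueError("n_agents must be positive")
        props = tuple(float(p) for p in self.age_proportions)
        if len(props) != 3 or any(p < 0 for p in props):
            raise ValueError("age_proportions must be 3 non-negative values")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("age_proportions must sum to 1")
        if not 0.0 <= self.p_high_education <= 1.0:
            raise ValueError("p_high_education must lie in [0, 1]")
        for mean, sd in (self.income_low_ed, self.income_high_ed):
            if mean <= 0 or sd <= 0:
                raise ValueError("income means/sds must be strictly positive")
        if self.income_threshold <= 0:
            raise ValueError("income_threshold must be strictly positive")
        if self.scenario not in _SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {_SCENARIOS}"
            )
        if self.baseline_dispersion <= 0:
            raise ValueError("baseline_dispersion must be strictly positive")
        object.__setattr__(self, "age_proportions", props)
        object.__setattr__(
            self, "baseline_mean_by_income", self._resolve_baseline_means()
        )

    def _resolve_baseline_means(self) -> dict[IncomeCategory, float]:
        raw = self.baseline_mean_by_income
        if raw is None:
            return dict(_BASELINE_MEANS[self.scenario])
        out: dict[IncomeCategory, float] = {}
        for key, value in raw.items():
            cat = key if isinstance(key, IncomeCategory) else IncomeCategory[str(key).upper()]
            value = float(value)
            if value <= 0:
                raise ValueError("baseline purchasing means must be positive")
            out[cat] = value
        if set(out) != set(IncomeCategory):
            raise ValueError("baseline_mean_by_income must cover both income categories")
        return out


def _stratum_codes(age: np.ndarray, inc: np.ndarray, edu: np.ndarray) -> np.ndarray:
    # mixed radix: age (3) x income (2) x education (2) -> 0..11
    return age * (len(IncomeCategory) * len(Education)) + inc * len(Education) + edu


def stratum_label(code: int) -> tuple[AgeGroup, IncomeCategory, Education]:
    """Decode a stratum code into its (age, income, education) tuple."""
    age, rest = divmod(int(code), len(IncomeCategory) * len(Education))
    inc, edu = divmod(rest, len(Education))
    return AgeGroup(age), IncomeCategory(inc), Education(edu)


class Population:
    """Ordered collection of agents backed by flat numpy arrays.

    Demographic arrays are frozen after construction (read-only views);
    only ``upf_kcal_week`` changes as the simulation runs.
    """

    def __init__(
        self,
        *,
        age_group: np.ndarray,
        education: np.ndarray,
        income_continuous: np.ndarray,
        income_category: np.ndarray,
        upf_kcal_week: np.ndarray,
        config: PopulationConfig,
        rng_seed=None,
    ):
        age = np.array(age_group, dtype=np.int8)
        edu = np.array(education, dtype=np.int8)
        inc = np.array(income_continuous, dtype=float)
        cat = np.array(income_category, dtype=np.int8)
        upf = np.array(upf_kcal_week, dtype=float)
        n = len(age)
        if not (len(edu) == len(inc) == len(cat) == len(upf) == n):
            raise ValueError("all agent arrays must have equal length")
        if n != config.n_agents:
            raise ValueError("array length does not match config.n_agents")
        if np.any(upf < 0):
            raise ValueError("upf_kcal_week must be non-negative")
        for arr in (age, edu, inc, cat):
            arr.flags.writeable = False
        self._age = age
        self._edu = edu
        self._income = inc
        self._cat = cat
        self.upf_kcal_week = upf
        self.config = config
        self.rng_seed = rng_seed
        codes = _stratum_codes(age.astype(int), cat.astype(int), edu.astype(int))
        codes.flags.writeable = False
        self._codes = codes
        self._counts = np.bincount(codes, minlength=N_STRATA)
        self._applied_policies: set = set()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._age)

    def __getitem__(self, i: int) -> Agent:
        i = int(i)
        if not 0 <= i < len(self):
            raise IndexError(f"agent id {i} out of range")
        return Agent(
            id=i,
            age_group=AgeGroup(int(self._age[i])),
            education=Education(int(self._edu[i])),
            income_continuous=float(self._income[i]),
            income_category=IncomeCategory(int(self._cat[i])),
            upf_kcal_week=float(self.upf_kcal_week[i]),
        )

    def __iter__(self) -> Iterator[Agent]:
        return (self[i] for i in range(len(self)))

    # -- read-only demographic views ----------------------------------------
    @property
    def age_group(self) -> np.ndarray:
        return self._age

    @property
    def education(self) -> np.ndarray:
        return self._edu

    @property
    def income_continuous(self) -> np.ndarray:
        return self._income

    @property
    def income_cat(self) -> np.ndarray:
        return self._cat

    @property
    def stratum_codes(self) -> np.ndarray:
        """Per-agent code of the (age x income x education) stratum, 0..11."""
        return self._codes

    @property
    def stratum_counts(self) -> np.ndarray:
        return self._counts

    # -- summaries -----------------------------------------------------------
    def mean_purchasing(self) -> float:
        return float(self.upf_kcal_week.mean())

    def group_means(self, labels: np.ndarray, n_groups: int) -> np.ndarray:
        """Mean purchasing per integer-labelled group; NaN for empty groups."""
        counts = np.bincount(labels, minlength=n_groups).astype(float)
        sums = np.bincount(labels, weights=self.upf_kcal_week, minlength=n_groups)
        with np.errstate(invalid="ignore"):
            return sums / counts

    def income_group_means(self) -> dict[IncomeCategory, float]:
        means = self.group_means(self._cat.astype(int), len(IncomeCategory))
        return {c: float(means[c]) for c in IncomeCategory if not np.isnan(means[c])}

    def education_group_means(self) -> dict[Education, float]:
        means = self.group_means(self._edu.astype(int), len(Education))
        return {e: float(means[e]) for e in Education if not np.isnan(means[e])}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "age_group": [AgeGroup(a).label for a in self._age],
                "education": [Education(e).label for e in self._edu],
                "income": self._income,
                "income_category": [IncomeCategory(c).label for c in self._cat],
                "upf_kcal_week": self.upf_kcal_week,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def generate_population(config: PopulationConfig, seed) -> Population:
    """Draw a population with exact category counts and stochastic incomes.

    Age-group and education counts follow largest-remainder rounding of the
    configured proportions (so they are identical across seeds); attribute
    pairings are randomised by independent shuffles.  Incomes come from
    education-specific log-normals parameterised so the natural-scale mean
    and SD equal the configured values; the income category is a strict
    threshold on the draw.  Baseline purchasing is drawn per income group
    from a log-normal with the group mean and CV ``baseline_dispersion``.
    """
    rng = np.random.default_rng(seed)
    n = config.n_agents

    age_counts = largest_remainder_counts(n, config.age_proportions)
    age = np.repeat(np.arange(3, dtype=np.int8), age_counts)
    rng.shuffle(age)

    n_high_ed = largest_remainder_counts(
        n, (1.0 - config.p_high_education, config.p_high_education)
    )[1]
    edu = np.zeros(n, dtype=np.int8)
    edu[:n_high_ed] = 1
    rng.shuffle(edu)

    income = np.empty(n, dtype=float)
    for level, (mean, sd) in (
        (Education.LOW, config.income_low_ed),
        (Education.HIGH, config.income_high_ed),
    ):
        mask = edu == int(level)
        mu, sigma = lognormal_params(mean, sd)
        income[mask] = rng.lognormal(mu, sigma, mask.sum())

    cat = (income > config.income_threshold).astype(np.int8)

    upf = np.empty(n, dtype=float)
    for category, mean in config.baseline_mean_by_income.items():
        mask = cat == int(category)
        mu, sigma = lognormal_params(mean, config.baseline_dispersion * mean)
        upf[mask] = rng.lognormal(mu, sigma, mask.sum())
    upf = np.maximum(upf, 0.0)

    return Population(
        age_group=age,
        education=edu,
        income_continuous=income,
        income_category=cat,
        upf_kcal_week=upf,
        config=config,
        rng_seed=seed,
    )


def stratum_means(population: Population):
    """Mean purchasing per occupied (age, income, education) stratum.

    Empty strata are absent from the returned mapping.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    counts = population.stratum_counts
    sums = np.bincount(
        population.stratum_codes, weights=population.upf_kcal_week, minlength=N_STRATA
    )
    out = {}
    for code in range(N_STRATA):
        if counts[code] > 0:
            out[stratum_label(code)] = float(sums[code] / counts[code])
    return out
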