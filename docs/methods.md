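# Methods

## Model overview

`upfsim` is a discrete-time (weekly) agent-based model of household
ultra-processed-food (UPF) purchasing among adult female primary food
purchasers. The model has three layers:

1. a **synthetic population** with fixed socio-demographics and one
   mutable state variable per agent (weekly UPF purchasing, kcal/week);
2. a **static homophilous small-world friendship network** over which
   social influence flows;
3. **weekly dynamics** (peer signal + group norms) punctuated by a
   one-time **policy shock** (tax, warning label, advertising change).

Scenario runs burn in 100 weeks off the reporting clock, record weeks
1–208, and apply the policy immediately after the week-52 update, so the
recorded week-52 mean is the pre-policy level. Effects are summarised as
the percent change in mean purchasing between weeks 52 and 208 and as
absolute/relative gaps between income strata.

## Population

Age group (25/50/25 %), education (27 % high) and, derived from income,
the income category are fixed at initialisation. Counts are allocated by
**largest-remainder rounding**, not Bernoulli draws: the configured
proportions are treated as exact population structure, which removes a
nuisance source of replicate variance (a 1000-agent population always has
exactly 270 high-education agents). Incomes are log-normal per education
group; the configured natural-scale (mean, SD) pairs are converted
analytically to log-scale (μ, σ) so the distribution's analytic moments
reproduce the inputs exactly. Incomes strictly above 1890 pesos/week are
high income — the boundary itself is low income, a documented (and
testable) reading of "above a threshold".

Baseline purchasing is drawn per income group from a log-normal with the
group's configured mean and a coefficient of variation
`baseline_dispersion` (default 0.30). Only the group means are externally
anchored; the shape and dispersion are this package's choice — purchasing
is non-negative and right-skewed, and a CV of 0.30 gives realistic
within-group heterogeneity without frequent extreme draws. The CV is
exposed in the config because no external source pins it.

## Network

The generator is a degree-constrained homophilous Watts–Strogatz variant:

* agents are ordered on a ring by a noisy one-dimensional embedding of
  their (income, education, age) stratum; the homophily weight *w* scales
  the embedding against unit-variance noise, so *w* = 0 yields a random
  ring and large *w* sorts agents into contiguous stratum blocks;
* each agent connects to her nearest ring neighbours (base degree 4 for
  the default target of 5.47);
* 10 % of lattice edges are rewired, and extra edges are added up to
  exactly `round(n · 5.47 / 2)` edges, with endpoints sampled with
  probability ∝ exp(w · similarity), where similarity is the fraction of
  matching attributes (0, 1/3, 2/3, 1);
* a repair pass guarantees the minimum degree of 3; the maximum of 50 is
  enforced during sampling.

This reproduces the three required features with two parameters: hard
degree bounds, small-world structure (local clustering from the lattice,
short paths from rewired/extra ties) and attribute assortativity that
increases monotonically with *w*. The mean degree is exact by
construction up to rare repair additions. Mean path length is reported
over the largest connected component, since rewiring can in rare cases
disconnect the graph; this is documented rather than hidden. The network
is static after construction (no tie churn).

## Dynamics

Both weekly sub-updates use one rule: if the absolute difference between
the agent's value and the reference exceeds the perception threshold
(default 50 kcal/week — uncertainty about friends' true purchasing), the
agent moves `adjustment_fraction × conformity_resistance` (default
0.10 × 1.0) of the difference toward the reference; otherwise she does
not move. The signal sub-update (reference = neighbour mean) runs first,
then the norms sub-update (reference = stratum mean). Updates are
**synchronous from a start-of-step snapshot**: both references are
computed from the values at the start of the week, and the norms
sub-update is applied to the post-signal value. This makes a step
independent of agent iteration order and exactly reproducible.

`conformity_resistance` is kept separate from the stated 10 % fraction
because the resistance to conforming is a calibrated quantity while the
10 % fraction is stated outright; the default of 1.0 recovers the literal
10 % rule, and the calibration search may select a smaller value. The
50-kcal threshold applies identically to the norms comparison.

Two structural consequences matter for interpretation:

* the norms sub-update preserves each stratum's mean exactly (when all
  members are outside the deadband), so persistent income-group gaps are
  eroded only through cross-group network ties;
* the deadband freezes adjustment below the 50 kcal scale, so "full
  mixing" in the absence of homophily means the income gap collapses to
  roughly the threshold scale (~50 kcal), not to zero.

## Policy operators

Taxes use a **linear (point) elasticity**: factor `1 − 1.2 τ`. The
constant-elasticity power form `(1 + τ)^−1.2` would give 0.615 at τ = 0.5
instead of the 0.40 implied by the reported 60 % reduction. Labels are an
education-stratified shift (−22 % low education, −29 % high education);
advertising uses elasticity 0.113. Simultaneous instruments compose
**multiplicatively** by default: the reported combined outcomes
(72/70/68/31 % reductions) are only consistent with the product of the
per-instrument factors, while a literal additive reading would predict
~88–90 % for the maximal combination. An `additive` composition switch is
retained for sensitivity analysis. The policy is a one-time level shift
at the activation week — re-applying the factors weekly would decay
purchasing toward zero, contradicting the stable post-policy levels the
model is meant to produce. The tax factor is uniform across income; an
income-scaled price-burden variant would require an external mapping from
income to effective UPF price that is not available, and is out of scope.

## Calibration

Free parameters: homophily weight, conformity resistance, and the two
income-group baseline means. Targets: (1) equilibrium no-policy
population mean within 5 kcal of 3033 kcal/week; (2) the configured
income ordering (high > low pre-transition, reversed post-transition) at
every reported week; (3) a persistent gap of at least 25 kcal/week at the
end of the evaluation window ("distributions do not fully converge").

The **equilibrium mean** is defined as the average over the last 26 weeks
of a 52-week no-policy window after burn-in, averaged over replicates —
a tail window smooths Monte-Carlo noise where a single-step read-out
would not. The search is a coarse grid over (homophily weight ∈ {2, 4,
6, 8}) × (conformity resistance ∈ {0.5, 1.0}) with one local refinement
of the weight, preferring candidates that satisfy ordering and
distinctness and, among those, the smallest mean error. Baseline means
are only adjusted — by proportionally rescaling both group means toward
the target — when the stated defaults miss the 5 kcal tolerance under
the selected dynamics; the rescaling converges in one or two iterations
because the equilibrium mean responds almost linearly. Calibration uses
20 replicates per candidate; all replicate seeds derive from the master
seed, so calibration is deterministic given (seed, search grid).

The defaults `homophily_weight = 6.0` and `conformity_resistance = 1.0`
are representative calibrated values; the calibration procedure re-selects
them for the seed at hand. The emergent pre-policy income gap depends on
these calibrated parameters and is treated as a qualitative quantity
(ordering and persistence), not a numeric target.

## Experiments and aggregation

Each replicate regenerates population and network from its own seed
(replicate-level structural variation); dynamics are deterministic given
the initial state, so all randomness lives in initialisation. Replicate
seeds are spawned from the master seed with numpy's `SeedSequence`
splitter, giving independent streams for population and network and exact
**paired-seed comparisons**: two scenarios sharing a master seed have
bit-identical pre-policy trajectories, so post-activation differences are
pure policy effects.

Stratum trajectories are pooled across replicates (total kcal over total
agents), so pooled stratum means weighted by pooled sizes reconstruct the
pooled population mean exactly at every step — replicate-weighted
averaging of per-replicate stratum means would not have this property
when stratum sizes vary across replicates. The relative income gap uses
the larger stratum mean as denominator. Reduction percentages are
reported against the same run's week-52 level; the paired no-policy
scenario provides a robustness comparison and nearly coincides because
the no-policy equilibrium is stable (week-52 and week-208 means differ by
well under 1 %).

## Problem sizes and numerical choices

Default experiments use 1000 agents, 100 + 208 weeks and 200 replicates;
the test suite and the acceptance script use 20–25 replicates (and
smaller populations for pure-mechanics tests), which keeps the replicate
standard error of scenario means far below the reported tolerances while
running in seconds. Replicate spread of the week-208 mean scales as
1/√R, which is verified empirically. Purchasing is floored at zero
(unreachable under the partial-adjustment rule but enforced), degenerate
inputs (empty populations, infeasible degree bounds, confiscatory taxes
driving the price factor non-positive, double policy application) raise
errors rather than produce silent output.

## What the synthetic data does and does not capture

The generator *is* the study input — there is no external dataset. It
reproduces marginal distributions (age, education, income, baseline
purchasing means) and a stylised homophilous friendship topology. It does
not model households with men or children, within-household bargaining,
spatial food access, cross-price substitution, product reformulation, or
tie formation over time. Passing tests therefore demonstrate internal
consistency of the mechanism and fidelity to the configured effect sizes
(elasticities and label effects drawn from evaluation literature), not
predictive accuracy for any real population: policy effect estimates
inherit the assumption that those effect sizes transfer to the simulated
context.

## Known limitations

* The homophily weight and conformity resistance are jointly weakly
  identified by the calibration targets (several (w, c) pairs satisfy
  all three criteria); the search breaks ties by mean error, so the
  selected pair can vary with the seed. Reported policy effects are
  insensitive to the choice because policy factors act multiplicatively
  on a stable equilibrium.
* With the perception deadband active, equilibria are sets (any
  configuration with all agents within the threshold of both references
  is absorbing), so the equilibrium reached depends on initial draws;
  tail-window averaging over replicates absorbs this.
* The advertising operator treats a change in advertising as an
  instantaneous exposure shift across the whole population; no
  heterogeneity in media exposure is modelled.
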