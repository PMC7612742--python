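# upfsim

An agent-based simulator of weekly household purchasing of
ultra-processed foods (UPF) under tax, front-of-package warning-label and
advertising policies, with social-network influence and health-equity
stratified outcomes.

## The problem

Latin American countries have led the world in UPF policy — Mexico's 8 %
junk-food tax, Chile's warning-label law, advertising restrictions — but
the equity impact of a policy depends on *who* currently purchases the
most UPF. As national income rises, peak UPF consumption shifts from
high- to low-socio-economic-status households (the "social transition").
`upfsim` is a policy laboratory for comparing policy combinations on both
sides of that transition: it simulates 1000 adult female household food
purchasers, embedded in a homophilous small-world friendship network,
each adjusting her weekly UPF purchasing (kcal/week) in response to
friends, group norms and policy shocks.

## The model

Each agent *i* has fixed age group (25/50/25 % younger/middle/older),
education (27 % high), and a log-normal weekly income (mean/SD 889/911
pesos for low education, 2044/2225 for high; incomes above 1890 pesos are
"high income"). Her state is weekly UPF purchasing x_i (kcal/week),
initialised per income group: pre-transition 3446 (high) / 2966 (low),
post-transition 2620 / 3100.

Every week, with snapshot values x:

1. **social signal** — if |x_i − mean of network neighbours| > 50 kcal,
   x_i moves 10 % of the way toward the neighbour mean;
2. **social norms** — the same rule against the mean of all agents with
   her (age × income × education) profile.

The friendship graph is a degree-constrained homophilous Watts–Strogatz
variant: mean degree 5.47, every degree in [3, 50], ties preferentially
formed between agents with matching attributes
(P ∝ exp(w · similarity), with the homophily weight w calibrated).

Policies act once, at week 52 of a 208-week run (after a 100-week
burn-in), as multiplicative level shifts:

| instrument | factor |
|---|---|
| tax at rate τ | 1 − 1.2 τ (own-price elasticity −1.2) |
| warning label | 0.78 (low education) / 0.71 (high education) |
| advertising change a | 1 + 0.113 a (advertising elasticity 0.113) |

Combined policies multiply their factors. The free parameters (homophily
weight, conformity resistance, income-group baseline means) are
calibrated so the no-policy equilibrium population mean is 3033 ± 5
kcal/week with a persistent income-group gap.

## Worked example

```bash
$ upfsim run --preset tax20 --replicates 25 --seed 1 --outdir out
tax20: pre-policy 3034 -> final 2306 kcal/week (24.0% reduction)

$ upfsim run --preset tax50_label_adv-50 --replicates 25 --seed 1 --outdir out
tax50_label_adv-50: pre-policy 3034 -> final 871 kcal/week (71.3% reduction)
```

A 20 % tax cuts mean purchasing from the calibrated 3034 kcal/week
equilibrium to 2306 kcal/week — a 24 % reduction, the full own-price
response at elasticity −1.2. The maximal combination (50 % tax + labels +
halved advertising) removes 71.3 %. Each run writes a tidy per-week CSV
(population and income/education stratum means, replicate SD) and a JSON
summary including the absolute and relative income-strata gaps, e.g. for
`tax20` the pre-policy gap of 360 kcal/week (10.8 % of the high-income
mean) is preserved in relative terms post-tax:

```json
{
  "scenario": "tax20",
  "mean_pre_policy": 3034.26,
  "mean_final": 2306.04,
  "reduction_pct": 24.0,
  "gap_relative_pre_policy": 10.81,
  "gap_relative_final": 10.81
}
```

The same library surface is available in Python
(`upfsim.run_scenario`, `upfsim.scenario_grid`, `upfsim.calibrate`,
`upfsim.equity_report`), and `upfsim calibrate | grid | report` cover
calibration, paired-seed policy grids and equity gap tables.

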