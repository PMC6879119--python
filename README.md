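# pwidsim

Dynamic compartmental modelling of injection drug use (IDU) initiation as a
behavioural transmission process, and of the population-level impact of
scaling up opioid agonist treatment (OAT) among people who inject drugs
(PWID).

The package provides:

- **`pwidsim.params`** — the full sampling-distribution table for all model
  inputs (demography, overdose mortality, drug-use transitions, OAT effect
  sizes, calibration targets) and seeded Monte Carlo parameter-set sampling.
- **`pwidsim.dynamics`** — a seven-compartment ODE system (non-users, naive
  drug users, four PWID strata crossed by assisting-history × OAT
  enrollment, former PWID) with a prevalence-proportional assisted-initiation
  force, excess overdose death at OAT entry/exit, and trajectory integration
  with exact cumulative event-flux accounting.
- **`pwidsim.calibration`** — joint root-solving of the initiation
  coefficient, drug-use cessation rate, unassisted-initiation count and OAT
  enrollment rate so each sampled set's equilibrium hits its four targets
  (non-IDU prevalence, PWID prevalence, self-initiated share, OAT coverage).
- **`pwidsim.scenarios`** — baseline and 40/50/60% OAT-coverage scale-up
  projections over a decade, with per-set relative reductions and
  2.5–97.5% uncertainty intervals.
- **`pwidsim.sensitivity`** — partial rank correlation coefficients (PRCC)
  and the nine preset one-way analyses with common random numbers.
- **`pwidsim.effects`** — modified Poisson regression (Poisson GLM, log
  link, robust sandwich variance) for adjusted relative risks of a binary
  outcome, and REML random-effects meta-analysis of site-level log-RRs,
  including the shipped printed site-level estimates.
- **`pwidsim.cohort`** — synthetic three-city cohorts reproducing the
  published site marginals with user-specified true relative risks, used to
  validate the regression/pooling stack by parameter recovery.
- **`pwidsim.pipeline`** — end-to-end orchestration with YAML config,
  stage-seeded reproducibility and a JSON manifest.

## Command line

```bash
# sample, calibrate and project scale-up scenarios
pwidsim simulate --n-sets 1000 --seed 7 --coverages 0.4 0.5 0.6 --out results/

# PRCC of the year-10 initiation reduction from a finished run
pwidsim prcc results/

# the nine one-way sensitivity presets (or a single one)
pwidsim oneway --n-sets 1000 --seed 7 --preset all --out results/

# REML pooling of the shipped site-level relative risks
pwidsim pool

# synthetic three-city cohort records
pwidsim synth --seed 0 --out cohort.csv
```

`simulate` writes `parameter_sets.csv`, `scenario_per_set.csv`,
`scenario_summary.csv`, `pooled_effects.csv`, optionally `prcc.csv` /
`oneway.csv`, and a `manifest.json` recording seeds, convergence counts and
table hashes; re-running the same configuration reproduces every table
bitwise.

## Modelling notes

- Entrants replace all non-overdose deaths, so the population declines only
  through overdose and OAT-transition excess deaths (~0.01%/year at the
  calibrated baseline). Equilibria are therefore *stationary-composition*
  states (derivative parallel to the state); with the default
  population-tracking unassisted-initiation count they are exact invariants
  of the flow.
- Scale-up solves the enrollment rate against the new equilibrium coverage
  (sustained coverage) and applies it as a step at time zero.
- Relative reductions are computed per parameter set against that set's own
  baseline run, then averaged.
- One-way deviations are normalised by the modified analysis's impact by
  default (`normalize="baseline"` switches the denominator).
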