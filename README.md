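# lungcea

A Markov cohort cost-effectiveness model comparing first-line
nivolumab-ipilimumab combination therapy against platinum-doublet
chemotherapy in advanced non-small cell lung cancer.

The model tracks a cohort through four health states — stable disease on
first-line treatment, stable disease on second-line treatment, progressed
disease, and death — on a 1-month cycle over a 10-year horizon. Per-cycle
transition probabilities are derived from digitized overall-survival (OS) and
progression-free-survival (PFS) curves via a cause-specific hazard split;
beyond the trial follow-up window (42 months) curves are extended either by
disease-specific annual conditional survival (base case) or by
general-population life-table mortality (cure assumption). Costs (2020 USD)
and QALYs are discounted at 3%/year.

Analyses provided:

- **Base case** — discounted cost/QALYs per arm, incremental
  cost-effectiveness ratio (ICER, reported raw and rounded to the nearest
  $100), net monetary benefit at a $100 000/QALY willingness-to-pay threshold;
  healthcare or societal perspective.
- **One-way deterministic sensitivity analysis** — every parameter varied over
  its printed 95% CI (else ±20% of the mean), tornado output; plus an OS
  hazard-ratio analysis that regenerates the intervention OS curve from the
  comparator curve by proportional hazards.
- **Threshold searches** — bisection on the monthly combination drug price
  ($1 tolerance) and on the maximum treatment duration (fractional months,
  prorated final-cycle drug cost).
- **Scenario analyses** — societal perspective, cure extrapolation,
  immunotherapy continued past progression, maintenance pemetrexed, and
  biomarker-subgroup curve sets.
- **Probabilistic sensitivity analysis** — gamma-distributed costs,
  beta-distributed utilities and transition probabilities (one beta-derived
  hazard multiplier per curve per replicate), with cost-effectiveness
  acceptability curves. Unknown SDs follow the 20%-of-mean rule.
- **Synthetic data** — piecewise-exponential two-arm OS/PFS curves with exact
  medians and proportional hazards (default OS HR 0.73), a life table, a
  conditional-survival table, and the full base-case parameter fixture, so the
  entire pipeline runs without external data.

## Command-line usage

```bash
# generate a complete synthetic input bundle
lungcea synth --out bundle --seed 1

# deterministic base case (traces + JSON summary)
lungcea run --config bundle/config.yaml --out results/run

# one-way DSA tornado
lungcea dsa --config bundle/config.yaml --out results/dsa

# threshold searches
lungcea threshold --config bundle/config.yaml --out results/thr --variable monthly_price
lungcea threshold --config bundle/config.yaml --out results/thr --variable max_duration

# named scenarios (incl. subgroup curve sets in the bundle)
lungcea scenarios --config bundle/config.yaml --out results/scn

# probabilistic sensitivity analysis + CEAC
lungcea psa --config bundle/config.yaml --out results/psa --reps 1000 --seed 1
```

Every command writes a `manifest.json` (config hash, input digests, seed,
package version) alongside its outputs; identical inputs and seed give
identical outputs.

## Input formats

- **Survival curves**: headered two-column delimited text `(month, survival)`;
  non-integer months are interpolated log-linearly onto the monthly grid.
- **Life table**: `(age, annual_death_probability)`; **conditional survival**:
  `(year, annual_conditional_survival)`.
- **Parameters**: YAML with one `{name, mean, sd?, ci95?, kind}` entry per
  table row; missing SDs are imputed as 20% of the mean.
- **Run config**: YAML wiring the files together plus run settings (horizon,
  discount rate, perspective, WTP, extrapolation mode) and per-arm strategy
  blocks (treatment-duration cap, second-line uptake, scenario flags).

## Validation design

- The cohort trace reproduces the input OS curve to 1e-9 per cycle by
  construction (marginal-OS death hazard in every alive state).
- The cohort engine is cross-checked against an independent seeded
  individual-level microsimulation (1e5 patients) within 3 Monte Carlo
  standard errors.
- Threshold searches are self-consistent (re-running the model at the returned
  value reproduces the target WTP) and checked against a $1-resolution grid
  scan on a toy model.
- Distribution parameterizations round-trip their (mean, SD) analytically and
  empirically on 1e5 seeded draws.
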