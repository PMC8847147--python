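# phenosel

Phenotypic selection on vegetative and reproductive phenology in a
perennial herb, as a tested, reusable pipeline:

1. **Synthetic data** (`phenosel.simulate`) — individual-level leaf-out and
   first-flowering dates (bivariate normal with configurable correlation),
   ln-normal plant size, zero-inflated negative-binomial seed counts driven
   by a known linear/quadratic/correlational selection surface, plus an
   observation layer: discrete census visits with sequential leaflet
   unfolding and bud growth, shoot measurements, and per-fruit seed-predator
   entry holes. Every downstream stage is testable against known truth.
2. **Phenology estimation** (`phenosel.phenology`) — continuous leaf-out
   and first-flowering days from interval-censored census observations via
   an empirical-percentile mapping (quadratic unfolding model for leaf-out,
   bud size for flowering), grazed-plant imputation models, development
   time, and the cylinder aboveground-volume size measure.
3. **Fitness** (`phenosel.fitness`) — intact (undamaged) developed seeds
   per individual; opened pods use the exponential saturation model
   `1 - exp(-1.218 * holes_per_seed)` for the preyed-upon share.
4. **Selection inference** (`phenosel.selection`) — Lande–Arnold models:
   trait standardization and fitness relativization under a local
   (within-year) or global (across-years) scheme; total selection
   differentials (with plant size as covariate), direct gradients,
   development-time selection, correlational and quadratic models; squared
   terms reported doubled (gamma scale); VIF diagnostics; Pearson trait
   correlations; and the direct-vs-total comparison rule for flagging
   indirect selection.
5. **BCa bootstrap** (`phenosel.bootstrap`) — case-resampling bootstrap
   with bias-corrected and accelerated intervals built from first
   principles (mid-rank bias correction, jackknife acceleration, type-7
   quantiles), with a vectorised fast path for regression coefficients.
6. **CLI and reporting** (`phenosel.cli`, `phenosel.pipeline`,
   `phenosel.report`) — a config-driven end-to-end runner producing
   selection tables for all model families × years × both schemes, a
   grouped report table, comparison flags, correlation tables, plottable
   CSVs and a run manifest. Identical config + seed ⇒ byte-identical CSVs.

## CLI

```bash
# synthetic dataset (census/shoots/fruits/truth CSVs + config file)
phenosel simulate --n 200 --seed 1 --out runs/sim

# stage by stage
phenosel estimate-phenology --census runs/sim/census.csv --shoots runs/sim/shoots.csv --out runs/seasons.csv
phenosel fitness --fruits runs/sim/fruits.csv --seasons runs/seasons.csv --out runs/seasons_fit.csv
phenosel select --seasons runs/seasons_fit.csv --scheme local -B 10000 --seed 1 --out runs/selection.csv
phenosel report --selection runs/selection.csv --out runs/table1.txt

# or end to end from a config file
phenosel all --config config.yaml --out runs/full
```

A config file is plain `key: value` text (YAML-compatible). Synthetic mode:

```yaml
synthetic:
  n_individuals: 200
  year_labels: [2013, 2014, 2015]
  rho: 0.4
  beta_ffd: -0.5
  zero_inflation_pi: 0.4
  rng_seed: 1
schemes: [local, global]
n_replicates: 10000
seed: 42
```

Real-data mode replaces `synthetic:` with `census_csv`, `fruits_csv` and
`shoots_csv` paths (a config may not mix the two). Exit codes: 0 ok,
1 user error, 2 internal error.

## Data dictionary

Column-level documentation of every CSV read or written by the pipeline is
in [`docs/data_dictionary.md`](docs/data_dictionary.md).

## Conventions

- Sample SD uses the n−1 denominator; relativized fitness has mean exactly
  1 in its reference group; size is ln-transformed before standardization.
- First-order estimates come from linear-only models; quadratic and
  correlational estimates from the extended models. Squared-term
  coefficients (and their intervals) are doubled in all reports; the
  interaction is not doubled by default (`--double-interaction` to change).
- Bootstrap resampling unit is the data row within the analysed year;
  empirical quantiles use linear interpolation (type 7).
- Significance = the 95% BCa interval excludes zero (closed interval).
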