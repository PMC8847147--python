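# Data dictionary

All files are plain CSV with a header row. Days are day-of-year: integers
for observations, continuous reals for estimated event days. Intervals
between census visits are half-open `(previous visit, detection visit]`.

## census.csv (input / synthetic output)

One row per individual × visit.

| column | type | meaning |
|---|---|---|
| `individual_id` | str | stable within a year |
| `year` | int/str | season label |
| `day` | int | day-of-year of the visit |
| `leaflets_total` | int | total leaflets on the focal shoot |
| `leaflets_unfolded` | int | unfolded leaflets at this visit; `0 <= unfolded <= total` |
| `bud_size` | float or empty | size of the largest bud (mm) |
| `flowers_open` | int | open flowers at this visit |
| `grazed` | bool | grazing recorded at/before this visit |
| `true_leaf_out_day` | float | synthetic only: hidden truth, carried through |
| `true_ffd` | float | synthetic only: hidden truth, carried through |

Visits must be strictly increasing in `day` within an individual.

## shoots.csv (input / synthetic output)

One row per individual × year: `individual_id`, `year`,
`shoot_height` (cm), `shoot_diameter` (mm), `n_shoots` (count).

## fruits.csv (input / synthetic output)

One row per fruit: `individual_id`, `year`, `n_seeds` (counted, or
estimated from pod-wall indentations for opened pods), `n_entry_holes`
(closed pods: number of seeds with entry holes; opened pods: pod-wall
entry-hole count), `pod_opened` (bool), `per_seed_holes_observed` (bool,
true for the closed-pod inspection path).

## truth.csv (synthetic output)

Per individual × year: `individual_id`, `year`, `leaf_out_day`, `ffd`,
`ln_size`, `w_expected` (clamped expected relative fitness),
`seed_count` (realized zero-inflated negative-binomial draw).

## plant_seasons.csv (pipeline output; acceptance-script input format)

One row per individual × year (the analysis unit):

| column | type | meaning |
|---|---|---|
| `individual_id`, `year` | | keys |
| `leaf_out_day` | float | estimated day the first leaflet unfolded |
| `first_flowering_day` | float | estimated day the first flower opened |
| `development_time` | float | `first_flowering_day - leaf_out_day`, exactly |
| `shoot_height`, `shoot_diameter`, `n_shoots` | float | size measurements |
| `aboveground_volume` | float | `(0.5 * diameter)^2 * height * pi * n_shoots` |
| `fitness_intact_seeds` | float | developed seeds not damaged by the seed predator; fractional via the opened-pod estimate |
| `leaf_out_missing`, `ffd_missing` | bool | event not estimable |
| `ffd_midpoint` | bool | missing bud size; interval midpoint used |
| `ffd_imputed_grazed` | bool | flowering day imputed from the grazed-plant model |

`plant_seasons_all.csv` contains every individual; `plant_seasons.csv`
only rows passing the completeness filter (both event days, positive
volume, fitness present).

## selection_tables.csv (pipeline output)

Long format: `family` (one of `total_leafout`, `total_ffd`,
`total_devtime`, `direct_linear`, `direct_correlational`, `direct_full`),
`year`, `scheme` (`local`/`global`), `n`, `term`, `estimate`,
`bca_lower`, `bca_upper`, `significant`, `doubled`, `vif`,
`source_model` (`linear` = linear-only fit, `extended` = fit with the
squared term added). Squared-term rows are on the doubled (gamma) scale.

## table1_<scheme>.csv / .txt (pipeline output)

Wide report grouped into sections (a) total selection on leaf-out day,
(b) total selection on first flowering day, (c) direct selection; per-year
columns `estimate_<year>`, `lower_<year>`, `upper_<year>`,
`significant_<year>`. In the text rendering `*` marks estimates whose
BCa interval excludes zero.

## comparisons.csv (pipeline output)

`scheme`, `year`, `term`, `direct_estimate`, `total_bca_lower`,
`total_bca_upper`, `differs` (direct estimate outside the closed total
interval), `interpretation`.

## correlations.csv (pipeline output)

Per year: `n`, Pearson `r` between raw leaf-out and first flowering day,
`t`, `df`, two-sided `p`.

## manifest.json (pipeline output)

Config digest (sha256), seed, replicate count, confidence level, schemes,
option flags, per-year sample sizes, package version, and all warnings
emitted during the run.

## simulation_config.txt (synthetic output)

`key: value` lines of every simulation parameter, re-loadable as a config.
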