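# Data dictionary

Column conventions for every CSV the package reads or writes.

## Survey haul tables (two-table dialect)

`hauls.csv` — one row per haul:

| column | type | meaning |
|---|---|---|
| haul_id | str | unique haul identifier |
| year | int | survey year |
| region | str | region code used by filters (e.g. ICES division) |
| distance_km | float, optional | tow distance |
| wingspread_km | float, optional | trawl wing-end separation |
| duration_min | float, optional | tow duration (imputation covariate) |
| depth_m | float, optional | seabed depth (imputation covariate) |
| swept_area_km2 | float, optional | distance x wingspread; imputed when absent |

`lengths.csv` — one row per haul x species x 1-cm class with catch:

| column | type | meaning |
|---|---|---|
| haul_id | str | joins to hauls.csv |
| species | str | taxon or analysis group |
| length_cm | float | 1-cm class midpoint |
| count | int | fish counted (raised to haul total) |
| subsample_factor | float, optional | applied multiplicatively when present |

## Length composition (tidy output of survey processing)

| column | type | meaning |
|---|---|---|
| species | str | |
| year | int | |
| length_cm | float | class midpoint |
| kg_km2_cm | float | biomass density per 1-cm class |

Annual totals of `kg_km2_cm` are the survey index u'; a year summing to
zero is missing, not zero.

## Parameter tables

- length–weight: `species, a, b` with weight(g) = a·length(cm)^b
- taxon mapping: `taxon, group` (unmapped taxa go to the `discard-only` group)
- minimum landing sizes: `species, mls_cm, basis (legal|de-facto),
  effective_year`
- observer length frequencies (retention fitting): `species, length_cm,
  n_landed, n_discarded`
- age compositions (q-from-age): `year, age, n_landed_thousands,
  w_landed_kg, n_discarded_thousands, w_discarded_kg`
- observed discard-rate fragments (compare_p): `species, p_observed`
  (optional `source`, `years`)
- group membership (aggregation): `species, group` with group in
  {reference, non-TAC, other, discard-only}

## Annual observations (simulator output / model input)

| column | type | meaning |
|---|---|---|
| species | str | |
| year | int | |
| index_kg_km2 | float | observed survey index u'; NaN = missing |
| landings_tonnes | float | observed landings L' |
| discards_tonnes | float | observed discards D'; NaN/absent for landings-only |

Synthetic truth bundles are JSON objects with the generating Q, u, q paths,
ogive parameters, observation sds, MLS and the exact forward-model
catch/discard/landing series (`discardcast.io.truth_to_json`).

## Results

- `<name>_series.csv`: `quantity (C|D|L|p|q|Q|u), species, year, median,
  lo, hi` — posterior median and 95% credible interval.
- `<name>_params.csv`: structural parameter summaries.
- `<name>_runlog.json`: seed, MCMC configuration, convergence flag and
  max split-R-hat.
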