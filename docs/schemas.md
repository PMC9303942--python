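# File schemas

All files are plain CSV with one header row; floats are written with 17
significant digits (`%.17g`) and read back with round-trip precision, so
every writer/reader pair is lossless. Configuration is YAML.

## species.csv — life-history parameters (one row per species)

| column | units | constraint |
|---|---|---|
| name | – | unique label |
| w_min | g | 0 < w_min < w_mat < w_inf |
| w_inf | g | asymptotic mass |
| w_mat | g | maturation mass |
| L_inf | cm | asymptotic length |
| h | g^(1−n)/yr | maximum intake coefficient |
| n | – | intake exponent |
| gamma | – | search-volume coefficient |
| q | – | search exponent |
| beta | – | predator–prey mass ratio, > 1 |
| sigma | – | diet breadth (log scale), > 0 |
| alpha | – | assimilation efficiency, (0, 1] |
| ks | g^(1−p)/yr | standard metabolism coefficient |
| p | – | metabolism exponent |
| mu_b0 | 1/yr·g^(1−n) | background mortality coefficient |
| erepro | – | reproduction efficiency, (0, 1] |
| R_max | numbers/yr | Beverton–Holt recruitment ceiling, > 0 |

Row-level invariant violations are reported with 1-based file row numbers.

## interaction.csv — availability matrix

Square matrix, species labels as both the first column (index) and the
header; entry (i, j) is the availability θ_ij ∈ [0, 1] of prey species j to
predator species i. Row and column label orders must match.

## selectivity.csv — gear selectivities (one row per gear × species)

| column | units | constraint |
|---|---|---|
| gear | – | gear label |
| species | – | species label |
| w50 | g | mass at 50% selection, > 0 |
| slope | – | sigmoid steepness (in ln w), > 0 |
| Q | – | catchability, ≥ 0 |

## nutrients.csv — concentration profiles (one row per species)

Columns: `species` plus exactly the seven nutrient columns
`calcium, iron, zinc, selenium, vitamin_a, vitamin_d, omega3`, each the
concentration per 100 g edible tissue (mg for calcium/iron/zinc, µg for
selenium/vitamin_a/vitamin_d, g for omega3); all ≥ 0.

## catch.csv — regional catch records

| column | units | constraint |
|---|---|---|
| region | – | EEZ / country label |
| taxon | – | species, genus or family name |
| rank | – | one of `species`, `genus`, `family` |
| catch_tonnes | t/yr | ≥ 0 (mean over a stated period) |
| vulnerability | – | intrinsic index in [1, 100] (may be empty) |

## species_profiles.csv — profile table for catch-table mode

Columns: `species, genus, family` plus one column per nutrient. Genus- and
family-rank catch records resolve to the unweighted mean over member
species.

## Configuration YAML

Sections are merged over the defaults:

```yaml
grid:      {n_bins: 100, resource_decades: 3.0}
numerics:  {dt: 0.1, tol: 1.0e-5, t_max: 600.0}
sweep:     {effort_max: 4.0, effort_step: 0.05,
            collapse_threshold: 0.10, neutrality_tolerance: 0.05}
optimiser: {f_bounds: [0.01, 2.0], n_starts: 5}
seed: 0
```

## Outputs of `yield-curves`

- `fmsy.csv` — species, F_MSY (1/yr), yield_at_FMSY (t/yr), B0 (t).
- `catch_by_species.csv` — tidy: effort, species, catch_tonnes.
- `nutrient_yield.csv` — tidy: effort, nutrient, yield (nutrient units/yr;
  amount per 100 g × tonnes × 10⁴).
- `indicators.csv` — effort, exploitation_rate, total_catch,
  community_biomass, fishable_biomass, mean_max_size, n_collapsed,
  collapsed_species (semicolon-joined).
- `rescaled.csv` — every series as a proportion of its maximum.
- `summary.csv` — one row per quantity (total_catch and each nutrient):
  maximum, F_at_maximum (effort multiplier), exploitation_at_maximum,
  ratio_to_F_mMSY, classification, yield_at_mMSY_fraction.

## Outputs of `optimise`

- `optimised.csv` — tidy: nutrient, species, F_star, F_baseline, F_delta,
  yield_star, feasible, delta_nutrient_yield, delta_total_catch,
  delta_fishable_biomass.
- `optimise_diagnostics.json` — per nutrient: feasibility, evaluation
  counts, failed starts.

## Outputs of `framework`

- `framework.csv` — tidy per region × nutrient: evenness, vulnerability,
  totals, delta_vulnerability, classification, region means ± 2 SEM.
- `global_deviation.csv` — per nutrient: n_regions, frac_negative,
  frac_positive, frac_zero.
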