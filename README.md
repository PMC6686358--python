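# spomlab

Stochastic patch occupancy models (SPOMs) for plant metapopulations on
linear urban patch networks — e.g. the spontaneous flora of street-tree
bases, where each tree pit is a habitat patch and each street is treated
as one metapopulation per species.

The package implements four annual-census Markov-chain models, forward
simulation, maximum-likelihood fitting with AICc model selection, and an
ensemble layer that regresses best-model proportions on street geography
and species traits.

## Models

Per patch *i* and year *t*, an empty patch is colonized with probability
`C_i(t)` and an occupied patch goes extinct with probability `E_i(t)`:

| label  | colonization                   | extinction            | k |
|--------|--------------------------------|-----------------------|---|
| PRM    | constant `C` (external rain)   | `E (1 − C_i)`         | 2 |
| LM     | `1 − exp(−y · S_i)`            | `E (1 − C_i)`         | 3 |
| PRM+R  | constant `C`                   | `E (1 − C_i)^R`       | 3 |
| LM+R   | `1 − exp(−y · S_i)`            | `E (1 − C_i)^R`       | 4 |

`S_i = Σ_{j≠i} O_j · exp(−α d_ij)` is connectivity under a negative
exponential dispersal kernel (`1/α` = mean dispersal distance).  The
non-rescue extinction is the rescue form with `R ≡ 1`, so the rescue
models nest the base models.

## Layout

- `spomlab.spom_models` — domain types (`PatchNetwork`, `OccupancySeries`,
  `ModelSpec`, `ParameterVector`) and the per-patch probability functions.
- `spomlab.simulator` — synchronous forward simulation, linear street
  generation, green-space distances, and full synthetic multi-street /
  multi-species study generation with per-pair RNG substreams.
- `spomlab.inference` — transition datasets (with survey-gap handling),
  the factorized transition likelihood, multi-start Nelder–Mead MLE on
  transformed scales, AICc, and four-way model selection.
- `spomlab.ensemble` — best-model proportions by street/species,
  quasi-binomial logit GLMs of grouped proportions, and packaged fixture
  tables (15 streets, 15 species) with their headline quantities.
- `spomlab.io_cli` / `spomlab.cli` — CSV formats, YAML study configs,
  run manifests, pipeline orchestration, and the `spomlab` CLI.

## CLI

```sh
# full synthetic pipeline: simulate → select → aggregate → glm
spomlab simulate -c config.yaml -o run/

# fit one model / select among the four for one street
spomlab fit    --occupancy occ.csv --network net.csv --model LM
spomlab select --occupancy occ.csv --network net.csv

# aggregate best-model labels and regress proportions
spomlab aggregate --best-models run/best_models.csv --by street
spomlab glm --table counts.csv --successes successes --covariate dist

# recompute the fixture-table quantities
spomlab reproduce-tables
```

Occupancy CSVs have a `patch_id` column followed by calendar-year
columns with cells in `{0, 1, NA}` (a fully-`NA` column marks a skipped
survey year).  Network CSVs have `patch_id,street_id,x_m,y_m` with
planar coordinates in meters.  See `tests/test_io_cli.py::study_doc`
for the YAML study-config schema.

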