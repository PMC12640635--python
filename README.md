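# reefshift

Reef-monitoring biostatistics pipeline: thermal-stress climatology,
benthic community-change analysis, diversity/bleaching summaries and a
composite site-ranking index, with a synthetic-data generator so the whole
pipeline is testable without field data.

## What it does

- **`reefshift.thermal`** — monthly SST climatology and its Maximum of
  Monthly Means (MMM), bleaching threshold (MMM + 0.5 °C) and per-month
  cooling thresholds, a modified degree-heating-week series (trailing
  84-day window, hotspot magnitudes summed and divided by 7, in °C-weeks),
  annual warm/cool-day counts, OLS trend fits (with per-decade slope
  conversion and optional covariates such as ONI), and monthly aggregation
  of sub-daily logger records.
- **`reefshift.community`** — from-scratch SIMPER: Bray–Curtis
  dissimilarity decomposed into per-variable contributions over all
  between-period sample pairs, consistency ratios, ranked cumulative
  contributions, percentage change of period means, permutation p-values
  with an add-one correction (floor 1/101 at 100 permutations), and the
  site-period mean imputation rule.
- **`reefshift.diversity`** — per-transect Shannon diversity (nats),
  bleaching prevalence with a configurable set of "bleached" health
  states, logit/inverse-logit helpers and proportion bounding to
  [0.0001, 0.9999].
- **`reefshift.erfi`** — Ecological Recovery Feasibility Index: PCA on six
  standardized site-level indicators (coral, CCA, turf, cyanobacteria,
  bleaching prevalence, Shannon diversity), loading-magnitude weights
  `L_j = |l_j1| + |l_j2| + |l_j3|`, signed direction weights `D_j`
  (defaults: coral +4, CCA +2, diversity +2, cyanobacteria −2,
  bleaching −2, turf −3), composite `C_j = L_j × D_j`, raw site scores
  `Σ_j C_j z_ij` and a [0, 1] min–max normalization.
- **`reefshift.synthetic`** — daily SST simulator (seasonal cycle, linear
  trend, stationary AR(1) noise, half-sine warm-anomaly pulses) and a
  survey simulator (Dirichlet benthic compositions with a configurable
  before/after concentration shift; belt-transect colony counts with
  site-level diversity and logit-normal bleached fractions).
- **`reefshift.io` / `reefshift.pipeline` / `reefshift.cli`** — CSV schema
  validation, period labelling, and the orchestrated `run-all` pipeline.

## CLI

```bash
reefshift simulate --out sim/ --seed 5
reefshift thermal --sst sim/sst.csv --out out/ --baseline-years 1985-1990,1993
reefshift simper --benthic sim/benthic.csv \
    --before 2024-03-01 2024-09-30 --after 2024-12-01 2025-02-28 \
    --permutations 100 --seed 0 --out out/
reefshift diversity --belt sim/belt.csv --out out/
reefshift erfi --benthic sim/benthic.csv --belt sim/belt.csv \
    --window 2025-01-01 2025-02-28 --out out/
reefshift run-all --config pipeline.json
```

`run-all` reads a JSON/YAML config (see `reefshift.pipeline.PipelineConfig`
for the keys) and writes stage CSVs, a run log and a summary JSON.

### CSV schemas

| table   | columns |
|---------|---------|
| SST     | `date, sst_c` |
| benthic | `site, date, transect, category, proportion` |
| belt    | `site, date, transect, taxon, health_state, count` |
| logger  | `site, datetime, temp_c` |

Dates are ISO 8601. Health states:
`healthy, pale, partially_bleached, mostly_bleached, bleached`.
Per-transect benthic proportions must sum to 1 (±0.05 is renormalized with
a warning; larger closure errors are rejected).

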