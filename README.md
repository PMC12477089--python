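# phenodist

Analysis pipeline for well-plate phenotypic profiling (Cell Painting-style)
data at 96-well scale: cell-level morphological feature tables are QC-filtered
and normalized against vehicle (DMSO) wells, reduced by PCA, scored as squared
Mahalanobis distances from the vehicle centroid, and modeled against
concentration to derive benchmark concentrations (BMCs). The package also
implements a vehicle-only-plate background study quantifying how solvent
control placement and per-well cell count bias the distance metric, and a
synthetic plate generator with implanted ground truth (plus an independent
analytic oracle) so every stage can be verified end to end.

## Pipeline

1. **plate_model** — plate maps, long-format cell tables, feature→category
   catalogs, multi-plate batch assembly (plain CSV I/O).
2. **normalization** — well QC (≥100 analyzable cells, ≤50% count reduction
   vs the vehicle median), then three steps: robust cell-level z against the
   pooled vehicle cells (median / scaled MAD), well-median aggregation, and
   division by the vehicle wells' per-feature SD.
3. **multivariate_distance** — PCA (centered + unit-scaled, components
   retained to 95% cumulative variance) and squared Mahalanobis distances
   from the vehicle centroid using a Moore–Penrose generalized inverse of the
   retained-score covariance; global or per-category.
4. **concentration_response** — BMR = vehicle median + 1 MAD of the vehicle
   distances; ten-model concentration–response family (constant, poly1,
   poly2, power, hill, gain_loss, exp2–exp5) fitted by maximum likelihood
   under a t(4) error model; AIC winner, continuous hitcall, BMC by
   root-finding the BMR crossing, bootstrap 95% confidence limits, and the
   exclusion rules (hitcall < 0.9, BMC above the top tested concentration,
   missing confidence limit).
5. **background_variability** — 21 re-normalizations of a DMSO-only plate
   (whole plate + each of 8 rows and 12 columns as the designated solvent
   control) and OLS regressions of distance on cell count, per iteration and
   pooled.
6. **synthetic_data** — seeded 96-well batches (8 vehicle wells, inert and
   cytotoxic control series, 3 test chemicals in triplicate over 8 half-log
   concentrations), with block-correlated features, a row-wise cell-count
   gradient, Hill-shaped feature shifts and cytotoxic count reduction; the
   analytic oracle computes each chemical's true BMC without touching the
   production code path.
7. **pipeline / cli** — orchestration, run manifests, command line.

## Command line

```sh
# synthetic batch (plate maps + cell tables + ground truth)
phenodist simulate --seed 1 --out-dir sim/

# full analysis from files: normalize -> PCA/distances -> fits -> report
phenodist run-all --platemap sim/platemap.csv \
    --cells sim/cells_P1.csv --cells sim/cells_P2.csv \
    --cells sim/cells_P3.csv --cells sim/cells_P4.csv \
    --catalog sim/feature_catalog.csv --seed 1 --out-dir results/

# one-shot synthetic end-to-end
phenodist run-all --simulate --seed 1 --out-dir results/

# individual stages
phenodist normalize --platemap ... --cells ... --out-dir ...
phenodist distance  --platemap ... --cells ... --out-dir ...
phenodist fit       --platemap ... --cells ... --out-dir ...

# DMSO-only plate background study (21 reference iterations, heatmap grids,
# regression summaries)
phenodist background --platemap dmso/platemap.csv --cells dmso/cells.csv \
    --out-dir bg/
```

`run-all` writes `normalized_profile.csv`, `exclusions.csv`, `distances.csv`,
`fits.csv` and a `manifest.json` with the config hash; `--per-plate` analyzes
each plate as its own batch, `--categorical` adds per-category fits.
Exit codes: 0 ok, 1 user error, 2 internal error.

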