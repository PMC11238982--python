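# basindiv

Basin-scale biodiversity analysis of gridded species occurrence records.

`basindiv` is a tested, reusable implementation of a common macroecological
workflow for sparse marine occurrence data: clean and grid Darwin Core-style
records onto a 1° lattice, build a presence–absence matrix, compute alpha
richness, occurrence-based Shannon diversity and pairwise Sørensen beta
diversity partitioned into turnover and nestedness, diagnose sampling effort
(rarefaction/extrapolation, redundancy, coverage tables), detect hot/cold
spots (Getis-Ord G\*) and spatial autocorrelation (Moran's I), interpolate
cell statistics (IDW, ordinary kriging), build standardized environmental
predictor tables, select variables with a two-stage random-forest procedure,
fit GAMs with a residual autocovariate (RAC) under BIC selection, and fit
generalized dissimilarity models (GDM) with monotone I-splines and PCA/RGB
composition maps.

A first-class synthetic-data module generates occurrence scenarios with
known ground truth (niche-driven richness gradients, hotspots, controlled
spatial autocorrelation, tagged "dirty" records), so every stage of the
pipeline has a recovery test.

## Layout

| module | contents |
|---|---|
| `basindiv.grid` | lon/lat grid conventions, cell ids, great-circle distance |
| `basindiv.synthetic` | environmental fields, species pools, occurrence simulation, ground truth |
| `basindiv.occurrences` | reading, ordered cleaning rules, taxonomy harmonization, gridding, PAM, cell filters |
| `basindiv.environment` | depth/period averaging, block-mean resampling, temperature deviation/stability, standardization, Spearman matrix |
| `basindiv.diversity` | alpha/Shannon, beta partition (βsor = βsim + βsne), per-cell beta means, redundancy, dominant species |
| `basindiv.effort` | rarefaction/extrapolation with bootstrap CIs, spherical cell areas, region coverage tables |
| `basindiv.spatial` | queen/distance-band weights, Moran's I, Getis-Ord G\*, IDW, ordinary kriging |
| `basindiv.models` | random-forest variable selection, GAM (statsmodels backend), RAC, BIC/ΔBIC tables |
| `basindiv.gdm` | I-spline basis, monotone IRLS-NNLS dissimilarity fit, importance, PCA/RGB maps |
| `basindiv.pipeline` / `basindiv.cli` | config validation, end-to-end orchestration with a checksummed manifest, `basindiv` CLI |

## CLI

Everything is reachable through the `basindiv` executable:

```sh
# synthetic scenario with ground truth
basindiv simulate --outdir demo --seed 1 --dirty-fraction 0.1

# stage by stage
basindiv clean demo/occurrences.csv --out demo/clean.csv --report demo/report.json \
        --period 1993:2019 --depth 0:200
basindiv grid demo/clean.csv --out demo/gridded.csv
basindiv pam demo/gridded.csv --out demo/pam.csv --min-richness 10 \
        --exclude-lon-band -110,-170
basindiv div alpha demo/pam.csv --out demo/alpha.csv
basindiv effort demo/pam.csv --out demo/curve.csv --boot 200 --seed 1
basindiv spatial gstar demo/alpha.csv --weights queen --out demo/hotspots.csv
basindiv env standardize demo/env_table.csv --out demo/env_std.csv
basindiv model demo/env_std.csv demo/alpha.csv --family poisson --rac
basindiv gdm demo/pam.csv demo/env_std.csv --out demo/gdm.json --map-out demo/rgb.csv

# or the whole pipeline from one YAML config
basindiv run --config config.yaml --seed 1
```

A minimal config needs only `outdir`; all other keys (grid spec, 0–200 m
depth window, 1993–2019 period, −110…−170° exclusion band, min-richness 10,
weights scheme, model families) are filled with documented defaults.
`basindiv run` writes every artifact plus a `manifest.json` with SHA-256
checksums; reruns with the same seed are bit-identical.

## Conventions worth knowing

- Cells are half-open `[x, x+1) × [y, y+1)` boxes keyed by the SW corner;
  longitudes are wrapped into `[−180, 180)` and the antimeridian is treated
  as adjacent by the spatial weights.
- Sample standard deviation (`ddof=1`) is used throughout, including the
  two-point slice SD inside the temperature-stability computation.
- Shannon uses occurrence counts as abundance proxies (`p_i = n_i / N`);
  this is a documented caveat of occurrence-only data.
- G\* uses binary queen contiguity *including self*; Moran's I and the RAC
  exclude self.
- The GDM fit keeps all spline coefficients nonnegative, so fitted
  transforms are monotone and predicted dissimilarities live in `[0, 1)`.
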