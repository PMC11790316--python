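# gridhotspots

Spatiotemporal hotspot analysis for gridded air-pollution exposure surfaces.

Long-running exposure products (e.g. annual PM2.5 at 1 km × 1 km) make it
possible to ask not just *where* pollution is high, but where it is high
**relative to its surroundings**, and whether such local accumulations are
persistent, appearing, or fading.  `gridhotspots` implements that analysis as
a reusable pipeline for epidemiologists and air-quality analysts:

1. **Lattice & weights** — build the cell lattice from a raster-style cell
   table, form queen-contiguity binary spatial weights (up to 8 neighbors per
   cell, self-inclusion for the star statistic), and prune cells whose
   neighbor set is empty.
2. **Yearly Gi\*** — for each year, the Getis-Ord Gi\* statistic per cell

   ```
   Gi* = [ Σⱼ wᵢⱼ xⱼ − X̄ Σⱼ wᵢⱼ ] / ( S · √( [ n Σⱼ wᵢⱼ² − (Σⱼ wᵢⱼ)² ] / (n−1) ) )
   X̄ = Σⱼ xⱼ / n        S = √( Σⱼ xⱼ² / n − X̄² )
   ```

   with Monte-Carlo conditional randomization (default nsim = 99) for
   pseudo p-values, and yearly labels **hotspot** (Gi\* > 0, p < 0.05),
   **coldspot** (Gi\* < 0, p < 0.05) or **ns**.
3. **Trend taxonomy** — split the window into two halves T1/T2, count
   hotspot years per cell, and classify: **consistent** (≥5 in T1, ≥3 in
   T2), **declining** (≥3 in T1, ≤2 in T2), **emerging** (≤3 in T1, ≥4 in
   T2), else **inconsistent**.
4. **Summaries** — per-unit area and population shares by category,
   exposure-bin tables of long-term means, threshold exceedance (default
   40 μg/m³, the Indian annual NAAQS), and point-gazetteer overlay.

A synthetic-data module generates multi-year fields with planted source
regimes (always-on, late-onset, early-shutdown) and a co-registered
population surface, so the whole pipeline is testable end to end without
external data.

## Worked example

Run the bundled three-regime study (60×60 cells, 12 years, SD-5 noise,
three planted sources of amplitude 15):

```python
from gridhotspots import PipelineConfig, run_pipeline

config = PipelineConfig(
    output_dir="demo_out",
    seed=1,
    simulate=dict(
        n_rows=60, n_cols=60, n_years=12,
        base_level=40.0, noise_sd=5.0, spatial_corr_length=0.0,
        sources=[
            dict(center=[15, 15], radius=2, amplitude=15.0, active_years=list(range(1, 13))),
            dict(center=[15, 45], radius=2, amplitude=15.0, active_years=list(range(7, 13))),
            dict(center=[45, 30], radius=2, amplitude=15.0, active_years=list(range(1, 7))),
        ],
    ),
)
results = run_pipeline(config)
print(results["zonal"][["category", "n_cells", "area_pct", "population", "population_pct"]]
      .round(2).to_string(index=False))
```

prints

```
    category  n_cells  area_pct  population  population_pct
  consistent       18      0.50     2984.74            0.34
    emerging       27      0.75     8807.84            1.01
   declining       29      0.81     5406.05            0.62
inconsistent     3526     97.94   856931.11           98.03
```

The three planted cores (13 cells each) are recovered inside the consistent,
emerging and declining classes; the extra cells in each class are the bump
fringes plus a small number of chance flags (the permutation test admits
p ∈ {0.01, …, 0.04} under the null, about a 4% yearly hotspot rate).  All
output tables (yearly labels, trend categories, zonal/bin/exceedance
summaries, a manifest with config hash and seed) land in `demo_out/`.

The same pipeline runs from the command line:

```sh
gridhotspots simulate --config config.yaml --outdir data/
gridhotspots run --config config.yaml
gridhotspots validate --config config.yaml
```

with `lattice`, `gistar`, `trend` and `summarize` subcommands for running
stages individually on CSV inputs.

## Scope

The package analyses a *given* exposure surface; it does not estimate
exposure from monitors or satellites, compute global autocorrelation
indices, or produce cartography.  Hotspots are always relative to the
spatial unit analysed, so results depend on the unit partition supplied.
See `docs/methods.md` for the model, the design decisions and known
limitations.
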