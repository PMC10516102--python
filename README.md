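# sdmpipe

Ensemble species distribution modelling (SDM) under climate-change
scenarios, with conservation accounting: range loss/gain, stacked
species richness, and two assessments of protected-area (PA)
effectiveness — a per-species gap analysis and a richness
randomization null model.

The package targets the common conservation-biogeography workflow in
which occurrence records for a set of species (e.g., Amazonian
carnivores) are modelled against bioclimatic predictors in the present
and projected onto future climates from multiple general circulation
models under two emission pathways. Because the real inputs (WorldClim
layers, GBIF occurrences, WDPA footprints) are bulky downloads, a
first-class synthetic-data module simulates landscapes with the same
statistical structure — spatially autocorrelated, strongly collinear
climate fields; scenario-shifted futures; climate-driven land cover;
connected PA footprints — and *virtual species* with known Gaussian
niches, so every stage of the pipeline can be validated against ground
truth.

## The method

1. **Climate space.** The 19 bioclimatic variables are collinear, so
   models use the leading principal components of the correlation
   matrix — the smallest set of axes explaining ≥ 95% of variance.
   Future climates are projected with the coefficients estimated on
   present data, keeping all scenarios in one space.
2. **Occurrences.** Records are thinned to one per cell at twice the
   predictor resolution. Pseudo-absences are drawn 1:1 with presences
   among cells *outside* the presences' environmental envelope
   (BIOCLIM-style min–max box on the PCA axes).
3. **Partitioning.** Species with ≥ 15 records get a checkerboard
   block cross-validation whose block size is optimized by three
   simultaneous criteria — minimal Moran's I, minimal environmental
   distance between fold centroids, minimal fold-count SD — aggregated
   by rank sum. Sparser species get a random 3-fold split.
4. **Models.** Five algorithms: GLM (binomial, linear + quadratic
   terms), a MaxEnt-like penalized logistic model on presence vs
   background, random forest, a calibrated SVM, and a Gaussian-process
   classifier. Per algorithm, fold models are averaged into one
   continuous suitability map.
5. **Ensemble & threshold.** Algorithms scoring above the
   across-algorithm mean test Jaccard are averaged into the ensemble;
   the map is binarized at the threshold maximizing the Jaccard index
   (TP/(TP+FP+FN)) at the evaluation points, and the same threshold is
   reused for future projections.
6. **Range accounting.** Binary ranges are masked to the permitted
   vegetation classes of each scenario's land-cover model; species
   with |Δarea| < 5% are "stable", otherwise loss/gain; richness maps
   are cell-wise sums of the binary ranges.
7. **PA effectiveness.** PAs are clipped to the biome and dropped
   below 50 km². Each species' protected fraction is compared with a
   range-size-dependent representation target — 100% below 1,000 km²,
   10% above 250,000 km², log-interpolated between — and classified
   Protected / Partially Protected / Gap / Not Protected at 90/70/20%
   attainment. The null model re-places each PA footprint 999 times at
   random (size, orientation and shape preserved) and calls the PA
   effective when the observed mean richness reaches the top 5% of the
   null distribution (p < 0.05, p = (1 + #{null ≥ obs})/1000).

## Worked example

Run the full synthetic analysis (40×40 grid, 3 virtual species, two
scenarios × two GCMs) from Python:

```python
from sdmpipe import RunConfig, run_pipeline

cfg = RunConfig(grid_rows=40, grid_cols=40, n_species=3, n_gcms=2,
                null_reps=199, n_pas=10, master_seed=7)
res = run_pipeline(cfg, "out")
print(res["tables"]["range_change.csv"].round(2).to_string(index=False))
```

which prints:

```
species scenario  area_present_km2  area_future_km2  pct_change change_class  suitability_change_pct
  vsp01    rcp45           59700.0          40500.0      -32.16         loss                  -15.69
  vsp01    rcp85           59700.0          29800.0      -50.08         loss                  -32.27
  vsp02    rcp45           89100.0          79700.0      -10.55         loss                    6.23
  vsp02    rcp85           89100.0          60400.0      -32.21         loss                    0.82
  vsp03    rcp45           67000.0          41300.0      -38.36         loss                  -16.18
  vsp03    rcp85           67000.0          31300.0      -53.28         loss                  -34.73
```

Each row is one species × scenario: its present and future potential
distribution areas after land-cover masking, the percent change, and
the stability class (here every species loses range, and losses are
roughly twice as large under the high-emission scenario). The same run
writes `evaluations.csv` (per-fold Jaccard/AUC per algorithm — in this
run mean Jaccard 0.83–0.93 and AUC 0.94–0.99 across the five
algorithms), `gap_analysis.csv`, `null_model.csv` (0 of 10 simulated
PAs protect richness better than chance in any scenario),
`protected_richness.csv` (13.8% of present richness inside PAs,
falling to 5.8% under the pessimistic scenario), richness and range
rasters as ASCII grids, and a `manifest.json` of file hashes — rerunning
with the same master seed reproduces every artifact byte-for-byte.

The same pipeline is available from the shell:

```sh
sdmpipe run-all --seed 7 --out out/
sdmpipe simulate --rows 40 --cols 40 --out stack/
sdmpipe pca --stack stack/ --out pca.json
```

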