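# vegspec

Classifying grass-dominated vegetation communities from hyperspectral
reflectance.

Grasslands are hard to map at fine thematic resolution: the categories
ecologists need (plant communities and sub-communities, or groupings by
dominant species) differ in subtle spectral detail, individual plants are
small relative to sensor pixels, and much of the interesting vegetation sits
in narrow objects — field margins, ditches — whose pixels mix neighbouring
vegetation types. `vegspec` implements, as a reusable and tested pipeline,
the analysis chain used to study these questions with airborne hyperspectral
imagery (hundreds of bands, 400–2500 nm, 1 m pixels) and hand-held field
spectroscopy:

- **Spectral covariates** — Savitzky–Golay smoothed first derivatives at
  every band (local polynomial fits that remain exact on uneven wavelength
  grids); position/value of the reflectance minimum in 660–750 nm;
  first-derivative extrema in five diagnostic regions (495–550, 550–650,
  970–1090, 1110–1205, 1205–1285 nm); red-edge derivative peaks in
  690–750 nm with their heights, positions and ratios; and a configurable
  vegetation-index registry (NDVI, PRI, ARI, mARI, WBI, NDLI, CAI, RGRI,
  RVSI).
- **Simulated multispectral data** — degradation of hyperspectral spectra
  to 13-band (Sentinel-2-like) and 8-band (Landsat-8-OLI-like) sensors via
  Gaussian spectral response functions, `w_k ∝ exp(−(λ_k−c)²/2σ²)` with
  `σ = FWHM / (2√(2 ln 2))`, unit-normalised on the actual grid.
- **Class-balanced random forest** — every tree draws a per-category capped
  bootstrap (at most `downsample_target` samples per category), balancing
  errors between common and rare categories; out-of-bag (OOB) bookkeeping;
  `mtry = ⌊√p⌋` by default.
- **Geographic validation** — per vegetation type, patches are split into
  two contiguous geographic halves (principal-axis median cut, western half
  trains); validation repeats five capped random draws and reports overall
  accuracy `Σxᵢᵢ/N` and Cohen's kappa
  `κ = (N·Σxᵢᵢ − Σxᵢ₊x₊ᵢ) / (N² − Σxᵢ₊x₊ᵢ)`.
- **Variable selection** — permutation importance on a large ranking forest
  (`ntree=2000`, `mtry=p/2` at full scale) followed by a single forward pass
  retaining covariates that strictly improve OOB accuracy.
- **Dominant-species clustering** — plots reduced to their three most
  abundant species' percent cover, clustered by the unsupervised-forest
  recipe (observed vs column-permuted reference, shared-leaf proximity,
  `d = √(1−p)`, partitioning around medoids) at several cluster counts.
- **Synthetic scenes** — a generator producing labelled pixel spectra with
  patch geometry, nested category labels, wide/narrow edge conditions,
  species cover tables and monthly phenology, so the entire chain is
  testable without any proprietary imagery.

## Worked example

```python
from vegspec import (ExperimentConfig, run_experiment,
                     SyntheticConfig, default_archetypes)

config = ExperimentConfig(
    synthetic=SyntheticConfig(archetypes=default_archetypes(4, 5), n_bands=151),
    variants=("hyperspectral", "sim13", "sim8"),
    resolutions=("community", "finest"),
    edge_conditions=("wide", "narrow"),
    ntree=100, downsample_targets={"wide": 100, "narrow": 60}, repeats=5)
result = run_experiment(config, seed=1)
print(result.summary.round(3).to_string(index=False))
```

prints (abridged):

```
      variant resolution   edge  accuracy_mean  kappa_mean
hyperspectral  community   wide          1.000       1.000
hyperspectral     finest   wide          0.992       0.990
        sim13     finest   wide          0.992       0.990
         sim8     finest   wide          0.848       0.810
hyperspectral     finest narrow          0.272       0.090
         sim8     finest narrow          0.194      -0.007
```

Read by column: accuracy and kappa fall from hyperspectral to the 8-band
simulation, from coarse communities to the finest categories, and — sharply
— from wide patches to edge-mixed narrow ones, the qualitative pattern the
method was built to quantify. `examples/` contains one short script per
capability (scene generation, covariates, band simulation, classification,
variable selection, clustering, the experiment grid), each printing the
numbers it computes and what they mean. The `vegspec` command exposes the
same stages as subcommands (`vegspec synth`, `vegspec features`,
`vegspec simulate-bands`, `vegspec classify`, `vegspec select-vars`,
`vegspec cluster-cover`, `vegspec experiment`).

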