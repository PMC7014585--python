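# Methods

This note documents the models and procedures `vegspec` implements, the
defaults and why, the synthetic data's scope, and the numerical choices made
where the design was genuinely open. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` compute.

## Spectral data model

Spectra live on a strictly increasing wavelength grid in nm (300–2600 nm
accepted; airborne campaigns of this kind use 622 bands over 400–2500 nm).
Reflectance is stored as a fraction; tables whose maximum exceeds 2 are
treated as percent and divided by 100 (both conventions circulate in
spectral libraries). Small negatives (≥ −0.05) and values up to 1.5 are
tolerated as atmospheric-correction and bright-target artefacts. "The band
at λ" always means the band whose centre is nearest λ, ties to the lower
wavelength. Coordinates are planar metric (easting/northing) consistent
with 1 m pixels; no CRS handling is attempted.

A shipped `RegionMask` (`WATER_VAPOUR_MASK`: 1340–1460, 1790–1960,
2400–2600 nm) supports removing the atmospheric water-vapour windows where
airborne reflectance is unusable. Which wavelengths a given campaign
actually excluded varies with the instrument and processing; the shipped
mask is an editable convention, not a measured value.

## Savitzky–Golay first derivative

The first derivative suppresses additive background (soil) signal but
amplifies noise, so it is computed from a smoothing polynomial: for each
band, a degree-`polyorder` polynomial is least-squares fitted to the
`window` nearest bands *against the actual wavelengths*, and its analytic
derivative is evaluated at the band centre. On uniform grids this equals
the classical SG convolution (including the endpoint handling of one-sided
full-length windows); on the uneven grids of field spectroradiometers the
per-window fit stays exact where fixed coefficients would not. Defaults
`window=9`, `polyorder=2` — a light smoothing level; the selection procedure
that picks the level by classification accuracy is available as
`select_smoothing_level` (ties go to the smaller window, i.e. less
smoothing). Higher-order derivatives are deliberately not offered: they
amplify noise further for little discriminative gain.

## Covariate families

* airborne/field hyperspectral mode: derivative at every band; reflectance
  minimum (position, value) in 660–750 nm; derivative extrema
  (position, value of min and max) in 495–550, 550–650, 970–1090, 1110–1205
  and 1205–1285 nm; the registry indices; red-edge peak covariates.
* red-edge peaks: strict local maxima of the derivative in 690–750 nm
  (plateaus count once, at their lowest wavelength), capped at the three
  tallest and indexed by ascending wavelength. Airborne mode emits heights
  and pairwise height ratios; field mode adds peak wavelengths, wavelength
  ratios, and the local maximum reflectance in the peak region with its
  ratios to the heights — hand-held spectra are clean enough for positional
  covariates to carry signal. Both heights and ratios carry provenance
  tags so either view can be selected downstream.
* multispectral mode: band reflectances, all unordered pairwise band ratios
  R_i/R_j (i < j by wavelength; orientation is monotone-invertible, so one
  direction suffices), and the registry indices whose wavelengths the band
  set can resolve.
* no pre-selection is applied at assembly; the classifier and the variable
  selection see everything.

Undefined covariates (absent peaks, zero denominators, non-positive log
arguments) become NaN and are imputed with the column median; when a
train/validation split is declared the median is computed on training rows
only, so no validation information leaks through fill values. Columns
undefined on all (training) rows are dropped with a warning. Note that on
smooth synthetic spectra with a single derivative maximum, the second and
third peak columns are typically all-undefined and are dropped — the family
census in the log records this.

The index registry is structured config (`name`, `expression` over `R<nm>`
tokens and `mean(R<lo>:R<hi>)` ranges). The nine shipped definitions are the
standard literature forms. An index is considered applicable to a
multispectral band set if every required wavelength has a band centre within
20 nm (range terms need one band inside the range); 20 nm is roughly half a
typical broadband FWHM, and is configurable. NDLI is not scale-invariant
(its denominator −log(R1754·R1680) shifts under a multiplicative factor);
tests assert its exact transformation law rather than invariance.

## Band simulation

Broadband values are convex combinations of hyperspectral bands under a
pure Gaussian spectral response per band (σ = FWHM / (2√(2 ln 2))),
renormalised to unit sum on the actual — possibly masked — grid, so
excluded wavelengths never contribute. Shipped band sets are the nominal
published Sentinel-2 MSI centres/FWHM (13 bands) and Landsat 8 OLI
excluding panchromatic (8 bands), kept in editable YAML: tabulated
instrument response curves are deliberately not reproduced, since the
Gaussian model is the documented convention this pipeline follows and the
tables vary by instrument revision. Spatial properties are untouched.

## Class-balanced forest

Common vegetation categories contribute far more pixels than rare ones,
and an ordinary bootstrap then buys majority-class accuracy with
minority-class error. Each tree in the ensemble therefore draws a
per-category capped bootstrap: `min(n_c, downsample_target)` draws *with
replacement* within each category (the description "randomly reduced"
leaves replacement open; within-category bootstrap keeps every tree's draw
a bootstrap and is recorded in config). Out-of-bag votes are accumulated
per sample over the trees that did not draw it; ties in the majority vote
go to the first class in sorted order, making all predictions
deterministic. The tree learner is CART (`scikit-learn`) with `mtry`
features tried per split; `mtry` defaults to ⌊√p⌋. `ntree=2000` is the
full-scale setting for stable accuracy estimates; the package default is
200, and tests/acceptance use 30–500 depending on the problem size —
estimates are noisier but orderings are stable at the scales used.
Downsampling caps at full scale: 1000 (community-level wide), 1500
(dominant-species wide), 300 (narrow), shipped as `DOWNSAMPLE_PRESETS`.

## Geographic split and validation

"Split each type's patches geographically into two halves" admits many
constructions; the implemented rule is deterministic: project patch
centroids onto the first principal axis of their layout (axis oriented
towards +x, ties +y), cut at the median projection, and let the half
containing the westernmost centroid train. Types with one patch are split
the same way at pixel level; types with fewer than two samples are
excluded. Degenerate layouts (all projections equal) fall back to an even
split of the lexicographic ordering. Validation draws up to the
downsampling cap per category without replacement, five times by default,
and reports accuracy and kappa per repeat with mean/min/max summaries.
Kappa is computed from the confusion matrix (rows = reference, columns =
prediction — stated explicitly since conventions differ); a saturated
chance term (denominator zero) is reported as NaN rather than forced.

## Variable selection

Permutation importance: permute one covariate's values across all samples
(one permutation per covariate per seed; repetition is available through
seeds), re-predict each tree's OOB samples, and take the increase in OOB
error over baseline. Constant covariates get importance 0 by definition,
and consume a permutation draw anyway so the random stream is alignment-
stable across datasets. Ranking uses a large forest with `mtry=p/2`
(importance becomes more conditional at high mtry). The ranked list is
traversed once; a candidate is kept iff OOB accuracy strictly increases
(`min_improvement=0`, configurable; "improves" is read strictly since no
tolerance is documented). No restart after rejections. Downsampling
destabilises rankings between repeat runs, so selection is intended for
data that need no downsampling (e.g. field spectroscopy samples); the
pipeline does not forbid other uses.

## Dominant-species clustering

Top-3 reduction keeps each plot's three largest percent covers (ties at
rank 3 resolved alphabetically), zeroes the rest, and drops species no plot
retains. Covers are used unstandardised — they already share one scale.
The unsupervised-forest chain is pinned explicitly: (1) a reference table
with every species column independently permuted (marginals preserved,
joint structure destroyed); (2) a forest classifying observed vs reference;
(3) proximity p_ij = fraction of trees in which plots i and j share a
terminal node; (4) dissimilarity d = √(1−p); (5) partitioning around
medoids (classic BUILD + SWAP, deterministic) at each requested cluster
count. Cluster counts are user-supplied; the field campaign this emulates
used 17/9/7/4 for wide-patch data (`RESOLUTION_PRESET_WIDE`). Labels are
1-based and contiguous; degenerate inputs (identical rows) can leave
medoids unused, in which case fewer clusters are returned.

## Synthetic scenes

The generator exists to give every pipeline stage labelled input with
controllable class structure. The reflectance model is phenomenological:
visible baseline + Gaussian green peak (σ=25 nm) − Gaussian chlorophyll
well (σ=30 nm), a logistic red edge rising to a NIR plateau with a gentle
linear SWIR decline beyond 1300 nm, multiplicative Gaussian water wells at
1450/1940 nm, and optional extra narrow absorption features. It reproduces
the canonical grass spectrum shape — including a first-derivative maximum
on the red edge — but is not a radiative-transfer model and makes no
biophysical claims.

Scenes place wide (9×9 px) and narrow (3×12 px) patches per category on a
shuffled slot grid; farms are spatial blocks of slots. Wide patches emit
only interior pixels (outer 2 m trimmed, as edge-influenced ground truth
is trimmed in practice); narrow patches emit everything, with pixels
within 2 px of the boundary convexly mixed with the clean archetype
spectrum of the nearest other patch's category (soil end-member if the
scene has a single patch), weight decaying linearly from 0.7 at the
boundary. Mixing with neighbouring *vegetation* — not just soil — is the
mechanism that makes narrow objects genuinely hard: a soil admixture
shifts all categories alike and a forest simply learns it. The 2 px depth
mirrors the 2 m edge zone trimmed from wide patches. Per-pixel variation:
relative jitter (SD 5%) on amplitude-like parameters, 1.5 nm jitter on
positions, white noise (SD 0.008) plus a spectrally correlated component
(SD 0.004, 60 nm scale). Defaults for the category hierarchy mirror the
emulated campaign's scale (12 communities / 20 finest categories), with a
`narrow_feature_archetypes` preset whose categories differ only in small
red-edge shifts and σ=8 nm absorption lines — the condition under which
spectral resolution matters most.

Monthly phenology scales every category's deviation from the across-
category mean parameters by a per-month separation factor (May 0.60,
June 0.85, July 1.00, August 0.80, September 0.55) plus small NIR and
red-edge-width offsets: swards converge when short (spring) or senescent
(autumn) and are most distinct in peak season. With neutral effects all
months generate identical spectra.

Scenes are pure functions of (config, seed): manifests embed the full
config and regenerate bit-identical output. What the generator does *not*
emulate: radiative transfer, atmospheric residuals, sensor-specific noise,
within-patch floristic gradients, georeferencing error, and temporal
autocorrelation between months beyond the parameter offsets. Passing tests
therefore demonstrate that the pipeline's machinery behaves correctly and
that its qualitative orderings follow from the stated mechanisms — not
that any particular accuracy level transfers to real imagery.

## Experiment grid and reproducibility

`run_experiment` executes variant × resolution × edge cells on one
generated scene: degrade spectra, assemble covariates (imputation medians
from training rows), split geographically, fit the balanced forest, and
evaluate with repeated capped draws. Cell seeds derive from the run seed
via `SeedSequence`, so cells are independent and the whole run is
reproducible from the manifest alone; a failing cell is marked in the
result table without aborting the run. Artifacts: per-repeat confusion
matrices, result and summary tables, JSON manifest.

## Problem sizes used in tests and acceptance

Scenes of 3–8 categories at 61–421 bands, forests of 30–500 trees, and
5–20 seeds per property; the variable-selection check uses a ranking
forest of 400 trees (`mtry=p/2`) and selection forests of 120 trees on
200×50 problems. These sizes are the package's chosen desk-scale study
conditions; orderings and recovery properties are asserted as majorities
over seeds, matching how stochastic-pipeline claims should be read.

## Known limitations

* The geographic split rule is one reasonable construction of a
  two-half geographic split, not the only one.
* The proximity clustering uses all trees (the standard form), not only
  trees where both samples are out of bag.
* Index applicability (20 nm) is a convention; borderline indices (e.g.
  NDVI at 783 nm vs the nominal 800 nm) move in or out with it.
* The forward selection inherits OOB noise: with small forests it
  occasionally admits noise covariates whose OOB estimate fluctuated
  upward; larger selection forests reduce this at linear cost.
* PAM is exact BUILD+SWAP, O(k·n²) per sweep — intended for plot counts in
  the hundreds, not for pixel-scale clustering.
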