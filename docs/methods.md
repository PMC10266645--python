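# Methods

## Scope and data model

`somspec` models soil organic matter (SOM, g/kg) from VNIR diffuse
reflectance. Spectra live in a `SpectrumSet` — per-sample vectors on a
strictly increasing, uniform integer wavelength grid — tagged with one of
five representations: `RAW` (as measured), `R` (Savitzky–Golay smoothed),
`LR` (log₁₀(1/R)), `CR` (continuum removed), `FDR` (first derivative).
Reflectance is stored as a fraction in [0, 1]; files on a percent scale are
rejected rather than silently rescaled, because a silent factor of 100 is
the most common corruption of spectra tables.

## Preprocessing

* **Smoothing.** Savitzky–Golay with an 11-band window and polynomial
  order 2 (defaults; any odd window > order is accepted). Edges are
  *trimmed*, not padded: half a window disappears at each end, mapping the
  native 2151-band, 350–2500 nm grid to 2141 bands over 355–2495 nm. All
  downstream representations share that grid.
* **LR** uses base-10 logarithms, the soil-spectroscopy convention for
  "inverse-log reflectance". Values ≤ 0 raise an error naming the sample and
  band; nothing is clipped.
* **CR** divides each spectrum by its upper convex hull anchored at the
  first and last band of the full working range (the standard full-spectrum
  continuum). The hull is computed by a monotone-chain scan; outputs lie in
  (0, 1] with exact 1 at the anchors.
* **FDR** uses central differences at interior bands and one-sided
  differences at the two boundary bands, preserving the band count so that
  all four representations stay column-aligned. The truncation error is
  second order in the 1 nm step; for features wider than ~10 nm it is
  negligible against instrument noise.
* All transforms require the smoothed `R` tag as input; deriving LR/CR/FDR
  from smoothed reflectance (rather than raw) is a deliberate choice — the
  derivative especially is noise-amplifying, and smoothing first is standard
  practice.

## Spectral-index search

DOA = R(600) − (R(550) + R(650))/2 measures the visible arch that flattens
as SOM rises; it is always computed on `R`. For band pairs, DI/RI/NDI maps
hold the Pearson correlation between the index and SOM for every ordered
pair on the grid. Implementation notes:

* The DI map is computed in closed form from band means, the band Gram
  matrix and the SOM–band covariances (cov(y, Rᵢ−Rⱼ) = cᵢ−cⱼ,
  var(Rᵢ−Rⱼ) = Vᵢ+Vⱼ−2Sᵢⱼ). RI and NDI have no such decomposition and are
  computed by a vectorized per-denominator-column sweep.
* Cells are *invalid* — excluded from ranking, not set to zero — when the
  index vector has (numerically) zero variance or any denominator is within
  1e-12 of zero. Spurious maxima from degenerate cells therefore cannot
  arise.
* DI and NDI are antisymmetric in (i, j), so mirrored pairs carry identical
  |r|; ranking collapses them to the i < j orientation. Both RI orderings
  remain distinct candidates (Rᵢ/Rⱼ and Rⱼ/Rᵢ are different features). Ties
  in |r| break to the lexicographically smaller pair, making selection
  deterministic.
* The SI feature table stacks DOA with the top-k DI/RI/NDI indexes of each
  of the four representations: 1 + 12k columns (13 at k = 1, 37 at k = 3).
  By default the search uses all samples, mirroring the original study
  design; a calibration-only mode exists for leakage-free variants and is
  recorded in the run provenance.
* `band_step` computes maps on a strided wavelength subset. Full-resolution
  maps (2141² cells) cost a few seconds each; stride 4 is the pragmatic
  default inside the end-to-end pipeline and changes selected pairs by at
  most a few nm on smooth soil spectra.

## CARS

Competitive adaptive reweighted sampling selects characteristic bands by
iterating, for run i = 1..N (default N = 50):

1. draw ⌈0.8 n⌉ calibration samples without replacement;
2. fit PLS on the retained bands (components chosen by inner CV on the
   subsample, capped at 10, ties to fewest) and weight each band by its
   absolute regression coefficient;
3. *forced selection*: keep the top ⌈ratio(i)·p⌉ bands, with
   ratio(i) = exp(−k(i−1)), k = ln(p/2)/(N−1), so ratio runs from 1 down to
   2/p;
4. *adaptive reweighted sampling*: draw p bands with replacement with
   probability proportional to weight and retain the distinct picks (the
   canonical constant draw count);
5. score the retained subset by 10-fold RMSECV over all calibration
   samples, minimizing over PLS component counts.

The subset with minimum RMSECV wins; ties go to the earliest run. If the
retained set collapses below two bands the trace is truncated and the best
run is taken over completed runs. RMSECV evaluates every component count
from a single PLS fit per fold: NIPALS extracts components greedily, so the
K-component coefficient vector is a partial sum of rank-one terms of a
larger fit (verified against per-component refits to 1e-10 in the tests).
Everything is driven by one `numpy` Generator seeded from the config, so a
`CARSConfig` fully determines a `CARSResult`.

The Monte-Carlo schedule defaults (50 runs, 0.8 sampling ratio, 10-fold
RMSECV, ≤10 components) follow common CARS usage; they are explicit config,
and the benchmark tests show median compression below 10% of the input bands
with ≥8/10 planted informative bands recovered.

## Split, models, evaluation

* **Kennard–Stone** seeds with the two most distant samples (Euclidean) and
  greedily adds the sample maximizing the minimum distance to the selected
  set; ties break to the lower row index. The distance space is the
  smoothed R spectra — standard practice when the split must serve every
  feature route. The default split fraction is 133/178.
* **Model families.** RF (trees ∈ {100, 500, 1000, 1500, 2000},
  predictors-per-split 1–5), linear-kernel SVR (C = 2⁻⁴..2⁴, features and
  target standardized), a ReLU multilayer perceptron (hidden layers
  400/600/500, 1000 epochs, tuned penalty grid {0, 1e-5, 1e-4}), and PLSR
  (components 1..min(20, p, fold-capped), ties to fewer). All tuned by grid
  search minimizing 10-fold CV RMSE on the calibration set with unshuffled
  folds, so a (spec, seed) pair is fully reproducible. The MLP stands in
  for the original deep-network configuration: per-layer dropout and an L1
  penalty are not available in scikit-learn's `MLPRegressor`, so the stated
  penalty grid is carried over as the L2 `alpha` grid — the only deliberate
  deviation in the model suite, and a documented one.
* **Metrics.** R² = 1 − SSE/SST and RMSE with divisor n; RPD and LCCC use
  sample standard deviations (n−1) and are computed on the validation set.
  This mixed divisor convention is intentional and matches the printed
  formulas the package reproduces. A perfect fit yields RPD = ∞, reported
  as the "high" class; a constant prediction yields LCCC = 0 via the
  covariance form of Lin's coefficient.

## Synthetic data

`generate_soil_spectra` emulates the structure of lab-measured paddy-soil
spectra: SOM from a truncated normal whose *post-truncation* moments are
matched to the configured mean 28.54 and sd 7.80 g/kg over 11.85–58.22; a
monotone baseline rising through the visible; multiplicative Gaussian
absorption features near 1400/1900/2200 nm with per-sample random depths
(water/clay nuisance, independent of SOM); exponential darkening
exp(−β(λ)·SOM_eff) with β largest over 400–900 nm; and a 550–650 nm arch
whose amplitude shrinks with SOM, so DOA correlates negatively with SOM.

`SOM_eff = SOM + N(0, som_noise_sd)` injects compositional variability that
darkens spectra exactly like organic matter and is therefore inseparable
from it by any model. It bounds the achievable accuracy: the default
2.3 g/kg is chosen so a well-specified model reaches validation R² ≈ 0.85
(Kennard–Stone validation subsets have sd near 5.9 g/kg, and
5.9·√0.15 ≈ 2.3). Per-band measurement noise defaults to 0.001 reflectance
units, the magnitude of a well-averaged lab spectrum.

What the generator does **not** emulate: detector-junction artifacts,
SOM-dependent absorption-feature depths, nonlinear SOM–reflectance
saturation, and spatial/batch structure. Passing tests therefore certify the
pipeline's algorithms and their statistical behavior under a known
ground truth — not field-scale predictive accuracy, which is data dependent.

`generate_planted_index_data` adds a narrow antisymmetric contrast
(reflectance up at band i, down at band j, sd 8% with σ = 2.5 nm) and
rebuilds SOM from the realized standardized index value plus calibrated
noise, so the SOM–index correlation hits the requested target exactly in
population; any target |r| ≤ 1 is attainable by construction.
`generate_planted_bands_data` is the band-selector benchmark: a few
informative columns carrying a linear SOM signal inside a pure-noise matrix.

## Pipeline and reproducibility

`run_full_pipeline` chains the stages for every enabled route
(SI/SI3 tables, full-spectrum per transform, CARS subset per transform) ×
model family, evaluates each fit, and writes a report bundle (report CSV,
selected-index tables, CARS band lists and traces, split, provenance). The
provenance block records the config hash, the seed, library versions, and
whether index selection used all samples. One global seed fans out to
per-stage seeds through fixed offsets (generator +0, CARS +100+transform,
models +200+slot), so single stages can be re-run bit-identically. Index
selection on all samples is the paper-faithful default; CARS always runs on
calibration samples only.

## Problem sizes

Full-resolution index maps (2141 bands) are used in the acceptance script;
the end-to-end tests run maps and CARS at stride 4 (536 bands) and the
planted-pair recovery harness crops to a 231-band window around the planted
bands — the package's own choice of problem size for its test suite, with
the full-resolution path exercised by the acceptance run. The heavy model
grids (2000-tree forests, the 400/600/500 MLP) are exercised at reduced
settings in tests via explicit grid overrides; defaults remain the full
grids.

## Known limitations

* RI/NDI maps cost O(p²·n) with no closed form; very fine grids on large
  sample sets are the slowest step.
* CARS subset sizes depend on the weight concentration of the data; on
  near-rank-one synthetic spectra the algorithm can legitimately compress to
  a handful of bands, which is more aggressive than typical field results.
* The DNN family is an MLP approximation of the original dropout/L1
  configuration (see above).
* Metrics assume a non-degenerate validation set (n ≥ 2, positive observed
  variance); bootstrap uncertainty for the metrics is out of scope.
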