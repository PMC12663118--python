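# Methods

This note records the models, parameter choices and numerical decisions
behind `afbiomass`, and what the synthetic experiments do and do not show
about the method on real data.

## The estimation chain

The package estimates annual aboveground woody biomass density (AGBD,
Mg ha⁻¹) maps at 1 ha resolution and turns them into biome and continental
stock-change rates. The chain is: radar scene normalization → canopy
height model (CHM) → height-to-biomass conversion → significance-gated
change detection → backward series reconstruction → stock accounting →
plot validation. Each stage is a module with an explicit contract; the
pipeline module wires them together from a single validated configuration.

## Synthetic landscape: what it emulates

The generator (`synthdata`) produces a landscape with known truth so the
chain's statistical behaviour can be measured exactly.

* **Biomes.** A smooth random field thresholded at area quantiles yields
  blobby biome patches. Defaults: moist broadleaf forest (40 % area, mean
  300 Mg ha⁻¹, carrying capacity 450, growth 1.0 Mg ha⁻¹ yr⁻¹) and
  grassland/savanna (60 %, mean 32 Mg ha⁻¹ — the reported biome average —
  capacity 80, growth 0.4). Within-biome texture has CV 0.25.
* **Dynamics 2007–2017.** Undisturbed pixels grow by a per-pixel rate map,
  capped at carrying capacity. Each year, woody pixels (≥ 20 Mg ha⁻¹) are
  disturbed with probability 0.2 %/yr through 2010 and 1.5 %/yr after —
  the built-in sink-to-source transition — and a disturbance removes
  exactly 60 % of the pixel's biomass (logged, so detection can be scored).
* **Height–biomass truth.** h = h_max·(1 − exp(−AGBD/λ)) with h_max = 50 m,
  λ = 150 Mg ha⁻¹: invertible below saturation and saturating above
  ~350 Mg ha⁻¹, where real sensitivity is known to fade.
* **Radar.** HV = 0.08·(1 − exp(−0.01·AGBD)) + 0.003 in linear power on a
  50 m grid; HH shares the curve with higher amplitude and floor, so the
  polarisations are biomass-correlated. Speckle is multiplicative gamma
  noise with 64 equivalent looks — a 16-look 25 m mosaic aggregated to the
  50 m simulation grid. The moisture artefact is an additive field per
  year: a scene-wide random offset (SD 0.004) plus quarter-amplitude waves
  of wavelength ≥ 9 km. At continental scale moisture fronts are orders of
  magnitude larger than the ~2,000 ha normalization window; on a 12.8 km
  desk scene the faithful analogue is a near-uniform offset with a mild
  gradient, not a wave comparable to the window (which no windowed
  normalization could remove and no production scene would show).
* **Footprints.** Straight tracks, 25 m along-track spacing. rh100 = true
  height + N(0, 2 m); reported coordinates get N(0, 12 m) geolocation
  error (the first product version's error budget). Beam type (20 %
  coverage) and solar elevation (30 % daytime) are per-track orbit
  attributes; sensitivity (10 % below 0.95) and the quality flag (5 % bad)
  vary per footprint. Assigning beam/daytime per footprint instead would
  destroy almost every run of 4 consecutive survivors, which no clustering
  scheme could have survived.
* **Reference data.** Airborne-LiDAR patches are truth + N(0, 10 Mg ha⁻¹)
  at the 2016 acquisition year. Plots get an error SD of
  5 + 0.10·AGBD Mg ha⁻¹ (error growing with biomass, as in plot
  harmonisation error models), areas of 0.1–1 ha, and measurement years
  weighted 70 % towards 2007–2009, mimicking inventory archives.

Not emulated: orbital geometry and waveforms, terrain and incidence-angle
effects, de-striping, land-cover change, allometry error structure, and
any spatial correlation of plot errors. Passing tests therefore show that
the *inference chain* is correct and has the claimed statistical power
under these noise structures — not that a production run on real mosaics
would achieve the same accuracy.

## Stage-by-stage choices

### Normalization (`radar_prep`)

Circular disc kernel, 100 px diameter at 50 m (~1,963 ha); window moments
via FFT convolution; edges handled by renormalizing the kernel over valid
pixels. Statistics are computed on **linear power**, not dB (the indices
are power ratios and dB averaging biases means); dB↔linear converters are
provided at I/O. The baseline is the per-pixel mean of the 2007–2010
scenes (mean chosen over any single year for noise suppression). Windows
with zero SD pass through with a mean shift only and are counted. A
constant scene-wide artefact is removed exactly (closed form); the
normalization is exactly idempotent along that path, and only
approximately (about 1 %) for arbitrary scenes, because the window
statistics of a normalized scene are not identically the baseline's.
The 2011–2014 mosaic gap is enforced: configurations requesting radar for
those years are rejected rather than fabricated.

### Footprints

The 99.9th-percentile height cap is a linear-interpolation sample quantile
computed on the set surviving the instrument-quality rules, before the
land-cover rule (land cover is a semantic, not a quality, filter); a flag
switches the order. The cap is data-dependent, so re-filtering with a
fresh cap can trim up to 0.1 % more; passing the recorded cap makes the
filter exactly idempotent. Clusters are non-overlapping groups of 4
consecutive footprints anchored at the head of each run; leftovers are
discarded. The spatial k-fold regions are equal-count bands of the
Hilbert-curve ordering of cluster centroids: contiguous, deterministic,
sizes within 1.

### Height model

Each of the k = 10 members is a random forest (100 trees) trained on the
other 9 regions. Forests use `min_samples_leaf = 5` (the canonical
regression-forest node size): leaf-size-1 trees memorize individual
clusters, so a single geolocation-corrupted boundary cluster imprints
discontinuous spikes on the annual maps that masquerade as change.
All other hyperparameters are scikit-learn defaults, recorded in the
ensemble metadata. All k members predict every pixel; the mean is the
estimate and the sample SD (n−1 convention) the prediction error.

The fold spread only measures training-data variance. Where the radar
saturates, year-to-year prediction jitter is instead driven by radiometric
noise that all members see identically, so `predict_height` can propagate
input noise through the model by central differences: HH and HV perturbed
by one relative SD in opposite directions (the worst case for the ratio
indices), indices recomputed, and half the prediction swing added in
quadrature. The pipeline default is 6.25 % — the 16-look 25 m product
aggregated to one 100 m feature. Footprint measurement, sampling and
temporal-mismatch error components enter the same quadrature as flat
per-map SDs (defaults 0; independence assumed).

### Biomass model

OLS of √AGBD on CHM over a random 50 % calibration half; Snowdon's ratio
is computed on the same half (sums and means are equivalent), which makes
corrected predictions conserve the observed calibration total exactly — an
identity tested to 1e-9. A negative linear predictor is clamped to zero
before squaring (squaring would fabricate biomass from below-intercept
heights). The per-pixel SD combines the delta-method height term
|2·L·β₁·ratio|·sd_height with the back-transformed residual spread
2·|L|·residual_sd·ratio in quadrature; the exact production error formula
is not public, so this quadrature is the package's own documented scheme.

### Change detection

The SD-overlap rule is scale-invariant and antisymmetric in the two
dates. SDs entering the rule are the fully propagated map SDs (a flag
could switch to raw ensemble spread). Attribution ties (two equal largest
losses) go to the earliest year — deterministic and conservative. The
2010→2015 step across the mosaic gap is a single pairwise comparison;
inside the gap, reconstructed values are linear (flat apportioning) and
flagged `derived_only`. Mann–Kendall p-values use exhaustive permutation
enumeration for n ≤ 8 (tie-aware, cached by tie pattern — series here
have at most 7 usable years) and the tie-corrected normal approximation
with continuity correction above. Sen slopes below the 50 Mg ha⁻¹
saturation threshold are accepted at p < 0.05; above it, a user-supplied
per-biome IPCC mature-forest growth factor applies (pipeline defaults 0.5
and 0.3 Mg ha⁻¹ yr⁻¹ for forest and savanna; the source table prints no
values, so these are configuration, not constants).

### Consistent series and its uncertainty

The last map (2017) is the reference; walking backwards, each earlier map
subtracts the net significant change assigned inside the step and the
growth increment of undisturbed pixels, clamped at zero. Because every
year's map is the 2017 reference minus applied changes, the reference
error is common to all years and cancels in differences; the series SD
layers are therefore expressed **relative to the 2017 reference** (zero in
2017, accumulating the applied changes' SDs in quadrature going back).
Endpoint-SD quadrature in the period-rate CI then measures exactly the
uncertainty of the changes between the endpoints — which is what a
change rate's CI should carry; absolute-stock uncertainty would be added
separately if absolute stocks were the target. Backward-then-forward
reconstruction is the identity wherever clamping is inactive (tested).

### Accounting

Stock SD uses block quadrature: pixels fully correlated within 10 × 10
pixel (1 km) blocks, independent between blocks — pure pixel independence
grossly understates large-area uncertainty. The continental total is the
exact sum of biome totals. Percent rates are referenced to the final-year
continental stock. Carbon fraction defaults to 0.5 (0.47 available).

### Validation

Plots are shifted to the map year by per-biome linear growth (a simplified
temporal harmonisation; the full plot-error model is out of scope), then
aggregated to lattice cells: the global 0.1° graticule (11,132 m at the
equator) anchored at (0, 0), half-open with west/north edges inclusive.
On the 12.8 km demo landscape that yields ~4 cells, so the demo pipeline
uses a proportionally scaled 1,600 m cell (the library default remains
0.1°). R² is squared Pearson correlation by default — standard in
map-validation work — with the 1 − SSE/SST form always reported alongside.
RMSD² = MBD² + var(pred − ref) holds to 1e-9 by construction and is tested.

## Problem sizes and experiment design

The default landscape is 128 × 128 pixels at 100 m (16,384 ha): one full
pipeline run takes ~20 s, so the multi-seed experiments stay interactive.
Footprint density (400 tracks × 60 footprints) is set so the 10 % training
split holds ~200 clusters (~20 per spatial fold) — desk scale cannot
preserve both the mission's footprint density and its absolute training
count, and a stable fold forest needs the absolute number. The
sign-recovery experiment runs ten independent landscapes (seeds 1–10) and
requires the 2007–2010 rate positive, the 2015–2017 rate negative and
their 95 % CIs disjoint in at least nine; change-detection power
(recall ≥ 0.7, precision ≥ 0.9 for losses exceeding 3× the pixel SD, both
sides conditioned on that threshold) is pooled over the same ten runs, and
a zero-disturbance landscape bounds the false significant-loss rate at
0.5 % of pixels.

## Known limitations

* Radar saturation makes post-disturbance biomass in dense forest
  regress towards the mean, attenuating estimated losses by roughly a
  third to a half; per-landscape strong-loss recall varies (0.48–0.98
  across seeds) even though the pooled rate is ~0.8. The same physics
  implies real continental loss estimates are conservative at high AGBD.
* The fold-ensemble SD under-represents input-noise variance; the
  radiometric propagation recovers most but not all of it, and rare
  coherent prediction flips near forest decision boundaries can survive
  as false detections in unlucky realizations.
* The Hilbert-band spatial folds equalize counts, not autocorrelation;
  fold R² can vary widely (one region occasionally validates poorly).
* Uncertainty treats all error sources as independent Gaussians; the
  block-correlation length (1 km) and the growth increments' zero
  uncertainty are stated conventions, not estimates.
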