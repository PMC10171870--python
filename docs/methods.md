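# Methods

## The problem

Testing drug combinations by conventional titration needs one culture well
per regimen: three drugs at ten concentrations each (zero included) already
means `10^3` regimens before replicates. The stochastic-mixing approach
inverts this: a *single* sample is deliberately dosed non-uniformly by
point-injecting small pre-mixed volumes of drug plus fluorescent tag, so
that every cell receives its own random drug combination, recorded in its
retained tag intensities. Decoding per-cell barcodes then reconstructs the
entire dose–response surface from one dish.

`stochmix` implements both halves: a generative simulator of such
experiments, and the decoding pipeline (tile quantification, intensity
binning, ratio calibration, toxicity renormalization, response surfaces).

## Generative model

**Exposure fields.** A point injection is modelled as a static radial
Gaussian kernel of width `dispersion_scale` (μm) centred at the injection
site — the short-incubation idealization in which the initial forced
advection sets the concentration profile and later diffusion is neglected.
No transport PDE is solved; this is a deliberate non-goal. An optional
smooth multiplicative random surface (band-limited Gaussian noise,
correlation length half the dispersion scale, standardized to unit spatial
mean, relative amplitude `advection_jitter`) stands in for
injection-to-injection irregularity of the advection pattern. The paper
trail for the jitter amplitude is empty — it is a modelling choice, default
0. All agents of one injection share the *same* field array, exactly: that
shared dispersion is what makes an unconjugated tag a valid barcode for its
co-injected drug. Homogeneous (well-mixed) delivery is a constant field.

**Uptake.** Cell `i`'s uptake of agent `c` is
`u_ic = baseline + F_c(x_i) · η_ic`, with `η_ic` lognormal
(log-scale σ = `noise_sigma`, median 1), independent across cells and
agents. Single-time-point uptake is used as the proxy for integrated
exposure. The `baseline` floor stands in for background/autofluorescence;
experiments that need a bounded dynamic range (mesh binning on log axes)
use a small positive baseline (0.01–0.02 of peak dose). Suspension
cultures can be `reshuffle`d between sequential injections — a wash is a
uniform permutation of positions with accumulated uptake travelling with
the cell — which decorrelates sequentially delivered agents.

**Phenotype.** Three response kinds share per-drug Hill terms
`f_d(u) = 1 / (1 + (u/EC50_d)^h)`:

* `hill_survival` — survival probability `Π_d f_d`, Bernoulli life/death
  draw (the cytometry dead/live readout);
* `reporter_repression` — continuous reporter
  `base · Π_d f_d(u) · Π_c t_c(u)` with carrier-toxicity factors
  `t_c(u) = 1/(1+(u/τ_c)^2)` (the GFP-repression readout);
* `saturating_sensor` — monotone saturating function of total
  EC50-normalized dose.

Pairwise interaction coefficients `γ` act on log-dose:
`u_d → u_d · exp(γ Σ_e log1p(u_e/EC50_e))`. `γ = 0` reproduces Bliss
independence exactly; `γ < 0` is antagonism, `γ > 0` synergy. The source
material discusses interactions only qualitatively; this parameterization
was chosen because it is the simplest one whose null case is *exactly* the
additive reference the scorer uses, so classification tests are calibrated
by construction.

## Decoding pipeline

**Tiles.** Images are partitioned into square tiles (default 50 μm,
converted to whole pixels by flooring), each replaced by the mean of its
pixels per channel — an "effective pixel" averaging over a few cells. Edge
tiles keep their partial pixel sets and are flagged rather than dropped.
Lacunae (cell-free regions) are excluded by thresholding a reference
channel's tile means: absolute, quantile (default, 5%), or Otsu bimodal
split. The upstream work names the exclusion step but not its operator or
threshold; all three are exposed. Cell density maps report the covered
fraction of non-overlapping square windows, default area 10^4 μm².

**Binning.** 1D: cells stably sorted by a tag, grouped into runs of
exactly `r` cells (partial tail dropped, so equal-`n` bins keep SD
comparisons honest); by the Law of Large Numbers the SD of bin means of an
independently noised channel falls as `1/√r`. A centered moving average
(shrunken ends) is the dimensionality-preserving alternative. 2D: an
equal-width mesh (default 8×8 on log10 intensity) with a 30-cell occupancy
floor; under-occupied bins are merged into the nearest occupied centroid
(count-weighted moment pooling) or optionally dropped. Hierarchical
barcode clustering (average linkage, Euclidean on standardized log10
intensities) is provided for multi-drug barcodes; the linkage and scaling
are package choices — only the clustering family is given upstream.

**Calibration.** Ratios `R_i = tag_i / auxiliary` cancel global gain and
shared volume-like uptake factors; dividing by the homogeneous control's
population mean `R_ih` gives relative concentration, and the control's
known molarity (defaults {NC: 1, CP: 1, TXT: 0.1} μM) converts to absolute
units. Tag→drug calibration is OLS on coarse-grained bin means with
confidence and prediction bands (statsmodels). A `scale="log"` option fits
log10 bin means: a proportional relation has log–log slope exactly 1, and
this scale is immune to the regression dilution that multiplicative tag
noise causes on the linear scale (with σ = 0.3 the linear-scale population
slope is biased low by up to `1 − e^{−σ²}` ≈ 9% no matter how many cells
are averaged — a property of the estimand, not of the estimator).

**Toxicity renormalization.** The carrier-only control surface is fitted
by mean-centered RBF kernel ridge regression on the bins' log10 tag
coordinates, count-weighted, with bandwidth and ridge chosen by K-fold
cross-validation. Predictions are clipped positive; treated bins outside
the control's convex hull are flagged `extrapolated` and should not be
interpreted. Normalized phenotype = treated bin mean / predicted control
surface; 1 means no effect beyond carrier toxicity.

**Interaction scoring.** The Bliss reference for bin `(ix, iy)` is
`f(ix, iy₀) · f(ix₀, iy) / f(ix₀, iy₀)`, with marginals read from the
surface's own lowest occupied mesh row and column. Excess inhibition is
`log(reference) − log(observed)` on the fraction-remaining phenotype
(positive = stronger than Bliss = synergy), classified at a stated
tolerance (default 0.1 in log units); the run-level call is the
count-weighted mean excess over interior (joint-dose) bins. If the
double-low anchor bin is unoccupied the summary raises a not-identifiable
error rather than guessing.

**Time courses.** Per sample (compartment × harvest time), calibrated
concentrations are reported with error bars from random partitioning of
the population into groups of 100 cells (or a fixed number of groups,
e.g. 3), the SD of group means treated as independent measurements.
Pairwise per-cell dose distributions are normalized 2D histograms on log
axes.

## Canonical synthetic experiments

`stochmix.experiments` freezes the study conditions used by the tests and
the acceptance script: a 2×2 mm adherent chamber at 10 μm/pixel, 10^4
cells (5×10^3 for the two-pair correlation study, 2×10^4 for combination
surfaces, 8×10^3 for the death time course), uptake noise σ = 0.3
(σ = 0.5 where the noise distribution itself is under study), corner
injections with dispersion 400–800 μm, EC50s at roughly a third of peak
dose, baseline uptake 1–2% of peak. Sizes were chosen to keep the full
suite and the acceptance script in the seconds-to-minutes range while
leaving comfortable statistical margins.

What the generator deliberately does **not** emulate: time-dependent
transport (fields are static), cell division and migration, optical
point-spread functions and spectral overlap, photobleaching, saturation of
uptake, and sample-to-sample (extrinsic) variability beyond what the
distortion field induces. Passing tests therefore demonstrate that the
decoding machinery recovers what this idealized generative process
encodes; they do not certify performance on real imaging data, where
segmentation quality, spectral compensation and delivery kinetics add
error modes the simulator excludes by design.

## Numerical choices

* Coordinates: pixel `(row, col)` centre at `(col·px, row·px)` μm, origin
  top-left, row-major, 0-based; cells sample fields at the nearest pixel.
* Sorting is stable everywhere; ties keep input order (determinism).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived seeds use `SeedSequence` and stay
  below 2^31. Equal config + seed reproduces every CSV byte for byte.
* Mesh merging terminates because each step removes one bin; pooled SDs
  use exact two-group moment composition.
* Zero-variance channels in correlation matrices yield flagged-undefined
  entries, not NaN contagion; non-positive values under log scales are
  excluded with counts reported, never imputed.
* Event CSVs store intensities with 6 significant digits; float32 TIFF
  round-trips bitwise, with pixel size and channel names in a JSON
  sidecar.

## Known limitations

* The linear-scale tag→drug fit inherits the attenuation described above;
  use the log–log fit (or report both) when the proportionality constant
  matters.
* The interaction score needs occupied low-dose edges; delivery layouts
  whose tag distributions are strongly anti-correlated over many decades
  may lack the double-low anchor (the adjacent-corner layout in
  `combination_experiment` is chosen to provide it).
* Kernel-ridge toxicity surfaces are smooth interpolators: sharp toxicity
  cliffs would be smoothed, and extrapolation outside the control hull is
  flagged but not prevented.
* FCS support is read-only and list-mode (datatypes F/D/I); the bundled
  writer exists solely to generate fixtures.
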