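# stochmix

Single-sample stochastic drug mixing: simulate point-injection barcoded
drug-combination experiments and decode them back into dose–response.

## The idea

Screening drug combinations by ordinary titration needs one well per
regimen — three drugs at ten concentrations each is already
`10³ = 1000` wells. Stochastic mixing collapses this into one sample: each
drug is pre-mixed with an unconjugated fluorescent tag and point-injected
into the culture, so the transient dispersion field gives every cell its
own random drug combination, *recorded* in the cell's retained tag
intensities. Because drug and tag share the same dispersion field, tag
intensity is a per-cell barcode of drug exposure — no chemical conjugation
required. Decoding proceeds by coarse graining: averaging cells over
tag-ordered bins (or pixels over ~50 μm tiles) suppresses intrinsic
cell-to-cell uptake noise by the Law of Large Numbers, after which

* a linear fit of binned drug vs. tag intensity calibrates the barcode
  (`R² ≈ 1` on simulated co-delivery),
* ratios `Rᵢ/Rᵢₕ` against an auxiliary volume dye and a homogeneously
  dosed control convert intensities to absolute concentrations (μM),
* a cross-validated 2D regression of a carrier-only control removes
  carrier (quantum-dot) toxicity from the phenotype, and
* 2D tag-intensity bins (≥30 cells each) assemble the normalized
  phenotype into a two-drug response surface, scored against a Bliss
  independence reference for antagonism/synergy.

The package ships a full generative simulator (Gaussian dispersion
kernels, shared fields for co-injected agents, lognormal multiplicative
uptake noise, Hill phenotypes with tunable interactions, carrier
toxicity, disk-rendered images), so the whole pipeline is testable
without any external data.

## Worked example

Calibrate a conjugation-free barcode on a simulated corner injection of a
pre-mixed (tag, drug) pair — 10⁴ cells, uptake noise σ = 0.3, true
proportionality 1:

```python
import stochmix as sx

cells = sx.codelivery_experiment(seed=7, n=10_000)

rho = sx.correlation_matrix(cells, ["tag", "drug"])
print("single-cell rho:", round(rho[("tag", "drug")], 3))

bins = sx.ordered_binning(cells, "tag", r=50)          # 200 bins of 50 cells
fit = sx.fit_tag_drug(bins, "tag", "drug", scale="log")
print(f"log-log slope: {fit.slope:.3f}  R^2: {fit.r_squared:.4f}  bins: {fit.n_bins}")

mean, sd = sx.population_mean_with_error(cells, "drug", partition_size=100, seed=0)
print(f"population drug uptake: {mean:.4f} +/- {sd:.4f} (a.u.)")
```

```
single-cell rho: 0.904
log-log slope: 0.995  R^2: 0.9998  bins: 200
population drug uptake: 0.0646 +/- 0.0166 (a.u.)
```

The single-cell correlation of 0.90 is what the shared dispersion field
buys before any coarse graining; binning 50 cells at a time averages the
multiplicative noise away, and the fitted log–log slope of 0.995 recovers
the true tag→drug proportionality (exponent 1) to half a percent. The
error bar on the population mean is the SD of means of random 100-cell
groups.

There is also a CLI over the same stages:

```sh
stochmix run --config demo.yaml --seed 2 --out out/   # simulate -> bin -> surface
stochmix tiles --image field.tiff --tile-um 50 --lacunae quantile:0.05 --out out/
stochmix bin --events out/events.csv --mode ordered --order-by tag --r 50 --out bins.csv
```

Every run directory contains the resolved config and seed; identical
config + seed reproduces every output byte for byte.

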