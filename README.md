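# phytoscale

Metabolic-scaling analysis of phytoplankton community metabolism, as a tested,
reusable pipeline. The package simulates or ingests individual cell-size
distributions and oxygen-flux measurements, fits the size- and
temperature-dependence of gross primary production (GPP) and community
respiration (CR) by maximum likelihood, and tests the two headline scaling
predictions:

1. **Proportionality** — temperature-corrected community rate is directly
   proportional to mass-corrected biomass (log–log SMA slope 1).
2. **Metabolic compensation** — total abundance trades off against average
   individual metabolic rate under a zero-sum community energy budget
   (log–log SMA slope −1).

## Model

Individual metabolic rate: `b_i(T) = b(Tc) · m_i^α · exp(E·(1/(k·Tc) − 1/(k·T)))`
with mass `m_i` (µg C), size-scaling exponent `α`, activation energy `E` (eV),
`k = 8.62×10⁻⁵ eV K⁻¹` and reference temperature `Tc = 291.15 K` (18 °C).
Community rate is the per-litre sum over all individuals. Fitting is Gaussian
maximum likelihood on the natural-log rate; conditional on `α` the predictor is
linear in `ln b(Tc)` and `E`, so the seeded multistart runs over `α` alone
(identical maximum, better conditioning). Confidence intervals are
profile-likelihood intervals at the χ²₁ 95% cutoff.

> **Temperature-correction sign convention.** Corrected rate = observed rate
> **divided** by `exp(E·(1/(k·Tc) − 1/(k·T)))`. Multiplying (a plausible
> reading of the rearranged balance identity) would inflate warm-assay rates
> instead of removing the direct temperature effect; with division a
> noise-free model rate corrects exactly onto mass-corrected biomass.

## Modules

| module | what it does |
| --- | --- |
| `phytoscale.core` | forward model: Boltzmann factor, Q10, individual/community rates, mass-corrected biomass, temperature correction |
| `phytoscale.simulate` | synthetic 2×2×10 warming experiment: lognormal size distributions, model-generated rates, zero-sum abundance, ASV tables |
| `phytoscale.picurve` | Eilers-type photosynthesis–irradiance curves; multistart least squares, lowest-AIC fit; GPP at saturation, dark respiration |
| `phytoscale.inference` | concentrated ML fit, treatment-split model comparison by likelihood-ratio test, profile CIs |
| `phytoscale.sma` | standardised major axis regression, slope tests, bootstrap CIs, the two headline tests |
| `phytoscale.sizes` | forward scatter → diameter → biovolume → carbon; heterotroph biomass fraction; ISD summaries |
| `phytoscale.composition` | rarefaction, Bray–Curtis, PCoA, sequential-SS two-factor PERMANOVA (all first principles) |
| `phytoscale.pipeline` / `phytoscale.cli` | end-to-end orchestration with seeded determinism, manifest, report |

The headline tests default to a bootstrap over *communities* that refits the
ML model inside every replicate ("data and model"), so parameter-estimation
uncertainty is propagated into the slope intervals; `bootstrap="cases"`
selects a plain point-level resample.

## CLI

```bash
phytoscale simulate --seed 1 --outdir sim           # synthetic dataset
phytoscale sizes cytometry.csv --out masses.csv     # FSC/diameter -> µg C
phytoscale fit-pi sim/pi_curves.csv                 # light-response fits
phytoscale fit-mst sim/communities.csv sim/masses.csv --flux gpp
phytoscale scaling sim/communities.csv sim/masses.csv
phytoscale compose sim/asv_counts.csv sim/sample_meta.csv
phytoscale run --config examples/config.yaml --outdir results
phytoscale report results
```

Exit codes: 0 ok, 2 configuration error, 3 data error, 4 convergence failure.
`run` emits `manifest.json` (package version, per-stage seeds, SHA-256 of all
inputs/outputs); re-running the same config reproduces outputs byte-for-byte.

## Data formats

All I/O is plain CSV/JSON; see `docs/data_dictionary.md` for every column.
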