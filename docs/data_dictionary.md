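# Data dictionary

All tables are UTF-8 CSV with a mandatory header row, comma separator, "."
decimal; floats are serialised at 12 significant digits.

## communities.csv (one row per microcosm)

| column | type | meaning |
| --- | --- | --- |
| community_id | str | unique microcosm label |
| mesocosm | str | source mesocosm label (shared by its two incubator replicates) |
| mesocosm_treatment | {ambient, warm} | long-term warming treatment of the source mesocosm |
| incubator_treatment | {ambient, warm} | short-term assay treatment |
| incubator_t | float, K | assay temperature |
| n_cells | int | number of recorded individuals in masses.csv |
| scale_to_litre | float | multiplier converting the recorded cell list to per-litre abundance |
| n_tot | float, cells L⁻¹ | total abundance = n_cells × scale_to_litre |
| gpp_obs | float, µmol O₂ L⁻¹ h⁻¹ | observed gross primary production (blank until flux extraction) |
| cr_obs | float, µmol O₂ L⁻¹ h⁻¹ | observed community respiration |

## masses.csv (long format)

| column | type | meaning |
| --- | --- | --- |
| community_id | str | joins to communities.csv |
| mass_ug_c | float, µg C | carbon mass of one recorded individual |

## pi_curves.csv (light-response observations)

| column | type | meaning |
| --- | --- | --- |
| community_id | str | joins to communities.csv |
| irradiance | float, µmol photons m⁻² s⁻¹ | light level (0 allowed) |
| o2_flux | float, µmol O₂ L⁻¹ h⁻¹ | net oxygen flux (negative = consumption) |
| is_dark | bool | True for the dark respiration measurement |

## cytometry event tables (input to `phytoscale sizes`)

| column | type | meaning |
| --- | --- | --- |
| community_id | str | microcosm label |
| population | {autotroph, heterotroph} | pre-labelled population |
| fsc *or* diameter | float | forward scatter (instrument units) or diameter (µm); exactly one of the two columns must be present |

## asv_counts.csv / sample_meta.csv

`asv_counts.csv`: first column `sample_id`, then one non-negative integer
column per taxon. `sample_meta.csv`: `sample_id`, `mesocosm_treatment`,
`incubator_treatment`.

## truth.json (simulator output)

Generating parameters per flux (`ln_b_tc`, `alpha`, `activation_energy`,
`sigma`, `t_ref`), the zero-sum energy budget, noise SDs and the seed.

## Pipeline outputs

- `pi_fits.csv` — per-community curve parameters (`p_max`, `i_opt`, `s`,
  `r_d`), extracted `gpp`/`cr`, RSS, AIC, convergence diagnostics.
- `mst_fit.json` — per-flux ML estimates, σ, log-likelihood, AIC, 95% profile
  CIs, model label.
- `model_comparison.csv` — likelihood-ratio rows per candidate treatment
  split (statistic, df, p, AICs, preferred model).
- `scaling_results.json` — SMA slope/intercept/R², slope-test (b0, r, df, p),
  bootstrap CIs for the proportionality (GPP, CR) and compensation (GPP)
  tests.
- `corrected_rates.csv` — tidy per-community plotting table:
  mass-corrected biomass and temperature-corrected rate per flux, average
  individual GPP, abundance, biomass, treatments.
- `distances.csv`, `pcoa.csv`, `permanova.json` — composition stage outputs.
- `manifest.json` — package version, per-stage seeds, SHA-256 hashes of all
  inputs and outputs.
- `report.txt` / `report.json` — human-readable and machine-readable summary.
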