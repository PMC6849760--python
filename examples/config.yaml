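# Full-pipeline configuration: simulate a 2x2x10 experiment and analyse it.
# Replace the `simulation` block with `simulation: null` plus communities_csv/
# masses_csv/pi_csv/asv_csv/sample_meta_csv paths to analyse real tables.
outdir: results
seed: 1
t_ref: 291.15

simulation:
  n_mesocosms_per_treatment: 10
  n_cells: 2000
  noise_sd: 0.3
  abundance_noise_sd: 0.15

rates_source: pi        # "pi" fits light curves; "observed" uses gpp_obs/cr_obs
n_starts_pi: 200
n_starts_mst: 50
n_boot: 1000
n_perm: 9999
min_reads: 1000
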