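# Small end-to-end demonstration dataset: 60 proteins, 2 fractions,
# peptide-level quantification exercised, reduced chain length.
outdir: smoke_out
seed: 20
q_threshold: 0.01
peptide_level: true
sim:
  n_proteins: 60
  effect_null_fraction: 0.8
  alpha_sd: 0.5
  gamma_sd: 0.3
  noise_sd: 0.15
  detection_quantile: 0.2
  qualitative_fraction: 0.05
  peptide_dispersion: 0.15
  seed: 20
mcmc:
  iterations: 3000
  burnin: 500
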