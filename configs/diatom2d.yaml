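# Two-parameter diatom calibration on synthetic forcing: mu0 and
# k_light are sampled, the remaining parameters held at the generating
# values; Gaussian cost with sigma_chl = 5 ug chl/L and truncated
# Cauchy priors; observations every third day at noon.
study: diatom2d
seed: 0
outdir: runs/diatom2d
calibrate_params: [mu0, k_light]
sigma_chl: 5.0
every_third: true
synthetic:
  start: "2001-04-01"
  end: "2001-10-31"
mcmc:
  n_chains: 2
  n_steps: 800
  n_warmup_runs: 2
  warmup_steps: 120
  target_acceptance: 0.35
analysis:
  nbins: 10
  no_log: [f_si]
graph:
  margin: 2.0
  nbins: 10
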