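# Toy calibration study: y(t, x) = x1 * sin((t - x2)^3), flat prior on
# (0, 2)^2, Gaussian noise 0.05.  Set toy.zeta_free: true for the
# hierarchical fractional-norm likelihood, delayed_acceptance: true for
# the GP+KL accelerated sampler.
study: toy
seed: 0
outdir: runs/toy
toy:
  sigma: 0.05
  n_points: 200
  zeta: 2.0
  zeta_free: false
delayed_acceptance: false
mcmc:
  n_chains: 2
  n_steps: 2000
  n_warmup_runs: 3
  warmup_steps: 200
  target_acceptance: 0.35
surrogate:
  n_init: 32
  n_iter: 12
  kl_tol: 1.0e-4
analysis:
  nbins: 10
  no_log: [x1, x2, zeta]
graph:
  margin: 2.0
  nbins: 10
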