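# phytocal

Bayesian calibration and posterior dependence analysis of a Lagrangian
riverine diatom model.

## The problem

Simple mechanistic water-quality models are routinely calibrated
against a single observed variable — here, chlorophyll-a at a river
monitoring station — and even a six-parameter model turns out to be
overparameterized: many different parameter combinations fit the data
equally well (*equifinality*). `phytocal` implements the full workflow
for diagnosing and exploiting this structure:

1. **Process model.** Water parcels released at an upstream boundary
   drift for a discharge-dependent travel time
   τ = τ_ref (Q_ref / Q)^(1/3) and act as closed biological reactors:

       dC_chl/dt = (μ − σ) C_chl,        dC_Si/dt = −μ f_Si C_chl,

   with growth μ = μ0 · F_light · F_Si limited by the depth-averaged
   Smith light factor (with algal self-shading λ = λ_S C_chl) and a
   Michaelis–Menten silica factor C_Si/(K_Si + C_Si), and a loss rate
   σ = σ0 below 20 °C and σ0·a^(T−20) above. Six parameters
   (μ0, λ_S, K_light, f_Si, σ0, a) are calibrated.
2. **Inference.** A Gaussian cost function (or a hierarchical
   fractional-norm ℓ_ζ likelihood whose norm order ζ is itself
   sampled), heavy-tailed truncated-Cauchy priors whose scales are set
   so that P(θ_k < θ_k\*) = 0.9, and Metropolis–Hastings sampling with
   reflection at zero, per-parameter proposal tuning to ~35%
   acceptance, and Gelman–Rubin / autocorrelation diagnostics.
3. **Acceleration.** Delayed-acceptance MCMC: a function-valued
   surrogate — Karhunen–Loève (functional-PCA) reduction of the model's
   output curves with one Matérn-5/2 Gaussian process per retained
   weight — screens proposals cheaply; survivors are corrected with the
   exact posterior, so the stationary distribution is unchanged while
   full-model evaluations drop to roughly the stage-one pass rate
   (~1/3). Bayesian global optimization (expected improvement over a
   Sobol design) concentrates the training set near the posterior mode.
4. **Posterior structure.** Marginal and conditional marginal
   histograms, PCA/EOF of the parameter correlation matrix with the
   effective dimension dof = M²/Σλ_k², Gaussian graphical models fitted
   by iterative proportional fitting with deviance-based edge pruning
   (EED/EID scores), and a discrete Bayesian network with conditional
   probability tables and exact evidence propagation.

Everything runs on synthetic data: a generator emulates seasonal
forcing (radiation, temperature, discharge, boundary silica) and noisy
observations, plus the closed-form toy blackbox
y(t, x) = x1·sin((t − x2)³) used to validate the samplers.

## Worked example

Calibrate the toy blackbox against noisy data (reference parameters
(1.15, 1.4), noise 0.05) and check mixing:

```python
import numpy as np
from phytocal.synthetic_data import ToyConfig, generate_toy_data, toy_model
from phytocal.inference import BoxPrior, LikelihoodSpec, make_log_posterior
from phytocal.sampling import MCMCConfig, run_mh, autocorr_length

cfg = ToyConfig()                       # 200 t-points on [0, 3], sigma = 0.05
t, y = generate_toy_data(cfg, seed=42)
log_post = make_log_posterior(
    lambda x: toy_model(t, x), y, LikelihoodSpec(sigma=cfg.sigma), BoxPrior()
)
mc = MCMCConfig(n_chains=1, n_steps=10_000, n_warmup_runs=5, warmup_steps=500, seed=7)
chain = run_mh(log_post, mc, prior=BoxPrior())[0]
print("mean :", chain.samples.mean(axis=0))
print("sd   :", chain.samples.std(axis=0))
print("tau  :", [round(autocorr_length(chain.samples[:, k]), 1) for k in range(2)])
```

prints

```
mean : [1.14352229 1.40042529]
sd   : [0.13169678 0.02826374]
tau  : [4.7, 5.1]
```

— the posterior mean recovers the generating amplitude 1.15 well within
one posterior standard deviation, the shift parameter 1.4 almost
exactly, and the tuned chain decorrelates within a few steps.

The full study pipelines are configuration driven:

```bash
phytocal run-all --config configs/toy.yaml --seed 1 --outdir runs/toy
phytocal run-all --config configs/diatom2d.yaml --seed 1 --outdir runs/diatom2d
```

Each run writes chains, acceptance/evaluation bookkeeping, marginal
histograms, PCA/EOF tables, the pruned graphical model, the Bayesian
network, and a manifest with content hashes under the output directory.
Set `delayed_acceptance: true` (or use the `surrogate` verb) to run the
GP+KL-accelerated sampler, and `toy.zeta_free: true` for the
hierarchical ℓ_ζ noise model.

## Layout

| Module | Contents |
| --- | --- |
| `phytocal.process_model` | forcing container, parcel ODEs, RK4 simulator |
| `phytocal.synthetic_data` | forcing/observation generators, toy blackbox |
| `phytocal.inference` | Cauchy/box priors, Gaussian cost, ℓ_ζ likelihood |
| `phytocal.sampling` | MH, proposal tuning, delayed acceptance, diagnostics |
| `phytocal.surrogate` | GP regression, noise estimation, EI/Bayesian optimization, KL expansion |
| `phytocal.posterior_analysis` | marginals, conditionals, PCA/EOF, dof |
| `phytocal.graphical` | partial correlations, IPF, edge pruning, Bayesian network |
| `phytocal.pipeline` / `phytocal.cli` | configuration-driven orchestration |

See `docs/methods.md` for the modeling assumptions, numerical choices
and known limitations.
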