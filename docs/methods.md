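# Methods

This note records the models, numerical choices and limitations behind
`phytocal`, in the order of the pipeline.

## Lagrangian process model

A parcel released at the upstream boundary at time t_a − τ arrives at
the observation station at t_a. Travel time depends only on discharge,
τ = τ_ref (Q_ref/Q)^(1/3) with τ_ref = 10 d at Q_ref = 270 m³/s;
discharge is read at the arrival time, and so is the water depth D used
for light averaging (constant per trajectory). The state equations are

    dC_chl/dt = (μ(t) − σ(t)) C_chl
    dC_Si/dt  = −μ(t) f_Si C_chl

with μ = μ0 F_light F_Si. F_light is the depth average of the Smith
saturation I e^{−λz} / sqrt(K_light² + I² e^{−2λz}) with self-shading
λ = λ_S C_chl; the average has the closed form
(asinh(I/K) − asinh(I e^{−λD}/K)) / (λD), which the implementation uses
(a quadrature route is kept for cross-checking — both agree to 1e-8).
F_Si = C_Si/(K_Si + C_Si) with K_Si fixed at 0.1 mg Si/L, so growth is
halved when silica falls to 0.1 mg Si/L. The loss rate is σ0 below the
20 °C threshold and σ0 a^{T−20} at or above it (continuous at the
threshold, temperature as daily means).

Initial conditions: C_chl = 10 µg/L for every parcel (overwritten
within days by growth/loss), C_Si = max(boundary silica at release,
2 mg Si/L). Optional exclusion windows (1–2-week calendar intervals)
zero the silica equation's right-hand side while the growth limitation
keeps using the frozen silica value.

**Units of f_Si.** f_Si multiplies chlorophyll (µg chl/L) and depletes
silica (mg Si/L), so its unit here is mg Si per µg chl. Literature
ratios quoted per unit carbon convert by the C:chl mass ratio; at
C:chl ≈ 40 and Si:C ≈ 0.8 g/g this gives ≈ 0.02 mg Si/µg chl, which is
the synthetic-truth default.

**Integration.** Classical RK4. Forcing is hourly, interpolated
linearly; the stiffness is mild, so a 1 h step is the default. Each
trajectory uses n = round(24τ/dt) equal steps so it lands exactly on
the arrival time. States are clipped at zero after every step — the
silica equation has no source term and would otherwise overshoot
negative when C_Si ≈ 0. The clipping makes the arrival concentration
only first-order accurate in the step for trajectories that exhaust
silica; away from that regime the scheme shows the expected high-order
error decay (hourly step within 1e-3 of a 0.01 h reference). The
depth–discharge relation is site specific and unpublished; the package
accepts polynomial coefficients and defaults to a power-law fit
D = 0.4 Q^0.35 (≈ 2.8 m at 270 m³/s, ≈ 4 m at 730 m³/s).

All per-trajectory forcing is precompiled once (`SeriesSimulator`), so
repeated evaluation at new parameters — the MCMC inner loop — is pure
array arithmetic, ~25 ms for a season of daily arrivals.

## Synthetic data

The forcing generator produces hourly radiation (seasonal daily peak ×
diurnal half-sine × daily lognormal cloud factor), daily-mean
temperature (seasonal cosine peaking near July 20 + AR(1) noise;
defaults put ~3 months above the 20 °C threshold so the hot loss branch
is exercised), discharge (mean-reverting daily log-walk around
270 m³/s) and boundary silica (spring-high/summer-low cosine).
Observations are model output at daily-noon arrivals (optionally every
third day) plus i.i.d. Gaussian noise, σ_chl = 5 µg chl/L by default.
Every generator is a pure function of (config, seed).

What the generator does **not** emulate: tributary loads, dispersion,
observation gaps, non-Gaussian sensor error, inter-annual regime
changes, and any correlation between forcing variables beyond their
seasonal cycles. Passing tests therefore demonstrate correctness of the
algorithms under the stated noise model, not skill on real river data.

The toy blackbox y(t, x) = x1 sin((t − x2)³) uses reference values
(1.15, 1.4), noise 0.05 and — a free choice, since only the model and
noise level are prescribed — 200 equispaced t-points on [0, 3], which
covers both the flat region near t = x2 and the fast oscillations at
larger t.

## Priors, cost and likelihood

Each parameter gets an independent half-line Cauchy prior
p(θ) = (2/π) b/(b² + θ²) with b = θ\*/tan(πP\*/2), so the CDF reaches
P\* = 0.9 at the stated plausibility bound θ\*
(defaults 3.5, 0.05, 500, 0.4, 2.0, 2.0 in the parameter order
μ0, λ_S, K_light, f_Si, σ0, a). The Gaussian cost

    J = 1/(2Nt) Σ (f_i − d_i)²/σ_chl² − Σ_k log p(θ_k)

serves directly as the negative log-posterior. The hierarchical
alternative uses the ℓ_ζ likelihood
p(d|θ,ζ) = exp(−ℓ)/(2·2σ·Γ(1+1/ζ)) with
ℓ = 1/Nt Σ |(f_i−d_i)/(2σ)|^ζ; the normalization is added once per
evaluation (the loss itself is already averaged over Nt), and ζ, when
free, carries a Gaussian prior (mean 2, sd 0.5) truncated to ζ > 0.
Both formulations deliberately average the misfit over the series
length; at ζ = 2 they coincide up to a constant when σ_chl = √2 σ.

## Sampling

Metropolis–Hastings with diagonal Gaussian proposals; positivity is
enforced by reflecting negative proposals (|θ'|), which preserves
proposal symmetry and detailed balance. Updates are coordinate-cycled
by default (matching per-parameter acceptance bookkeeping); warmup runs
5 rounds of 500 iterations, rescaling each coordinate's step by
exp(1.5·(acc − 0.35)) after every round — any standard
stochastic-approximation rule targeting 35% works; this one was chosen
for monotone, bounded per-round corrections — and freezes the scales
before sampling. Starts are drawn from the prior.

Delayed acceptance screens each proposal with the surrogate posterior
(plain MH ratio), evaluates the true posterior only for survivors, and
accepts with min(1, [p(θ')/p(θ)]·[p̃(θ)/p̃(θ')]); the surrogate is
never refined during sampling (doing so would break detailed balance).
Counters record proposals, stage-one passes and full-model evaluations,
so the evaluation economy is read off the chain object.

Diagnostics: Gelman–Rubin potential scale reduction across chains, and
integrated autocorrelation time via Geyer's initial-positive-sequence
pairwise windowing (white noise → ~1, AR(1) with ρ → (1+ρ)/(1−ρ)).

The toy posterior is not perfectly unimodal for every noise
realization: the cubic phase makes shifted x2 values weakly supported,
and an occasional chain lingers there, inflating its empirical
autocorrelation time severalfold. Summaries over several independent
chains therefore use the per-parameter median.

## Surrogate

GP regression is scikit-learn's `GaussianProcessRegressor` with a
Constant × Matérn-5/2 (or squared-exponential) kernel plus a white
noise term, maximum-likelihood hyperparameters by multi-start L-BFGS,
and a linear mean model fitted by least squares and subtracted before
the GP (predictions add it back). Predictive variance excludes the
fitted observation noise (latent-function variance); tiny negative
floating-point residues are clipped.

Noise estimation fits a squared-exponential GP with free timescale to a
series and reports the ML white-noise standard deviation — the
procedure that sets σ_chl from data alone without trusting the process
model.

Bayesian optimization minimizes the scalar L2 cost: a scrambled Sobol
design over the prior box, then expected-improvement acquisitions
(closed form, minimization orientation: the improvement is
f_best − f̄(x); the acquisition maximizes over a fresh Sobol candidate
set each iteration). All evaluated points seed the surrogate training
design.

The Karhunen–Loève expansion eigendecomposes the N×N collocation matrix
A_ij = ⟨f_i, f_j⟩ under the 1/Nt-weighted discrete inner product
(efficient when grid points outnumber snapshots; the nonzero spectrum
equals the grid-space covariance route's). Snapshots are mean-centered
(standard functional PCA; the mean is restored on prediction), basis
functions are snapshot combinations normalized to ⟨φ_i, φ_j⟩ = δ_ij,
and truncation keeps components with λ_k/λ_1 ≥ 1e-4 by default, the
ratio that bounds the relative L2 reconstruction error. Tail
diagnostics report the exact tail sum, the crude (N−r)λ_r bound, the
log–log fitted decay exponent α and the decay-model estimate λ_r ζ(α)
(flagged divergent for α ≤ 1; it is an order-of-magnitude estimate, not
a sharp bound).

The function-valued surrogate carries one GP per retained KL weight;
its predictions enter the *exact* likelihood and prior, so auxiliary
likelihood parameters (ζ) are handled analytically and only the forward
map is approximated. A compiled fast path evaluates all component means
with shared distance computations (identical to the reference
predictions to float precision) so delayed acceptance runs at ~2 kHz.

## Posterior analysis

Histograms use 10 equal-range bins over each column's unconditioned
[min, max] with half-open (A, B] bins, and conditional histograms reuse
the unconditioned range so shapes are directly comparable.
PCA/EOF analysis works on the correlation matrix of log-transformed
draws (all parameters except f_Si, whose posterior is roughly
symmetric) — correlation, not covariance, to remove physical units. The
effective dimension is dof = (Σλ)²/Σλ² = M²/Σλ² ∈ [1, M]; this
spread-of-spectrum form is used because it is permutation invariant,
equals M exactly for a flat spectrum and 1 for a rank-one posterior.

## Graphical models

Partial correlations come from the inverted correlation matrix,
Sp_ij = −P_ij/√(P_ii P_jj); zeros of Sp and of the precision matrix
coincide, so missing GGM edges are zero partial correlations. The
constrained MLE V for a given edge set is computed by iterative
proportional fitting in Speed–Kiiveri form: cycle over the maximal
cliques, updating the precision on each clique by S_CC⁻¹ − (V_CC)⁻¹
until the clique marginals match. Off-clique precision entries are
never touched, so fitted partial correlations vanish *exactly* on
missing edges and clique correlations reproduce the sample values.
Model fit is the deviance dev = N ln(|V|/|S|); single-edge scores are
the deviance increment of excluding one more edge (EED) or
re-establishing a removed one (EID).

Pruning is greedy backward elimination: repeatedly remove the
smallest-EED edge while that EED is strictly below
max(eed_floor, margin × largest EID of the removed edges), with
margin = 2 and eed_floor the 99.9% χ²(1) quantile (≈ 10.8) by default.
The floor encodes "a single-edge restriction this cheap is statistical
noise" and makes the automated rule robust: consecutive order
statistics of χ²(1)-scale scores easily differ by more than the margin,
so a margin-only rule can stop arbitrarily early on pure-noise data.
Setting margin = 0 and eed_floor = 0 keeps the saturated graph. At
N = 1e5 the rule recovers a known 5-node structure in ≥ 9/10 seeded
replicates and returns the empty graph on independent data.

The Bayesian network orients the undirected edges along a user-supplied
node ordering (earlier → later; acyclic by construction), discretizes
each node into 10 equal-range bins, and fits conditional probability
tables with a pseudo-count of 1 (avoids zero rows in sparse parent
configurations); nodes are limited to 3 parents by default to keep CPTs
tractable. Queries run exact variable elimination; without evidence
they reproduce the fitted marginals, and conditionals agree with direct
sub-sampling of the draws to total-variation distance < 0.1 on
correlated, skewed sample sets. No causal reading is attached to edge
directions — the nodes are calibration parameters, not mechanisms.

## Pipeline

Stages communicate only through serialized artifacts (CSV/JSON) under
the run directory; each stage derives its sub-seed from the global seed
by stable hashing of the stage name, and the manifest records content
hashes, so deterministic artifacts reproduce bit for bit under the same
config and seed. The shipped `diatom2d` study calibrates (μ0, K_light)
with the other parameters held at their generating values — a
deliberate restriction: a trustworthy GP surrogate over the full 6-D
parameter space would need far more support points than a desk-scale
design provides, and the 2-D slice already exhibits the strong
μ0–K_light posterior correlation that makes coordinate-wise sampling
inefficient.

## Problem sizes

Default study sizes keep the whole test suite and the acceptance script
desk-scale: toy calibrations use 10,000-step chains (6 chains in the
acceptance script), surrogate builds use ~44 design points, the
structure-recovery study uses 10 replicates of 1e5 draws from a 5-node
model, and the synthetic diatom recovery uses one season of every-third
-day observations with an 800-step chain. These sizes are the package's
validation defaults; all of them are configuration entries.

## Known limitations

* The clipping-induced accuracy loss at silica exhaustion (above).
* The ℓ_ζ likelihood's averaged misfit makes the posterior "tempered"
  relative to an i.i.d. product likelihood — posterior widths depend on
  Nt only through the averaging; this follows the calibration
  construction used throughout and matters when comparing against
  fully Bayesian error models.
* GGM pruning assumes approximate multinormality of the (transformed)
  draws; heavy remaining skew biases deviances.
* The BN requires discretization; 10 bins × 3 parents is a coarse
  representation of continuous dependence.
* `estimate_noise` assumes a stationary timescale and near-Gaussian
  error; trends faster than the fitted length scale leak into the noise
  estimate.
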