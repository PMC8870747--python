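"""Metropolis-Hastings MCMC with positivity reflection, proposal tuning,
delayed acceptance, and convergence diagnostics.

Proposals are Gaussian and symmetric; positivity of parameters is kept
by flipping negative proposals into the positive range (reflection at
zero preserves proposal symmetry and hence detailed balance).  Updates
can be joint or coordinate-wise (Metropolis-within-Gibbs); per-parameter
proposal scales are adapted during a warmup phase toward a target
acceptance rate and frozen before sampling.

Delayed acceptance screens each proposal with a cheap surrogate
posterior first; only proposals surviving this stage trigger an
evaluation of the true posterior, whose acceptance ratio is corrected
by the inverse surrogate ratio so that the stationary distribution is
the exact posterior regardless of surrogate quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "Chain",
    "MCMCConfig",
    "mh_step",
    "tune_proposals",
    "run_mh",
    "delayed_acceptance_step",
    "gibbs_da_run",
    "gelman_rubin",
    "autocorr_length",
]

LogPost = Callable[[np.ndarray], float]


@dataclass
class MCMCConfig:
    """Sampler settings.

    ``n_chains``/``n_steps`` default to the full study scale (1000
    chains of 1000 iterations); individual runs typically override
    them.  Warmup consists of ``n_warmup_runs`` sequential adaptation
    rounds of ``warmup_steps`` iterations each, targeting
    ``target_acceptance`` (0.35) per coordinate; scales are frozen
    afterwards.
    """

    n_chains: int = 1000
    n_steps: int = 1000
    n_warmup_runs: int = 5
    warmup_steps: int = 500
    target_acceptance: float = 0.35
    thinning: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_steps", "n_warmup_runs", "warmup_steps", "thinning"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must be in (0, 1)")


@dataclass
class Chain:
    """One MCMC chain with acceptance and evaluation bookkeeping."""

    samples: np.ndarray                 # (n_kept, dim)
    log_post: np.ndarray                # (n_kept,)
    accepted: np.ndarray                # per-iteration acceptance fraction
    proposal_scales: np.ndarray
    seed: int | None = None
    n_full_evals: int = 0               # true-posterior evaluations
    n_stage1_pass: int = 0              # proposals surviving the surrogate stage
    n_proposals: int = 0                # total proposals considered
    coord_accept: np.ndarray | None = None  # per-coordinate acceptance rates

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))

    @property
    def full_eval_fraction(self) -> float:
        """Fraction of proposals that required a true-model evaluation
        (the surrogate stage-1 pass rate under delayed acceptance)."""
        return self.n_stage1_pass / max(self.n_proposals, 1)


def _propose(state, scales, rng, coord=None, reflect=True):
    prop = np.array(state, dtype=float, copy=True)
    if coord is None:
        prop += rng.normal(size=prop.shape) * scales
    else:
        prop[coord] += rng.normal() * scales[coord]
    if reflect:
        np.abs(prop, out=prop)
    return prop


def mh_step(
    state: np.ndarray,
    logp: float,
    log_post: LogPost,
    proposal_scales: np.ndarray,
    rng: np.random.Generator,
    coord: int | None = None,
    reflect: bool = True,
):
    """One Metropolis-Hastings update; returns (state, logp, accepted).

    ``coord`` restricts the proposal to a single coordinate
    (Metropolis-within-Gibbs sub-step).
    """
    if not np.isfinite(logp):
        raise ValueError("current state has non-finite log-posterior")
    prop = _propose(state, proposal_scales, rng, coord, reflect)
    lp_prop = log_post(prop)
    if np.log(rng.uniform()) < lp_prop - logp:
        return prop, lp_prop, True
    return np.asarray(state, dtype=float), logp, False


def tune_proposals(
    log_post: LogPost,
    theta0: np.ndarray,
    config: MCMCConfig,
    rng: np.random.Generator,
    init_scales: np.ndarray | None = None,
    reflect: bool = True,
) -> np.ndarray:
    """Adapt per-coordinate proposal scales over sequential warmup runs.

    Each run performs ``warmup_steps`` coordinate-cycled updates and
    rescales every coordinate's step by exp(1.5 * (acc - target)),
    a stochastic-approximation move toward the target acceptance.
    A final acceptance outside [0.2, 0.5] triggers a warning only.
    """
    theta = np.array(theta0, dtype=float, copy=True)
    dim = theta.size
    scales = (
        np.array(init_scales, dtype=float, copy=True)
        if init_scales is not None
        else 0.25 * (np.abs(theta) + 0.1)
    )
    logp = log_post(theta)
    if not np.isfinite(logp):
        raise ValueError("tuning start has non-finite log-posterior")
    acc = np.zeros(dim)
    for _ in range(config.n_warmup_runs):
        n_acc = np.zeros(dim)
        for _ in range(config.warmup_steps):
            for k in range(dim):
                theta, logp, ok = mh_step(
                    theta, logp, log_post, scales, rng, coord=k, reflect=reflect
                )
                n_acc[k] += ok
        acc = n_acc / config.warmup_steps
        scales *= np.exp(1.5 * (acc - config.target_acceptance))
    if np.any(acc < 0.2) or np.any(acc > 0.5):
        warnings.warn(
            f"warmup acceptance {np.round(acc, 3)} outside [0.2, 0.5] "
            f"after {config.n_warmup_runs} rounds",
            RuntimeWarning,
        )
    return scales


def _run_single_chain(
    log_post, theta0, scales, n_steps, thinning, rng, mode, reflect, seed
) -> Chain:
    theta = np.array(theta0, dtype=float, copy=True)
    dim = theta.size
    logp = log_post(theta)
    if not np.isfinite(logp):
        raise ValueError("chain start has non-finite log-posterior")
    kept_s, kept_lp, kept_acc = [], [], []
    n_evals = 0
    coord_acc = np.zeros(dim)
    for it in range(n_steps):
        if mode == "coordinate":
            acc_frac = 0.0
            for k in range(dim):
                theta, logp, ok = mh_step(
                    theta, logp, log_post, scales, rng, coord=k, reflect=reflect
                )
                n_evals += 1
                acc_frac += ok
                coord_acc[k] += ok
            acc_frac /= dim
        else:
            theta, logp, ok = mh_step(
                theta, logp, log_post, scales, rng, reflect=reflect
            )
            n_evals += 1
            acc_frac = float(ok)
        if (it + 1) % thinning == 0:
            kept_s.append(theta.copy())
            kept_lp.append(logp)
            kept_acc.append(acc_frac)
    accepted = np.array(kept_acc)
    if np.all(accepted == 0.0):
        raise RuntimeError("chain accepted no proposals; check scales/posterior")
    return Chain(
        samples=np.array(kept_s),
        log_post=np.array(kept_lp),
        accepted=accepted,
        proposal_scales=np.asarray(scales, dtype=float),
        seed=seed,
        n_full_evals=n_evals,
        n_stage1_pass=n_evals,
        n_proposals=n_evals,
        coord_accept=coord_acc / n_steps,
    )


def run_mh(
    log_post: LogPost,
    config: MCMCConfig,
    prior=None,
    init: np.ndarray | None = None,
    scales: np.ndarray | None = None,
    mode: str = "coordinate",
    reflect: bool = True,
) -> list[Chain]:
    """Run ``config.n_chains`` independent MH chains.

    Starts are drawn from ``prior.sample`` (randomized locations in
    parameter space) unless ``init`` is given.  If ``scales`` is None,
    each chain adapts its own proposal scales during warmup, frozen
    before the sampling phase.  Chains are independent and the result
    does not depend on evaluation order.
    """
    if prior is None and init is None:
        raise ValueError("provide a prior to draw starts from, or an explicit init")
    root = np.random.default_rng(config.seed)
    chains = []
    for c in range(config.n_chains):
        sub = int(root.integers(2**31 - 1))
        rng = np.random.default_rng(sub)
        theta0 = (
            np.array(init, dtype=float, copy=True)
            if init is not None
            else prior.sample(1, rng)[0]
        )
        s = scales
        if s is None:
            s = tune_proposals(log_post, theta0, config, rng, reflect=reflect)
        chains.append(
            _run_single_chain(
                log_post, theta0, s, config.n_steps, config.thinning,
                rng, mode, reflect, sub,
            )
        )
    return chains


def delayed_acceptance_step(
    state: np.ndarray,
    lp_true: float,
    lp_surr: float,
    log_post_true: LogPost,
    log_post_surr: LogPost,
    proposal_scales: np.ndarray,
    rng: np.random.Generator,
    coord: int | None = None,
    reflect: bool = True,
):
    """Two-stage Metropolis-Hastings update.

    Stage 1 applies the usual acceptance test with the surrogate
    posterior (the symmetric-proposal ratio); survivors enter stage 2
    with acceptance probability

        min(1, [p(prop)/p(state)] * [p~(state)/p~(prop)]),

    so the exact posterior is the stationary distribution.  Returns
    ``(state, lp_true, lp_surr, accepted, full_eval)`` where
    ``full_eval`` flags a true-posterior evaluation (stage-1 survival).
    """
    if not np.isfinite(lp_surr):
        raise ValueError("current state has non-finite surrogate log-posterior")
    prop = _propose(state, proposal_scales, rng, coord, reflect)
    lp_surr_prop = log_post_surr(prop)
    # stage 1: surrogate screening
    if np.log(rng.uniform()) >= lp_surr_prop - lp_surr:
        return np.asarray(state, dtype=float), lp_true, lp_surr, False, False
    # stage 2: exact correction
    lp_true_prop = log_post_true(prop)
    log_ratio = (lp_true_prop - lp_true) - (lp_surr_prop - lp_surr)
    if np.log(rng.uniform()) < log_ratio:
        return prop, lp_true_prop, lp_surr_prop, True, True
    return np.asarray(state, dtype=float), lp_true, lp_surr, False, True


def gibbs_da_run(
    log_post_true: LogPost,
    log_post_surr: LogPost,
    config: MCMCConfig,
    init: np.ndarray,
    scales: np.ndarray | None = None,
    reflect: bool = True,
    mode: str = "coordinate",
) -> Chain:
    """Delayed-acceptance MCMC with coordinate-wise (Gibbs-style) updates.

    Proposal scales are tuned on the surrogate posterior (cheap) when
    not supplied.  One iteration cycles through all coordinates; on 1-D
    problems this reduces to plain delayed acceptance.  The auxiliary
    norm-order coordinate of a hierarchical likelihood is just an extra
    coordinate of ``init``.
    """
    rng = np.random.default_rng(config.seed)
    theta = np.array(init, dtype=float, copy=True)
    dim = theta.size
    if scales is None:
        scales = tune_proposals(log_post_surr, theta, config, rng, reflect=reflect)
    lp_surr = log_post_surr(theta)
    lp_true = log_post_true(theta)
    n_full = 1  # the initial state evaluation
    n_pass = 0
    n_prop = 0
    kept_s, kept_lp, kept_acc = [], [], []
    coords = range(dim) if mode == "coordinate" else (None,)
    for it in range(config.n_steps):
        acc = 0.0
        for k in coords:
            theta, lp_true, lp_surr, ok, full = delayed_acceptance_step(
                theta, lp_true, lp_surr, log_post_true, log_post_surr,
                scales, rng, coord=k, reflect=reflect,
            )
            n_prop += 1
            n_pass += full
            n_full += full
            acc += ok
        acc /= len(list(coords)) if mode == "coordinate" else 1
        if (it + 1) % config.thinning == 0:
            kept_s.append(theta.copy())
            kept_lp.append(lp_true)
            kept_acc.append(acc)
    return Chain(
        samples=np.array(kept_s),
        log_post=np.array(kept_lp),
        accepted=np.array(kept_acc),
        proposal_scales=np.asarray(scales, dtype=float),
        seed=config.seed,
        n_full_evals=n_full,
        n_stage1_pass=n_pass,
        n_proposals=n_prop,
    )


# --------------------------------------------------------------------------
# diagnostics


def gelman_rubin(chains) -> np.ndarray:
    """Potential scale reduction factor R per dimension.

    ``chains`` is a sequence of equally long (n, dim) sample arrays (or
    Chain objects); requires at least two chains.
    """
    arrs = [c.samples if isinstance(c, Chain) else np.asarray(c, float) for c in chains]
    if len(arrs) < 2:
        raise ValueError("need at least two chains")
    arrs = [a.reshape(len(a), -1) for a in arrs]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("chains must have equal lengths")
    x = np.stack(arrs)                       # (m, n, dim)
    means = x.mean(axis=1)                   # (m, dim)
    w = x.var(axis=1, ddof=1).mean(axis=0)   # within-chain variance
    b = n * means.var(axis=0, ddof=1)        # between-chain variance * n
    var_hat = (n - 1) / n * w + b / n
    return np.sqrt(var_hat / w)


def autocorr_length(chain_1d, max_lag: int | None = None) -> float:
    """Integrated autocorrelation time by initial-positive-sequence windowing.

    Sums tau = -1 + 2 * sum_m Gamma_m over pairwise sums
    Gamma_m = rho(2m) + rho(2m+1) of the empirical autocorrelation,
    truncated before the first non-positive pair (Geyer's initial
    positive sequence).  White noise gives ~1; an AR(1) process with
    coefficient rho gives (1+rho)/(1-rho).
    """
    x = np.asarray(chain_1d, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 samples")
    x = x - x.mean()
    var = np.dot(x, x)
    if var <= 0 or np.ptp(x) == 0:
        raise ValueError("autocorrelation time undefined for a constant chain")
    nfft = 1 << int(2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    acf /= acf[0]
    upper = n if max_lag is None else min(n, max_lag)
    tau = -1.0
    m = 0
    while 2 * m + 1 < upper:
        gamma = acf[2 * m] + acf[2 * m + 1]
        if gamma <= 0:
            break
        tau += 2.0 * gamma
        m += 1
    return max(tau, 1.0)
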