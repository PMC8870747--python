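"""Priors, cost functions and likelihoods.

Two noise models are available and can be combined with either a
truncated-Cauchy prior on the positive half-line or a flat box prior:

* the Gaussian cost function

      J(theta) = 1/(2 Nt) * sum_i (f_i - d_i)^2 / sigma_chl^2
                 - sum_k log p(theta_k),

  used directly as the negative log-posterior, and

* the hierarchical fractional-norm (l_zeta) likelihood

      log p(d | theta, zeta) = -l(d; theta, zeta)
                               - log(2 * (2 sigma) * Gamma(1 + 1/zeta)),
      l(d; theta, zeta) = 1/Nt * sum_i |(f_i - d_i) / (2 sigma)|^zeta,

  which interpolates Gaussian (zeta = 2) and Laplacian (zeta = 1)
  noise; zeta may be held fixed or sampled with a truncated Gaussian
  prior (mean 2, sd 0.5).

Note both constructions average the misfit over the Nt observations, so
the data term carries the same weight regardless of series length; the
normalization constant of the l_zeta likelihood is added once per
evaluation.  The two residual scalings (sigma_chl vs 2*sigma) differ by
a constant factor at zeta = 2; both are kept exactly as defined and are
selected by which entry point is used.

The truncated-Cauchy prior for parameter k is

    p(theta_k) = (2/pi) * b_k / (b_k^2 + theta_k^2),  theta_k >= 0,

with the scale b_k fixed by requiring the CDF to reach P* (default 0.9)
at a stated plausibility bound theta_k*:  b = theta* / tan(pi P* / 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln, ndtr

__all__ = [
    "PriorSpec",
    "BoxPrior",
    "LikelihoodSpec",
    "TABLE1_THETA_STAR",
    "cauchy_scale",
    "log_prior",
    "truncated_cauchy_cdf",
    "cost_function",
    "lq_loss",
    "log_likelihood",
    "log_zeta_prior",
    "make_log_posterior",
    "make_cost_log_posterior",
]

#: Plausibility bounds theta* for (mu0, lambda_s, k_light, f_si, sigma0, a):
#: values a calibrated parameter should exceed only with probability 1 - P*.
TABLE1_THETA_STAR = (3.5, 0.05, 500.0, 0.4, 2.0, 2.0)


def cauchy_scale(theta_star, p_star: float = 0.9):
    """Scale b of the truncated Cauchy prior: b = theta* / tan(pi P*/2).

    Solves CDF(theta*) = P* for the half-line Cauchy density
    (2/pi) b / (b^2 + theta^2), whose CDF is (2/pi) arctan(theta/b).
    """
    if not 0.0 < p_star < 1.0:
        raise ValueError("p_star must lie strictly between 0 and 1")
    theta_star = np.asarray(theta_star, dtype=float)
    if np.any(theta_star <= 0):
        raise ValueError("theta_star must be positive")
    out = theta_star / np.tan(np.pi * p_star / 2.0)
    return out if out.ndim else float(out)


def truncated_cauchy_cdf(theta, b):
    """CDF of the positive-half-line Cauchy prior: (2/pi) arctan(theta/b)."""
    theta = np.asarray(theta, dtype=float)
    out = np.where(theta < 0, 0.0, (2.0 / np.pi) * np.arctan(theta / b))
    return out if out.ndim else float(out)


@dataclass
class PriorSpec:
    """Independent truncated-Cauchy priors for the calibrated parameters."""

    theta_star: Sequence[float] = TABLE1_THETA_STAR
    p_star: float = 0.9
    names: Sequence[str] = ("mu0", "lambda_s", "k_light", "f_si", "sigma0", "a")

    def __post_init__(self) -> None:
        self.theta_star = np.asarray(self.theta_star, dtype=float)
        self.b = np.asarray(cauchy_scale(self.theta_star, self.p_star))

    @property
    def dim(self) -> int:
        return len(self.theta_star)

    def log_pdf(self, theta) -> float:
        theta = np.asarray(theta, dtype=float)
        if np.any(theta < 0):
            return -np.inf
        return float(
            np.sum(np.log(2.0 / np.pi) + np.log(self.b) - np.log(self.b**2 + theta**2))
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draws from the truncated prior via inverse CDF."""
        u = rng.uniform(0.0, 1.0, size=(n, self.dim))
        return self.b * np.tan(np.pi * u / 2.0)


@dataclass
class BoxPrior:
    """Flat prior on an axis-aligned box (used for the toy problem)."""

    bounds: Sequence[tuple] = ((0.0, 2.0), (0.0, 2.0))

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        if np.any(self.bounds[:, 1] <= self.bounds[:, 0]):
            raise ValueError("upper bounds must exceed lower bounds")
        self._log_vol = float(np.sum(np.log(self.bounds[:, 1] - self.bounds[:, 0])))

    @property
    def dim(self) -> int:
        return len(self.bounds)

    def log_pdf(self, theta) -> float:
        theta = np.asarray(theta, dtype=float)
        inside = np.all((theta >= self.bounds[:, 0]) & (theta <= self.bounds[:, 1]))
        return -self._log_vol if inside else -np.inf

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.bounds[:, 0], self.bounds[:, 1], size=(n, self.dim))


def log_prior(theta, prior_spec) -> float:
    """Joint log prior density; -inf outside the support."""
    return prior_spec.log_pdf(theta)


def cost_function(theta, f, d, sigma_chl: float, prior_spec) -> float:
    """Gaussian calibration cost J = data misfit + negative log prior.

    Serves as the negative log-posterior of the Gaussian error model.
    """
    f = np.asarray(f, dtype=float)
    d = np.asarray(d, dtype=float)
    if f.shape != d.shape:
        raise ValueError(f"model/data length mismatch: {f.shape} vs {d.shape}")
    if sigma_chl <= 0:
        raise ValueError("sigma_chl must be positive")
    nt = len(f)
    data_term = float(np.sum((f - d) ** 2)) / (2.0 * nt * sigma_chl**2)
    return data_term - prior_spec.log_pdf(theta)


def lq_loss(d, f, sigma: float, zeta: float) -> float:
    """Averaged fractional-norm misfit l = 1/Nt * sum |(f-d)/(2 sigma)|^zeta."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    f = np.asarray(f, dtype=float)
    if f.shape != d.shape:
        raise ValueError("model/data length mismatch")
    return float(np.mean(np.abs((f - d) / (2.0 * sigma)) ** zeta))


@dataclass
class LikelihoodSpec:
    """Scale and norm order of the l_zeta noise model.

    ``zeta_free`` makes zeta an extra sampled coordinate with a
    truncated Gaussian prior (mean ``zeta_prior_mean``, sd
    ``zeta_prior_sd``, restricted to zeta > 0).
    """

    sigma: float = 0.05
    zeta: float = 2.0
    zeta_free: bool = False
    zeta_prior_mean: float = 2.0
    zeta_prior_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.zeta <= 0:
            raise ValueError("sigma and zeta must be positive")


def log_likelihood(d, f, like_spec: LikelihoodSpec, zeta: float | None = None) -> float:
    """log p(d | theta, zeta) = -l - log(2 * (2 sigma) * Gamma(1 + 1/zeta))."""
    z = like_spec.zeta if zeta is None else float(zeta)
    if z <= 0:
        return -np.inf
    loss = lq_loss(d, f, like_spec.sigma, z)
    log_norm = np.log(2.0 * 2.0 * like_spec.sigma) + gammaln(1.0 + 1.0 / z)
    return -loss - float(log_norm)


def log_zeta_prior(zeta: float, like_spec: LikelihoodSpec) -> float:
    """Truncated Gaussian log prior for the norm order zeta (> 0)."""
    if zeta <= 0:
        return -np.inf
    m, s = like_spec.zeta_prior_mean, like_spec.zeta_prior_sd
    z = (zeta - m) / s
    log_trunc = np.log(ndtr(m / s))  # mass retained on (0, inf)
    return float(-0.5 * z**2 - np.log(s * np.sqrt(2 * np.pi)) - log_trunc)


def make_log_posterior(
    forward: Callable[[np.ndarray], np.ndarray],
    d,
    like_spec: LikelihoodSpec,
    prior,
) -> Callable[[np.ndarray], float]:
    """Log posterior with the l_zeta likelihood.

    The returned callable takes the parameter vector; when
    ``like_spec.zeta_free`` the last coordinate is zeta and the model
    parameters are the leading ones.
    """
    d = np.asarray(d, dtype=float)

    def log_post(theta_full: np.ndarray) -> float:
        theta_full = np.asarray(theta_full, dtype=float)
        if like_spec.zeta_free:
            theta, zeta = theta_full[:-1], float(theta_full[-1])
            lp = prior.log_pdf(theta) + log_zeta_prior(zeta, like_spec)
        else:
            theta, zeta = theta_full, like_spec.zeta
            lp = prior.log_pdf(theta)
        if not np.isfinite(lp):
            return -np.inf
        f = forward(theta)
        return log_likelihood(d, f, like_spec, zeta) + lp

    return log_post


def make_cost_log_posterior(
    forward: Callable[[np.ndarray], np.ndarray],
    d,
    sigma_chl: float,
    prior_spec,
) -> Callable[[np.ndarray], float]:
    """Log posterior as the negative Gaussian cost, log p = -J(theta)."""
    d = np.asarray(d, dtype=float)

    def log_post(theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if not np.isfinite(prior_spec.log_pdf(theta)):
            return -np.inf
        f = forward(theta)
        return -cost_function(theta, f, d, sigma_chl, prior_spec)

    return log_post
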