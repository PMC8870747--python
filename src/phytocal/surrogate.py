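"""Gaussian-process surrogates with Karhunen-Loeve output reduction.

Components:

* GP regression (Matern-5/2 or squared-exponential kernel, optional
  linear mean model, maximum-likelihood hyperparameters) via
  scikit-learn, exposed with the textbook predictive equations
  (latent-function mean and variance, noise separated out);
* maximum-likelihood noise estimation for a time series, the procedure
  that sets the observational scale sigma of the calibration;
* expected improvement and Bayesian global optimization of a scalar
  cost over a box, seeded by a Sobol space-filling design;
* Karhunen-Loeve (functional PCA) expansion of an ensemble of output
  curves via the N x N collocation matrix of pairwise inner products,
  A_ij = <f_i, f_j> with <u, v> = 1/Nt * sum_k u(t_k) v(t_k);
* the assembled function-valued surrogate: one GP per retained KL
  weight, predictions recombined as f~(t; x) = mean(t) + sum_k
  z~_k(x) phi_k(t), substituted into the *exact* likelihood and prior
  so auxiliary likelihood parameters (the norm order) stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import zeta as riemann_zeta
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, Matern, WhiteKernel

from .inference import LikelihoodSpec, log_likelihood, log_zeta_prior

__all__ = [
    "GPModel",
    "KLBasis",
    "FunctionSurrogate",
    "TruncationDiagnostics",
    "gp_fit",
    "gp_predict",
    "estimate_noise",
    "expected_improvement",
    "bayes_optimize",
    "kl_expand",
    "truncation_error",
    "build_function_surrogate",
    "surrogate_log_posterior",
]


@dataclass
class GPModel:
    """A fitted GP regressor plus its (optional) linear mean model."""

    gpr: GaussianProcessRegressor
    mean_coef: np.ndarray       # (d+1,): intercept then slopes; zeros if no mean model
    X: np.ndarray
    y: np.ndarray
    kernel_family: str

    def _mean(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.mean_coef[0] + X @ self.mean_coef[1:]

    @property
    def noise_var(self) -> float:
        return float(self.gpr.kernel_.k2.noise_level)

    @property
    def signal_var(self) -> float:
        return float(self.gpr.kernel_.k1.k1.constant_value)

    @property
    def length_scale(self) -> np.ndarray:
        return np.atleast_1d(self.gpr.kernel_.k1.k2.length_scale)

    def log_marginal_likelihood(self) -> float:
        return float(self.gpr.log_marginal_likelihood())

    def predict(self, X_star):
        return gp_predict(self, X_star)


def _make_kernel(kernel_family: str, dim: int, y_var: float, span: np.ndarray):
    ls0 = np.maximum(0.3 * span, 1e-3)
    ls_bounds = (1e-3, 1e4)
    amp = ConstantKernel(max(y_var, 1e-6), (1e-8, 1e6))
    if kernel_family == "matern52":
        base = Matern(length_scale=ls0, length_scale_bounds=ls_bounds, nu=2.5)
    elif kernel_family in ("rbf", "sqexp"):
        base = RBF(length_scale=ls0, length_scale_bounds=ls_bounds)
    else:
        raise ValueError(f"unknown kernel family {kernel_family!r}")
    noise = WhiteKernel(
        noise_level=max(y_var, 1e-6) * 1e-2, noise_level_bounds=(1e-12, 1e6)
    )
    return amp * base + noise


def gp_fit(
    X,
    y,
    kernel_family: str = "matern52",
    mean_model: str | None = "linear",
    n_restarts: int = 3,
    seed: int = 0,
) -> GPModel:
    """Fit a GP with maximum-likelihood hyperparameters.

    A linear trend (ordinary least squares) is fitted first and
    subtracted; the GP models the residuals, and predictions add the
    trend back.  Hyperparameter optimization uses multi-start L-BFGS
    (``n_restarts`` extra random starts, deterministic under ``seed``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < X.shape[1] and X.shape[0] == 1:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if n < 3:
        raise ValueError("need at least 3 training points")
    if len(y) != n:
        raise ValueError("X and y lengths differ")
    if mean_model == "linear":
        design = np.column_stack([np.ones(n), X])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    elif mean_model in (None, "zero"):
        coef = np.zeros(d + 1)
    elif mean_model == "constant":
        coef = np.concatenate([[y.mean()], np.zeros(d)])
    else:
        raise ValueError(f"unknown mean model {mean_model!r}")
    resid = y - (coef[0] + X @ coef[1:])
    span = X.max(axis=0) - X.min(axis=0)
    kernel = _make_kernel(kernel_family, d, float(resid.var()) or 1.0, span)
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        alpha=1e-10,
        normalize_y=False,
        n_restarts_optimizer=n_restarts,
        random_state=seed,
    )
    gpr.fit(X, resid)
    return GPModel(gpr=gpr, mean_coef=coef, X=X, y=y, kernel_family=kernel_family)


def gp_predict(model: GPModel, x_star):
    """Predictive mean and latent-function variance at ``x_star``.

    Implements f_bar = m(x*) + K*(K + sigma_n^2 I)^-1 (y - m(X)) and
    var = K** - K*(K + sigma_n^2 I)^-1 K*^T; the estimated observation
    noise is excluded from the predictive variance, and tiny negative
    floating-point residues are clipped to zero.
    """
    x_star = np.atleast_2d(np.asarray(x_star, dtype=float))
    mu_gp, sd = model.gpr.predict(x_star, return_std=True)
    # scikit-learn's variance includes the fitted WhiteKernel level
    var = np.maximum(sd**2 - model.noise_var, 0.0)
    mean = mu_gp + model._mean(x_star)
    return mean, var


def estimate_noise(t, d, n_restarts: int = 5, seed: int = 0) -> float:
    """Maximum-likelihood observation noise of a time series.

    Fits a squared-exponential GP with free timescale and free noise
    level to the series; the returned sigma_n is the ML noise standard
    deviation of the decomposition "kernel-smoothed signal + white
    noise".  This is the procedure that sets the observational error
    scale of the calibration from the data alone.
    """
    t = np.asarray(t, dtype=float).reshape(-1, 1)
    d = np.asarray(d, dtype=float).ravel()
    if len(t) < 20:
        raise ValueError("need at least 20 points to estimate noise")
    y0 = d - d.mean()
    span = float(t.max() - t.min())
    dt = float(np.min(np.diff(np.sort(t.ravel())))) or span / len(t)
    kernel = ConstantKernel(y0.var() or 1.0, (1e-8, 1e8)) * RBF(
        length_scale=span / 10, length_scale_bounds=(dt, 10 * span)
    ) + WhiteKernel(noise_level=(y0.var() or 1.0) * 0.1, noise_level_bounds=(1e-12, 1e8))
    gpr = GaussianProcessRegressor(
        kernel=kernel, alpha=1e-12, n_restarts_optimizer=n_restarts, random_state=seed
    )
    gpr.fit(t, y0)
    if not np.isfinite(gpr.log_marginal_likelihood()):
        raise RuntimeError("noise estimation failed: non-finite marginal likelihood")
    return float(np.sqrt(gpr.kernel_.k2.noise_level))


def expected_improvement(model: GPModel, x_star, f_best: float) -> np.ndarray:
    """Closed-form expected improvement for *minimization* of a cost.

    EI = delta * Phi(delta/s) + s * phi(delta/s), with improvement
    delta = f_best - f_bar(x*) over the incumbent and s the posterior
    standard deviation; for s = 0 this degenerates to max(delta, 0).
    """
    mean, var = gp_predict(model, x_star)
    s = np.sqrt(var)
    delta = f_best - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(s > 0, delta / np.where(s > 0, s, 1.0), 0.0)
    ei = np.where(
        s > 0,
        delta * norm.cdf(u) + s * norm.pdf(u),
        np.maximum(delta, 0.0),
    )
    return np.maximum(ei, 0.0)


def bayes_optimize(
    objective: Callable[[np.ndarray], float],
    bounds,
    n_init: int = 16,
    n_iter: int = 15,
    seed: int = 0,
    n_candidates: int = 2048,
):
    """Bayesian global optimization of a scalar cost over a box.

    Starts from a Sobol space-filling design of ``n_init`` points over
    the whole box (the prior range), then acquires ``n_iter`` further
    points by maximizing expected improvement of a direct GP surrogate
    of the cost over a fresh Sobol candidate set each iteration.

    Returns ``(x_best, X, y)`` with every evaluated point; the full
    evaluated set can seed the training design of a function-valued
    surrogate.
    """
    bounds = np.asarray(bounds, dtype=float)
    d = len(bounds)
    sob = qmc.Sobol(d, scramble=True, seed=seed)
    X = qmc.scale(sob.random(n_init), bounds[:, 0], bounds[:, 1])
    y = np.array([float(objective(x)) for x in X])
    finite = np.isfinite(y)
    if finite.sum() < 0.5 * n_init:
        raise RuntimeError(
            f"objective non-finite at {n_init - finite.sum()}/{n_init} design points"
        )
    for it in range(n_iter):
        model = gp_fit(
            X[finite], y[finite], kernel_family="matern52", mean_model="linear",
            n_restarts=2, seed=seed + it + 1,
        )
        f_best = float(y[finite].min())
        cand = qmc.scale(sob.random(n_candidates), bounds[:, 0], bounds[:, 1])
        ei = expected_improvement(model, cand, f_best)
        x_new = cand[int(np.argmax(ei))]
        y_new = float(objective(x_new))
        X = np.vstack([X, x_new])
        y = np.append(y, y_new)
        finite = np.append(finite, np.isfinite(y_new))
    best = int(np.nanargmin(np.where(finite, y, np.nan)))
    return X[best], X, y


# --------------------------------------------------------------------------
# Karhunen-Loeve expansion


@dataclass
class KLBasis:
    """Orthonormal output basis from an ensemble of curves.

    ``eigenvalues`` is the full descending spectrum of the collocation
    matrix; ``basis`` holds the first ``rank`` basis functions (rows),
    orthonormal under the 1/Nt-weighted discrete inner product;
    ``mean`` is the ensemble mean restored on reconstruction.
    """

    eigenvalues: np.ndarray     # (N,), descending, >= 0
    basis: np.ndarray           # (rank, Nt)
    mean: np.ndarray            # (Nt,)
    rank: int

    def project(self, curves) -> np.ndarray:
        """KL weights z_k = <f - mean, phi_k>; returns (n, rank)."""
        f = np.atleast_2d(np.asarray(curves, dtype=float)) - self.mean
        return f @ self.basis.T / self.basis.shape[1]

    def reconstruct(self, weights) -> np.ndarray:
        weights = np.atleast_2d(np.asarray(weights, dtype=float))
        return self.mean + weights @ self.basis


def kl_expand(
    snapshots,
    rank: int | None = None,
    tol: float = 1e-4,
    center: bool = True,
):
    """Karhunen-Loeve expansion of N output curves on a common grid.

    Builds the collocation matrix A_ij = <f_i, f_j> (1/Nt-weighted
    inner product), eigendecomposes it, and assembles orthonormal basis
    functions from snapshot combinations.  Truncation keeps ``rank``
    components if given, otherwise all components with
    lambda_k / lambda_1 >= ``tol``; null eigenvalues are always
    dropped.  Returns ``(KLBasis, Z)`` where ``Z[i, k]`` is the weight
    of snapshot i on component k.
    """
    F = np.atleast_2d(np.asarray(snapshots, dtype=float))
    n, nt = F.shape
    if n < 2:
        raise ValueError("need at least 2 snapshots")
    mean = F.mean(axis=0) if center else np.zeros(nt)
    Fc = F - mean
    A = Fc @ Fc.T / nt
    lam, V = np.linalg.eigh(A)
    lam = lam[::-1]
    V = V[:, ::-1]
    lam = np.maximum(lam, 0.0)
    lam1 = lam[0] if lam[0] > 0 else 1.0
    positive = lam > max(1e-14 * lam1, 0.0)
    if rank is None:
        keep = (lam / lam1 >= tol) & positive
        r = max(int(keep.sum()), 1)
    else:
        r = min(int(rank), int(positive.sum()))
        r = max(r, 1)
    basis = (Fc.T @ V[:, :r] / np.sqrt(lam[:r])).T     # (r, Nt)
    kl = KLBasis(eigenvalues=lam, basis=basis, mean=mean, rank=r)
    Z = np.sqrt(lam[:r]) * V[:, :r]                    # z_k(x_i) = <f_i, phi_k>
    return kl, Z


@dataclass
class TruncationDiagnostics:
    """Tail-error diagnostics of a truncated eigenspectrum."""

    tail_sum: float             # sum_{k>r} lambda_k (exact)
    crude_bound: float          # (N - r) * lambda_r
    alpha: float                # fitted spectral decay exponent
    refined: float              # lambda_r * zeta(alpha); inf if divergent
    divergent: bool             # True when alpha <= 1


def truncation_error(eigenvalues, r: int) -> TruncationDiagnostics:
    """Truncation-error bound and spectral-decay diagnostics at rank r.

    The exact tail sum bounds the relative squared reconstruction
    error; the crude bound (N - r) * lambda_r ignores decay; assuming
    lambda_k ~ k**(-alpha) (alpha fitted by log-log regression of the
    spectrum), the refined estimate is lambda_r * zeta(alpha) with the
    Riemann zeta function, divergent for alpha <= 1.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    scale = max(abs(lam[0]) if len(lam) else 1.0, 1.0)
    if np.any(lam < -1e-12 * scale) or np.any(np.diff(lam) > 1e-9 * scale):
        raise ValueError("eigenvalues must be non-negative and descending")
    lam = np.maximum(lam, 0.0)
    n = len(lam)
    if not 1 <= r <= n:
        raise ValueError("rank r out of range")
    tail = float(lam[r:].sum())
    crude = float((n - r) * lam[r - 1])
    pos = lam > max(lam[0], 1e-300) * 1e-14
    k = np.arange(1, n + 1)[pos]
    if pos.sum() >= 3:
        slope, _ = np.polyfit(np.log(k), np.log(lam[pos]), 1)
        alpha = float(-slope)
    else:
        alpha = np.inf
    divergent = alpha <= 1.0
    refined = np.inf if divergent else float(lam[r - 1] * riemann_zeta(alpha))
    return TruncationDiagnostics(
        tail_sum=tail, crude_bound=crude, alpha=alpha,
        refined=refined, divergent=divergent,
    )


@dataclass
class FunctionSurrogate:
    """KL basis plus one GP per retained weight: x -> full output curve."""

    kl: KLBasis
    gps: list
    train_X: np.ndarray

    def _compile(self):
        """Cache per-component kernel data for fast mean prediction.

        All component GPs share the training inputs, so the predictive
        means reduce to one distance computation plus per-component
        Matern-5/2 evaluations; equals gp_predict's mean to float
        precision.
        """
        self._ls = np.stack([g.length_scale * np.ones(self.train_X.shape[1])
                             for g in self.gps])              # (r, d)
        self._sig = np.array([g.signal_var for g in self.gps])
        self._alpha = np.stack([g.gpr.alpha_.ravel() for g in self.gps])  # (r, n)
        self._mean_coef = np.stack([g.mean_coef for g in self.gps])       # (r, d+1)
        self._compiled = True

    def predict_weights(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if not getattr(self, "_compiled", False):
            self._compile()
        out = np.empty((len(x), len(self.gps)))
        diff = x[:, None, :] - self.train_X[None, :, :]       # (m, n, d)
        for k in range(len(self.gps)):
            r = np.sqrt(np.sum((diff / self._ls[k]) ** 2, axis=-1))  # (m, n)
            sr5 = np.sqrt(5.0) * r
            kern = self._sig[k] * (1.0 + sr5 + sr5**2 / 3.0) * np.exp(-sr5)
            out[:, k] = kern @ self._alpha[k] + (
                self._mean_coef[k, 0] + x @ self._mean_coef[k, 1:]
            )
        return out

    def predict(self, x) -> np.ndarray:
        """Surrogate output curve(s) f~(t; x) = mean + sum z~_k(x) phi_k."""
        z = self.predict_weights(x)
        out = self.kl.reconstruct(z)
        return out[0] if np.asarray(x).ndim == 1 else out


def build_function_surrogate(
    train_X,
    snapshots,
    rank: int | None = None,
    tol: float = 1e-4,
    seed: int = 0,
) -> FunctionSurrogate:
    """Train the function-valued surrogate on design points and outputs.

    One Matern-5/2 GP with a linear mean model is fitted per retained
    KL weight z_k(x).
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    kl, Z = kl_expand(snapshots, rank=rank, tol=tol)
    gps = []
    for k in range(kl.rank):
        try:
            gps.append(
                gp_fit(
                    train_X, Z[:, k], kernel_family="matern52",
                    mean_model="linear", n_restarts=2, seed=seed + k,
                )
            )
        except Exception as err:  # pragma: no cover - defensive tagging
            raise RuntimeError(f"GP fit failed for KL component {k}") from err
    return FunctionSurrogate(kl=kl, gps=gps, train_X=train_X)


def surrogate_log_posterior(
    fsurr: FunctionSurrogate,
    d,
    like_spec: LikelihoodSpec,
    prior,
) -> Callable[[np.ndarray], float]:
    """Surrogate posterior: surrogate curve in the exact likelihood.

    The surrogate replaces only the forward model f(theta); the
    likelihood, the prior, and the dependence on the norm order zeta
    (last coordinate when ``like_spec.zeta_free``) remain exact.
    """
    d = np.asarray(d, dtype=float)

    def log_post(theta_full: np.ndarray) -> float:
        theta_full = np.asarray(theta_full, dtype=float)
        if like_spec.zeta_free:
            theta, z = theta_full[:-1], float(theta_full[-1])
            lp = prior.log_pdf(theta) + log_zeta_prior(z, like_spec)
        else:
            theta, z = theta_full, like_spec.zeta
            lp = prior.log_pdf(theta)
        if not np.isfinite(lp):
            return -np.inf
        f = fsurr.predict(theta)
        return log_likelihood(d, f, like_spec, z) + lp

    return log_post
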